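"""Association of estimated cell-mixture proportions with subject metadata.

For each candidate number of cell types K, each estimated proportion
column is regressed on the covariate with a logit-link quasi-binomial
model (dispersion from Pearson residuals, Wald inference).  The global
minimum p over all components and all K is the observed statistic; its
null distribution is obtained by permuting the covariate against the
fixed estimated proportions — deconvolution never sees the covariate, so
its output is permutation-invariant and is not re-run.  The permutation
p-value uses the add-one formula, bounded below by 1/(B + 1).

The quasi-binomial IRLS here is deliberately hand-vectorised across
permutation columns (two-parameter closed-form weighted least squares per
column) so thousands of permutations cost a few matrix operations; its
agreement with the statsmodels GLM quasi-binomial fit is verified in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, SampleSheet, ValidationError
from .deconvolution import ReferenceFreeMixture
from .preprocess import select_most_variable

logger = logging.getLogger(__name__)

_MU_EPS = 1e-10
_DISPERSION_FLOOR = 1e-10


def _qb_wald_p(y: np.ndarray, X: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Wald p for the slope of logit-link quasi-binomial fits.

    ``y`` is one proportion vector (n,), ``X`` holds one covariate per
    column (n, B); a p-value is returned for every column.  Degenerate
    fits (constant response or covariate) return p = 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, B = X.shape
    if np.ptp(y) == 0:
        return np.ones(B)
    ybar = np.clip(y.mean(), _MU_EPS, 1 - _MU_EPS)
    b0 = np.full(B, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(B)
    yc = y[:, None]
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + X * b1[None, :], -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        wz = w * eta + (yc - mu)      # w * working response
        S0 = w.sum(axis=0)
        S1 = (w * X).sum(axis=0)
        S2 = (w * X * X).sum(axis=0)
        T0 = wz.sum(axis=0)
        T1 = (wz * X).sum(axis=0)
        det = S0 * S2 - S1 * S1
        ok = det > 1e-12 * np.maximum(S0 * S2, 1e-300)
        new_b0 = np.where(ok, (S2 * T0 - S1 * T1) / np.where(ok, det, 1.0), b0)
        new_b1 = np.where(ok, (S0 * T1 - S1 * T0) / np.where(ok, det, 1.0), b1)
        shift = np.max(np.abs(new_b1 - b1)) if B else 0.0
        b0, b1 = new_b0, new_b1
        if shift < 1e-10:
            break
    eta = np.clip(b0[None, :] + X * b1[None, :], -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    pearson = (yc - mu) ** 2 / np.maximum(w, _MU_EPS)
    phi = np.maximum(pearson.sum(axis=0) / (n - 2), _DISPERSION_FLOOR)
    S0 = w.sum(axis=0)
    S1 = (w * X).sum(axis=0)
    S2 = (w * X * X).sum(axis=0)
    det = S0 * S2 - S1 * S1
    ok = det > 1e-12 * np.maximum(S0 * S2, 1e-300)
    var_b1 = np.where(ok, phi * S0 / np.where(ok, det, 1.0), np.inf)
    t = b1 / np.sqrt(var_b1)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(ok, np.clip(p, 0.0, 1.0), 1.0)


def quasibinomial_p(omega_k, covariate) -> float:
    """Wald p-value for a single proportion-vs-covariate regression.

    Fits omega ~ logistic(b0 + b1 * covariate) with quasi-binomial
    variance (phi * mu * (1 - mu)); returns the two-sided Wald p for b1
    on n - 2 degrees of freedom.  Constant proportions or covariates give
    p = 1 by convention.
    """
    y = np.asarray(omega_k, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValidationError("proportions must lie in [0, 1]")
    if len(y) != len(x):
        raise ValidationError("omega and covariate lengths differ")
    if len(y) < 5:
        raise ValidationError("need at least 5 observations")
    if np.ptp(x) == 0:
        return 1.0
    return float(_qb_wald_p(y, x[:, None])[0])


@dataclass
class MixturePermutationResult:
    """Min-P permutation test of mixture proportions vs one covariate."""

    covariate_name: str
    k_grid: list[int]
    observed_min_p: float
    perm_min_p: np.ndarray
    p_perm: float
    B: int
    seed: int

    def summary(self) -> str:
        return (
            f"Mixture-association permutation test for {self.covariate_name!r}\n"
            f"  K grid: {self.k_grid}, permutations: {self.B}\n"
            f"  observed min p = {self.observed_min_p:.3g}\n"
            f"  permutation p = {self.p_perm:.3g}"
        )

    def to_dict(self) -> dict:
        return {
            "covariate_name": self.covariate_name,
            "k_grid": [int(k) for k in self.k_grid],
            "observed_min_p": float(self.observed_min_p),
            "p_perm": float(self.p_perm),
            "B": int(self.B),
            "seed": int(self.seed),
        }


def test_metadata_association(
    bm: BetaMatrix,
    sheet: SampleSheet,
    covariate: str,
    k_grid,
    B: int = 1000,
    seed: int = 0,
    top_variable: int = 10_000,
    max_iter: int = 100,
) -> MixturePermutationResult:
    """Permutation min-P test spanning all candidate K.

    For each K the mixture is fitted once; the covariate is then permuted
    B times against the fixed proportions, and the permutation
    distribution of the minimum quasi-binomial p (over components and K)
    calibrates the observed minimum.
    """
    if B < 19:
        raise ValidationError("B must be >= 19")
    k_grid = sorted(set(int(k) for k in k_grid))
    if covariate not in sheet.data.columns:
        raise ValidationError(f"covariate {covariate!r} absent from sample sheet")
    cov = sheet.data.loc[list(bm.sample_ids), covariate].astype(float)
    keep = cov.notna()
    if (~keep).any():
        logger.info(
            "dropping %d sample(s) with missing %s", int((~keep).sum()), covariate
        )
    cov = cov[keep]
    sub = bm.select_samples(list(cov.index))
    n = sub.n_samples
    usable = [k for k in k_grid if k <= n]
    for k in set(k_grid) - set(usable):
        logger.warning("skipping K=%d: exceeds sample count n=%d", k, n)
    if not usable:
        raise ValidationError("no usable K in k_grid")
    working = select_most_variable(sub, min(top_variable, sub.n_probes))
    rng = np.random.default_rng(seed)
    x_obs = cov.to_numpy()
    perms = np.column_stack([rng.permutation(x_obs) for _ in range(B)])
    observed = 1.0
    perm_min = np.ones(B)
    model = ReferenceFreeMixture(working)
    for k in usable:
        fit_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        res = model.fit(k, seed=fit_seed, max_iter=max_iter)
        for comp in res.Omega.columns:
            y = res.Omega[comp].to_numpy()
            if np.ptp(y) == 0:
                continue
            observed = min(observed, float(_qb_wald_p(y, x_obs[:, None])[0]))
            perm_min = np.minimum(perm_min, _qb_wald_p(y, perms))
    p_perm = (1.0 + float(np.sum(perm_min <= observed))) / (B + 1.0)
    return MixturePermutationResult(
        covariate_name=covariate,
        k_grid=k_grid,
        observed_min_p=observed,
        perm_min_p=perm_min,
        p_perm=p_perm,
        B=B,
        seed=seed,
    )
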