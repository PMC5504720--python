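"""Reference-free cell-mixture deconvolution.

Factorises a CpG-by-sample beta matrix Y (m x n) as Y ~ Mu @ Omega.T where
Mu (m x K) holds K latent cell-type methylomes constrained to [0, 1] and
Omega (n x K) holds per-sample mixture proportions constrained to the
probability simplex — a convex variant of non-negative matrix
factorisation.  The number of putative cell types K is chosen by
bootstrap: specimens are resampled with replacement, the model is fitted
on each resample, and K minimising the mean out-of-bag reconstruction
deviance wins.

The fit alternates two convex sub-problems, each solved by monotone
projected-gradient descent, so the Frobenius objective is non-increasing
across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .containers import BetaMatrix, ValidationError
from .preprocess import select_most_variable

logger = logging.getLogger(__name__)

_TINY = 1e-12


def _project_rows_to_simplex(W: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, K = W.shape
    U = np.sort(W, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, K + 1)
    cond = U - css / ind > 0
    rho = K - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(W - theta[:, None], 0.0)


def _solve_omega(
    Y: np.ndarray,
    Mu: np.ndarray,
    W0: np.ndarray | None = None,
    max_steps: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Simplex-constrained least squares for all samples at once.

    Minimises ||Y - Mu W^T||_F^2 over rows of W on the simplex by
    projected gradient with the exact Lipschitz step, which never
    increases the objective.
    """
    n = Y.shape[1]
    K = Mu.shape[1]
    G = Mu.T @ Mu
    YtM = Y.T @ Mu
    lam = max(float(np.linalg.eigvalsh(G)[-1]), _TINY)
    step = 1.0 / (2.0 * lam)
    W = np.full((n, K), 1.0 / K) if W0 is None else W0.copy()
    for _ in range(max_steps):
        grad = 2.0 * (W @ G - YtM)
        W_new = _project_rows_to_simplex(W - step * grad)
        if np.max(np.abs(W_new - W)) < tol:
            W = W_new
            break
        W = W_new
    return W


def _solve_mu(
    Y: np.ndarray,
    W: np.ndarray,
    Mu0: np.ndarray,
    max_steps: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Box-constrained least squares for the methylomes, all probes at once."""
    Q = W.T @ W
    YW = Y @ W
    lam = max(float(np.linalg.eigvalsh(Q)[-1]), _TINY)
    step = 1.0 / (2.0 * lam)
    Mu = Mu0.copy()
    for _ in range(max_steps):
        grad = 2.0 * (Mu @ Q - YW)
        Mu_new = np.clip(Mu - step * grad, 0.0, 1.0)
        if np.max(np.abs(Mu_new - Mu)) < tol:
            Mu = Mu_new
            break
        Mu = Mu_new
    return Mu


def _fit_arrays(
    Y: np.ndarray,
    K: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    inner_steps: int = 30,
):
    """Alternating fit on a raw m x n array; returns (Mu, W, trace, converged)."""
    m, n = Y.shape
    if K > n:
        raise ValidationError(f"K = {K} exceeds the sample count n = {n}")
    if K > m:
        raise ValidationError(f"K = {K} exceeds the probe count m = {m}")
    if np.any(np.isnan(Y)):
        raise ValidationError("deconvolution input must not contain missing values")
    if K == 1:
        Mu = Y.mean(axis=1, keepdims=True)
        W = np.ones((n, 1))
        rss = float(np.sum((Y - Mu) ** 2))
        return Mu, W, np.array([rss]), True
    km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(Y.T)
    Mu = np.clip(km.cluster_centers_.T, 0.0, 1.0)
    W = _solve_omega(Y, Mu, max_steps=inner_steps * 4)
    trace = [float(np.sum((Y - Mu @ W.T) ** 2))]
    converged = False
    for _ in range(max_iter):
        W = _solve_omega(Y, Mu, W0=W, max_steps=inner_steps)
        Mu = _solve_mu(Y, W, Mu, max_steps=inner_steps)
        rss = float(np.sum((Y - Mu @ W.T) ** 2))
        trace.append(rss)
        prev = trace[-2]
        if prev - rss <= tol * max(prev, _TINY):
            converged = True
            break
    return Mu, W, np.asarray(trace), converged


@dataclass
class MixtureResults:
    """Fitted cell-mixture decomposition.

    Attributes
    ----------
    Mu : DataFrame (probes x K)
        Putative cell-type methylomes, entries in [0, 1].
    Omega : DataFrame (samples x K)
        Mixture proportions; rows on the probability simplex.
    objective_trace : ndarray
        Frobenius residual sum of squares per outer iteration
        (non-increasing).
    """

    Mu: pd.DataFrame
    Omega: pd.DataFrame
    K: int
    objective_trace: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        rows = self.Omega.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValidationError("Omega rows must sum to 1")

    @property
    def component_names(self) -> list[str]:
        return list(self.Omega.columns)

    def smallest_component(self) -> str:
        """Label of the component with the smallest mean proportion."""
        return str(self.Omega.mean(axis=0).idxmin())

    def reconstruction(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Mu.to_numpy() @ self.Omega.to_numpy().T,
            index=self.Mu.index,
            columns=self.Omega.index,
        )

    def summary(self) -> str:
        means = self.Omega.mean(axis=0)
        lines = [
            f"Reference-free mixture model (K = {self.K})",
            f"  probes: {self.Mu.shape[0]}, samples: {self.Omega.shape[0]}",
            f"  converged: {self.converged} "
            f"(final RSS = {self.objective_trace[-1]:.4g}, "
            f"{len(self.objective_trace)} iterations)",
            "  mean proportions:",
        ]
        for name, v in means.items():
            lines.append(f"    {name}: {v:.3f}")
        return "\n".join(lines)


class ReferenceFreeMixture:
    """Model object for reference-free deconvolution of a beta matrix.

    Parameters
    ----------
    bm : BetaMatrix
        Complete (no missing values) methylation fractions.

    Examples
    --------
    >>> model = ReferenceFreeMixture(bm)
    >>> res = model.fit(K=3, seed=0)
    >>> res.Omega.head()
    """

    def __init__(self, bm: BetaMatrix):
        if np.any(np.isnan(bm.values)):
            raise ValidationError(
                "missing betas present; call drop_incomplete_probes() first"
            )
        self.bm = bm

    def fit(
        self,
        K: int,
        max_iter: int = 300,
        tol: float = 1e-6,
        seed: int = 0,
        inner_steps: int = 30,
    ) -> MixtureResults:
        # Work in canonical (sorted) sample order so the fit is invariant
        # to the order in which samples arrive; restore order afterwards.
        order = np.argsort(self.bm.sample_ids.astype(str))
        Y = self.bm.values[:, order]
        Mu, W, trace, converged = _fit_arrays(
            Y, K, max_iter=max_iter, tol=tol, seed=seed, inner_steps=inner_steps
        )
        if not converged:
            logger.warning(
                "mixture fit (K=%d) did not converge in %d iterations", K, max_iter
            )
        # Canonical component order: descending mean proportion.
        comp_order = np.argsort(-W.mean(axis=0), kind="stable")
        Mu, W = Mu[:, comp_order], W[:, comp_order]
        inverse = np.argsort(order)
        names = [f"celltype_{k+1}" for k in range(K)]
        return MixtureResults(
            Mu=pd.DataFrame(Mu, index=self.bm.probe_ids, columns=names),
            Omega=pd.DataFrame(W[inverse], index=self.bm.sample_ids, columns=names),
            K=K,
            objective_trace=trace,
            converged=converged,
        )


def fit_mixture(
    bm: BetaMatrix,
    K: int,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> MixtureResults:
    """Convenience wrapper: ``ReferenceFreeMixture(bm).fit(K, ...)``."""
    return ReferenceFreeMixture(bm).fit(K, max_iter=max_iter, tol=tol, seed=seed)


@dataclass
class KSelectionResult:
    """Bootstrap model-selection record for the number of cell types."""

    k_grid: list[int]
    mean_bootstrap_deviance: pd.Series
    chosen_K: int
    n_boot: int
    seed: int

    def summary(self) -> str:
        lines = [f"Bootstrap K selection ({self.n_boot} resamples, seed {self.seed})"]
        for k, d in self.mean_bootstrap_deviance.items():
            marker = " <- chosen" if k == self.chosen_K else ""
            lines.append(f"  K={k}: deviance {d:.6g}{marker}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_grid": [int(k) for k in self.k_grid],
            "mean_bootstrap_deviance": {
                str(k): float(v) for k, v in self.mean_bootstrap_deviance.items()
            },
            "chosen_K": int(self.chosen_K),
            "n_boot": int(self.n_boot),
            "seed": int(self.seed),
        }


def select_k(
    bm: BetaMatrix,
    k_grid,
    n_boot: int = 100,
    top_variable: int = 10_000,
    seed: int = 0,
    max_iter: int = 50,
    inner_steps: int = 20,
) -> KSelectionResult:
    """Choose the number of cell types by out-of-bag bootstrap deviance.

    The matrix is restricted to the ``top_variable`` most variable probes.
    For each of ``n_boot`` resamples of specimens (with replacement) and
    each candidate K, the mixture is fitted on the resample and scored on
    the out-of-bag specimens by bi-cross-validation: each held-out
    sample's proportions are estimated by simplex projection using one
    random half of the probes, and the deviance is the mean squared
    residual on the other half.  Scoring on probes not used for the
    projection is what penalises spurious components — a plain projection
    residual decreases with K even on unstructured data.  ``chosen_K`` is
    the smallest K attaining the minimum mean deviance.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValidationError("k_grid must be nonempty")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    sub = select_most_variable(bm, min(top_variable, bm.n_probes))
    Y = sub.values
    n = Y.shape[1]
    usable = [k for k in k_grid if k <= n]
    for k in set(k_grid) - set(usable):
        logger.warning("skipping K=%d: exceeds sample count n=%d", k, n)
    if not usable:
        raise ValidationError("no K in k_grid is <= the sample count")
    rng = np.random.default_rng(seed)
    sums = {k: 0.0 for k in usable}
    counts = {k: 0 for k in usable}
    m = Y.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        probe_perm = rng.permutation(m)
        fit_half, eval_half = probe_perm[: m // 2], probe_perm[m // 2:]
        Yb, Yo = Y[:, idx], Y[:, oob]
        for k in usable:
            fit_seed = int(
                np.random.SeedSequence([seed, b, k]).generate_state(1)[0] % (2**31)
            )
            Mu_b, _, _, _ = _fit_arrays(
                Yb, k, max_iter=max_iter, seed=fit_seed, inner_steps=inner_steps
            )
            W_o = _solve_omega(Yo[fit_half], Mu_b[fit_half])
            dev = float(np.mean((Yo[eval_half] - Mu_b[eval_half] @ W_o.T) ** 2))
            sums[k] += dev
            counts[k] += 1
    mean_dev = pd.Series({k: sums[k] / counts[k] for k in usable}).sort_index()
    minval = mean_dev.min()
    chosen = int(min(k for k in usable if mean_dev[k] == minval))
    return KSelectionResult(
        k_grid=list(k_grid),
        mean_bootstrap_deviance=mean_dev,
        chosen_K=chosen,
        n_boot=n_boot,
        seed=seed,
    )


def match_components(Omega_est, Omega_true):
    """Optimal column matching between estimated and true proportions.

    Returns ``(perm, mae)`` where ``perm[j]`` is the estimated column
    assigned to true column ``j`` (minimising total absolute difference via
    the Hungarian algorithm) and ``mae`` is the resulting mean absolute
    error over all entries.
    """
    est = np.asarray(Omega_est, dtype=float)
    true = np.asarray(Omega_true, dtype=float)
    if est.shape != true.shape:
        raise ValidationError(
            f"shape mismatch: estimated {est.shape} vs true {true.shape}"
        )
    K = est.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(est[:, i] - true[:, j]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    mae = float(cost[rows, cols].sum() / est.size)
    return perm, mae
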