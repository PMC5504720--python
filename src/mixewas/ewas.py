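"""Per-CpG moderated linear models of M values on risk factors.

Each probe's logit2-transformed betas are regressed on a shared design
matrix (intercept + risk factors, optionally + K-1 estimated cell-type
proportions, the smallest-mean component dropped to avoid
multi-collinearity).  Residual variances are shrunk across probes by the
empirical-Bayes scheme of moderated t-statistics: a scaled inverse
chi-square prior (d0, s0^2) is estimated by moment matching on the log
residual variances, and each probe's posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the t-statistic, which then has d0 + d degrees of
freedom.  Multiple testing is controlled per covariate across probes with
Benjamini-Hochberg q-values; the default genome-wide threshold is
Q = 0.01.  The difference between a CpG's unadjusted and cell-adjusted
coefficients (the *delta coefficient*) flags composition-confounded loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import MValueMatrix, SampleSheet, ValidationError
from .deconvolution import MixtureResults

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.01


@dataclass
class DesignMatrix:
    """Aligned design for the per-CpG regressions."""

    sample_ids: pd.Index
    column_names: list[str]
    values: np.ndarray
    dropped_component: str | None = None
    n_dropped_samples: int = 0

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_names)


def _expand_categorical(series: pd.Series, name: str) -> pd.DataFrame:
    """Indicator columns against the most frequent level as reference."""
    counts = series.value_counts()
    reference = counts.index[0]
    levels = [lv for lv in counts.index if lv != reference]
    out = {}
    for lv in levels:
        out[f"{name}[{lv}]"] = (series == lv).astype(float)
    return pd.DataFrame(out, index=series.index)


def build_design(
    sheet: SampleSheet,
    covariates,
    mixture: MixtureResults | None = None,
) -> DesignMatrix:
    """Intercept + covariates (+ K-1 mixture proportion columns).

    Samples with missing values in any requested covariate are dropped
    (count logged).  When a mixture is supplied, all proportion columns
    except the smallest-mean component enter the design.  The result is
    rank-checked; a deficiency raises an error naming collinear columns.
    """
    covariates = list(covariates)
    missing = [c for c in covariates if c not in sheet.data.columns]
    if missing:
        raise ValidationError(f"covariates absent from sample sheet: {missing}")
    sub = sheet.data[covariates].copy() if covariates else pd.DataFrame(index=sheet.data.index)
    complete = sub.dropna(axis=0).index if covariates else sheet.data.index
    n_dropped = len(sheet.data.index) - len(complete)
    if n_dropped:
        logger.info(
            "dropping %d sample(s) with missing values in %s", n_dropped, covariates
        )
    blocks = [pd.DataFrame({"intercept": 1.0}, index=complete)]
    for cov in covariates:
        col = sheet.data.loc[complete, cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            blocks.append(_expand_categorical(col, cov))
        else:
            blocks.append(col.astype(float).to_frame(cov))
    dropped_component = None
    if mixture is not None:
        omega = mixture.Omega
        absent = [s for s in complete if s not in omega.index]
        if absent:
            raise ValidationError(f"samples missing from mixture proportions: {absent[:5]}")
        dropped_component = mixture.smallest_component()
        keep = [c for c in omega.columns if c != dropped_component]
        blocks.append(omega.loc[complete, keep])
    design = pd.concat(blocks, axis=1)
    X = design.to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"design has {X.shape[1]} parameters but only {X.shape[0]} samples"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.columns[i] for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1))]
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(
        sample_ids=pd.Index(complete, name="sample_id"),
        column_names=list(design.columns),
        values=X,
        dropped_component=dropped_component,
        n_dropped_samples=n_dropped,
    )


def fit_cpg_models(M: MValueMatrix, X: DesignMatrix, covariate: str) -> pd.DataFrame:
    """Ordinary least squares per probe, vectorised across the matrix.

    Returns a DataFrame indexed by probe with columns ``coefficient``,
    ``stderr``, ``sigma2`` (residual variance), ``df`` (residual degrees
    of freedom) and ``se_unscaled`` (the covariate's design leverage
    sqrt((X'X)^-1_jj), so stderr = sqrt(sigma2) * se_unscaled).
    """
    if covariate not in X.column_names:
        raise ValidationError(f"covariate {covariate!r} not in design columns")
    missing = [s for s in X.sample_ids if s not in M.sample_ids]
    if missing:
        raise ValidationError(f"design samples absent from M matrix: {missing[:5]}")
    Y = M.data[list(X.sample_ids)].to_numpy().T  # n x m
    n, p = X.values.shape
    if n <= p:
        raise ValidationError(f"n = {n} samples <= p = {p} parameters")
    XtX_inv = np.linalg.inv(X.values.T @ X.values)
    B = XtX_inv @ X.values.T @ Y  # p x m
    resid = Y - X.values @ B
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    j = X.column_names.index(covariate)
    c_j = float(np.sqrt(XtX_inv[j, j]))
    coef = B[j]
    return pd.DataFrame(
        {
            "coefficient": coef,
            "stderr": np.sqrt(sigma2) * c_j,
            "sigma2": sigma2,
            "df": float(df),
            "se_unscaled": c_j,
        },
        index=M.probe_ids,
    )


@dataclass
class ModerationParams:
    """Empirical-Bayes prior on residual variances."""

    d0: float      # prior degrees of freedom; may be inf
    s0_sq: float   # prior variance


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(sigma2, df) -> ModerationParams:
    """Moment-matching estimate of (d0, s0^2) from log residual variances."""
    s2 = np.asarray(sigma2, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    pos = s2 > 0
    if pos.sum() < 2:
        raise ValidationError("moderation needs >= 2 probes with positive variance")
    z = np.log(s2[pos])
    dp = d[pos]
    e = z - digamma(dp / 2.0) + np.log(dp / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    resid_var = evar - float(np.mean(polygamma(1, dp / 2.0)))
    if resid_var <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(resid_var)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderate(fits: pd.DataFrame, params: ModerationParams | None = None) -> pd.DataFrame:
    """Moderated t-statistics and p-values for a table of per-probe fits.

    With ``params.d0 == 0`` the result equals the ordinary t-test; with
    ``d0 == inf`` every probe shares the prior variance ``s0_sq``.
    """
    if len(fits) < 2:
        raise ValidationError("moderation needs an ensemble of >= 2 probes")
    s2 = fits["sigma2"].to_numpy()
    d = fits["df"].to_numpy()
    if np.all(s2 == 0):
        raise ValidationError("all residual variances are zero; degenerate ensemble")
    if params is None:
        params = estimate_moderation(s2, d)
    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        s_tilde2 = np.full_like(s2, s0)
        df_total = np.full_like(d, np.inf)
    else:
        s_tilde2 = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    denom = fits["se_unscaled"].to_numpy() * np.sqrt(s_tilde2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits["coefficient"].to_numpy() / denom
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2.0 * stats.t.sf(np.abs(t_mod), finite_df)
    out = fits.copy()
    out["t_moderated"] = t_mod
    out["p_value"] = np.clip(p, 0.0, 1.0)
    out.attrs["moderation"] = params
    return out


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-d vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def delta_coefficients(adjusted, unadjusted) -> pd.Series:
    """Per-probe confounding diagnostic: coef(unadjusted) - coef(adjusted)."""
    adj = adjusted.table if isinstance(adjusted, EwasResults) else adjusted
    unadj = unadjusted.table if isinstance(unadjusted, EwasResults) else unadjusted
    if not adj.index.equals(unadj.index):
        raise ValidationError("adjusted and unadjusted results cover different probes")
    if isinstance(adjusted, EwasResults) and isinstance(unadjusted, EwasResults):
        if adjusted.covariate_name != unadjusted.covariate_name:
            raise ValidationError("delta requires the same covariate in both models")
    return (unadj["coefficient"] - adj["coefficient"]).rename("delta")


@dataclass
class EwasResults:
    """Per-CpG association results for one covariate and one design.

    ``table`` columns: coefficient, stderr, t_moderated, p_value, q_value.
    """

    table: pd.DataFrame
    covariate_name: str
    model_tag: str                 # "adjusted" | "unadjusted"
    moderation: ModerationParams
    n_samples: int

    def significant(self, q_threshold: float = DEFAULT_Q_THRESHOLD) -> pd.DataFrame:
        return self.table[self.table["q_value"] < q_threshold]

    def hyper_hypo_counts(self, q_threshold: float = DEFAULT_Q_THRESHOLD):
        sig = self.significant(q_threshold)
        return int((sig["coefficient"] > 0).sum()), int((sig["coefficient"] < 0).sum())

    def summary(self, q_threshold: float = DEFAULT_Q_THRESHOLD) -> str:
        n_sig = len(self.significant(q_threshold))
        hyper, hypo = self.hyper_hypo_counts(q_threshold)
        d0 = self.moderation.d0
        return "\n".join(
            [
                f"EWAS of {self.covariate_name} ({self.model_tag} model, "
                f"n = {self.n_samples} samples, {len(self.table)} probes)",
                f"  prior df d0 = {d0:.3g}, prior variance s0^2 = "
                f"{self.moderation.s0_sq:.3g}",
                f"  significant at Q < {q_threshold:g}: {n_sig} "
                f"({hyper} hypermethylated, {hypo} hypomethylated)",
            ]
        )


class CpGAssociationModel:
    """Moderated per-CpG linear model of M values on a design matrix.

    Examples
    --------
    >>> design = build_design(sheet, ["age"], mixture=mix_results)
    >>> res = CpGAssociationModel(mvalues, design).fit("age")
    >>> res.significant(0.01)
    """

    def __init__(self, mvalues: MValueMatrix, design: DesignMatrix):
        self.mvalues = mvalues
        self.design = design

    def fit(
        self,
        covariate: str,
        params: ModerationParams | None = None,
    ) -> EwasResults:
        fits = fit_cpg_models(self.mvalues, self.design, covariate)
        moderated = moderate(fits, params)
        moderated["q_value"] = bh_qvalues(moderated["p_value"].to_numpy())
        tag = "adjusted" if self.design.dropped_component is not None else "unadjusted"
        cols = ["coefficient", "stderr", "t_moderated", "p_value", "q_value"]
        return EwasResults(
            table=moderated[cols],
            covariate_name=covariate,
            model_tag=tag,
            moderation=moderated.attrs["moderation"],
            n_samples=len(self.design.sample_ids),
        )


def run_ewas(
    mvalues: MValueMatrix,
    sheet: SampleSheet,
    covariate: str,
    adjust_covariates=(),
    mixture: MixtureResults | None = None,
) -> EwasResults:
    """Build the design and fit the moderated model in one call."""
    design = build_design(sheet, [covariate, *adjust_covariates], mixture=mixture)
    return CpGAssociationModel(mvalues, design).fit(covariate)
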