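"""Epigenetic clocks and age acceleration.

A clock is a fixed linear combination of CpG beta values predicting
biological age (with an optional calibration transform, e.g. the
log-linear under-adult-age form used by multi-tissue clocks) or, for
mitotic-score clocks, the plain mean beta over the CpG set.  *Age
acceleration* is the residual of DNA-methylation age regressed on
chronological age; its association with risk factors is assessed by
univariate and joint ordinary least squares.

Clocks are data, not code: a coefficient table plus a transform spec.
Published coefficient sets can be dropped in via :func:`mixewas.io.read_clock`;
the test suite uses synthetic, exactly invertible clocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_FLOOR = 0.95


def forward_transform(age, spec: dict):
    """Chronological age -> linear-predictor scale."""
    age = np.asarray(age, dtype=float)
    kind = spec.get("type", "identity")
    if kind == "identity":
        return age
    if kind == "log_linear":
        adult = float(spec.get("adult_age", 20.0))
        return np.where(
            age <= adult,
            np.log((age + 1.0) / (adult + 1.0)),
            (age - adult) / (adult + 1.0),
        )
    raise ValidationError(f"unknown transform type {kind!r}")


def inverse_transform(lp, spec: dict):
    """Linear-predictor scale -> age (inverse of :func:`forward_transform`)."""
    lp = np.asarray(lp, dtype=float)
    kind = spec.get("type", "identity")
    if kind == "identity":
        return lp
    if kind == "log_linear":
        adult = float(spec.get("adult_age", 20.0))
        return np.where(
            lp <= 0,
            (adult + 1.0) * np.exp(lp) - 1.0,
            adult + lp * (adult + 1.0),
        )
    raise ValidationError(f"unknown transform type {kind!r}")


@dataclass
class EpigeneticClock:
    """Coefficient-table DNA-methylation age predictor.

    ``kind = "linear"``: predicted age = T^-1(intercept + sum w_j * beta_j).
    ``kind = "mean"``: mitotic-score style, score = mean beta over the set
    (weights ignored, identity transform).
    """

    name: str
    coefficients: pd.Series        # probe_id -> weight (per unit beta)
    intercept: float = 0.0
    transform: dict = field(default_factory=lambda: {"type": "identity"})
    kind: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "mean"):
            raise ValidationError(f"unknown clock kind {self.kind!r}")
        if self.coefficients.index.has_duplicates:
            raise ValidationError("duplicate probes in clock coefficients")

    @property
    def expected_n_cpgs(self) -> int:
        return len(self.coefficients)

    def predict(
        self,
        bm: BetaMatrix,
        missing_policy: str = "error",
        coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
    ) -> pd.Series:
        """Per-sample DNA-methylation age (or mitotic score).

        Clock CpGs absent from the matrix reduce coverage; below
        ``coverage_floor`` the prediction errors out.  NaN betas at
        present clock CpGs are handled per ``missing_policy``: "error",
        or "impute_cohort_mean" (probe mean across samples).
        """
        if self.expected_n_cpgs == 0:
            raise ValidationError("clock has no CpGs")
        present = self.coefficients.index.intersection(bm.probe_ids)
        coverage = len(present) / self.expected_n_cpgs
        if coverage < coverage_floor:
            raise ValidationError(
                f"clock {self.name!r}: only {len(present)}/{self.expected_n_cpgs} "
                f"CpGs present (coverage {coverage:.1%} < floor {coverage_floor:.1%})"
            )
        if coverage < 1:
            logger.info(
                "clock %s: %d of %d CpGs available",
                self.name, len(present), self.expected_n_cpgs,
            )
        block = bm.data.loc[present]
        if block.isna().any().any():
            if missing_policy == "error":
                raise ValidationError(
                    f"missing betas at clock CpGs of {self.name!r}"
                )
            if missing_policy == "impute_cohort_mean":
                block = block.apply(lambda row: row.fillna(row.mean()), axis=1)
            else:
                raise ValidationError(f"unknown missing_policy {missing_policy!r}")
        if self.kind == "mean":
            return block.mean(axis=0).rename(self.name)
        lp = self.intercept + block.mul(self.coefficients.loc[present], axis=0).sum(axis=0)
        return pd.Series(
            inverse_transform(lp.to_numpy(), self.transform),
            index=bm.sample_ids,
            name=self.name,
        )

    def overlap_with(self, cpg_ids) -> int:
        """Number of clock CpGs appearing in a CpG set (reporting helper)."""
        return int(self.coefficients.index.isin(pd.Index(cpg_ids)).sum())


def dnam_age(
    clock: EpigeneticClock,
    bm: BetaMatrix,
    missing_policy: str = "error",
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
) -> pd.Series:
    """Functional alias for :meth:`EpigeneticClock.predict`."""
    return clock.predict(bm, missing_policy=missing_policy, coverage_floor=coverage_floor)


def age_acceleration(dnam, chrono) -> pd.Series:
    """Residuals of DNAm age regressed on chronological age (OLS)."""
    dnam = pd.Series(dnam)
    chrono = np.asarray(chrono, dtype=float)
    if len(dnam) < 3:
        raise ValidationError("need at least 3 samples")
    if np.ptp(chrono) == 0:
        raise ValidationError("chronological age is constant; residuals undefined")
    X = np.column_stack([np.ones(len(chrono)), chrono])
    coef, *_ = np.linalg.lstsq(X, dnam.to_numpy(dtype=float), rcond=None)
    resid = dnam.to_numpy(dtype=float) - X @ coef
    return pd.Series(resid, index=dnam.index, name="acceleration")


@dataclass
class AgeAccelerationResult:
    """Per-sample clock output with the cohort-regression residual."""

    table: pd.DataFrame   # columns: dnam_age, chrono_age, acceleration
    clock_name: str

    def summary(self) -> str:
        t = self.table
        rho = t["dnam_age"].corr(t["chrono_age"], method="spearman")
        return (
            f"Clock {self.clock_name!r}: n = {len(t)}\n"
            f"  Spearman(dnam_age, chrono_age) = {rho:.3f}\n"
            f"  acceleration sd = {t['acceleration'].std():.3f}"
        )


def compute_age_acceleration(
    clock: EpigeneticClock,
    bm: BetaMatrix,
    sheet: SampleSheet,
    missing_policy: str = "error",
) -> AgeAccelerationResult:
    """Predict, regress on chronological age, and package the residuals."""
    pred = clock.predict(bm, missing_policy=missing_policy)
    chrono = sheet.data.loc[pred.index, "age"].astype(float)
    accel = age_acceleration(pred, chrono.to_numpy())
    return AgeAccelerationResult(
        table=pd.DataFrame(
            {"dnam_age": pred, "chrono_age": chrono, "acceleration": accel}
        ),
        clock_name=clock.name,
    )


def _covariate_columns(sheet: SampleSheet, covariate: str, index) -> pd.DataFrame:
    col = sheet.data.loc[index, covariate]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        counts = col.value_counts()
        ref = counts.index[0]
        return pd.DataFrame(
            {f"{covariate}[{lv}]": (col == lv).astype(float) for lv in counts.index[1:]},
            index=index,
        )
    return col.astype(float).to_frame(covariate)


def acceleration_associations(accel, sheet: SampleSheet, covariates):
    """Univariate and joint OLS of acceleration on risk factors.

    Returns ``(univariate, joint)`` coefficient tables with columns
    coefficient/stderr/p_value per term.  Zero-variance terms are dropped
    with a logged warning; samples missing a covariate are dropped from
    the model(s) involving it.
    """
    accel = pd.Series(accel)
    uni_rows = []
    joint_blocks = []
    for cov in covariates:
        cols = _covariate_columns(sheet, cov, accel.index)
        keep_cols = []
        for name in cols.columns:
            if np.nanstd(cols[name].to_numpy(dtype=float)) == 0:
                logger.warning("dropping constant term %r", name)
                continue
            keep_cols.append(name)
        cols = cols[keep_cols]
        if cols.empty:
            continue
        joint_blocks.append(cols)
        rows = cols.dropna().index
        X = sm.add_constant(cols.loc[rows])
        fit = sm.OLS(accel.loc[rows], X).fit()
        for name in keep_cols:
            uni_rows.append(
                (cov, name, fit.params[name], fit.bse[name], fit.pvalues[name])
            )
    univariate = pd.DataFrame(
        uni_rows, columns=["covariate", "term", "coefficient", "stderr", "p_value"]
    )
    joint = pd.DataFrame(
        columns=["term", "coefficient", "stderr", "p_value"]
    )
    if joint_blocks:
        Xj = pd.concat(joint_blocks, axis=1)
        rows = Xj.dropna().index
        fit = sm.OLS(accel.loc[rows], sm.add_constant(Xj.loc[rows])).fit()
        joint = pd.DataFrame(
            {
                "term": [t for t in fit.params.index if t != "const"],
                "coefficient": [fit.params[t] for t in fit.params.index if t != "const"],
                "stderr": [fit.bse[t] for t in fit.params.index if t != "const"],
                "p_value": [fit.pvalues[t] for t in fit.params.index if t != "const"],
            }
        )
    return univariate, joint
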