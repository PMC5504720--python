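"""Value transforms and probe filters applied ahead of modelling."""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    MValueMatrix,
    ProbeAnnotation,
    SEX_CHROMOSOMES,
    ValidationError,
)

#: Offset added to the intensity denominator; regularises betas computed
#: from low-intensity probes.
INTENSITY_OFFSET = 100.0

#: Default logit clip bound keeping M values finite at beta = 0 or 1.
DEFAULT_EPSILON = 1e-6


def beta_from_intensities(meth_signal, unmeth_signal):
    """Methylation fraction from methylated/unmethylated fluorescence.

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100).  Signals may be
    negative after background correction; they are clamped at zero.  The
    result lies in [0, 1).
    """
    meth = np.asarray(meth_signal, dtype=float)
    unmeth = np.asarray(unmeth_signal, dtype=float)
    if np.any(np.isnan(meth)) or np.any(np.isnan(unmeth)):
        raise ValidationError("intensities must be numeric, got NaN")
    m = np.maximum(meth, 0.0)
    u = np.maximum(unmeth, 0.0)
    out = m / (m + u + INTENSITY_OFFSET)
    return out if out.ndim else float(out)


def beta_to_mvalue(beta, epsilon: float = DEFAULT_EPSILON):
    """logit2 transform: M = log2(b / (1 - b)), b clipped to [eps, 1-eps].

    Odd-symmetric around beta = 0.5 (f(1 - b) = -f(b)).
    """
    if not 0 < epsilon < 0.5:
        raise ValidationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.asarray(beta, dtype=float)
    valid = np.isnan(b) | ((b >= 0) & (b <= 1))
    if not np.all(valid):
        raise ValidationError(f"beta outside [0, 1]: {b[~valid].ravel()[:5]}")
    clipped = np.clip(b, epsilon, 1 - epsilon)
    out = np.log2(clipped / (1 - clipped))
    out = np.where(np.isnan(b), np.nan, out)
    return out if out.ndim else float(out)


def mvalue_to_beta(mvalue):
    """Inverse logit2: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(mvalue, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


def to_mvalues(bm: BetaMatrix, epsilon: float = DEFAULT_EPSILON) -> MValueMatrix:
    """Transform a whole beta matrix to M values."""
    return MValueMatrix(
        pd.DataFrame(
            beta_to_mvalue(bm.values, epsilon),
            index=bm.probe_ids,
            columns=bm.sample_ids,
        )
    )


def filter_probes(
    bm: BetaMatrix,
    ann: ProbeAnnotation,
    exclude_flags: Iterable[str] = ("sex_chromosome", "cross_reactive", "snp_overlap"),
) -> BetaMatrix:
    """Drop probes carrying any excluded mask flag.

    When ``sex_chromosome`` is excluded, probes on chrX/chrY are removed
    whether or not their mask column says so.  Probe order is preserved and
    the operation is idempotent.
    """
    exclude = set(exclude_flags)
    sub = ann.for_probes(bm.probe_ids)
    masks = sub.mask_sets()
    drop = masks.map(lambda flags: bool(flags & exclude)).to_numpy()
    if "sex_chromosome" in exclude:
        drop |= sub.data["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
    keep = bm.probe_ids[~drop]
    return BetaMatrix(bm.data.loc[keep])


def select_most_variable(bm: BetaMatrix, count: int) -> BetaMatrix:
    """Keep the ``count`` probes with largest across-sample beta variance.

    Ties are broken by probe id (lexicographic) for determinism; the
    selected probes are returned in their original matrix order.  Requires
    at least two samples.
    """
    if count < 1:
        raise ValidationError(f"count must be >= 1, got {count}")
    if bm.n_samples < 2:
        raise ValidationError("variance undefined with fewer than 2 samples")
    if count >= bm.n_probes:
        return bm
    variances = bm.data.var(axis=1, ddof=1)
    order = sorted(bm.probe_ids, key=lambda p: (-variances[p], str(p)))
    chosen = set(order[:count])
    keep = [p for p in bm.probe_ids if p in chosen]
    return BetaMatrix(bm.data.loc[keep])
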