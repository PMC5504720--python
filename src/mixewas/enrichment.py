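"""Region-set enrichment, matched-background resampling and related tests.

Significant CpGs (Q below threshold) are tested for overlap with labelled
genomic interval sets against the background universe of all analysed
CpGs, with a 2x2 Fisher exact test per set.  Because gains and losses of
methylation are biologically distinct at regulatory sites, the analysis
is stratified by coefficient sign (hyper- vs hypomethylation with the
covariate).  A matched background — random CpGs with the query's
CpG-island profile — supports the progression contrast, where the
distributions of tumour-vs-normal effect sizes at query and matched CpGs
are compared with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ProbeAnnotation, RegionSet, ValidationError
from .ewas import DEFAULT_Q_THRESHOLD, bh_qvalues


def overlap_counts(query, universe, ann: ProbeAnnotation, rs: RegionSet):
    """2x2 counts of region overlap for query vs the rest of the universe.

    Returns (a, b, c, d): query-in-set, query-out, rest-in, rest-out.  A
    probe at annotated position p is inside an interval (start, end) iff
    start <= p < end.
    """
    query = pd.Index(query)
    universe = pd.Index(universe)
    if not query.isin(universe).all():
        raise ValidationError("query must be a subset of the universe")
    sub = ann.for_probes(universe)
    if sub.data["position"].isna().any():
        missing = sub.data.index[sub.data["position"].isna()].tolist()[:5]
        raise ValidationError(f"probes missing coordinates: {missing}")
    inside = rs.contains(
        sub.data["chromosome"].to_numpy(), sub.data["position"].to_numpy()
    )
    is_query = universe.isin(query)
    a = int(np.sum(inside & is_query))
    b = int(np.sum(~inside & is_query))
    c = int(np.sum(inside & ~is_query))
    d = int(np.sum(~inside & ~is_query))
    return a, b, c, d


def fisher_enrichment(counts):
    """Two-sided Fisher exact test on a 2x2 overlap table.

    Returns (odds_ratio, ci_low, ci_high, p_value).  The odds ratio is the
    sample OR a*d/(b*c); the 95% CI uses the log-OR normal approximation,
    with a 0.5 continuity correction applied only when a zero cell exists.
    """
    a, b, c, d = (int(x) for x in counts)
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValidationError("empty query or empty rest; enrichment undefined")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds_ratio = np.inf if a * d > 0 else (0.0 if a == 0 else np.inf)
    else:
        odds_ratio = (a * d) / (b * c)
    if a == 0:
        odds_ratio = 0.0
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    log_or = np.log((a_ * d_) / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci_low = float(np.exp(log_or - 1.959963984540054 * se))
    ci_high = float(np.exp(log_or + 1.959963984540054 * se))
    return float(odds_ratio), ci_low, ci_high, float(p)


@dataclass
class EnrichmentRecord:
    """One region set x direction enrichment result."""

    set_label: str
    direction: str          # "hyper" | "hypo" | "all"
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float = np.nan
    status: str = "ok"      # "ok" | "skipped"


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def stratified_enrichment(
    results,
    universe,
    ann: ProbeAnnotation,
    region_sets,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Direction-stratified Fisher enrichment over a list of region sets.

    ``results`` is an EwasResults or its table (signed coefficients and
    q-values, indexed by probe).  Significant CpGs are split by
    coefficient sign; each region set is tested within each direction and
    Benjamini-Hochberg q-values are assigned across sets within a
    direction.  Empty strata yield rows with status "skipped".
    """
    table = results.table if hasattr(results, "table") else results
    universe = pd.Index(universe)
    sig = table[table["q_value"] < q_threshold]
    strata = {
        "hyper": sig.index[sig["coefficient"] > 0],
        "hypo": sig.index[sig["coefficient"] < 0],
    }
    all_records = []
    for direction, query in strata.items():
        if len(query) == 0:
            for rs in region_sets:
                all_records.append(
                    EnrichmentRecord(
                        rs.label, direction, 0, 0, 0, 0,
                        np.nan, np.nan, np.nan, np.nan, np.nan, "skipped",
                    )
                )
            continue
        records = []
        for rs in region_sets:
            counts = overlap_counts(query, universe, ann, rs)
            odds, lo, hi, p = fisher_enrichment(counts)
            records.append(
                EnrichmentRecord(rs.label, direction, *counts, odds, lo, hi, p)
            )
        qvals = bh_qvalues([r.p_value for r in records])
        for r, q in zip(records, qvals):
            r.q_value = float(q)
        all_records.extend(records)
    return _records_frame(all_records)


def sample_matched_background(query, universe, ann: ProbeAnnotation, seed: int = 0,
                              match_field: str = "island_relation"):
    """Random non-query CpGs matching the query's annotation profile.

    Samples, without replacement and per stratum of ``match_field``,
    exactly as many probes as the query has in that stratum; the result is
    disjoint from the query.
    """
    query = pd.Index(query)
    universe = pd.Index(universe)
    if not query.isin(universe).all():
        raise ValidationError("query must be a subset of the universe")
    sub = ann.for_probes(universe)
    strata = sub.data[match_field]
    pool = universe[~universe.isin(query)]
    rng = np.random.default_rng(seed)
    chosen = []
    for value, n_needed in strata.loc[query].value_counts().items():
        candidates = pool[strata.loc[pool] == value]
        if len(candidates) < n_needed:
            raise ValidationError(
                f"stratum {value!r}: need {n_needed} matched probes, "
                f"only {len(candidates)} available"
            )
        chosen.extend(rng.choice(candidates, size=n_needed, replace=False))
    return pd.Index(chosen)


def ks_compare(x, y):
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|; the p-value is computed exactly when
    n*m <= 10,000 and from the asymptotic Kolmogorov distribution
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("KS comparison requires nonempty samples")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def cpg_expression_correlation(
    M, expr: pd.DataFrame, pairs, ann: ProbeAnnotation | None = None
) -> pd.DataFrame:
    """Spearman correlation between CpG M values and gene expression.

    ``pairs`` maps probe_id -> gene; correlations use the samples shared
    by both matrices (at least 5 required).  The probe's gene region is
    carried through when annotation is supplied, for context-dependency
    summaries (promoter vs gene body).
    """
    mdata = M.data if hasattr(M, "data") else M
    shared = [s for s in mdata.columns if s in expr.columns]
    if len(shared) < 5:
        raise ValidationError(
            f"only {len(shared)} shared samples; need at least 5"
        )
    rows = []
    for probe, gene in dict(pairs).items():
        if probe not in mdata.index or gene not in expr.index:
            raise ValidationError(f"pair ({probe!r}, {gene!r}) not present in matrices")
        mv = mdata.loc[probe, shared].to_numpy(dtype=float)
        ev = expr.loc[gene, shared].to_numpy(dtype=float)
        rho, p = stats.spearmanr(mv, ev)
        region = (
            ann.data.loc[probe, "gene_region"] if ann is not None else None
        )
        rows.append((probe, gene, float(rho), float(p), region))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene", "rho", "p_value", "gene_region"]
    ).set_index("probe_id")
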