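import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixewas import (
    MValueMatrix,
    ProbeAnnotation,
    RegionSet,
    ValidationError,
    cpg_expression_correlation,
    fisher_enrichment,
    ks_compare,
    overlap_counts,
    sample_matched_background,
    stratified_enrichment,
)


def _annotation(n, rng=None, islands=None):
    rng = rng or np.random.default_rng(0)
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": ["chr1"] * n,
                "position": np.arange(1, n + 1) * 100,
                "island_relation": islands
                or list(rng.choice(["island", "shore", "shelf", "open_sea"], n)),
                "gene_region": ["promoter"] * n,
                "masks": [""] * n,
            },
            index=pd.Index([f"cg{i:03d}" for i in range(n)], name="probe_id"),
        )
    )


def _regions(intervals, label="RS"):
    return RegionSet(label, pd.DataFrame(intervals,
                                         columns=["chromosome", "start", "end"]))


class TestOverlapCounts:
    def test_query_equals_universe(self):
        ann = _annotation(6)
        rs = _regions([("chr1", 0, 250)])
        a, b, c, d = overlap_counts(ann.probe_ids, ann.probe_ids, ann, rs)
        assert (c, d) == (0, 0)
        assert a + b == 6

    def test_empty_region_set(self):
        ann = _annotation(5)
        rs = _regions([])
        a, b, c, d = overlap_counts(ann.probe_ids[:2], ann.probe_ids, ann, rs)
        assert (a, c) == (0, 0) and (b, d) == (2, 3)

    def test_half_open_convention(self):
        ann = _annotation(1)  # position 100
        inside = _regions([("chr1", 100, 101)])
        outside = _regions([("chr1", 101, 200)])
        assert overlap_counts(ann.probe_ids, ann.probe_ids, ann, inside)[0] == 1
        assert overlap_counts(ann.probe_ids, ann.probe_ids, ann, outside)[0] == 0

    def test_query_outside_universe_rejected(self):
        ann = _annotation(5)
        rs = _regions([])
        with pytest.raises(ValidationError):
            overlap_counts(["cgXXX"], ann.probe_ids, ann, rs)


def _fisher_oracle_p(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities."""
    n1, n2, k = a + b, c + d, a + c
    rv = stats.hypergeom(n1 + n2, n1, k)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisherEnrichment:
    def test_example_table(self):
        odds, lo, hi, p = fisher_enrichment((20, 80, 100, 900))
        assert odds == pytest.approx(2.25)
        assert p == pytest.approx(_fisher_oracle_p(20, 80, 100, 900), rel=1e-9)
        assert lo < 2.25 < hi

    def test_zero_overlap_boundary(self):
        odds, lo, hi, p = fisher_enrichment((0, 100, 50, 850))
        assert odds == 0.0
        assert p == pytest.approx(_fisher_oracle_p(0, 100, 50, 850), rel=1e-9)

    def test_identical_rates(self):
        odds, _, _, p = fisher_enrichment((10, 90, 10, 90))
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_reciprocal_odds_ratios(self):
        a, b, c, d = 30, 20, 15, 35
        or1 = fisher_enrichment((a, b, c, d))[0]
        or2 = fisher_enrichment((c, d, a, b))[0]
        assert or1 == pytest.approx(1 / or2)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment((0, 0, 5, 5))

    def test_random_tables_match_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b == 0 or c + d == 0:
                continue
            _, _, _, p = fisher_enrichment((a, b, c, d))
            assert p == pytest.approx(_fisher_oracle_p(a, b, c, d), rel=1e-8, abs=1e-12)


class TestStratifiedEnrichment:
    def _results(self, ann, sig_ids, coefs):
        table = pd.DataFrame(
            {"coefficient": 0.0, "q_value": 1.0}, index=ann.probe_ids
        )
        table.loc[sig_ids, "q_value"] = 0.001
        table.loc[sig_ids, "coefficient"] = coefs
        return table

    def test_sign_flip_swaps_strata(self):
        rng = np.random.default_rng(3)
        ann = _annotation(40, rng)
        rs = [_regions([("chr1", 0, 1500)], "A"), _regions([("chr1", 2000, 3000)], "B")]
        sig = ann.probe_ids[:10]
        coefs = rng.choice([-1.0, 1.0], 10)
        out1 = stratified_enrichment(self._results(ann, sig, coefs),
                                     ann.probe_ids, ann, rs)
        out2 = stratified_enrichment(self._results(ann, sig, -coefs),
                                     ann.probe_ids, ann, rs)
        for label in ("A", "B"):
            hyper1 = out1[(out1.direction == "hyper") & (out1.set_label == label)]
            hypo2 = out2[(out2.direction == "hypo") & (out2.set_label == label)]
            assert hyper1.iloc[0]["p_value"] == pytest.approx(hypo2.iloc[0]["p_value"])
            assert hyper1.iloc[0]["a"] == hypo2.iloc[0]["a"]

    def test_single_direction_skips_other(self):
        ann = _annotation(30)
        rs = [_regions([("chr1", 0, 1000)], "A")]
        out = stratified_enrichment(
            self._results(ann, ann.probe_ids[:5], np.ones(5)),
            ann.probe_ids, ann, rs,
        )
        hypo = out[out.direction == "hypo"]
        assert (hypo.status == "skipped").all()
        hyper = out[out.direction == "hyper"]
        assert (hyper.status == "ok").all()


class TestMatchedBackground:
    def test_profile_matches_query(self):
        rng = np.random.default_rng(7)
        ann = _annotation(200, rng)
        query = ann.probe_ids[:40]
        bg = sample_matched_background(query, ann.probe_ids, ann, seed=1)
        assert len(bg) == len(query)
        assert not bg.isin(query).any()
        q_prof = ann.data.loc[query, "island_relation"].value_counts()
        b_prof = ann.data.loc[bg, "island_relation"].value_counts()
        pd.testing.assert_series_equal(q_prof.sort_index(), b_prof.sort_index())

    def test_two_seeds_differ_same_profile(self):
        ann = _annotation(200)
        query = ann.probe_ids[:30]
        bg1 = sample_matched_background(query, ann.probe_ids, ann, seed=1)
        bg2 = sample_matched_background(query, ann.probe_ids, ann, seed=2)
        assert set(bg1) != set(bg2)
        p1 = ann.data.loc[bg1, "island_relation"].value_counts()
        p2 = ann.data.loc[bg2, "island_relation"].value_counts()
        pd.testing.assert_series_equal(p1.sort_index(), p2.sort_index())

    def test_insufficient_stratum_named(self):
        ann = _annotation(10, islands=["island"] * 6 + ["shore"] * 4)
        query = ann.probe_ids[:6]  # all islands; no non-query islands left
        with pytest.raises(ValidationError, match="island"):
            sample_matched_background(query, ann.probe_ids, ann, seed=0)


def _ks_oracle(x, y):
    grid = np.concatenate([x, y])
    fx = np.array([(x <= t).mean() for t in grid])
    fy = np.array([(y <= t).mean() for t in grid])
    return np.max(np.abs(fx - fy))


class TestKSCompare:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        D, p = ks_compare(x, x)
        assert D == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        D, _ = ks_compare([1, 2, 3], [10, 11])
        assert D == 1.0

    def test_breakpoint_oracle_example(self):
        D, _ = ks_compare([1, 2, 3], [1.5, 2.5])
        assert D == pytest.approx(_ks_oracle(np.array([1., 2, 3]),
                                             np.array([1.5, 2.5])))

    def test_random_samples_match_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(size=rng.integers(3, 15))
            D, _ = ks_compare(x, y)
            assert D == pytest.approx(_ks_oracle(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_compare([], [1.0])


class TestExpressionCorrelation:
    def _mat(self, values, index, samples):
        return pd.DataFrame(values, index=index, columns=samples)

    def test_monotone_association(self, rng):
        samples = [f"S{i}" for i in range(10)]
        m = rng.normal(size=10)
        M = MValueMatrix(self._mat([m], ["cg1"], samples))
        expr = self._mat([np.exp(m)], ["G1"], samples)
        out = cpg_expression_correlation(M, expr, {"cg1": "G1"})
        assert out.loc["cg1", "rho"] == pytest.approx(1.0)
        expr_neg = self._mat([-m], ["G1"], samples)
        out = cpg_expression_correlation(M, expr_neg, {"cg1": "G1"})
        assert out.loc["cg1", "rho"] == pytest.approx(-1.0)

    def test_null_p_uniform(self, rng):
        samples = [f"S{i}" for i in range(30)]
        ps = []
        for _ in range(300):
            M = MValueMatrix(self._mat([rng.normal(size=30)], ["cg1"], samples))
            expr = self._mat([rng.normal(size=30)], ["G1"], samples)
            ps.append(cpg_expression_correlation(M, expr, {"cg1": "G1"}).loc["cg1", "p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_shared_samples_rejected(self, rng):
        M = MValueMatrix(self._mat([rng.normal(size=3)], ["cg1"], ["A", "B", "C"]))
        expr = self._mat([[1.0, 2.0]], ["G1"], ["A", "B"])
        with pytest.raises(ValidationError):
            cpg_expression_correlation(M, expr, {"cg1": "G1"})
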