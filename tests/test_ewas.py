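import numpy as np
import pandas as pd
import pytest

from mixewas import (
    CpGAssociationModel,
    MValueMatrix,
    ModerationParams,
    SampleSheet,
    ValidationError,
    bh_qvalues,
    build_design,
    delta_coefficients,
    fit_cpg_models,
    moderate,
)
from mixewas.deconvolution import MixtureResults


def _sheet(n, rng, **extra):
    data = {"age": rng.uniform(20, 80, n), **extra}
    return SampleSheet(
        pd.DataFrame(data, index=pd.Index([f"S{i:02d}" for i in range(n)],
                                          name="sample_id"))
    )


def _mvalues(values, samples):
    return MValueMatrix(
        pd.DataFrame(
            values,
            index=[f"cg{i:03d}" for i in range(values.shape[0])],
            columns=samples,
        )
    )


def _mixture_from_omega(omega: pd.DataFrame) -> MixtureResults:
    K = omega.shape[1]
    mu = pd.DataFrame(
        np.full((4, K), 0.5), index=[f"cg{i:03d}" for i in range(4)],
        columns=omega.columns,
    )
    return MixtureResults(Mu=mu, Omega=omega, K=K,
                          objective_trace=np.array([1.0]), converged=True)


class TestBuildDesign:
    def test_smallest_component_dropped(self, rng):
        sheet = _sheet(10, rng)
        c1 = 0.5 + rng.uniform(-0.05, 0.05, 10)
        c3 = 0.2 + rng.uniform(-0.05, 0.05, 10)
        omega = pd.DataFrame(
            {"celltype_1": c1, "celltype_2": 1 - c1 - c3, "celltype_3": c3},
            index=sheet.sample_ids,
        )
        design = build_design(sheet, ["age"], mixture=_mixture_from_omega(omega))
        assert design.dropped_component == "celltype_3"
        assert "celltype_3" not in design.column_names
        assert {"celltype_1", "celltype_2"} <= set(design.column_names)

    def test_unadjusted_shape(self, rng):
        design = build_design(_sheet(12, rng), ["age"])
        assert design.values.shape == (12, 2)
        assert design.column_names == ["intercept", "age"]

    def test_missing_covariate_value_drops_sample(self, rng):
        parous = (np.arange(10) % 2).astype(float)
        sheet = _sheet(10, rng, parous=parous)
        sheet.data.loc["S03", "parous"] = np.nan
        design = build_design(sheet, ["age", "parous"])
        assert "S03" not in design.sample_ids
        assert design.n_dropped_samples == 1

    def test_rank_deficiency_names_columns(self, rng):
        sheet = _sheet(10, rng)
        sheet.data["age_copy"] = sheet.data["age"]
        with pytest.raises(ValidationError, match="age_copy"):
            build_design(sheet, ["age", "age_copy"])


class TestFitCpGModels:
    def test_constant_outcome(self, rng):
        sheet = _sheet(8, rng)
        design = build_design(sheet, ["age"])
        M = _mvalues(np.full((3, 8), 1.7), list(sheet.sample_ids))
        fits = fit_cpg_models(M, design, "age")
        np.testing.assert_allclose(fits["coefficient"], 0.0, atol=1e-12)
        np.testing.assert_allclose(fits["sigma2"], 0.0, atol=1e-12)

    def test_exact_linearity(self, rng):
        sheet = _sheet(8, rng)
        design = build_design(sheet, ["age"])
        ages = sheet.data["age"].to_numpy()
        M = _mvalues(np.vstack([2 * ages, -0.5 * ages]), list(sheet.sample_ids))
        fits = fit_cpg_models(M, design, "age")
        np.testing.assert_allclose(fits["coefficient"], [2.0, -0.5], atol=1e-10)
        np.testing.assert_allclose(fits["stderr"], 0.0, atol=1e-8)

    def test_against_normal_equations_oracle(self, rng):
        sheet = _sheet(8, rng)
        design = build_design(sheet, ["age"])
        Y = rng.normal(size=(5, 8))
        M = _mvalues(Y, list(sheet.sample_ids))
        fits = fit_cpg_models(M, design, "age")
        X = design.values
        for i in range(5):
            beta = np.linalg.solve(X.T @ X, X.T @ Y[i])
            resid = Y[i] - X @ beta
            s2 = resid @ resid / (8 - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            assert fits["coefficient"].iloc[i] == pytest.approx(beta[1], abs=1e-10)
            assert fits["stderr"].iloc[i] == pytest.approx(se, abs=1e-10)

    def test_overparameterised_rejected(self, rng):
        from mixewas import DesignMatrix

        samples = pd.Index(["S00", "S01", "S02"], name="sample_id")
        design = DesignMatrix(
            sample_ids=samples,
            column_names=["intercept", "age", "a"],
            values=np.column_stack([np.ones(3), rng.normal(size=(3, 2))]),
        )
        M = _mvalues(rng.normal(size=(2, 3)), list(samples))
        with pytest.raises(ValidationError):
            fit_cpg_models(M, design, "age")

    def test_design_with_too_many_parameters_rejected(self, rng):
        sheet = _sheet(3, rng, a=rng.normal(size=3), b=rng.normal(size=3))
        with pytest.raises(ValidationError):
            build_design(sheet, ["age", "a", "b"])


class TestModerate:
    def _fits(self, rng, m=400, n=20):
        sheet = _sheet(n, rng)
        design = build_design(sheet, ["age"])
        M = _mvalues(rng.normal(size=(m, n)), list(sheet.sample_ids))
        return fit_cpg_models(M, design, "age"), n

    def test_d0_zero_equals_ols_t(self, rng):
        fits, n = self._fits(rng, m=100)
        out = moderate(fits, ModerationParams(d0=0.0, s0_sq=1.0))
        t_ols = fits["coefficient"] / fits["stderr"]
        np.testing.assert_allclose(out["t_moderated"], t_ols, atol=1e-10)

    def test_d0_infinite_orders_by_coefficient(self, rng):
        fits, _ = self._fits(rng, m=50)
        out = moderate(fits, ModerationParams(d0=np.inf, s0_sq=0.5))
        order_t = np.argsort(np.abs(out["t_moderated"].to_numpy()))
        order_c = np.argsort(np.abs(fits["coefficient"].to_numpy()))
        np.testing.assert_array_equal(order_t, order_c)

    def test_null_type_one_error_calibrated(self, rng):
        fits, _ = self._fits(rng, m=500, n=20)
        out = moderate(fits)
        rate = (out["p_value"] < 0.05).mean()
        assert 0.03 < rate < 0.07

    def test_probe_order_invariance(self, rng):
        fits, _ = self._fits(rng, m=80)
        out = moderate(fits)
        shuffled = fits.sample(frac=1, random_state=1)
        out_shuffled = moderate(shuffled)
        np.testing.assert_allclose(
            out_shuffled.loc[out.index, "p_value"], out["p_value"], atol=1e-12
        )

    def test_degenerate_ensemble_rejected(self, rng):
        fits, _ = self._fits(rng, m=10)
        fits["sigma2"] = 0.0
        with pytest.raises(ValidationError):
            moderate(fits)


def _bh_oracle(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        vals = [t * m / (p <= t).sum() for t in p if t >= pi]
        q[i] = min(min(vals), 1.0)
    return q


class TestBHQvalues:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_examples(self, p, expected):
        np.testing.assert_allclose(bh_qvalues(p), expected, atol=1e-12)

    def test_against_exhaustive_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(bh_qvalues(p), _bh_oracle(p), atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=200)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_qvalues([0.5, 1.5])


class TestDeltaCoefficients:
    def test_identical_fits_zero(self, rng):
        sheet = _sheet(10, rng)
        design = build_design(sheet, ["age"])
        M = _mvalues(rng.normal(size=(20, 10)), list(sheet.sample_ids))
        res = CpGAssociationModel(M, design).fit("age")
        delta = delta_coefficients(res, res)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_positive_confounding_positive_delta(self):
        # composition tracks age; probe methylation tracks composition only
        rng = np.random.default_rng(5)
        n = 40
        omega1 = np.linspace(0.2, 0.8, n) + rng.normal(0, 0.02, n)
        age = 20 + 60 * (omega1 - 0.2) / 0.6 + rng.normal(0, 4, n)
        samples = pd.Index([f"S{i:02d}" for i in range(n)], name="sample_id")
        sheet = SampleSheet(pd.DataFrame({"age": age}, index=samples))
        omega = pd.DataFrame(
            {"celltype_1": omega1, "celltype_2": 1 - omega1}, index=samples
        )
        M = _mvalues(np.vstack([5 * omega1, rng.normal(size=n)]), list(samples))
        mixture = _mixture_from_omega(omega)
        adj = CpGAssociationModel(M, build_design(sheet, ["age"], mixture=mixture)).fit("age")
        unadj = CpGAssociationModel(M, build_design(sheet, ["age"])).fit("age")
        delta = delta_coefficients(adj, unadj)
        assert delta.iloc[0] > 0.02  # confounded probe
        assert abs(delta.iloc[1]) < abs(delta.iloc[0])

    def test_probe_mismatch_rejected(self, rng):
        sheet = _sheet(10, rng)
        design = build_design(sheet, ["age"])
        M = _mvalues(rng.normal(size=(6, 10)), list(sheet.sample_ids))
        res = CpGAssociationModel(M, design).fit("age")
        other = res.table.iloc[:4]
        with pytest.raises(ValidationError):
            delta_coefficients(res.table, other)
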