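"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure a reference-free,
cell-mixture-adjusted methylation association study assumes: a bulk tissue
whose beta values are a convex mixture of K latent cell-type methylomes,
per-subject mixture proportions on the simplex that drift with age,
a planted set of age-associated CpGs (majority gaining methylation with
age), truncated-Gaussian measurement noise on the beta scale, uniform
island/gene-region annotation on autosomes, region sets with planted
overlap enrichment, and paired tumour cohorts whose planted deviations are
exaggerated.  Every draw is controlled by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    GENE_REGIONS,
    ISLAND_RELATIONS,
    ProbeAnnotation,
    RegionSet,
    SampleSheet,
    ValidationError,
)
from .preprocess import beta_to_mvalue, mvalue_to_beta

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: Default fraction of planted age-CpGs that gain methylation with age.
DEFAULT_HYPER_FRACTION = 0.69
#: Default beta-scale noise standard deviation.
DEFAULT_NOISE_SD = 0.03
#: Default Dirichlet concentration for mixture proportions.
DEFAULT_CONCENTRATION = 30.0


@dataclass
class SimulationTruth:
    """Ground truth for one simulated cohort."""

    Mu_true: pd.DataFrame        # m x K cell-type methylomes (fractions)
    Omega_true: pd.DataFrame     # n x K mixture proportions (rows on simplex)
    age_slopes: pd.Series        # planted per-probe slope, M-units/year
    seed: int
    enriched_region_label: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        row_sums = self.Omega_true.to_numpy().sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-10):
            raise ValidationError("Omega_true rows must sum to 1")
        mu = self.Mu_true.to_numpy()
        if np.any((mu < 0) | (mu > 1)):
            raise ValidationError("Mu_true entries must lie in [0, 1]")
        if np.any(self.age_slopes.to_numpy() == 0):
            raise ValidationError("planted slopes must be nonzero")

    @property
    def age_cpg_ids(self) -> pd.Index:
        return self.age_slopes.index


def _probe_ids(m: int) -> pd.Index:
    return pd.Index([f"cg{i:07d}" for i in range(1, m + 1)], name="probe_id")


def _sample_ids(n: int, prefix: str = "S") -> pd.Index:
    return pd.Index([f"{prefix}{i:04d}" for i in range(1, n + 1)], name="sample_id")


def _mixture_mean(p0: np.ndarray, drift: float, ages: np.ndarray, center: float) -> np.ndarray:
    """Dirichlet mean shifted linearly with age along a fixed direction."""
    K = len(p0)
    u = np.zeros(K)
    if K >= 2:
        u[0], u[-1] = 1.0, -1.0
    mean = p0[None, :] + drift * (ages[:, None] - center) * u[None, :]
    if np.any(mean <= 0) or np.any(mean >= 1):
        raise ValidationError(
            "drift so large the Dirichlet mean leaves the simplex interior"
        )
    return mean


def simulate_cohort(
    n: int = 100,
    m: int = 2000,
    K: int = 3,
    age_range: tuple[float, float] = (18.0, 82.0),
    drift: float = 0.0,
    n_age_cpgs: int = 0,
    slope: float = 0.02,
    hyper_fraction: float = DEFAULT_HYPER_FRACTION,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
    shared_fraction: float = 0.7,
    cell_type_specific: bool = False,
    base_props=None,
):
    """Simulate a bulk-methylation cohort with full ground truth.

    Parameters
    ----------
    n, m, K
        Subjects, probes and latent cell types.
    age_range
        Subject ages drawn uniformly on this interval (years).
    drift
        Linear shift of the Dirichlet mixture mean per year of age: the
        first component gains ``drift`` per year, the last loses it.
    n_age_cpgs, slope, hyper_fraction
        Number of planted age-associated CpGs, their absolute effect on the
        logit2 (M-value) scale per year, and the fraction with positive
        sign (hypermethylating with age).
    noise_sd
        SD of the truncated-Gaussian beta-scale measurement noise.
    concentration
        Dirichlet concentration of the mixture proportions.
    shared_fraction
        Fraction of probes whose methylome is identical across cell types;
        the rest diverge and carry the deconvolution signal.
    cell_type_specific
        When True, planted age effects are weighted by the first cell
        type's proportion instead of acting on the bulk methylome.
    base_props
        Mean mixture proportions (length K, positive, normalised
        internally).  Default: decreasing sizes proportional to K..1.

    Returns
    -------
    (BetaMatrix, SampleSheet, ProbeAnnotation, SimulationTruth)
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if not 0 <= hyper_fraction <= 1:
        raise ValidationError("hyper_fraction must lie in [0, 1]")
    if n_age_cpgs > m:
        raise ValidationError("n_age_cpgs cannot exceed the probe count")
    rng = np.random.default_rng(seed)
    probes, samples = _probe_ids(m), _sample_ids(n)
    lo, hi = age_range
    center = 0.5 * (lo + hi)
    ages = rng.uniform(lo, hi, size=n)

    # Latent methylomes: a shared bimodal baseline, plus per-cell-type
    # divergence at a subset of probes.
    base = np.clip(rng.beta(0.4, 0.4, size=m), 0.02, 0.98)
    Mu = np.tile(base[:, None], (1, K))
    divergent = rng.random(m) >= shared_fraction
    if K > 1:
        Mu[divergent] = np.clip(
            rng.beta(0.3, 0.3, size=(int(divergent.sum()), K)), 0.02, 0.98
        )

    # Mixture proportions: Dirichlet around an age-shifted mean.  The
    # default mean is decreasing so components have distinct sizes; pass
    # balanced base_props with concentration = K for a flat Dirichlet
    # (near-pure specimens, the convex-NMF identifiability regime).
    if base_props is None:
        p0 = np.arange(K, 0, -1, dtype=float)
    else:
        p0 = np.asarray(base_props, dtype=float)
        if len(p0) != K or np.any(p0 <= 0):
            raise ValidationError("base_props must be K positive values")
    p0 = p0 / p0.sum()
    if K == 1:
        Omega = np.ones((n, 1))
    else:
        mean = _mixture_mean(p0, drift, ages, center)
        Omega = rng.dirichlet(np.ones(K), size=n)  # placeholder shape
        for i in range(n):
            Omega[i] = rng.dirichlet(concentration * mean[i])

    bulk = Omega @ Mu.T  # n x m expected betas

    # Planted age effects on the logit2 scale.  Age-drift CpGs sit at
    # intermediate methylation in vivo (island shores, enhancers), so
    # planted probes are drawn from the mid-methylation range where a
    # logit-scale shift is observable over beta-scale noise.
    slopes = pd.Series(dtype=float)
    if n_age_cpgs > 0:
        eligible = np.flatnonzero((Mu.min(axis=1) >= 0.15) & (Mu.max(axis=1) <= 0.85))
        if len(eligible) < n_age_cpgs:
            eligible = np.arange(m)
        planted = rng.choice(eligible, size=n_age_cpgs, replace=False)
        n_hyper = int(round(hyper_fraction * n_age_cpgs))
        signs = np.concatenate([np.ones(n_hyper), -np.ones(n_age_cpgs - n_hyper)])
        rng.shuffle(signs)
        slopes = pd.Series(signs * slope, index=probes[planted])
        shift = slopes.to_numpy()[None, :] * (ages[:, None] - center)
        if cell_type_specific:
            shift = shift * Omega[:, [0]] * K
        mvals = beta_to_mvalue(np.clip(bulk[:, planted], 1e-4, 1 - 1e-4))
        bulk[:, planted] = mvalue_to_beta(mvals + shift)

    betas = np.clip(bulk + rng.normal(0.0, noise_sd, size=bulk.shape), 0.0, 1.0)
    bm = BetaMatrix(pd.DataFrame(betas.T, index=probes, columns=samples))

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "age": ages,
                "bmi": np.clip(rng.normal(27.6, 5.5, size=n), 15.0, 55.0),
                "parous": rng.binomial(1, 0.56, size=n),
                "family_history": np.where(
                    rng.random(n) < 0.1, np.nan, rng.binomial(1, 0.51, size=n)
                ),
                "race": rng.choice(
                    ["white", "hispanic", "african_american"],
                    size=n,
                    p=[0.86, 0.09, 0.05],
                ),
            },
            index=samples,
        )
    )

    # Island relation tracks baseline methylation, as on the real array
    # (islands unmethylated, open sea methylated): this is what makes an
    # island-matched background comparable in M-value variance.
    base_level = Mu.mean(axis=1)
    island_relation = np.select(
        [base_level < 0.15, base_level < 0.5, base_level < 0.85],
        ["island", "shore", "shelf"],
        default="open_sea",
    )
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": rng.choice(AUTOSOMES, size=m),
                "position": rng.integers(10_000, 200_000_000, size=m),
                "island_relation": island_relation,
                "gene_region": rng.choice(GENE_REGIONS, size=m),
                "gene_symbol": [f"GENE{i % 997:04d}" for i in range(m)],
                "masks": [""] * m,
            },
            index=probes,
        )
    )

    truth = SimulationTruth(
        Mu_true=pd.DataFrame(Mu, index=probes, columns=[f"celltype_{k+1}" for k in range(K)]),
        Omega_true=pd.DataFrame(Omega, index=samples, columns=[f"celltype_{k+1}" for k in range(K)]),
        age_slopes=slopes,
        seed=seed,
        params={
            "n": n,
            "m": m,
            "K": K,
            "age_range": (float(lo), float(hi)),
            "age_center": center,
            "drift": drift,
            "slope": slope,
            "hyper_fraction": hyper_fraction,
            "noise_sd": noise_sd,
            "concentration": concentration,
            "base_props": p0.tolist(),
            "cell_type_specific": cell_type_specific,
        },
    )
    return bm, sheet, ann, truth


def simulate_region_sets(
    ann: ProbeAnnotation,
    n_sets: int,
    planted_set_fraction: float,
    truth: SimulationTruth,
    seed: int = 0,
    background_rate: float = 0.1,
    half_width: int = 100,
) -> list[RegionSet]:
    """Region sets with one planted enrichment.

    One randomly chosen set covers planted age-CpGs at rate
    ``planted_set_fraction`` and all other probes at ``background_rate``;
    the remaining sets cover every probe at the background rate.  The
    planted label is recorded on ``truth.enriched_region_label``.
    """
    if not 0 <= planted_set_fraction <= 1:
        raise ValidationError("planted_set_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [f"TF{i:02d}" for i in range(1, n_sets + 1)]
    planted_label = labels[int(rng.integers(n_sets))]
    is_age = ann.probe_ids.isin(truth.age_cpg_ids)
    positions = ann.data["position"].to_numpy()
    chroms = ann.data["chromosome"].to_numpy()
    sets = []
    for label in labels:
        member = rng.random(len(ann.probe_ids)) < background_rate
        if label == planted_label:
            member[is_age] = rng.random(int(is_age.sum())) < planted_set_fraction
        idx = np.flatnonzero(member)
        intervals = pd.DataFrame(
            {
                "chromosome": chroms[idx],
                "start": np.maximum(positions[idx] - half_width, 0),
                "end": positions[idx] + half_width,
            }
        )
        sets.append(RegionSet(label, intervals))
    truth.enriched_region_label = planted_label
    return sets


def simulate_tumor_normal(
    normal: BetaMatrix,
    truth: SimulationTruth,
    exaggeration: float = 3.0,
    n_tumors: int = 50,
    seed: int = 0,
    age_range: tuple[float, float] | None = None,
    progression_years: float = 20.0,
):
    """Tumour cohort from the normal generative model with exaggerated
    planted deviations.

    Tumour subjects are drawn from the same mixture/methylome model and
    age distribution as the matched normal cohort.  At planted age-CpGs
    the tumour carries, on top of the normal age deviation, an extra
    deregulation of ``(exaggeration - 1) * slope * progression_years`` on
    the logit scale — i.e. the tumour behaves as if it had drifted
    ``progression_years`` further along each planted CpG's ageing
    trajectory, scaled by the exaggeration multiplier.  With
    ``exaggeration = 1`` the tumour model is identical to the normal one.
    """
    if exaggeration < 1:
        raise ValidationError("exaggeration must be >= 1")
    rng = np.random.default_rng(seed)
    p = truth.params
    K = p["K"]
    lo, hi = p["age_range"]
    center = p["age_center"]
    if age_range is None:
        age_range = (lo, hi)
    samples = _sample_ids(n_tumors, prefix="T")
    probes = truth.Mu_true.index
    ages = rng.uniform(age_range[0], age_range[1], size=n_tumors)
    Mu = truth.Mu_true.to_numpy()
    p0 = np.asarray(p["base_props"])
    if K == 1:
        Omega = np.ones((n_tumors, 1))
    else:
        mean = _mixture_mean(p0, p["drift"], ages, center)
        Omega = np.empty((n_tumors, K))
        for i in range(n_tumors):
            Omega[i] = rng.dirichlet(p["concentration"] * mean[i])
    bulk = Omega @ Mu.T
    if len(truth.age_slopes):
        planted_pos = probes.get_indexer(truth.age_slopes.index)
        slopes_row = truth.age_slopes.to_numpy()[None, :]
        shift = slopes_row * (ages[:, None] - center) + (
            (exaggeration - 1.0) * slopes_row * progression_years
        )
        mvals = beta_to_mvalue(np.clip(bulk[:, planted_pos], 1e-4, 1 - 1e-4))
        bulk[:, planted_pos] = mvalue_to_beta(mvals + shift)
    betas = np.clip(bulk + rng.normal(0.0, p["noise_sd"], size=bulk.shape), 0.0, 1.0)
    bm = BetaMatrix(pd.DataFrame(betas.T, index=probes, columns=samples))
    sheet = SampleSheet(pd.DataFrame({"age": ages}, index=samples))
    return bm, sheet


def make_synthetic_clock(
    n_cpgs: int = 30,
    age_range: tuple[float, float] = (20.0, 60.0),
    beta_range: tuple[float, float] = (0.2, 0.8),
    name: str = "synthetic-clock",
    transform: dict | None = None,
    kind: str = "linear",
):
    """Construct an invertible synthetic clock for testing.

    Every clock CpG shares a linear beta-vs-age trajectory spanning
    ``beta_range`` over ``age_range``; weights and intercept are chosen so
    the linear predictor equals the (transformed) chronological age.
    """
    from .clocks import EpigeneticClock

    probes = pd.Index([f"clk{i:04d}" for i in range(1, n_cpgs + 1)], name="probe_id")
    if kind == "mean":
        return EpigeneticClock(
            name=name,
            coefficients=pd.Series(1.0 / n_cpgs, index=probes),
            intercept=0.0,
            transform={"type": "identity"},
            kind="mean",
        )
    (alo, ahi), (blo, bhi) = age_range, beta_range
    b = (bhi - blo) / (ahi - alo)           # beta gained per transformed-age unit
    a = blo - b * alo
    weights = pd.Series(1.0 / (n_cpgs * b), index=probes)
    intercept = -a / b
    return EpigeneticClock(
        name=name,
        coefficients=weights,
        intercept=intercept,
        transform=transform or {"type": "identity"},
        kind="linear",
    )


def simulate_clock_cohort(
    clock,
    ages,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_extra_probes: int = 50,
) -> BetaMatrix:
    """Beta matrix whose clock prediction equals the target ages.

    Clock CpG betas are set to the (uniform) value that makes the clock's
    linear predictor equal the transformed target age, then perturbed by
    ``noise_sd``; additional non-clock probes carry unrelated noise.
    """
    from .clocks import forward_transform

    ages = np.asarray(ages, dtype=float)
    if len(clock.coefficients) == 0:
        raise ValidationError("clock has no CpGs")
    rng = np.random.default_rng(seed)
    samples = _sample_ids(len(ages), prefix="C")
    if clock.kind == "mean":
        x = np.asarray(ages, dtype=float)  # target score directly
    else:
        lp = forward_transform(ages, clock.transform)
        total_w = clock.coefficients.sum()
        if total_w == 0:
            raise ValidationError("clock weights sum to zero; cannot invert")
        x = (lp - clock.intercept) / total_w
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("target ages outside the clock's calibrated range")
    J = len(clock.coefficients)
    clock_block = np.tile(x[None, :], (J, 1))
    if noise_sd > 0:
        clock_block = np.clip(
            clock_block + rng.normal(0.0, noise_sd, size=clock_block.shape), 0.0, 1.0
        )
    extra_ids = pd.Index(
        [f"ncg{i:05d}" for i in range(1, n_extra_probes + 1)], name="probe_id"
    )
    extra_block = np.clip(
        rng.beta(2, 2, size=(n_extra_probes, 1))
        + rng.normal(0.0, max(noise_sd, 0.01), size=(n_extra_probes, len(ages))),
        0.0,
        1.0,
    )
    data = pd.DataFrame(
        np.vstack([clock_block, extra_block]),
        index=clock.coefficients.index.append(extra_ids),
        columns=samples,
    )
    return BetaMatrix(data)
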