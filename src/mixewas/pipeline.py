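"""Orchestration of the discovery, validation and progression analyses.

``run_discovery`` executes the full reference-free workflow on one
cohort: probe filtering, bootstrap selection of the number of cell
types, mixture fitting, permutation testing of proportion-covariate
associations, cell-adjusted and unadjusted moderated EWAS with delta
coefficients, and direction-stratified region enrichment.  All stage
outputs are plain TSV/JSON files plus a run manifest, so any stage can
be rerun in isolation and identical configs reproduce identical bytes.

``run_validation`` replicates a discovery CpG set in an independent
cohort (own deconvolution, adjusted model restricted to the discovery
CpGs, direction concordance, nominal and Bonferroni counts).
``run_progression`` contrasts tumour-vs-normal effect sizes at the
query CpGs against an annotation-matched random background with a
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError
from .deconvolution import ReferenceFreeMixture, select_k
from .enrichment import ks_compare, sample_matched_background, stratified_enrichment
from .ewas import (
    CpGAssociationModel,
    bh_qvalues,
    build_design,
    delta_coefficients,
    fit_cpg_models,
    moderate,
)
from .io import load_dataset, read_region_sets
from .mixture_association import test_metadata_association
from .preprocess import filter_probes, select_most_variable, to_mvalues

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a discovery run needs, round-trippable to YAML."""

    beta_path: str
    sample_path: str
    annotation_path: str
    output_dir: str
    regions_path: str | None = None
    covariates: list[str] = field(default_factory=lambda: ["age"])
    k_grid: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    n_boot: int = 100
    top_variable: int = 10_000
    q_threshold: float = 0.01
    permutations: int = 1000
    seeds: dict = field(
        default_factory=lambda: {
            "select_k": 1,
            "fit_mixture": 2,
            "permutation": 3,
            "background": 4,
        }
    )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.8g")


def discovery_analysis(
    bm: BetaMatrix,
    sheet: SampleSheet,
    ann: ProbeAnnotation,
    region_sets=None,
    covariates=("age",),
    k_grid=(1, 2, 3, 4, 5),
    n_boot: int = 100,
    top_variable: int = 10_000,
    q_threshold: float = 0.01,
    permutations: int = 1000,
    seeds: dict | None = None,
) -> dict:
    """In-memory discovery workflow; returns a results bundle dict."""
    seeds = {"select_k": 1, "fit_mixture": 2, "permutation": 3, "background": 4, **(seeds or {})}
    bundle: dict = {"stages": []}
    filtered = filter_probes(bm, ann).drop_incomplete_probes()
    bundle["n_probes_retained"] = filtered.n_probes
    bundle["stages"].append("filter_probes")
    logger.info("filter: %d -> %d probes", bm.n_probes, filtered.n_probes)

    k_grid = sorted(set(int(k) for k in k_grid))
    if len(k_grid) > 1:
        ksel = select_k(
            filtered, k_grid, n_boot=n_boot, top_variable=top_variable,
            seed=seeds["select_k"],
        )
        chosen_k = ksel.chosen_K
        bundle["k_selection"] = ksel
    else:
        chosen_k = k_grid[0]
        bundle["k_selection"] = None
    bundle["chosen_K"] = chosen_k
    bundle["stages"].append("select_k")

    working = select_most_variable(filtered, min(top_variable, filtered.n_probes))
    mixture = ReferenceFreeMixture(working).fit(chosen_k, seed=seeds["fit_mixture"])
    bundle["mixture"] = mixture
    bundle["stages"].append("fit_mixture")

    bundle["mixture_association"] = {}
    for cov in covariates:
        col = sheet.data.get(cov)
        if col is None or col.dtype == object:
            logger.info("skipping mixture association for non-numeric %r", cov)
            continue
        bundle["mixture_association"][cov] = test_metadata_association(
            working, sheet, cov, k_grid, B=permutations,
            seed=seeds["permutation"], top_variable=top_variable,
        )
    bundle["stages"].append("mixture_association")

    mvalues = to_mvalues(filtered)
    design_adj = build_design(sheet, list(covariates), mixture=mixture)
    design_unadj = build_design(sheet, list(covariates), mixture=None)
    bundle["ewas"] = {}
    bundle["delta"] = {}
    for cov in covariates:
        if cov not in design_adj.column_names:
            continue  # categorical covariates expand; skip per-term extraction
        adjusted = CpGAssociationModel(mvalues, design_adj).fit(cov)
        unadjusted = CpGAssociationModel(mvalues, design_unadj).fit(cov)
        bundle["ewas"][cov] = {"adjusted": adjusted, "unadjusted": unadjusted}
        bundle["delta"][cov] = delta_coefficients(adjusted, unadjusted)
    bundle["stages"].extend(["ewas", "delta"])

    bundle["enrichment"] = {}
    if region_sets:
        universe = filtered.probe_ids
        for cov, models in bundle["ewas"].items():
            bundle["enrichment"][cov] = stratified_enrichment(
                models["adjusted"], universe, ann, region_sets,
                q_threshold=q_threshold,
            )
    bundle["stages"].append("stratified_enrichment")
    return bundle


def run_discovery(config: PipelineConfig) -> dict:
    """Load inputs per config, run the discovery workflow, persist outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        bm, sheet, ann = load_dataset(
            config.beta_path, config.sample_path, config.annotation_path
        )
        region_sets = (
            read_region_sets(config.regions_path) if config.regions_path else None
        )
        stage = "analysis"
        bundle = discovery_analysis(
            bm, sheet, ann, region_sets,
            covariates=config.covariates,
            k_grid=config.k_grid,
            n_boot=config.n_boot,
            top_variable=config.top_variable,
            q_threshold=config.q_threshold,
            permutations=config.permutations,
            seeds=config.seeds,
        )
        stage = "write"
        mixture = bundle["mixture"]
        _write_tsv(mixture.Mu, out / "mu.tsv", "probe_id")
        _write_tsv(mixture.Omega, out / "omega.tsv", "sample_id")
        if bundle["k_selection"] is not None:
            (out / "k_selection.json").write_text(
                json.dumps(bundle["k_selection"].to_dict(), indent=2)
            )
        for cov, res in bundle["mixture_association"].items():
            (out / f"mixture_assoc_{cov}.json").write_text(
                json.dumps(res.to_dict(), indent=2)
            )
        counts = {}
        for cov, models in bundle["ewas"].items():
            delta = bundle["delta"][cov]
            for tag, res in models.items():
                table = res.table.assign(delta=delta)
                _write_tsv(table, out / f"ewas_{cov}_{tag}.tsv", "probe_id")
                counts[f"{cov}_{tag}_q{config.q_threshold:g}"] = int(
                    len(res.significant(config.q_threshold))
                )
        for cov, table in bundle["enrichment"].items():
            table.to_csv(out / f"enrichment_{cov}.tsv", sep="\t", index=False,
                         float_format="%.8g")
        manifest = {
            "package_version": __version__,
            "seeds": config.seeds,
            "stages": bundle["stages"],
            "n_samples": int(bm.n_samples),
            "n_probes_input": int(bm.n_probes),
            "n_probes_retained": int(bundle["n_probes_retained"]),
            "chosen_K": int(bundle["chosen_K"]),
            "significant_counts": counts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
        return bundle
    except Exception:
        logger.error("discovery pipeline failed at stage %r", stage)
        raise


@dataclass
class ValidationResult:
    """Replication of a discovery CpG set in an independent cohort."""

    table: pd.DataFrame
    concordance: float           # fraction with the discovery sign
    n_nominal: int               # p < 0.05 and concordant direction
    n_bonferroni: int            # p < 0.05 / n_discovery
    bonferroni_threshold: float
    missing_cpgs: list

    def summary(self) -> str:
        return (
            f"Validation on {len(self.table)} of "
            f"{len(self.table) + len(self.missing_cpgs)} discovery CpGs\n"
            f"  direction concordance: {self.concordance:.1%}\n"
            f"  concordant at nominal P < 0.05: {self.n_nominal}\n"
            f"  significant at Bonferroni P < {self.bonferroni_threshold:.3g}: "
            f"{self.n_bonferroni}"
        )


def run_validation(
    bm: BetaMatrix,
    sheet: SampleSheet,
    discovery,
    covariate: str = "age",
    K: int | None = None,
    k_grid=(1, 2, 3, 4, 5),
    n_boot: int = 50,
    top_variable: int = 10_000,
    seed: int = 0,
) -> ValidationResult:
    """Reference-free adjusted model restricted to the discovery CpGs.

    ``discovery`` is an EwasResults or a coefficient table indexed by the
    discovery CpGs (signs define concordance).  Deconvolution uses the
    validation cohort's own most-variable CpGs.  The Bonferroni threshold
    is 0.05 divided by the *discovery* set size.
    """
    disc_table = discovery.table if hasattr(discovery, "table") else discovery
    discovery_cpgs = pd.Index(disc_table.index)
    shared = discovery_cpgs.intersection(bm.probe_ids)
    missing = discovery_cpgs.difference(bm.probe_ids).tolist()
    if len(shared) == 0:
        raise ValidationError("no discovery CpGs present in the validation cohort")
    if missing:
        logger.info("%d discovery CpGs absent from validation cohort", len(missing))
    complete = bm.drop_incomplete_probes()
    working = select_most_variable(complete, min(top_variable, complete.n_probes))
    if K is None:
        K = select_k(complete, k_grid, n_boot=n_boot, top_variable=top_variable,
                     seed=seed).chosen_K
    mixture = ReferenceFreeMixture(working).fit(K, seed=seed)
    mvalues = to_mvalues(complete.select_probes(shared))
    design = build_design(sheet, [covariate], mixture=mixture)
    res = CpGAssociationModel(mvalues, design).fit(covariate)
    table = res.table.copy()
    table["discovery_coefficient"] = disc_table.loc[shared, "coefficient"]
    concordant = np.sign(table["coefficient"]) == np.sign(table["discovery_coefficient"])
    table["concordant"] = concordant
    bonf = 0.05 / len(discovery_cpgs)
    return ValidationResult(
        table=table,
        concordance=float(concordant.mean()),
        n_nominal=int((concordant & (table["p_value"] < 0.05)).sum()),
        n_bonferroni=int((table["p_value"] < bonf).sum()),
        bonferroni_threshold=bonf,
        missing_cpgs=missing,
    )


@dataclass
class ProgressionResult:
    """Tumour-vs-normal contrast at query CpGs vs matched background."""

    table: pd.DataFrame          # per-CpG status coefficient / p for query+matched
    ks_statistic: float
    ks_p: float
    frac_query_significant: float
    frac_matched_significant: float
    matched_cpgs: pd.Index

    def summary(self) -> str:
        return (
            f"Progression contrast: KS D = {self.ks_statistic:.3f}, "
            f"p = {self.ks_p:.3g}\n"
            f"  query CpGs at P < 0.05: {self.frac_query_significant:.1%}\n"
            f"  matched background at P < 0.05: {self.frac_matched_significant:.1%}"
        )


def run_progression(
    normal: BetaMatrix,
    normal_sheet: SampleSheet,
    tumor: BetaMatrix,
    tumor_sheet: SampleSheet,
    query_cpgs,
    ann: ProbeAnnotation,
    seed: int = 0,
    match_field: str = "island_relation",
) -> ProgressionResult:
    """Age-adjusted moderated tumour-vs-normal models, KS vs matched CpGs.

    Both cohorts must carry subject age (the models adjust for it) and
    share the query CpGs.  Effect sizes at the query are compared with an
    island-relation-matched random CpG set drawn from the shared universe.
    """
    if "age" not in normal_sheet.data.columns or "age" not in tumor_sheet.data.columns:
        raise ValidationError("both cohorts need an age column for adjustment")
    query_cpgs = pd.Index(query_cpgs)
    universe = normal.probe_ids.intersection(tumor.probe_ids)
    query = query_cpgs.intersection(universe)
    if len(query) == 0:
        raise ValidationError("cohorts share none of the query CpGs")
    tumor_data = tumor.data.loc[universe]
    if tumor_data.columns.intersection(normal.sample_ids).any():
        tumor_data = tumor_data.add_suffix("_tumor")
    combined = pd.concat([normal.data.loc[universe], tumor_data], axis=1)
    status = np.concatenate([np.zeros(normal.n_samples), np.ones(tumor.n_samples)])
    ages = np.concatenate(
        [
            normal_sheet.data.loc[normal.sample_ids, "age"].to_numpy(dtype=float),
            tumor_sheet.data.loc[tumor.sample_ids, "age"].to_numpy(dtype=float),
        ]
    )
    sheet = SampleSheet(
        pd.DataFrame({"age": ages, "status": status}, index=combined.columns)
    )
    mvalues = to_mvalues(BetaMatrix(combined))
    design = build_design(sheet, ["status", "age"])
    fits = fit_cpg_models(mvalues, design, "status")
    moderated = moderate(fits)
    moderated["q_value"] = bh_qvalues(moderated["p_value"].to_numpy())
    matched = sample_matched_background(query, universe, ann.for_probes(universe),
                                        seed=seed, match_field=match_field)
    coef_q = moderated.loc[query, "coefficient"].to_numpy()
    coef_m = moderated.loc[matched, "coefficient"].to_numpy()
    D, p = ks_compare(coef_q, coef_m)
    sub = moderated.loc[query.append(pd.Index(matched))].copy()
    sub["group"] = ["query"] * len(query) + ["matched"] * len(matched)
    return ProgressionResult(
        table=sub,
        ks_statistic=D,
        ks_p=p,
        frac_query_significant=float((moderated.loc[query, "p_value"] < 0.05).mean()),
        frac_matched_significant=float((moderated.loc[matched, "p_value"] < 0.05).mean()),
        matched_cpgs=pd.Index(matched),
    )
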