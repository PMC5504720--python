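"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated with a header row.  Beta matrices carry probes
as rows (first column ``probe_id``) and samples as columns.  Region sets
use BED3+name (0-based, half-open intervals).  Clocks are a coefficient
TSV plus a JSON transform spec.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    ProbeAnnotation,
    RegionSet,
    SampleSheet,
    ValidationError,
)


def read_beta_matrix(path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"{path}: beta value {values[i, j]:g} outside [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    bm.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", keep_default_na=False,
                     na_values=[""])
    df["masks"] = df.get("masks", pd.Series("", index=df.index)).fillna("")
    return ProbeAnnotation(df)


def write_annotation(ann: ProbeAnnotation, path) -> None:
    ann.data.to_csv(path, sep="\t", index_label="probe_id")


def read_region_sets(path) -> list[RegionSet]:
    """Read BED3+name; one RegionSet per distinct name, file order kept."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "label"],
        comment="#",
    )
    if df["label"].isna().any():
        raise ValidationError(f"{path}: BED file requires a name (4th) column")
    sets = []
    for label in df["label"].unique():
        sub = df.loc[df["label"] == label, ["chromosome", "start", "end"]]
        sets.append(RegionSet(str(label), sub.reset_index(drop=True)))
    return sets


def write_region_sets(region_sets, path) -> None:
    rows = []
    for rs in region_sets:
        for _, iv in rs.intervals.iterrows():
            rows.append((iv["chromosome"], int(iv["start"]), int(iv["end"]), rs.label))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def load_dataset(beta_path, sample_path, annotation_path):
    """Load and cross-validate a (betas, sample sheet, annotation) bundle.

    IDs are aligned across the three files; samples or probes present in
    one file but absent from its partner raise an error naming the
    offenders.  The returned sheet and annotation are reordered to match
    the beta matrix.
    """
    bm = read_beta_matrix(beta_path)
    sheet = read_sample_sheet(sample_path)
    ann = read_annotation(annotation_path)
    missing_samples = [s for s in bm.sample_ids if s not in sheet.data.index]
    if missing_samples:
        raise ValidationError(
            f"samples in beta matrix but not sample sheet: {missing_samples[:5]}"
        )
    extra_samples = [s for s in sheet.data.index if s not in bm.sample_ids]
    if extra_samples:
        raise ValidationError(
            f"samples in sample sheet but not beta matrix: {extra_samples[:5]}"
        )
    missing_probes = [p for p in bm.probe_ids if p not in ann.data.index]
    if missing_probes:
        raise ValidationError(
            f"probes lacking annotation: {missing_probes[:5]}"
        )
    return bm, sheet.for_samples(bm.sample_ids), ann.for_probes(bm.probe_ids)


def read_clock(coef_path, transform_path):
    """Read a clock coefficient TSV (probe_id, weight) + JSON transform."""
    from .clocks import EpigeneticClock

    coef = pd.read_csv(coef_path, sep="\t", index_col="probe_id")["weight"]
    with open(transform_path) as fh:
        spec = json.load(fh)
    return EpigeneticClock(
        name=spec.get("name", Path(str(coef_path)).stem),
        coefficients=coef,
        intercept=float(spec.get("intercept", 0.0)),
        transform=spec.get("transform", {"type": "identity"}),
        kind=spec.get("kind", "linear"),
    )


def write_clock(clock, coef_path, transform_path) -> None:
    clock.coefficients.rename("weight").to_csv(coef_path, sep="\t", index_label="probe_id")
    with open(transform_path, "w") as fh:
        json.dump(
            {
                "name": clock.name,
                "intercept": clock.intercept,
                "transform": clock.transform,
                "kind": clock.kind,
            },
            fh,
            indent=2,
        )
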