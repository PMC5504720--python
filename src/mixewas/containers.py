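"""In-memory containers for methylation array data.

A methylation *beta value* is the fraction of methylated signal at one CpG
site, constrained to [0, 1].  For linear modelling the logit2 transform of
beta (the *M value*) is preferred because it stabilises the variance near
the boundaries.  Containers here are thin, validated wrappers around pandas
DataFrames: probes index the rows, samples index the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
GENE_REGIONS = ("promoter", "exon", "intron", "intergenic")
MASK_FLAGS = ("sex_chromosome", "cross_reactive", "snp_overlap")
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


class ValidationError(ValueError):
    """Raised when an input violates a container contract."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation fractions in [0, 1].

    Parameters
    ----------
    data : DataFrame
        Probes as rows (index = probe ids), samples as columns.  Missing
        values are allowed on construction but must be dropped (see
        :meth:`drop_incomplete_probes`) before deconvolution or modelling.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if np.any(bad & ~np.isnan(values)):
            i, j = np.argwhere(bad & ~np.isnan(values))[0]
            raise ValidationError(
                f"beta value {values[i, j]:g} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_probes(self, probe_ids) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"unknown probes requested: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probe_ids)])

    def select_samples(self, sample_ids) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown samples requested: {missing[:5]}")
        return BetaMatrix(self.data[list(sample_ids)])

    def drop_incomplete_probes(self) -> "BetaMatrix":
        """Drop any probe with at least one missing beta value."""
        return BetaMatrix(self.data.dropna(axis=0))


@dataclass
class MValueMatrix:
    """CpG-by-sample matrix of logit2-transformed betas (log2 units)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values[~np.isnan(values)])):
            raise ValidationError("M values must be finite after clipping")
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation.

    Columns: ``chromosome``, ``position`` (1-based bp), ``island_relation``,
    ``gene_region``, optional ``gene_symbol``, and ``masks`` (a
    semicolon-joined set of exclusion flags drawn from :data:`MASK_FLAGS`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "position", "island_relation", "gene_region"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.data.index, "probe ids")
        bad_island = set(self.data["island_relation"]) - set(ISLAND_RELATIONS)
        if bad_island:
            raise ValidationError(f"unknown island_relation values: {sorted(bad_island)}")
        bad_region = set(self.data["gene_region"]) - set(GENE_REGIONS)
        if bad_region:
            raise ValidationError(f"unknown gene_region values: {sorted(bad_region)}")
        if "masks" not in self.data.columns:
            self.data = self.data.assign(masks="")
        flags = set()
        for m in self.data["masks"].fillna(""):
            flags.update(f for f in str(m).split(";") if f)
        bad_flags = flags - set(MASK_FLAGS)
        if bad_flags:
            raise ValidationError(f"unknown mask flags: {sorted(bad_flags)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def mask_sets(self) -> pd.Series:
        """Masks column parsed into frozensets of flags."""
        return self.data["masks"].fillna("").map(
            lambda m: frozenset(f for f in str(m).split(";") if f)
        )

    def for_probes(self, probe_ids) -> "ProbeAnnotation":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"probes lacking annotation: {missing[:5]}")
        return ProbeAnnotation(self.data.loc[list(probe_ids)])


@dataclass
class SampleSheet:
    """Subject metadata: one row per sample.

    ``age`` (years, required, positive); optional risk factors ``bmi``
    (kg/m^2), ``parous`` (0/1), ``family_history`` (0/1), ``race``
    (categorical).  Missing entries stay as NaN and are dropped, with a
    logged count, only when a model requests the affected covariate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "age" not in self.data.columns:
            raise ValidationError("sample sheet requires an 'age' column")
        _check_unique(self.data.index, "sample ids")
        ages = self.data["age"].to_numpy(dtype=float)
        if np.any(np.isnan(ages)) or np.any(ages <= 0):
            raise ValidationError("age must be present and > 0 for every sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def for_samples(self, sample_ids) -> "SampleSheet":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples missing from sheet: {missing[:5]}")
        return SampleSheet(self.data.loc[list(sample_ids)])


@dataclass
class RegionSet:
    """Labelled genomic intervals (BED convention: 0-based, half-open).

    A probe at annotated position ``p`` is counted inside an interval
    ``(chrom, start, end)`` iff ``start <= p < end``.
    """

    label: str
    intervals: pd.DataFrame  # columns: chromosome, start, end

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("region set label must be nonempty")
        required = {"chromosome", "start", "end"}
        if not required <= set(self.intervals.columns):
            raise ValidationError(f"intervals need columns {sorted(required)}")
        if len(self.intervals) and not (
            self.intervals["start"] < self.intervals["end"]
        ).all():
            raise ValidationError("every interval must satisfy start < end")
        self._merged: dict[str, np.ndarray] | None = None

    def _merged_by_chrom(self) -> dict[str, np.ndarray]:
        """Merged, sorted intervals per chromosome for fast point queries."""
        if self._merged is None:
            merged: dict[str, np.ndarray] = {}
            for chrom, sub in self.intervals.groupby("chromosome", sort=False):
                ivs = sub[["start", "end"]].to_numpy(dtype=np.int64)
                ivs = ivs[np.argsort(ivs[:, 0], kind="stable")]
                out = []
                for s, e in ivs:
                    if out and s <= out[-1][1]:
                        out[-1][1] = max(out[-1][1], e)
                    else:
                        out.append([s, e])
                merged[str(chrom)] = np.asarray(out, dtype=np.int64)
            self._merged = merged
        return self._merged

    def contains(self, chromosomes, positions) -> np.ndarray:
        """Vectorised membership test for probe points."""
        chromosomes = np.asarray(chromosomes, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        result = np.zeros(len(positions), dtype=bool)
        merged = self._merged_by_chrom()
        for chrom in np.unique(chromosomes):
            ivs = merged.get(str(chrom))
            if ivs is None or not len(ivs):
                continue
            sel = chromosomes == chrom
            pos = positions[sel]
            idx = np.searchsorted(ivs[:, 0], pos, side="right") - 1
            ok = idx >= 0
            ok[ok] = pos[ok] < ivs[idx[ok], 1]
            result[sel] = ok
        return result
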