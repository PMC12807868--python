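"""Core data containers shared by every pipeline stage.

All matrices are probes (rows) x samples (columns) pandas DataFrames wrapped in
thin validating classes.  Genomic coordinates are 1-based inclusive throughout
the package (the SEG convention); BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input data (bad values, duplicate identifiers, shape errors)."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what} ids: {dupes}")


@dataclass
class BetaMatrix:
    """Methylation fractions (beta values) in [0, 1], probes x samples.

    Missing measurements are stored as NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise FormatError(
                f"beta value out of [0, 1] at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {arr[r, c]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> pd.Series:
        """Missing-probe count per sample."""
        return self.values.isna().sum(axis=0)

    def impute_median(self) -> "BetaMatrix":
        """Replace missing values by the per-probe cohort median.

        Probes missing in every sample fall back to 0.5 (maximally
        uninformative beta).
        """
        med = self.values.median(axis=1).fillna(0.5)
        filled = self.values.T.fillna(med).T
        return BetaMatrix(filled)

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)])

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])


@dataclass
class IntensityMatrix:
    """Total probe fluorescence intensities, probes x samples; positive or NaN."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr <= 0) & ~np.isnan(arr)
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"non-positive intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {arr[r, c]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def select_samples(self, sample_ids: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[:, list(sample_ids)])


@dataclass
class ProbeManifest:
    """Per-probe genomic annotation.

    Columns: ``chromosome``, ``position`` (1-based bp), optional
    ``promoter_gene`` and ``ortholog_id`` (partner-array probe).  Indexed by
    probe id.
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"manifest missing column {col!r}")
        for col in ("promoter_gene", "ortholog_id"):
            if col not in self.table.columns:
                self.table[col] = pd.NA
        pos = self.table["position"]
        if (pos.dropna() < 1).any():
            raise FormatError("manifest positions must be >= 1")
        orth = self.table["ortholog_id"].dropna()
        if orth.duplicated().any():
            raise FormatError("ortholog_id must be unique per probe")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.table["chromosome"]))

    def probes_on(self, chromosome: str) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub.sort_values("position")


VALID_ROLES = {"tumor", "control", "immune", "allograft"}
VALID_SEX = {"female", "male", "unknown"}
VALID_PRESERVATION = {"fresh", "FFPE"}


@dataclass
class SampleSheet:
    """Sample annotation: model, entity, family, role, sex, preservation, batch."""

    table: pd.DataFrame

    REQUIRED = ("model", "entity", "family", "role", "sex", "preservation", "batch")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        for col, valid in (
            ("role", VALID_ROLES),
            ("sex", VALID_SEX),
            ("preservation", VALID_PRESERVATION),
        ):
            bad = set(self.table[col].dropna()) - valid
            if bad:
                raise FormatError(f"invalid {col} values: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_with(self, **criteria: str) -> pd.Index:
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            mask &= self.table[col] == val
        return self.table.index[mask]


SEG_COLUMNS = ["sample_id", "chromosome", "start", "end", "n_bins", "seg_mean", "call"]
VALID_CALLS = {"gain", "loss", "neutral"}


@dataclass
class SegmentTable:
    """Per-sample genomic segments with mean log2 copy-number ratio and call.

    Coordinates are 1-based inclusive.  Segments of one sample must not
    overlap within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table.columns) != SEG_COLUMNS:
            missing = [c for c in SEG_COLUMNS if c not in self.table.columns]
            if missing:
                raise FormatError(f"segment table missing columns {missing}")
            self.table = self.table[SEG_COLUMNS]
        bad_calls = set(self.table["call"]) - VALID_CALLS
        if bad_calls:
            raise ValidationError(f"invalid calls: {sorted(bad_calls)}")
        if (self.table["end"] < self.table["start"]).any():
            raise ValidationError("segment end < start")
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        for (sid, chrom), grp in self.table.groupby(["sample_id", "chromosome"]):
            g = grp.sort_values("start")
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if np.any(starts[1:] <= ends[:-1]):
                raise ValidationError(
                    f"overlapping segments for sample {sid!r} on {chrom!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.table["sample_id"]))

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table["sample_id"] == sample_id]

    @classmethod
    def empty(cls) -> "SegmentTable":
        return cls(pd.DataFrame(columns=SEG_COLUMNS))


SYNTENY_COLUMNS = [
    "mouse_chromosome",
    "mouse_start",
    "mouse_end",
    "human_chromosome",
    "human_start",
    "human_end",
]


@dataclass
class SyntenyMap:
    """Blocks pairing mouse intervals with human intervals (1-based inclusive).

    Human intervals originating from one mouse chromosome must be pairwise
    non-overlapping.
    """

    blocks: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SYNTENY_COLUMNS if c not in self.blocks.columns]
        if missing:
            raise FormatError(f"synteny map missing columns {missing}")
        self.blocks = self.blocks[SYNTENY_COLUMNS].reset_index(drop=True)
        for side in ("mouse", "human"):
            if (self.blocks[f"{side}_end"] < self.blocks[f"{side}_start"]).any():
                raise ValidationError(f"{side} block end < start")
        for mchrom, grp in self.blocks.groupby("mouse_chromosome"):
            for hchrom, sub in grp.groupby("human_chromosome"):
                g = sub.sort_values("human_start")
                if np.any(
                    g["human_start"].to_numpy()[1:] <= g["human_end"].to_numpy()[:-1]
                ):
                    raise ValidationError(
                        f"overlapping human intervals for mouse chromosome {mchrom!r}"
                    )

    def mouse_chromosomes(self) -> list[str]:
        return list(pd.unique(self.blocks["mouse_chromosome"]))

    def blocks_for(self, mouse_chromosome: str) -> pd.DataFrame:
        sub = self.blocks[self.blocks["mouse_chromosome"] == mouse_chromosome]
        if sub.empty:
            raise KeyError(f"mouse chromosome {mouse_chromosome!r} absent from map")
        return sub


@dataclass
class PipelineConfig:
    """Numeric constants of the pipeline; defaults are the published settings."""

    qc_outlier_quantile: float = 0.95
    diff_adj_p: float = 0.05
    diff_min_delta: float = 0.2
    top_sites: int = 10000
    human_top_sites: int = 15000
    match_iterations: int = 10
    match_subsample: float = 0.9
    stability_iterations: int = 500
    rf_trees: int = 1000
    ref_sites_per_population: int = 100
    cna_call_threshold: float = 0.1
    concordance_z_cutoff: float = 0.5
    concordance_meth_cutoff: float = 0.25
    top_variable_genes: int = 1000
    panel_genes: int = 130
    rng_seed: int = 0

    # stage-local seed offsets: each stage draws seed = rng_seed + offset so
    # stages are independently reproducible
    STAGE_OFFSETS = {
        "simulate": 0,
        "qc": 1000,
        "diffmeth": 2000,
        "crossmap": 3000,
        "deconv": 4000,
        "cna": 5000,
        "synteny": 6000,
    }

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "rng_seed":
                continue
            val = getattr(self, f.name)
            if val <= 0:
                raise ValidationError(f"config field {f.name} must be positive")
        if not (0 < self.match_subsample < 1):
            raise ValidationError("match_subsample must lie in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        return int(self.rng_seed) + self.STAGE_OFFSETS[stage]

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
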