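"""Readers and writers for the pipeline's exchange formats.

Tabular IO is TSV with '.' decimals; segments use the SEG format (1-based
inclusive coordinates); BED exports are 0-based half-open.  Every writer
produces files its paired reader accepts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    SEG_COLUMNS,
    SYNTENY_COLUMNS,
    BetaMatrix,
    FormatError,
    IntensityMatrix,
    PipelineConfig,
    ProbeManifest,
    SampleSheet,
    SegmentTable,
    SyntenyMap,
)

SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def _read_numeric_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate probe ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}"
            )
        out[col] = converted
    out.index.name = df.index.name
    return out


def read_beta_matrix(
    path: str | Path, manifest: ProbeManifest | None = None
) -> BetaMatrix:
    """Read a probes x samples beta-value TSV.

    Empty cells become missing; values outside [0, 1] raise a format error
    naming the offending probe.  If a manifest is given, probes absent from it
    raise.
    """
    df = _read_numeric_matrix(path)
    bm = BetaMatrix(df)
    if manifest is not None:
        missing = bm.probe_ids.difference(manifest.probe_ids)
        if len(missing):
            raise FormatError(
                f"{path}: {len(missing)} probes absent from manifest "
                f"(e.g. {list(missing[:3])})"
            )
    return bm


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def read_intensity_matrix(path: str | Path) -> IntensityMatrix:
    return IntensityMatrix(_read_numeric_matrix(path))


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.4f")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample_id")


def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"position": "Int64"})
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index_label="probe_id")


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV pairing query (mouse) probes with reference (human) probes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["query_probe", "reference_probe"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df["query_probe"].duplicated().any() or df["reference_probe"].duplicated().any():
        raise FormatError(f"{path}: ortholog pairing must be injective")
    return df


def write_ortholog_map(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[["query_probe", "reference_probe"]].to_csv(path, sep="\t", index=False)


def read_synteny_map(path: str | Path) -> SyntenyMap:
    df = pd.read_csv(path, sep="\t")
    return SyntenyMap(df)


def write_synteny_map(smap: SyntenyMap, path: str | Path) -> None:
    smap.blocks[SYNTENY_COLUMNS].to_csv(path, sep="\t", index=False)


def write_seg(segments: SegmentTable, path: str | Path) -> None:
    """Write a SegmentTable as SEG text (header + one row per segment).

    The gain/loss call is not part of SEG; readers re-derive it from the
    configured threshold.
    """
    lines = ["\t".join(SEG_HEADER)]
    for row in segments.table.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    str(row.sample_id),
                    str(row.chromosome),
                    str(int(row.start)),
                    str(int(row.end)),
                    str(int(row.n_bins)),
                    f"{row.seg_mean:.6f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_seg(path: str | Path, call_threshold: float = 0.1) -> SegmentTable:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SEG_HEADER:
        raise FormatError(f"{path}: expected SEG header {SEG_HEADER}")
    out = pd.DataFrame(
        {
            "sample_id": df["ID"].astype(str),
            "chromosome": df["chrom"].astype(str),
            "start": df["loc.start"].astype(int),
            "end": df["loc.end"].astype(int),
            "n_bins": df["num.mark"].astype(int),
            "seg_mean": df["seg.mean"].astype(float),
        }
    )
    out["call"] = np.select(
        [out["seg_mean"] > call_threshold, out["seg_mean"] < -call_threshold],
        ["gain", "loss"],
        default="neutral",
    )
    return SegmentTable(out[SEG_COLUMNS])


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write (chromosome, start, end[, name, score]) intervals as BED.

    Input coordinates are 1-based inclusive and converted to BED's 0-based
    half-open convention.
    """
    cols = list(intervals.columns)
    if cols[:3] != ["chromosome", "start", "end"]:
        raise FormatError("BED export needs chromosome/start/end as leading columns")
    out = intervals.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False, header=False)


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(json.load(fh))


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
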