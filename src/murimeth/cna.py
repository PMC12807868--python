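"""Copy-number estimation from probe intensities.

Per-probe log2 ratios against sex- and preservation-matched normal-tissue
references are combined into genomic bins, segmented per chromosome with a
seeded circular binary segmentation (CBS), and called gain/loss/neutral at a
strict +/-0.1 log2 threshold.  The chromosomal-instability statistic is the
fraction of bins whose value exceeds that threshold in magnitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    SEG_COLUMNS,
    IntensityMatrix,
    ProbeManifest,
    SampleSheet,
    SegmentTable,
    ValidationError,
)

logger = logging.getLogger("murimeth.cna")

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class CnReference:
    """Per-probe mean control intensities keyed by {female, male, FFPE}."""

    profiles: dict[str, pd.Series]
    n_controls: dict[str, int]

    def key_for(self, sex: str, preservation: str) -> str:
        """FFPE trumps sex: FFPE samples use the FFPE reference regardless of sex."""
        if preservation == "FFPE" and "FFPE" in self.profiles:
            return "FFPE"
        if sex in self.profiles:
            return sex
        available = sorted(self.profiles)
        if not available:
            raise ValidationError("no control reference available")
        return available[0]


def build_cn_reference(
    intensities: IntensityMatrix, sheet: SampleSheet
) -> CnReference:
    """Average control-sample intensities into female/male/FFPE references.

    Sex keys use fresh controls of that sex; the FFPE key uses FFPE controls of
    any sex.  A key with no contributing controls is absent (warning).
    """
    profiles: dict[str, pd.Series] = {}
    counts: dict[str, int] = {}
    selections = {
        "female": sheet.samples_with(role="control", sex="female", preservation="fresh"),
        "male": sheet.samples_with(role="control", sex="male", preservation="fresh"),
        "FFPE": sheet.samples_with(role="control", preservation="FFPE"),
    }
    for key, ids in selections.items():
        ids = [s for s in ids if s in intensities.sample_ids]
        if not ids:
            logger.warning("no controls for CNA reference key %r; key absent", key)
            continue
        profiles[key] = intensities.values[ids].mean(axis=1)
        counts[key] = len(ids)
    if not profiles:
        raise ValidationError("no control samples for any reference key")
    return CnReference(profiles, counts)


def probe_log_ratios(
    sample: pd.Series, reference: pd.Series, manifest: ProbeManifest
) -> pd.Series:
    """Median-centered per-probe log2(sample/reference).

    Centering subtracts the autosomal median so a uniform global intensity
    shift maps to ratio 0.
    """
    s = pd.Series(sample).dropna()
    r = reference.reindex(s.index).dropna()
    s = s.reindex(r.index)
    if (s <= 0).any() or (r <= 0).any():
        raise ValidationError("intensities must be strictly positive")
    ratios = np.log2(s / r)
    autosomal = ~manifest.table["chromosome"].reindex(ratios.index).isin(SEX_CHROMOSOMES)
    center = ratios[autosomal].median() if autosomal.any() else ratios.median()
    return ratios - center


@dataclass
class BinTrack:
    """Ordered genomic bins with mean log2 ratio, one track per sample."""

    bins: pd.DataFrame  # chromosome, start, end, n_probes, value

    def __post_init__(self) -> None:
        req = ["chromosome", "start", "end", "n_probes", "value"]
        missing = [c for c in req if c not in self.bins.columns]
        if missing:
            raise ValidationError(f"bin track missing columns {missing}")
        if not np.isfinite(self.bins["value"].to_numpy(dtype=float)).all():
            raise ValidationError("bin values must be finite")


def _make_bins(
    ratios: pd.Series,
    manifest: ProbeManifest,
    bin_size: int,
    min_probes_per_bin: int,
) -> pd.DataFrame:
    """Fixed-width genomic bins, greedily merged rightward until each holds
    >= ``min_probes_per_bin`` probes (a trailing light bin merges leftward)."""
    rows = []
    ann = manifest.table.reindex(ratios.index)
    for chrom, grp in ann.groupby("chromosome", sort=False):
        grp = grp.sort_values("position")
        vals = ratios.reindex(grp.index).to_numpy(dtype=float)
        pos = grp["position"].to_numpy(dtype=int)
        window = ((pos - 1) // bin_size).astype(int)

        chrom_bins: list[list] = []  # [start, end, count, sum]
        current = None
        for w in np.unique(window):
            members = window == w
            w_start = int(w * bin_size + 1)
            w_end = int((w + 1) * bin_size)
            cnt = int(members.sum())
            s = float(vals[members].sum())
            if current is None:
                current = [w_start, w_end, cnt, s]
            else:
                current[1] = w_end
                current[2] += cnt
                current[3] += s
            if current[2] >= min_probes_per_bin:
                chrom_bins.append(current)
                current = None
        if current is not None:
            if chrom_bins:
                last = chrom_bins[-1]
                last[1] = current[1]
                last[2] += current[2]
                last[3] += current[3]
            else:
                chrom_bins.append(current)
        for start, end, cnt, s in chrom_bins:
            rows.append((chrom, start, end, cnt, s / cnt))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_probes", "value"])


_EPS_VAR = 1e-12


def _allowed_arcs(n: int, min_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """Arc index pairs (i, j] whose cut produces no piece shorter than ``min_seg``.

    Pieces [0, i), [i, j), [j, n): empty flanks are allowed, short non-empty
    ones are not (the minimum-width rule of binary segmentation).
    """
    i_idx, j_idx = np.triu_indices(n + 1, k=1)
    k = j_idx - i_idx
    valid = (k > 0) & (k < n)
    valid &= k >= min_seg
    valid &= (i_idx == 0) | (i_idx >= min_seg)
    valid &= (j_idx == n) | (n - j_idx >= min_seg)
    return i_idx[valid], j_idx[valid]


def _arc_t_matrix(X: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample |t| of every arc (i, j] vs its complement.

    ``X`` is (m series) x (n bins); returns an (m x arcs) matrix.
    """
    m, n = X.shape
    S = np.concatenate([np.zeros((m, 1)), np.cumsum(X, axis=1)], axis=1)
    S2 = np.concatenate([np.zeros((m, 1)), np.cumsum(X**2, axis=1)], axis=1)
    k = (j_idx - i_idx).astype(float)
    arc = S[:, j_idx] - S[:, i_idx]
    arc2 = S2[:, j_idx] - S2[:, i_idx]
    tot = S[:, -1][:, None]
    tot2 = S2[:, -1][:, None]
    mean_in = arc / k
    mean_out = (tot - arc) / (n - k)
    ss_in = arc2 - arc**2 / k
    ss_out = (tot2 - arc2) - (tot - arc) ** 2 / (n - k)
    pooled = np.maximum(ss_in + ss_out, 0.0) / max(n - 2, 1)
    denom = np.sqrt(np.maximum(pooled, _EPS_VAR) * (1.0 / k + 1.0 / (n - k)))
    return np.abs(mean_in - mean_out) / denom


def _max_arc_stat(x: np.ndarray, min_seg: int = 1) -> tuple[float, int, int]:
    """Maximal pooled-t arc-vs-rest statistic over all min-width arcs (i, j]."""
    n = len(x)
    if n < 2 or np.ptp(x) == 0:
        return 0.0, 0, n
    i_idx, j_idx = _allowed_arcs(n, min_seg)
    if len(i_idx) == 0:
        return 0.0, 0, n
    t = _arc_t_matrix(x[None, :], i_idx, j_idx)[0]
    best = int(t.argmax())
    return float(t[best]), int(i_idx[best]), int(j_idx[best])


def _perm_pvalue(
    x: np.ndarray,
    observed: float,
    nperm: int,
    alpha: float,
    min_seg: int,
    rng: np.random.Generator,
    chunk: int = 250,
) -> float:
    """Permutation p-value of the max arc statistic with early stopping once
    non-significance at ``alpha`` is certain."""
    exceed = 0
    done = 0
    stop_at = int(np.ceil(alpha * nperm)) + 1
    i_idx, j_idx = _allowed_arcs(len(x), min_seg)
    while done < nperm:
        m = min(chunk, nperm - done)
        perms = np.array([rng.permutation(x) for _ in range(m)])
        t = _arc_t_matrix(perms, i_idx, j_idx)
        exceed += int((t.max(axis=1) >= observed).sum())
        done += m
        if exceed >= stop_at:
            break
    return (exceed + 1) / (done + 1)


def _cbs_breakpoints(
    x: np.ndarray,
    alpha: float,
    nperm: int,
    min_seg: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive circular binary segmentation; returns sorted interior breakpoints."""
    n = len(x)
    if n < 2 * min_seg:
        return []
    stat, i, j = _max_arc_stat(x, min_seg)
    if stat <= 0:
        return []
    p = _perm_pvalue(x, stat, nperm, alpha, min_seg, rng)
    if p >= alpha:
        return []
    cuts = sorted({i, j} - {0, n})
    bounds = [0] + cuts + [n]
    out = set(cuts)
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.update(a + c for c in _cbs_breakpoints(x[a:b], alpha, nperm, min_seg, rng))
    return sorted(out)


def _prune_short(values: np.ndarray, bounds: list[int], min_seg: int) -> list[int]:
    """Merge segments shorter than ``min_seg`` bins into the neighbor whose
    mean is closest."""
    bounds = list(bounds)
    changed = True
    while changed and len(bounds) > 2:
        changed = False
        seg_means = [
            values[bounds[k] : bounds[k + 1]].mean() for k in range(len(bounds) - 1)
        ]
        for k in range(len(bounds) - 1):
            if bounds[k + 1] - bounds[k] < min_seg:
                left_d = abs(seg_means[k] - seg_means[k - 1]) if k > 0 else np.inf
                right_d = (
                    abs(seg_means[k] - seg_means[k + 1])
                    if k < len(seg_means) - 1
                    else np.inf
                )
                drop = k if left_d <= right_d else k + 1
                del bounds[drop]
                changed = True
                break
    return bounds


def bin_and_segment(
    ratios: pd.Series,
    manifest: ProbeManifest,
    sample_id: str,
    bin_size: int = 100_000,
    min_probes_per_bin: int = 15,
    cbs_alpha: float = 0.01,
    nperm: int = 10_000,
    min_seg_bins: int = 3,
    call_threshold: float = 0.1,
    seed: int = 0,
) -> tuple[BinTrack, SegmentTable]:
    """Bin per-probe log2 ratios and segment each chromosome with seeded CBS.

    Segment means are the mean of member bins; calls are strict: gain above
    ``call_threshold``, loss below its negative.  A chromosome with < 2 bins
    becomes a single segment.
    """
    bins = _make_bins(ratios, manifest, bin_size, min_probes_per_bin)
    track = BinTrack(bins)
    rng = np.random.default_rng(seed)

    rows = []
    for chrom, grp in bins.groupby("chromosome", sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy(dtype=int)
        ends = grp["end"].to_numpy(dtype=int)
        n = len(vals)
        if n < 2:
            bounds = [0, n]
        else:
            cuts = _cbs_breakpoints(vals, cbs_alpha, nperm, min_seg_bins, rng)
            bounds = _prune_short(vals, [0] + cuts + [n], min_seg_bins)
        for a, b in zip(bounds[:-1], bounds[1:]):
            mean = float(vals[a:b].mean())
            call = "gain" if mean > call_threshold else "loss" if mean < -call_threshold else "neutral"
            rows.append((sample_id, chrom, int(starts[a]), int(ends[b - 1]), b - a, mean, call))
    segs = SegmentTable(pd.DataFrame(rows, columns=SEG_COLUMNS))
    return track, segs


def chromosomal_instability(track: BinTrack, threshold: float = 0.1) -> float:
    """Fraction of bins with |log2 ratio| strictly above ``threshold``."""
    vals = track.bins["value"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValidationError("empty bin track")
    return float((np.abs(vals) > threshold).mean())


def cohort_instability(tracks: dict[str, BinTrack], threshold: float = 0.1) -> pd.Series:
    """Per-sample instability plus the cohort mean under key ``__cohort__``."""
    per = pd.Series(
        {sid: chromosomal_instability(t, threshold) for sid, t in tracks.items()}
    )
    per["__cohort__"] = per.mean()
    return per


def cohort_cna_frequency(
    segments: SegmentTable, bin_grid: pd.DataFrame
) -> pd.DataFrame:
    """Per-bin fraction of samples called gain / loss.

    ``bin_grid`` holds (chromosome, start, end) rows shared by all samples; a
    bin's covering segment is the one containing its midpoint.  Bins no
    segment covers are reported with missing frequencies.
    """
    samples = segments.sample_ids
    if not samples:
        raise ValidationError("no samples in segment table")
    grid = bin_grid[["chromosome", "start", "end"]].reset_index(drop=True)
    mid = (grid["start"] + grid["end"]) // 2
    gain = np.zeros(len(grid))
    loss = np.zeros(len(grid))
    covered = np.zeros(len(grid))
    for sid in samples:
        segs = segments.for_sample(sid)
        for chrom, sub in segs.groupby("chromosome"):
            on_chrom = grid["chromosome"] == chrom
            if not on_chrom.any():
                continue
            m = mid[on_chrom]
            for seg in sub.itertuples(index=False):
                inside = on_chrom & (mid >= seg.start) & (mid <= seg.end)
                covered[inside] += 1
                if seg.call == "gain":
                    gain[inside] += 1
                elif seg.call == "loss":
                    loss[inside] += 1
    n = len(samples)
    uncovered = covered < n
    if uncovered.any():
        warnings.warn(f"{int(uncovered.sum())} bins not covered by all samples", stacklevel=2)
    out = grid.copy()
    out["gain_freq"] = gain / n
    out["loss_freq"] = loss / n
    out.loc[covered == 0, ["gain_freq", "loss_freq"]] = np.nan
    return out
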