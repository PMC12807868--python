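"""Cross-species CNA enrichment over synteny blocks.

For a recurrent mouse CNA on one chromosome, the statistic asks whether human
patients alter the syntenic human regions more than their genomic background:
per patient, enrichment = 100 x (fraction of syntenic bins altered in the CNA
direction) - 100 x (fraction of all bins altered in that direction).  Target
and reference cohorts are compared with a one-sided Welch t-test, and the
final score is the difference of cohort mean enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SegmentTable, SyntenyMap, ValidationError
from .cna import SEX_CHROMOSOMES

DIRECTIONS = {"gain", "loss"}


def syntenic_human_bins(
    smap: SyntenyMap,
    mouse_chromosome: str,
    bin_grid: pd.DataFrame,
    exclude_sex: bool = True,
) -> np.ndarray:
    """Indices of human grid bins whose midpoint falls in any block syntenic to
    ``mouse_chromosome``."""
    blocks = smap.blocks_for(mouse_chromosome)
    grid = bin_grid.reset_index(drop=True)
    mid = (grid["start"].to_numpy() + grid["end"].to_numpy()) // 2
    hit = np.zeros(len(grid), dtype=bool)
    for blk in blocks.itertuples(index=False):
        hit |= (
            (grid["chromosome"].to_numpy() == blk.human_chromosome)
            & (mid >= blk.human_start)
            & (mid <= blk.human_end)
        )
    if exclude_sex:
        hit &= ~grid["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
    return np.flatnonzero(hit)


def patient_enrichment(
    patient_calls: np.ndarray,
    syntenic_bins: np.ndarray,
    direction: str,
    combined: bool = False,
) -> float:
    """Per-patient enrichment score in percentage points.

    ``patient_calls`` holds per-bin {gain, loss, neutral} strings on the shared
    grid.  ``combined=True`` counts any non-neutral call instead of the single
    ``direction`` (the direction-specific mode is the default).
    """
    calls = np.asarray(patient_calls)
    if calls.size == 0:
        raise ValidationError("empty call track")
    if len(syntenic_bins) == 0:
        raise ValidationError("syntenic bin set is empty")
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {sorted(DIRECTIONS)}")
    altered = (calls != "neutral") if combined else (calls == direction)
    overlap = 100.0 * altered[syntenic_bins].mean()
    overall = 100.0 * altered.mean()
    return float(overlap - overall)


@dataclass
class EnrichmentResult:
    """Per-patient scores, one-sided Welch t-test, and the final mean-difference score."""

    target_scores: np.ndarray
    reference_scores: np.ndarray
    t_stat: float
    p_value: float
    final_score: float

    def __post_init__(self) -> None:
        for arr in (self.target_scores, self.reference_scores):
            if np.any(np.abs(arr) > 100 + 1e-9):
                raise ValidationError("enrichment scores must lie in [-100, 100]")
        expected = float(np.mean(self.target_scores) - np.mean(self.reference_scores))
        if not np.isclose(self.final_score, expected, atol=1e-9):
            raise ValidationError("final_score inconsistent with cohort means")


def enrichment_test(
    target_scores: np.ndarray,
    reference_scores: np.ndarray,
    equal_var: bool = False,
) -> EnrichmentResult:
    """One-sided t-test (alternative: target mean > reference mean).

    Welch by default; ``equal_var=True`` gives the pooled-variance flavor.
    The final enrichment score is mean(target) - mean(reference).
    """
    t_arr = np.asarray(target_scores, dtype=float)
    r_arr = np.asarray(reference_scores, dtype=float)
    if len(t_arr) < 2 or len(r_arr) < 2:
        raise ValidationError("need >= 2 patients per cohort")
    res = stats.ttest_ind(t_arr, r_arr, equal_var=equal_var, alternative="greater")
    return EnrichmentResult(
        target_scores=t_arr,
        reference_scores=r_arr,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        final_score=float(t_arr.mean() - r_arr.mean()),
    )


def reference_cohort_builder(
    entity_patients: dict[str, list[str]],
    target_entity: str,
    per_entity: int = 3,
    seed: int = 0,
) -> list[str]:
    """Seeded draw of ``per_entity`` patients from every non-target entity, pooled."""
    rng = np.random.default_rng(seed)
    pooled: list[str] = []
    for entity in sorted(entity_patients):
        if entity == target_entity:
            continue
        patients = sorted(entity_patients[entity])
        if len(patients) < per_entity:
            raise ValidationError(
                f"entity {entity!r} has {len(patients)} patients, need {per_entity}"
            )
        chosen = rng.choice(patients, size=per_entity, replace=False)
        pooled.extend(sorted(chosen))
    return pooled


def calls_on_grid(
    segments: SegmentTable, bin_grid: pd.DataFrame, sample_id: str
) -> np.ndarray:
    """Per-bin {gain, loss, neutral} call for one sample on the shared grid.

    A bin takes the call of the segment containing its midpoint; uncovered
    bins are neutral.
    """
    grid = bin_grid.reset_index(drop=True)
    mid = (grid["start"].to_numpy() + grid["end"].to_numpy()) // 2
    calls = np.full(len(grid), "neutral", dtype=object)
    segs = segments.for_sample(sample_id)
    for seg in segs.itertuples(index=False):
        inside = (
            (grid["chromosome"].to_numpy() == seg.chromosome)
            & (mid >= seg.start)
            & (mid <= seg.end)
        )
        calls[inside] = seg.call
    return calls
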