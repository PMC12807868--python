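"""Sample-level quality control and quantile normalization.

QC follows the three-metric outlier rule used for methylation arrays: per
sample, count missing probes, average intensity and probe success rate, then
exclude only samples that fall in the adverse 5% tail of *all three* metrics
simultaneously.  Cutoffs are computed once on the full sample set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaMatrix, IntensityMatrix, ValidationError


@dataclass
class QCMetrics:
    sample_id: str
    n_missing: int
    mean_intensity: float
    probe_success_rate: float

    def __post_init__(self) -> None:
        if self.n_missing < 0:
            raise ValidationError("n_missing must be >= 0")
        if not (0 <= self.probe_success_rate <= 1):
            raise ValidationError("probe_success_rate must lie in [0, 1]")


def compute_qc_metrics(
    betas: BetaMatrix, intensities: IntensityMatrix
) -> list[QCMetrics]:
    """Per-sample missing-probe count, mean intensity and probe success rate."""
    if list(betas.sample_ids) != list(intensities.sample_ids):
        raise ValidationError("beta and intensity matrices must share sample ids")
    n_probes = len(betas.probe_ids)
    out = []
    for sid in betas.sample_ids:
        n_miss = int(betas.values[sid].isna().sum())
        out.append(
            QCMetrics(
                sample_id=sid,
                n_missing=n_miss,
                mean_intensity=float(intensities.values[sid].mean()),
                probe_success_rate=1.0 - n_miss / n_probes,
            )
        )
    return out


def metrics_frame(metrics: list[QCMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_missing": [m.n_missing for m in metrics],
            "mean_intensity": [m.mean_intensity for m in metrics],
            "probe_success_rate": [m.probe_success_rate for m in metrics],
        },
        index=pd.Index([m.sample_id for m in metrics], name="sample_id"),
    )


def filter_outlier_samples(
    metrics: list[QCMetrics], quantile: float = 0.95
) -> tuple[list[str], list[str]]:
    """Split samples into (kept, excluded) by the three-metric conjunction rule.

    A sample is excluded iff it is strictly inside the adverse tail of all
    three metrics: n_missing above its ``quantile``, mean intensity below the
    ``1 - quantile`` point, probe success rate below the ``1 - quantile``
    point.  Strict inequalities make an all-identical cohort a no-op.
    """
    if len(metrics) < 2:
        raise ValidationError("need at least 2 samples for outlier filtering")
    df = metrics_frame(metrics)
    hi_missing = np.quantile(df["n_missing"], quantile)
    lo_intensity = np.quantile(df["mean_intensity"], 1 - quantile)
    lo_success = np.quantile(df["probe_success_rate"], 1 - quantile)
    adverse = (
        (df["n_missing"] > hi_missing)
        & (df["mean_intensity"] < lo_intensity)
        & (df["probe_success_rate"] < lo_success)
    )
    excluded = list(df.index[adverse])
    kept = list(df.index[~adverse])
    return kept, excluded


def quantile_normalize(matrix: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the mean-of-order-statistics distribution.

    After normalization all columns share one value multiset (the across-sample
    mean of sorted values); within-sample ranks are preserved and ties receive
    the average of their target values.  Missing values must be imputed first.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("quantile_normalize requires complete data; impute first")
    target = np.sort(X, axis=0).mean(axis=1)
    normalized = np.empty_like(X)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        col_sorted = X[order, j]
        assigned = target.copy()
        # tied runs receive the mean target value over their rank span
        run_start = 0
        for i in range(1, len(col_sorted) + 1):
            if i == len(col_sorted) or col_sorted[i] != col_sorted[run_start]:
                if i - run_start > 1:
                    assigned[run_start:i] = target[run_start:i].mean()
                run_start = i
        normalized[order, j] = assigned
    return BetaMatrix(
        pd.DataFrame(normalized, index=matrix.probe_ids, columns=matrix.sample_ids)
    )
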