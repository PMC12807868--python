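"""Reference-matrix construction and cell-population deconvolution.

The reference matrix holds, per population (eight immune populations plus a
tumor-average and a brain-average pseudo-population), the mean beta values of
its top marker CpGs: one-vs-rest differential sites at p < 0.05, ranked by
absolute delta-beta, top 100 each, pooled into a unique-row matrix (1,000 rows
at the defaults).  Bulk samples are then expressed as non-negative, sum-to-one
combinations of the reference columns, either by non-negative least squares or
by a robust iteratively reweighted (Huber) fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import BetaMatrix, ValidationError
from .diffmeth import _welch_moderated, moderate_variances

logger = logging.getLogger("murimeth.deconv")


@dataclass
class ReferenceMatrix:
    """CpG x population mean-beta matrix with the per-population marker sets."""

    values: pd.DataFrame  # rows: probe ids, columns: population labels
    markers: dict[str, list[str]]  # population -> its selected probes

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate population labels")
        arr = self.values.to_numpy()
        if np.any((arr < 0) | (arr > 1)):
            raise ValidationError("reference entries must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.values.columns)


def _single_profile_diff(
    profile: np.ndarray, rest: np.ndarray, probe_ids: pd.Index
) -> pd.DataFrame:
    """One-vs-rest test for a replicate-free pseudo-population profile.

    The profile has no replicate variance, so the test borrows the rest-pool
    variance (moderated toward the cohort prior): the statistic is the profile
    deviation from the rest mean scaled by the rest standard error inflated
    for a single new observation.
    """
    n = rest.shape[1]
    rest_mean = rest.mean(axis=1)
    delta = profile - rest_mean
    s2 = rest.var(axis=1, ddof=1)
    df = float(n - 1)
    post, d0, _ = moderate_variances(s2, np.full_like(s2, df))
    v = post * (1.0 + 1.0 / n)
    t = np.zeros_like(delta)
    p = np.ones_like(delta)
    ok = v > 0
    t[ok] = delta[ok] / np.sqrt(v[ok])
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df + d0)
    return pd.DataFrame(
        {"delta_beta": delta, "t_stat": t, "p_value": p},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def build_reference_matrix(
    pure_profiles: BetaMatrix,
    population_labels: pd.Series,
    tumor_avg: pd.Series,
    brain_avg: pd.Series,
    p_cut: float = 0.05,
    top_n: int = 100,
) -> ReferenceMatrix:
    """Construct the marker reference from pure immune profiles plus tumor and
    brain average pseudo-populations.

    Per population: one-vs-rest differential methylation, retain sites with
    p < ``p_cut``, take the ``top_n`` by absolute delta-beta.  A site already
    claimed by an earlier population is skipped and the next-ranked taken, so
    the row set has exactly ``(n_populations + 2) * top_n`` unique rows.
    A population with fewer than ``top_n`` significant sites is an error.
    """
    labels = pd.Series(population_labels).reindex(pure_profiles.sample_ids)
    if labels.isna().any():
        raise ValidationError("population labels missing for some samples")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValidationError(f"populations need >= 2 replicates: {small}")
    for name, vec in (("tumor", tumor_avg), ("brain", brain_avg)):
        if not vec.index.equals(pure_profiles.probe_ids):
            vec = vec.reindex(pure_profiles.probe_ids)
            if vec.isna().any():
                raise ValidationError(f"{name} average does not cover the probe universe")

    pure = pure_profiles.impute_median()
    X = pure.values.to_numpy(dtype=float)
    probe_ids = pure.probe_ids
    extra = {
        "tumor": tumor_avg.reindex(probe_ids).to_numpy(dtype=float),
        "brain": brain_avg.reindex(probe_ids).to_numpy(dtype=float),
    }
    populations = sorted(counts.index) + ["tumor", "brain"]

    claimed: set[str] = set()
    markers: dict[str, list[str]] = {}
    for pop in populations:
        if pop in extra:
            rest = np.column_stack([X, *(extra[o][:, None] for o in extra if o != pop)])
            res = _single_profile_diff(extra[pop], rest, probe_ids)
        else:
            cols = np.flatnonzero((labels == pop).to_numpy())
            rest_cols = np.setdiff1d(np.arange(X.shape[1]), cols)
            rest = np.column_stack([X[:, rest_cols], extra["tumor"], extra["brain"]])
            res, _, _ = _welch_moderated(X[:, cols], rest, probe_ids, prior_df=None)
        sig = res[res["p_value"] < p_cut].copy()
        if len(sig) < top_n:
            raise ValidationError(
                f"population {pop!r} has only {len(sig)} significant sites "
                f"(need {top_n})"
            )
        sig["_abs"] = sig["delta_beta"].abs()
        sig["_probe"] = sig.index.astype(str)
        ranked = sig.sort_values(["_abs", "_probe"], ascending=[False, True]).index
        picked: list[str] = []
        for probe in ranked:
            if probe in claimed:
                continue
            picked.append(probe)
            if len(picked) == top_n:
                break
        if len(picked) < top_n:
            raise ValidationError(
                f"population {pop!r}: fewer than {top_n} unclaimed significant sites"
            )
        claimed.update(picked)
        markers[pop] = picked

    rows = [probe for pop in populations for probe in markers[pop]]
    values = pd.DataFrame(index=pd.Index(rows, name="probe_id"), columns=populations, dtype=float)
    for pop in populations:
        if pop in extra:
            values[pop] = pd.Series(extra[pop], index=probe_ids).loc[rows].to_numpy()
        else:
            cols = labels.index[labels == pop]
            values[pop] = pure.values.loc[rows, cols].mean(axis=1).to_numpy()
    values = values.clip(0.0, 1.0)
    return ReferenceMatrix(values, markers)


@dataclass
class DeconvResult:
    """Population weights (non-negative, sum 1) and fit residual for one sample."""

    weights: pd.Series
    residual_norm: float

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if (w < 0).any():
            raise ValidationError("weights must be non-negative")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValidationError("weights must sum to 1")


def _huber_weights(resid: np.ndarray, k: float = 1.345) -> np.ndarray:
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale <= 0:
        return np.ones_like(resid)
    u = np.abs(resid) / scale
    w = np.ones_like(u)
    big = u > k
    w[big] = k / u[big]
    return w


def deconvolute(
    sample: pd.Series,
    reference: ReferenceMatrix,
    method: str = "robust",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> DeconvResult:
    """Estimate population fractions of one bulk beta profile.

    ``nnls``: non-negative least squares, weights renormalized to sum 1.
    ``robust``: iteratively reweighted least squares with Huber weighting and
    a non-negative inner solve, so outlier probes are downweighted while the
    weights stay on the constraint set throughout.  Samples covering < 95% of
    the reference rows trigger a warning; missing rows are dropped.  A
    collinear reference falls back to a small ridge penalty (with a warning).
    """
    y = pd.Series(sample).reindex(reference.values.index)
    coverage = 1.0 - y.isna().mean()
    if coverage < 0.95:
        warnings.warn(
            f"sample covers only {coverage:.1%} of reference rows; dropping missing",
            stacklevel=2,
        )
    keep = y.notna()
    y_arr = y[keep].to_numpy(dtype=float)
    R = reference.values.loc[keep.index[keep]].to_numpy(dtype=float)
    if len(y_arr) == 0:
        raise ValidationError("sample shares no probes with the reference")

    ridge = 0.0
    if np.linalg.matrix_rank(R) < R.shape[1]:
        warnings.warn("reference columns are collinear; using ridge fallback", stacklevel=2)
        ridge = 1e-6

    if ridge > 0:
        # augment with sqrt(ridge) * I rows so the NNLS solves stay defined
        R = np.vstack([R, np.sqrt(ridge) * np.eye(R.shape[1])])
        y_arr = np.concatenate([y_arr, np.zeros(R.shape[1])])

    if method == "nnls":
        w, rnorm = optimize.nnls(R, y_arr)
    elif method == "robust":
        w, _ = optimize.nnls(R, y_arr)
        for _ in range(max_iter):
            resid = y_arr - R @ w
            hw = _huber_weights(resid)
            sw = np.sqrt(hw)
            w_new, _ = optimize.nnls(R * sw[:, None], y_arr * sw)
            if np.max(np.abs(w_new - w)) < tol:
                w = w_new
                break
            w = w_new
        rnorm = float(np.linalg.norm(y_arr - R @ w))
    else:
        raise ValidationError(f"unknown method {method!r}")

    total = w.sum()
    if total <= 0:
        raise ValidationError("deconvolution produced an all-zero weight vector")
    weights = pd.Series(w / total, index=reference.values.columns, name="weight")
    return DeconvResult(weights, float(rnorm))


def deconvolute_matrix(
    betas: BetaMatrix, reference: ReferenceMatrix, method: str = "robust"
) -> pd.DataFrame:
    """Deconvolute every sample; rows = samples, columns = populations (+ residual)."""
    rows = {}
    for sid in betas.sample_ids:
        res = deconvolute(betas.values[sid], reference, method=method)
        rows[sid] = pd.concat([res.weights, pd.Series({"residual": res.residual_norm})])
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def evaluate_purity(
    validation: BetaMatrix,
    validation_labels: pd.Series,
    reference: ReferenceMatrix,
    method: str = "robust",
) -> pd.DataFrame:
    """Self-weight of pure validation profiles under the reference.

    Deconvolutes each validation sample and reports, per population, the mean
    and minimum weight assigned to the sample's own population.
    """
    labels = pd.Series(validation_labels).reindex(validation.sample_ids)
    unknown = set(labels.dropna()) - set(reference.populations)
    if labels.isna().any() or unknown:
        raise ValidationError(f"validation labels do not match reference populations: {sorted(unknown)}")
    fractions = deconvolute_matrix(validation, reference, method=method)
    self_w = pd.Series(
        [fractions.loc[sid, labels.loc[sid]] for sid in validation.sample_ids],
        index=validation.sample_ids,
        dtype=float,
    )
    out = pd.DataFrame(
        {
            "mean_self_weight": self_w.groupby(labels).mean(),
            "min_self_weight": self_w.groupby(labels).min(),
            "n_samples": self_w.groupby(labels).size(),
        }
    )
    out.index.name = "population"
    return out
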