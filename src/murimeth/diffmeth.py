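"""Differential methylation statistics and site selection.

The per-probe statistic is a moderated two-sample t: the Welch variance of the
group difference is shrunk toward a cohort-wide prior estimated by moment
matching of log variances (the standard empirical-Bayes scheme for array
data), which stabilizes probes with few replicates.  With the prior degrees of
freedom forced to 0 the statistic reduces exactly to the classical Welch t.

Effect sizes are delta-beta values: difference in mean methylation fraction
between the target group and all remaining samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import BetaMatrix, ValidationError

_MAX_DF = 1e7  # stand-in for an infinite prior (all probe variances equal)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(
    variances: np.ndarray, dfs: np.ndarray
) -> tuple[float, float]:
    """Moment-matching estimate of (prior_df, prior_var) from probe variances.

    Matches the mean and variance of log sample variances against the scaled
    chi-squared model; returns ``prior_df = inf`` (represented by a large
    finite value) when the observed spread is entirely explained by sampling.
    """
    var = np.asarray(variances, dtype=float)
    df = np.asarray(dfs, dtype=float)
    ok = (var > 0) & (df > 0) & np.isfinite(var) & np.isfinite(df)
    if ok.sum() < 2:
        return 0.0, float(var[ok].mean()) if ok.any() else 0.0
    z = np.log(var[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0).mean()
    if evar > 0:
        prior_df = 2.0 * _trigamma_inverse(evar)
        prior_var = np.exp(
            emean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0)
        )
    else:
        prior_df = _MAX_DF
        prior_var = np.exp(emean)
    return float(prior_df), float(prior_var)


def moderate_variances(
    variances: np.ndarray,
    dfs: np.ndarray,
    prior_df: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Shrink probe variances toward the cohort prior.

    ``prior_df=None`` estimates the prior from the data; ``prior_df=0``
    disables shrinkage (posterior = observed), exposing the Welch limit.
    Returns (posterior variances, prior_df, prior_var).
    """
    var = np.asarray(variances, dtype=float)
    df = np.asarray(dfs, dtype=float)
    if prior_df is None:
        d0, v0 = estimate_variance_prior(var, df)
    else:
        d0 = float(prior_df)
        _, v0 = estimate_variance_prior(var, df) if d0 > 0 else (0.0, 0.0)
    if d0 <= 0:
        return var.copy(), 0.0, v0
    post = (d0 * v0 + df * var) / (d0 + df)
    return post, d0, v0


@dataclass
class DiffSummary:
    """Per-probe differential table plus the fitted shrinkage parameters."""

    table: pd.DataFrame  # delta_beta, t_stat, p_value, adj_p indexed by probe
    prior_df: float = 0.0
    prior_var: float = 0.0


def differential_methylation(
    betas: BetaMatrix,
    group_labels: pd.Series,
    target_group: str,
    prior_df: float | None = None,
) -> DiffSummary:
    """Moderated target-vs-rest differential methylation per probe.

    Requires >= 2 samples on each side and complete data (impute first).
    Two-sided p-values from the moderated t on Welch-Satterthwaite + prior
    degrees of freedom; Benjamini-Hochberg adjustment over all probes.
    """
    labels = pd.Series(group_labels)
    in_group = betas.sample_ids[labels.reindex(betas.sample_ids) == target_group]
    out_group = betas.sample_ids.difference(in_group)
    if len(in_group) < 2 or len(out_group) < 2:
        raise ValidationError(
            f"need >= 2 samples per side, got {len(in_group)} vs {len(out_group)}"
        )
    X = betas.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("differential testing requires complete data; impute first")
    idx_in = betas.sample_ids.get_indexer(in_group)
    idx_out = betas.sample_ids.get_indexer(out_group)
    table, d0, v0 = _welch_moderated(X[:, idx_in], X[:, idx_out], betas.probe_ids, prior_df)
    return DiffSummary(table, d0, v0)


def _welch_moderated(
    A: np.ndarray, B: np.ndarray, probe_ids: pd.Index, prior_df: float | None
) -> tuple[pd.DataFrame, float, float]:
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    delta = m1 - m2
    v1 = A.var(axis=1, ddof=1)
    v2 = B.var(axis=1, ddof=1)
    v = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        df_w = v**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    df_w = np.where(v > 0, df_w, 0.0)

    post, d0, v0 = moderate_variances(v, df_w, prior_df=prior_df)
    df_total = np.minimum(df_w + d0, _MAX_DF)

    t = np.zeros_like(delta)
    p = np.ones_like(delta)
    ok = post > 0
    t[ok] = delta[ok] / np.sqrt(post[ok])
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total[ok])
    # zero posterior variance: degenerate null convention t = 0, p = 1
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "t_stat": t,
            "p_value": p,
            "adj_p": bh_adjust(p),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return table, d0, v0


def differential_methylation_omnibus(
    betas: BetaMatrix,
    group_labels: pd.Series,
    prior_df: float | None = None,
) -> DiffSummary:
    """Moderated one-way F test across all groups (multi-group site selection).

    ``delta_beta`` reports the range of group means (max - min) as the effect
    size used for tie-breaking.
    """
    labels = pd.Series(group_labels).reindex(betas.sample_ids)
    groups = labels.dropna().unique()
    if len(groups) < 2:
        raise ValidationError("omnibus test needs >= 2 groups")
    X = betas.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("differential testing requires complete data; impute first")
    n = X.shape[1]
    k = len(groups)
    if n - k < 1:
        raise ValidationError("omnibus test needs residual degrees of freedom")

    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    gmeans = []
    for g in groups:
        cols = betas.sample_ids.get_indexer(labels.index[labels == g])
        sub = X[:, cols]
        mg = sub.mean(axis=1)
        gmeans.append(mg)
        ssb += sub.shape[1] * (mg - grand) ** 2
        ssw += ((sub - mg[:, None]) ** 2).sum(axis=1)
    gmeans = np.array(gmeans)
    msb = ssb / (k - 1)
    df_w = float(n - k)
    s2 = ssw / df_w

    post, d0, _ = moderate_variances(s2, np.full_like(s2, df_w), prior_df=prior_df)
    df2 = min(df_w + d0, _MAX_DF)
    f = np.zeros_like(msb)
    p = np.ones_like(msb)
    ok = post > 0
    f[ok] = msb[ok] / post[ok]
    p[ok] = stats.f.sf(f[ok], k - 1, df2)
    degenerate = ~ok & (msb > 0)
    p[degenerate] = 0.0
    f[degenerate] = np.inf

    table = pd.DataFrame(
        {
            "delta_beta": gmeans.max(axis=0) - gmeans.min(axis=0),
            "t_stat": f,
            "p_value": p,
            "adj_p": bh_adjust(p),
        },
        index=pd.Index(betas.probe_ids, name="probe_id"),
    )
    return DiffSummary(table, d0, 0.0)


def select_top_sites(results: pd.DataFrame, k: int = 10000) -> list[str]:
    """The k probes with smallest p-value.

    Ties break by larger \\|delta_beta\\|, then lexicographic probe id, so the
    selection is deterministic.
    """
    if k > len(results):
        raise ValidationError(f"k={k} exceeds {len(results)} probes")
    df = results.copy()
    df["_abs_delta"] = df["delta_beta"].abs() if "delta_beta" in df else 0.0
    df["_probe"] = df.index.astype(str)
    ordered = df.sort_values(
        ["p_value", "_abs_delta", "_probe"], ascending=[True, False, True]
    )
    return list(ordered.index[:k])


def significant_promoter_sites(
    results: pd.DataFrame,
    manifest,
    adj_p: float = 0.05,
    min_delta: float = 0.2,
) -> pd.DataFrame:
    """Significant promoter probes grouped by gene.

    Keeps probes with adjusted p < ``adj_p``, \\|delta_beta\\| > ``min_delta``
    and a promoter-gene annotation; returns a (gene, probe_id, delta_beta,
    adj_p) table sorted by gene then probe.
    """
    genes = manifest.table["promoter_gene"].reindex(results.index)
    mask = (
        (results["adj_p"] < adj_p)
        & (results["delta_beta"].abs() > min_delta)
        & genes.notna()
    )
    out = pd.DataFrame(
        {
            "gene": genes[mask],
            "probe_id": results.index[mask],
            "delta_beta": results.loc[mask, "delta_beta"],
            "adj_p": results.loc[mask, "adj_p"],
        }
    ).reset_index(drop=True)
    return out.sort_values(["gene", "probe_id"]).reset_index(drop=True)


def top_variable_genes(expression: pd.DataFrame, k: int = 1000) -> list[str]:
    """The k genes with largest across-sample variance (ties by gene id)."""
    if k > len(expression):
        raise ValidationError(f"k={k} exceeds {len(expression)} genes")
    var = expression.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": var.index.astype(str)}).sort_values(
        ["var", "gene"], ascending=[False, True]
    )
    return list(order.index[:k])


@dataclass
class ConcordanceResult:
    """Genes passing both expression and methylation cutoffs, by sign quadrant."""

    table: pd.DataFrame  # per-gene expr_diff, meth_diff (intersection universe)
    quadrant_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    quadrant_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)


def expression_methylation_concordance(
    expr_diff: pd.Series,
    meth_diff: pd.Series,
    z_cut: float = 0.5,
    m_cut: float = 0.25,
) -> ConcordanceResult:
    """Count genes past both cutoffs in each expression/methylation quadrant.

    A gene qualifies when \\|expression z-score difference\\| > ``z_cut`` and
    \\|promoter methylation difference\\| > ``m_cut``; quadrants are keyed by
    ("up"/"down" expression, "hyper"/"hypo" methylation).
    """
    genes = expr_diff.index.intersection(meth_diff.index)
    if len(genes) == 0:
        raise ValidationError("gene universes do not intersect")
    e = expr_diff.loc[genes].astype(float)
    m = meth_diff.loc[genes].astype(float)
    table = pd.DataFrame({"expr_diff": e, "meth_diff": m})
    passing = (e.abs() > z_cut) & (m.abs() > m_cut)
    counts: dict[tuple[str, str], int] = {}
    lists: dict[tuple[str, str], list[str]] = {}
    for e_sign, e_name in ((1, "up"), (-1, "down")):
        for m_sign, m_name in ((1, "hyper"), (-1, "hypo")):
            sel = passing & (np.sign(e) == e_sign) & (np.sign(m) == m_sign)
            counts[(e_name, m_name)] = int(sel.sum())
            lists[(e_name, m_name)] = sorted(genes[sel])
    return ConcordanceResult(table, counts, lists)
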