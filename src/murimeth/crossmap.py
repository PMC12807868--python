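"""Cross-species matching of query tumors to a labeled reference cohort.

Mouse (query) samples are matched to human (reference) methylation classes on
a shared ortholog CpG panel through two independent arms:

* an iterated-embedding arm — repeated 2-D UMAP embeddings of the query with a
  random 90% of the reference, voting for the class at minimal mean embedding
  distance; and
* a class-balanced random forest trained on the reference panel, where every
  tree draws an equal bootstrap of min-class-size samples per class.

Per-model consensus calls are tested against class-frequency chance with a
one-sided exact binomial test, Benjamini-Hochberg corrected across models.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .core import BetaMatrix, ValidationError
from .diffmeth import bh_adjust, differential_methylation_omnibus, select_top_sites
from .qc import quantile_normalize

logger = logging.getLogger("murimeth.crossmap")

UMAP_KWARGS = {"n_neighbors": 15, "min_dist": 0.1, "metric": "euclidean", "n_components": 2}


def _umap_embed(X: np.ndarray, seed: int) -> np.ndarray:
    import umap  # deferred: heavy import

    kwargs = dict(UMAP_KWARGS)
    kwargs["n_neighbors"] = min(kwargs["n_neighbors"], X.shape[0] - 1)
    reducer = umap.UMAP(random_state=seed, **kwargs)
    return reducer.fit_transform(X)


@dataclass
class CrossPanel:
    """Ortholog CpG panel with jointly normalized reference + query betas."""

    betas: BetaMatrix  # panel probes x (reference + query samples), quantile normalized
    reference_samples: list[str]
    query_samples: list[str]
    reference_labels: pd.Series  # class per reference sample
    pairs: pd.DataFrame  # query_probe / reference_probe of the panel

    @property
    def classes(self) -> list[str]:
        return sorted(self.reference_labels.unique())


def build_cross_species_panel(
    reference: BetaMatrix,
    reference_labels: pd.Series,
    query: BetaMatrix,
    orthologs: pd.DataFrame,
    human_top_sites: int = 15000,
) -> CrossPanel:
    """Select the reference's top differentially methylated sites, keep those
    with an ortholog on the query array, and jointly quantile-normalize both
    cohorts restricted to that panel.

    Raises a "no ortholog panel" error when the intersection is empty.
    """
    if orthologs.empty:
        raise ValidationError("ortholog map is empty")
    labels = pd.Series(reference_labels).reindex(reference.sample_ids)
    if labels.nunique() < 2:
        raise ValidationError("reference needs >= 2 classes")
    ref = reference.impute_median()
    omni = differential_methylation_omnibus(ref, labels)
    k = min(human_top_sites, len(ref.probe_ids))
    top = set(select_top_sites(omni.table, k=k))

    mapped = orthologs[orthologs["reference_probe"].isin(top)]
    mapped = mapped[mapped["query_probe"].isin(query.probe_ids)]
    if mapped.empty:
        raise ValidationError("no ortholog panel: top sites share no probes with query")

    ref_panel = ref.values.loc[mapped["reference_probe"]]
    q = query.impute_median()
    query_panel = q.values.loc[mapped["query_probe"]]
    query_panel.index = mapped["reference_probe"].to_numpy()

    combined = pd.concat([ref_panel, query_panel], axis=1)
    normalized = quantile_normalize(BetaMatrix(combined))
    return CrossPanel(
        betas=normalized,
        reference_samples=list(reference.sample_ids),
        query_samples=list(query.sample_ids),
        reference_labels=labels,
        pairs=mapped.reset_index(drop=True),
    )


def iterated_embedding_match(
    panel: CrossPanel,
    n_iter: int = 10,
    subsample: float = 0.9,
    seed: int = 0,
    batch: bool = True,
    max_redraws: int = 20,
) -> pd.DataFrame:
    """Per-iteration nearest reference class for every query sample.

    Each iteration embeds a random ``subsample`` fraction of the reference
    together with the query into 2-D UMAP (iteration-derived seed) and votes
    for the class at minimal mean Euclidean distance.  ``batch=False`` embeds
    one query sample at a time (the literal per-sample procedure);
    ``batch=True`` embeds all queries jointly, which is equivalent for
    well-separated references and much faster.

    Returns an (iterations x query samples) frame of class votes.
    """
    rng = np.random.default_rng(seed)
    ref_ids = np.array(panel.reference_samples)
    labels = panel.reference_labels
    n_keep = max(1, int(round(subsample * len(ref_ids))))
    X = panel.betas.values

    votes = pd.DataFrame(
        index=pd.RangeIndex(n_iter, name="iteration"),
        columns=panel.query_samples,
        dtype=object,
    )
    for it in range(n_iter):
        chosen = None
        for attempt in range(max_redraws):
            cand = rng.choice(ref_ids, size=n_keep, replace=False)
            if labels.loc[cand].nunique() == labels.nunique():
                chosen = cand
                break
            logger.warning("iteration %d: subsampling emptied a class, redrawing", it)
        if chosen is None:
            raise ValidationError("subsampling repeatedly emptied a reference class")
        it_seed = seed + it

        if batch:
            cols = list(chosen) + list(panel.query_samples)
            emb = _umap_embed(X[cols].to_numpy().T, it_seed)
            ref_emb = emb[: len(chosen)]
            q_emb = emb[len(chosen) :]
            for qi, qs in enumerate(panel.query_samples):
                votes.loc[it, qs] = _nearest_class(q_emb[qi], ref_emb, labels.loc[chosen])
        else:
            for qs in panel.query_samples:
                cols = list(chosen) + [qs]
                emb = _umap_embed(X[cols].to_numpy().T, it_seed)
                votes.loc[it, qs] = _nearest_class(
                    emb[-1], emb[:-1], labels.loc[chosen]
                )
    return votes


def _nearest_class(
    query_xy: np.ndarray, ref_xy: np.ndarray, ref_labels: pd.Series
) -> str:
    d = np.linalg.norm(ref_xy - query_xy[None, :], axis=1)
    means = pd.Series(d).groupby(ref_labels.to_numpy()).mean()
    # deterministic tie-break: smallest mean distance, then class label
    return means.sort_index().idxmin()


def consensus_match(
    votes: pd.Series | pd.DataFrame, grouping: pd.Series
) -> pd.Series:
    """Most frequent vote per model; ties break lexicographically (logged).

    ``votes`` is either per-sample classes (Series indexed by sample) or an
    iterations x samples frame; ``grouping`` maps sample id to model.
    """
    if isinstance(votes, pd.DataFrame):
        long = votes.melt(var_name="sample", value_name="vote")
    else:
        long = pd.DataFrame({"vote": votes, "sample": votes.index})
    long["model"] = pd.Series(grouping).reindex(long["sample"]).to_numpy()
    if long["model"].isna().any():
        raise ValidationError("grouping misses some voting samples")

    out = {}
    for model, grp in long.groupby("model"):
        counts = Counter(grp["vote"])
        best = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == best)
        if len(winners) > 1:
            logger.info("model %s: consensus tie among %s, taking %s", model, winners, winners[0])
        out[model] = winners[0]
    return pd.Series(out, name="consensus").sort_index()


def per_sample_consensus(votes: pd.DataFrame) -> pd.Series:
    """Modal class per query sample over embedding iterations (ties lexicographic)."""
    result = {}
    for sample in votes.columns:
        counts = Counter(votes[sample])
        best = max(counts.values())
        result[sample] = sorted(c for c, n in counts.items() if n == best)[0]
    return pd.Series(result, name="match")


class BalancedRandomForest:
    """Random forest with per-tree stratified bootstraps of equal class size.

    Every tree trains on exactly min-class-size samples drawn with replacement
    from each class, which neutralizes class imbalance the same way the
    ``sampsize`` device does in classical random-forest implementations.
    Out-of-bag votes are tracked for balance diagnostics.
    """

    def __init__(self, n_trees: int = 1000, seed: int = 0, max_features: str = "sqrt"):
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.oob_votes_: pd.DataFrame | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValidationError("need >= 2 classes")
        class_idx = {c: np.flatnonzero(y == c) for c in self.classes_}
        m = min(len(v) for v in class_idx.values())
        if m < 2:
            raise ValidationError("smallest class needs >= 2 samples")
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        oob_counts = np.zeros((n, len(self.classes_)))
        cls_pos = {c: j for j, c in enumerate(self.classes_)}
        self.trees_ = []
        for _ in range(self.n_trees):
            rows = np.concatenate(
                [rng.choice(class_idx[c], size=m, replace=True) for c in self.classes_]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[rows], y[rows])
            self.trees_.append(tree)
            oob = np.setdiff1d(np.arange(n), rows)
            if len(oob):
                pred = tree.predict(X[oob])
                for i, c in zip(oob, pred):
                    oob_counts[i, cls_pos[c]] += 1
        self.oob_votes_ = pd.DataFrame(oob_counts, columns=self.classes_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((X.shape[0], len(self.classes_)))
        cls_pos = {c: j for j, c in enumerate(self.classes_)}
        for tree in self.trees_:
            for i, c in enumerate(tree.predict(X)):
                votes[i, cls_pos[c]] += 1
        # majority vote; ties resolved toward the lexicographically first class
        return self.classes_[votes.argmax(axis=1)]


def balanced_forest_match(
    panel: CrossPanel, n_trees: int = 1000, seed: int = 0
) -> tuple[pd.Series, BalancedRandomForest]:
    """Train the balanced forest on the reference panel and classify the query."""
    X = panel.betas.values
    ref_X = X[panel.reference_samples].to_numpy().T
    y = panel.reference_labels.loc[panel.reference_samples].to_numpy()
    forest = BalancedRandomForest(n_trees=n_trees, seed=seed).fit(ref_X, y)
    q_X = X[panel.query_samples].to_numpy().T
    preds = pd.Series(
        forest.predict(q_X), index=pd.Index(panel.query_samples, name="sample_id"),
        name="predicted_class",
    )
    return preds, forest


def match_significance(
    sample_matches: pd.Series,
    grouping: pd.Series,
    expected_entity: pd.Series,
    reference_labels: pd.Series,
) -> pd.DataFrame:
    """One-sided exact binomial test of per-model matching against chance.

    Per model: trials = query samples, successes = samples matched to the
    expected entity, null probability = that entity's frequency among the
    reference samples.  BH correction across models.
    """
    ref_freq = reference_labels.value_counts(normalize=True)
    rows = []
    models = sorted(pd.Series(grouping).unique())
    for model in models:
        samples = grouping.index[grouping == model]
        n = len(samples)
        expected = expected_entity.loc[model]
        k = int((sample_matches.loc[samples] == expected).sum())
        p0 = float(ref_freq.get(expected, 0.0))
        if not (0 < p0 < 1):
            raise ValidationError(
                f"null probability for entity {expected!r} must lie in (0, 1), got {p0}"
            )
        p = float(stats.binom.sf(k - 1, n, p0))  # P(X >= k)
        rows.append((model, expected, n, k, p0, p))
    out = pd.DataFrame(
        rows, columns=["model", "expected_entity", "n_samples", "n_matched", "p0", "p_value"]
    ).set_index("model")
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def _align_coords(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Procrustes alignment (translation, scale, rotation/reflection) of B to A."""
    mtx1, mtx2, _ = _procrustes(A, B)
    return mtx1, mtx2


def _procrustes(A: np.ndarray, B: np.ndarray):
    from scipy.spatial import procrustes

    return procrustes(A, B)


def embedding_stability(
    reference: BetaMatrix,
    n_iter: int = 500,
    subsample: float = 0.9,
    seed: int = 0,
    align: bool = True,
) -> pd.DataFrame:
    """Coordinate reproducibility of the reference embedding across subsampled runs.

    Embeds a random ``subsample`` fraction ``n_iter`` times, then for every
    pair of iterations correlates x and y coordinates over the shared samples.
    With ``align=True`` each pair is Procrustes-aligned first (rotation and
    reflection removed), since raw UMAP axes are arbitrary; ``align=False``
    gives the literal unaligned correlations.

    Returns one row per iteration pair with columns ``r_x`` and ``r_y``.
    """
    if len(reference.sample_ids) < 10:
        raise ValidationError("stability check needs >= 10 reference samples")
    rng = np.random.default_rng(seed)
    ids = np.array(reference.sample_ids)
    n_keep = max(3, int(round(subsample * len(ids))))
    X = reference.impute_median().values

    coords: list[pd.DataFrame] = []
    for it in range(n_iter):
        chosen = rng.choice(ids, size=n_keep, replace=False)
        emb = _umap_embed(X[list(chosen)].to_numpy().T, seed + it)
        coords.append(pd.DataFrame(emb, index=chosen, columns=["x", "y"]))

    rows = []
    for i in range(n_iter):
        for j in range(i + 1, n_iter):
            shared = coords[i].index.intersection(coords[j].index)
            if len(shared) < 3:
                continue
            A = coords[i].loc[shared].to_numpy()
            B = coords[j].loc[shared].to_numpy()
            if align:
                A, B = _align_coords(A, B)
            r_x = _safe_corr(A[:, 0], B[:, 0])
            r_y = _safe_corr(A[:, 1], B[:, 1])
            rows.append((i, j, r_x, r_y))
    return pd.DataFrame(rows, columns=["iter_a", "iter_b", "r_x", "r_y"])


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def mutational_load(
    mutation_counts: pd.Series, panel_genes: int = 130
) -> pd.Series:
    """Mutations per fixed gene panel: count divided by the panel size."""
    counts = pd.Series(mutation_counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("mutation counts must be >= 0")
    if panel_genes <= 0:
        raise ValidationError("panel size must be positive")
    return counts / panel_genes
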