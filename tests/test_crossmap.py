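"""Ortholog panel construction, matching arms, consensus and significance."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from murimeth.core import BetaMatrix, ValidationError
from murimeth.crossmap import (
    BalancedRandomForest,
    _align_coords,
    _safe_corr,
    build_cross_species_panel,
    balanced_forest_match,
    consensus_match,
    iterated_embedding_match,
    match_significance,
    mutational_load,
    per_sample_consensus,
)
from murimeth.simulate import SimCohortSpec, gen_cross_species_cohort


@pytest.fixture(scope="module")
def cross_fixture():
    spec = SimCohortSpec(
        n_classes=4, samples_per_class=4, n_probes=4000,
        signature_sites_per_class=80, noise_sd=0.05, seed=77,
    )
    return gen_cross_species_cohort(spec, ortholog_fraction=0.2,
                                    query_samples_per_class=2)


@pytest.fixture(scope="module")
def cross_panel(cross_fixture):
    fx = cross_fixture
    return build_cross_species_panel(
        fx.reference, fx.reference_labels, fx.query, fx.orthologs,
        human_top_sites=400,
    )


class TestPanel:
    def test_full_ortholog_coverage_gives_top_site_panel(self, cross_fixture):
        fx = cross_fixture
        full = pd.DataFrame({
            "query_probe": fx.query.probe_ids,
            "reference_probe": fx.reference.probe_ids,
        })
        panel = build_cross_species_panel(
            fx.reference, fx.reference_labels, fx.query, full, human_top_sites=100
        )
        assert len(panel.pairs) == 100

    def test_orthologs_outside_top_sites_error(self, cross_fixture):
        fx = cross_fixture
        with pytest.raises(ValidationError, match="empty|no ortholog"):
            build_cross_species_panel(
                fx.reference, fx.reference_labels, fx.query,
                fx.orthologs.iloc[0:0], human_top_sites=100,
            )

    def test_panel_size_matches_set_intersection(self, cross_fixture, cross_panel):
        from murimeth.diffmeth import differential_methylation_omnibus, select_top_sites

        fx = cross_fixture
        omni = differential_methylation_omnibus(
            fx.reference.impute_median(), fx.reference_labels
        )
        top = set(select_top_sites(omni.table, k=400))
        expected = top & set(fx.orthologs["reference_probe"])
        assert set(cross_panel.pairs["reference_probe"]) == expected


class TestEmbeddingArm:
    def test_votes_deterministic_under_seed(self, cross_panel):
        a = iterated_embedding_match(cross_panel, n_iter=1, seed=5)
        b = iterated_embedding_match(cross_panel, n_iter=1, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_well_separated_classes_recovered(self, cross_fixture, cross_panel):
        votes = iterated_embedding_match(cross_panel, n_iter=3, seed=9)
        truth = pd.Series(cross_fixture.truth.class_of_sample)
        match = per_sample_consensus(votes)
        assert (match == truth.loc[match.index]).mean() >= 0.9

    def test_reference_twin_query_wins_every_iteration(self):
        rng = np.random.default_rng(6)
        probes = [f"p{i}" for i in range(150)]
        # class signatures move probes in both directions so they survive
        # joint quantile normalization (a pure global shift would not)
        mu_a = np.where(np.arange(150) < 75, 0.2, 0.8)
        centers = {"A": mu_a, "B": 1 - mu_a}
        cols, labels = {}, {}
        for cls, mu in centers.items():
            for r in range(8):
                sid = f"{cls}{r}"
                cols[sid] = np.clip(mu + rng.normal(0, 0.02, 150), 0, 1)
                labels[sid] = cls
        ref = BetaMatrix(pd.DataFrame(cols, index=probes))
        twin = BetaMatrix(pd.DataFrame({"twin": ref.values["A0"]}, index=probes))
        pairs = pd.DataFrame({"query_probe": probes, "reference_probe": probes})
        panel = build_cross_species_panel(
            ref, pd.Series(labels), twin, pairs, human_top_sites=150
        )
        votes = iterated_embedding_match(panel, n_iter=3, seed=1)
        assert (votes["twin"] == "A").all()


class TestConsensus:
    def test_simple_majority(self):
        votes = pd.Series({"s1": "A", "s2": "A", "s3": "B"})
        grouping = pd.Series({"s1": "m", "s2": "m", "s3": "m"})
        assert consensus_match(votes, grouping).loc["m"] == "A"

    def test_tie_breaks_lexicographically(self):
        votes = pd.Series({"s1": "B", "s2": "A"})
        grouping = pd.Series({"s1": "m", "s2": "m"})
        assert consensus_match(votes, grouping).loc["m"] == "A"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_frequency_count(self, seed):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(30)]
        votes = pd.Series(rng.choice(list("ABC"), 30), index=samples)
        grouping = pd.Series(rng.choice(["m1", "m2", "m3"], 30), index=samples)
        result = consensus_match(votes, grouping)
        for model in grouping.unique():
            members = votes[grouping[grouping == model].index]
            counts = members.value_counts()
            best = counts.max()
            assert result.loc[model] == sorted(counts.index[counts == best])[0]


class TestBalancedForest:
    def test_separable_classes_classified_perfectly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (30, 20)), rng.normal(3, 0.3, (30, 20))])
        y = np.array(["lo"] * 30 + ["hi"] * 30)
        train = np.r_[0:20, 30:50]
        test = np.r_[20:30, 50:60]
        forest = BalancedRandomForest(n_trees=100, seed=3).fit(X[train], y[train])
        assert (forest.predict(X[test]) == y[test]).all()

    def test_training_sample_maps_to_own_class(self, cross_panel):
        preds, forest = balanced_forest_match(cross_panel, n_trees=100, seed=4)
        X = cross_panel.betas.values[cross_panel.reference_samples].to_numpy().T
        y = cross_panel.reference_labels.loc[cross_panel.reference_samples].to_numpy()
        assert (forest.predict(X) == y).all()

    def test_oob_votes_balanced_on_null_panel_despite_9_to_1_priors(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (100, 30))  # no class signal at all
        y = np.array(["big"] * 90 + ["small"] * 10)
        forest = BalancedRandomForest(n_trees=400, seed=6).fit(X, y)
        oob = forest.oob_votes_.to_numpy()
        frac_small = oob[:, list(forest.classes_).index("small")].sum() / oob.sum()
        assert abs(frac_small - 0.5) < 0.10

    def test_degenerate_smallest_class_rejected(self):
        X = np.zeros((3, 4))
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValidationError, match="smallest class"):
            BalancedRandomForest(n_trees=5).fit(X, y)


class TestMatchSignificance:
    def _frame(self, matches, grouping, expected, ref_labels):
        return match_significance(
            pd.Series(matches), pd.Series(grouping), pd.Series(expected),
            pd.Series(ref_labels),
        )

    def test_perfect_match_closed_form(self):
        # 5/5 successes at null 0.1: p = 0.1^5
        ref_labels = {f"r{i}": ("T" if i < 2 else f"o{i}") for i in range(20)}
        matches = {f"q{i}": "T" for i in range(5)}
        grouping = {f"q{i}": "m" for i in range(5)}
        out = self._frame(matches, grouping, {"m": "T"}, ref_labels)
        assert out.loc["m", "p_value"] == pytest.approx(1e-5)

    def test_zero_successes_give_p_one(self):
        ref_labels = {f"r{i}": ("T" if i < 5 else "o") for i in range(10)}
        matches = {f"q{i}": "o" for i in range(4)}
        grouping = {f"q{i}": "m" for i in range(4)}
        out = self._frame(matches, grouping, {"m": "T"}, ref_labels)
        assert out.loc["m", "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_binomial_tail_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.05, 0.95))
        # brute force: sum over all outcome vectors of length n
        brute = sum(
            comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
        )
        assert stats.binom.sf(k - 1, n, p0) == pytest.approx(brute, rel=1e-12)

    def test_invalid_null_probability_rejected(self):
        ref_labels = {"r0": "T"}  # p0 = 1
        with pytest.raises(ValidationError, match="null probability"):
            self._frame({"q0": "T"}, {"q0": "m"}, {"m": "T"}, ref_labels)


class TestStabilityHelpers:
    def test_identical_embeddings_correlate_perfectly(self):
        rng = np.random.default_rng(7)
        A = rng.normal(0, 1, (20, 2))
        a, b = _align_coords(A, A.copy())
        assert _safe_corr(a[:, 0], b[:, 0]) == pytest.approx(1.0)
        assert _safe_corr(a[:, 1], b[:, 1]) == pytest.approx(1.0)

    def test_mirrored_embedding_aligns_to_perfect_correlation(self):
        rng = np.random.default_rng(8)
        A = rng.normal(0, 1, (20, 2))
        M = A.copy()
        M[:, 0] *= -1  # x mirror
        a, b = _align_coords(A, M)
        assert _safe_corr(a[:, 0], b[:, 0]) == pytest.approx(1.0, abs=1e-9)
        assert _safe_corr(a[:, 1], b[:, 1]) == pytest.approx(1.0, abs=1e-9)


class TestEmbeddingStability:
    def test_clustered_data_more_stable_than_structureless(self):
        rng = np.random.default_rng(9)
        probes = [f"p{i}" for i in range(120)]
        mu = np.where(np.arange(120) < 60, 0.15, 0.85)
        cols = {}
        for r in range(10):
            cols[f"a{r}"] = np.clip(mu + rng.normal(0, 0.03, 120), 0, 1)
            cols[f"b{r}"] = np.clip((1 - mu) + rng.normal(0, 0.03, 120), 0, 1)
        clustered = BetaMatrix(pd.DataFrame(cols, index=probes))
        noise = BetaMatrix(pd.DataFrame(
            rng.random((120, 20)), index=probes,
            columns=[f"n{r}" for r in range(20)],
        ))
        from murimeth.crossmap import embedding_stability

        r_clustered = embedding_stability(clustered, n_iter=5, seed=3)
        r_noise = embedding_stability(noise, n_iter=5, seed=3)
        med = lambda df: np.median(np.abs(df[["r_x", "r_y"]].to_numpy()))
        assert med(r_clustered) > med(r_noise)

    def test_too_few_samples_rejected(self):
        bm = BetaMatrix(pd.DataFrame(np.full((10, 4), 0.5),
                                     index=[f"p{i}" for i in range(10)],
                                     columns=list("abcd")))
        from murimeth.crossmap import embedding_stability

        with pytest.raises(ValidationError):
            embedding_stability(bm, n_iter=2)


class TestMutationalLoad:
    def test_zero_and_linear_scaling(self):
        counts = pd.Series({"e1": 0, "e2": 260, "e3": 65})
        load = mutational_load(counts)
        assert load["e1"] == 0
        assert load["e2"] == pytest.approx(2.0)
        assert load["e3"] == pytest.approx(0.5)
        double = mutational_load(counts * 2)
        np.testing.assert_allclose(double, 2 * load)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mutational_load(pd.Series({"e": -1}))
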