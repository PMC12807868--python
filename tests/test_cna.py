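"""Copy-number references, log ratios, binning/CBS, instability, cohort frequency."""

import numpy as np
import pandas as pd
import pytest

from murimeth.cna import (
    BinTrack,
    bin_and_segment,
    build_cn_reference,
    chromosomal_instability,
    cohort_cna_frequency,
    cohort_instability,
    probe_log_ratios,
)
from murimeth.core import (
    IntensityMatrix,
    ProbeManifest,
    SampleSheet,
    SegmentTable,
    ValidationError,
)
from murimeth.simulate import SimCnaSpec, gen_cna_cohort


def _sheet(rows):
    return SampleSheet(pd.DataFrame(
        rows,
        columns=["model", "entity", "family", "role", "sex", "preservation", "batch"],
        index=pd.Index([r[-1] for r in []] or [f"s{i}" for i in range(len(rows))],
                       name="sample_id"),
    ))


@pytest.fixture(scope="module")
def cna_cohort():
    return gen_cna_cohort(SimCnaSpec(
        seed=51,
        planted_segments=(
            (("tumor00",), "chr1", 20_000_001, 60_000_000, 0.5),
            (("tumor01",), "chr2", 10_000_001, 40_000_000, -0.5),
        ),
    ))


class TestCnReference:
    def test_single_control_reference_equals_that_sample(self):
        probes = [f"p{i}" for i in range(10)]
        im = IntensityMatrix(pd.DataFrame({"c0": np.arange(1, 11, dtype=float)},
                                          index=probes))
        sheet = _sheet([["m", "ctl", "f", "control", "female", "fresh", "b"]])
        sheet.table.index = pd.Index(["c0"], name="sample_id")
        ref = build_cn_reference(im, SampleSheet(sheet.table))
        np.testing.assert_array_equal(ref.profiles["female"], im.values["c0"])

    def test_two_controls_average(self):
        probes = ["p0"]
        im = IntensityMatrix(pd.DataFrame({"c0": [100.0], "c1": [300.0]}, index=probes))
        table = pd.DataFrame(
            {"model": "m", "entity": "ctl", "family": "f", "role": "control",
             "sex": "female", "preservation": "fresh", "batch": "b"},
            index=pd.Index(["c0", "c1"], name="sample_id"),
        )
        ref = build_cn_reference(im, SampleSheet(table))
        assert ref.profiles["female"].iloc[0] == 200.0

    def test_reference_matches_per_probe_loop(self, cna_cohort):
        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        controls = cna_cohort.sheet.samples_with(role="control", sex="male",
                                                 preservation="fresh")
        vals = cna_cohort.intensities.values
        for probe in list(cna_cohort.manifest.probe_ids[:20]):
            manual = sum(vals.loc[probe, c] for c in controls) / len(controls)
            assert ref.profiles["male"].loc[probe] == pytest.approx(manual)

    def test_ffpe_key_trumps_sex(self, cna_cohort):
        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        ref.profiles["FFPE"] = ref.profiles["female"]
        assert ref.key_for("male", "FFPE") == "FFPE"
        assert ref.key_for("male", "fresh") == "male"


class TestLogRatios:
    def test_sample_equal_to_reference_gives_zero(self, cna_cohort):
        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        r = probe_log_ratios(ref.profiles["female"], ref.profiles["female"],
                             cna_cohort.manifest)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_uniform_doubling_centered_away(self, cna_cohort):
        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        r = probe_log_ratios(2.0 * ref.profiles["female"], ref.profiles["female"],
                             cna_cohort.manifest)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_planted_segment_mean_recovered(self, cna_cohort):
        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        info = cna_cohort.sheet.table.loc["tumor00"]
        key = ref.key_for(info["sex"], info["preservation"])
        r = probe_log_ratios(cna_cohort.intensities.values["tumor00"],
                             ref.profiles[key], cna_cohort.manifest)
        ann = cna_cohort.manifest.table
        on = (ann["chromosome"] == "chr1") & (ann["position"] > 20_000_000) \
            & (ann["position"] <= 60_000_000)
        n = int(on.sum())
        tol = 3 * 0.1 / np.sqrt(n) + 0.02  # noise sd 0.1, slight centering shift
        assert r[on.index[on]].mean() == pytest.approx(0.5, abs=tol)

    def test_nonpositive_rejected(self, cna_cohort):
        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        bad = ref.profiles["female"].copy()
        bad.iloc[0] = -1.0
        with pytest.raises(ValidationError):
            probe_log_ratios(bad, ref.profiles["female"], cna_cohort.manifest)


def _flat_manifest(n_probes=200, chroms=("chr1", "chr2"), spacing=200_000):
    rows = []
    per = n_probes // len(chroms)
    for c in chroms:
        for i in range(per):
            rows.append((c, 1 + i * spacing))
    probes = [f"p{i:04d}" for i in range(len(rows))]
    return ProbeManifest(pd.DataFrame(
        {"chromosome": [r[0] for r in rows], "position": [r[1] for r in rows],
         "promoter_gene": pd.NA, "ortholog_id": pd.NA},
        index=pd.Index(probes, name="probe_id"),
    ))


class TestSegmentation:
    def test_flat_noiseless_track_one_neutral_segment_per_chromosome(self):
        manifest = _flat_manifest()
        ratios = pd.Series(0.0, index=manifest.probe_ids)
        _, segs = bin_and_segment(ratios, manifest, "s", bin_size=2_000_000,
                                  nperm=500, seed=1)
        assert len(segs.table) == 2
        assert (segs.table["call"] == "neutral").all()

    def test_single_breakpoint_localized_within_one_bin(self):
        rng = np.random.default_rng(3)
        manifest = _flat_manifest(n_probes=400, chroms=("chr1",), spacing=100_000)
        vals = rng.normal(0, 0.02, 400)
        vals[200:] += 0.5  # step at probe 200 = position 20,000,001
        ratios = pd.Series(vals, index=manifest.probe_ids)
        _, segs = bin_and_segment(ratios, manifest, "s", bin_size=1_000_000,
                                  min_probes_per_bin=10, nperm=2000, seed=2)
        assert len(segs.table) == 2
        breakpoint = segs.table.iloc[1]["start"]
        assert abs(breakpoint - 20_000_001) <= 1_000_000

    def test_segment_means_equal_mean_of_member_bins(self, cna_cohort):
        from murimeth.cna import build_cn_reference

        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        r = probe_log_ratios(cna_cohort.intensities.values["tumor00"],
                             ref.profiles["female"], cna_cohort.manifest)
        track, segs = bin_and_segment(r, cna_cohort.manifest, "tumor00",
                                      bin_size=2_000_000, nperm=1000, seed=3)
        for seg in segs.table.itertuples(index=False):
            members = track.bins[
                (track.bins["chromosome"] == seg.chromosome)
                & (track.bins["start"] >= seg.start)
                & (track.bins["end"] <= seg.end)
            ]
            assert len(members) == seg.n_bins
            assert seg.seg_mean == pytest.approx(members["value"].mean())

    def test_reproducible_under_seed_and_probe_order(self, cna_cohort):
        from murimeth.cna import build_cn_reference

        ref = build_cn_reference(cna_cohort.intensities, cna_cohort.sheet)
        r = probe_log_ratios(cna_cohort.intensities.values["tumor01"],
                             ref.profiles["male"], cna_cohort.manifest)
        _, a = bin_and_segment(r, cna_cohort.manifest, "t", bin_size=2_000_000,
                               nperm=1000, seed=9)
        _, b = bin_and_segment(r, cna_cohort.manifest, "t", bin_size=2_000_000,
                               nperm=1000, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(r))
        shuffled_manifest = ProbeManifest(cna_cohort.manifest.table.iloc[perm])
        _, c = bin_and_segment(r.iloc[perm], shuffled_manifest, "t",
                               bin_size=2_000_000, nperm=1000, seed=9)
        assert sorted(map(tuple, c.table[["chromosome", "start", "end"]].to_numpy())) \
            == sorted(map(tuple, a.table[["chromosome", "start", "end"]].to_numpy()))


class TestInstability:
    def _track(self, values):
        n = len(values)
        return BinTrack(pd.DataFrame({
            "chromosome": "chr1",
            "start": np.arange(n) * 100 + 1,
            "end": (np.arange(n) + 1) * 100,
            "n_probes": 15,
            "value": values,
        }))

    def test_flat_track_zero(self):
        assert chromosomal_instability(self._track(np.zeros(10))) == 0.0

    def test_three_of_ten_bins_altered(self):
        vals = np.zeros(10)
        vals[:3] = 0.2
        assert chromosomal_instability(self._track(vals)) == pytest.approx(0.3)

    def test_threshold_is_strict(self):
        vals = np.full(4, 0.1)  # exactly at threshold: not altered
        assert chromosomal_instability(self._track(vals)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_count(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 0.15, 50)
        brute = sum(1 for v in vals if abs(v) > 0.1) / 50
        assert chromosomal_instability(self._track(vals)) == pytest.approx(brute)

    def test_cohort_mean(self):
        tracks = {"a": self._track(np.zeros(10)),
                  "b": self._track(np.full(10, 0.5))}
        out = cohort_instability(tracks)
        assert out["__cohort__"] == pytest.approx(0.5)


class TestCohortFrequency:
    GRID = pd.DataFrame({
        "chromosome": ["chr1"] * 10,
        "start": np.arange(10) * 1_000_000 + 1,
        "end": (np.arange(10) + 1) * 1_000_000,
    })

    def _segs(self, rows):
        return SegmentTable(pd.DataFrame(
            rows, columns=["sample_id", "chromosome", "start", "end",
                           "n_bins", "seg_mean", "call"],
        ))

    def test_single_sample_single_gain(self):
        segs = self._segs([
            ["s", "chr1", 1, 3_000_000, 3, 0.5, "gain"],
            ["s", "chr1", 3_000_001, 10_000_000, 7, 0.0, "neutral"],
        ])
        out = cohort_cna_frequency(segs, self.GRID)
        np.testing.assert_array_equal(out["gain_freq"][:3], 1.0)
        np.testing.assert_array_equal(out["gain_freq"][3:], 0.0)

    def test_disjoint_gains_split_frequency(self):
        segs = self._segs([
            ["a", "chr1", 1, 5_000_000, 5, 0.4, "gain"],
            ["a", "chr1", 5_000_001, 10_000_000, 5, 0.0, "neutral"],
            ["b", "chr1", 1, 5_000_000, 5, 0.0, "neutral"],
            ["b", "chr1", 5_000_001, 10_000_000, 5, 0.4, "gain"],
        ])
        out = cohort_cna_frequency(segs, self.GRID)
        np.testing.assert_allclose(out["gain_freq"], 0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_bin_tally(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for sid in ("a", "b", "c"):
            cut = int(rng.integers(1, 10)) * 1_000_000
            calls = rng.choice(["gain", "loss", "neutral"], size=2)
            rows.append([sid, "chr1", 1, cut, max(1, cut // 10**6),
                         0.4 if calls[0] == "gain" else -0.4 if calls[0] == "loss" else 0.0,
                         calls[0]])
            rows.append([sid, "chr1", cut + 1, 10_000_000, 1,
                         0.4 if calls[1] == "gain" else -0.4 if calls[1] == "loss" else 0.0,
                         calls[1]])
        segs = self._segs(rows)
        out = cohort_cna_frequency(segs, self.GRID)
        mids = (self.GRID["start"] + self.GRID["end"]) // 2
        for bi, mid in enumerate(mids):
            gains = losses = 0
            for sid in ("a", "b", "c"):
                sub = segs.for_sample(sid)
                cover = sub[(sub["start"] <= mid) & (sub["end"] >= mid)]
                call = cover.iloc[0]["call"]
                gains += call == "gain"
                losses += call == "loss"
            assert out.loc[bi, "gain_freq"] == pytest.approx(gains / 3)
            assert out.loc[bi, "loss_freq"] == pytest.approx(losses / 3)
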