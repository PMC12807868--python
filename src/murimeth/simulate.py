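"""Synthetic cohort generators with full ground-truth records.

The generators emulate the statistical structure the analysis stages assume:
class-structured beta matrices with planted population-specific differentially
methylated CpGs, probe-intensity profiles with planted segment-level
copy-number shifts, an ortholog probe subset shared between a "mouse" and a
"human" array universe, and a block-wise synteny map.  Every planted effect is
recorded in a :class:`TruthRecord` so downstream recovery tests never have to
re-derive the truth.

Baseline betas follow a two-component mixture concentrated near 0.1 and 0.9
(the marginal bimodality of methylation arrays); replicate noise is Gaussian
on the beta scale, truncated to [0, 1] by clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    IntensityMatrix,
    ProbeManifest,
    SampleSheet,
    SyntenyMap,
    ValidationError,
)

MOUSE_AUTOSOME_COUNT = 19


@dataclass
class SimCohortSpec:
    """Parameters of a class-structured methylome cohort.

    Defaults mirror the deconvolution-reference construction setting: 10
    populations, 5 replicates each, 50,000 probes, 200 disjoint signature
    sites per population shifted by 0.5, replicate noise sd 0.05.
    """

    n_classes: int = 10
    samples_per_class: int = 5
    n_probes: int = 50000
    signature_sites_per_class: int = 200
    signature_delta: float = 0.5
    noise_sd: float = 0.05
    baseline_mix: tuple[float, float, float] = (0.1, 0.9, 0.5)  # (low mode, high mode, weight of low)
    baseline_sd: float = 0.05
    n_bad_samples: int = 0
    promoter_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature_sites_per_class * self.n_classes > self.n_probes:
            raise ValidationError("signature sites exceed probe universe")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_bad_samples > self.n_classes * self.samples_per_class:
            raise ValidationError("more bad samples than samples")


@dataclass
class SimCnaSpec:
    """Parameters of an intensity cohort with planted copy-number segments.

    ``planted_segments`` holds (sample ids, chromosome, start, end, log2 shift)
    tuples; probes are evenly spaced per chromosome.
    """

    chromosomes: Sequence[tuple[str, int]] = (
        ("chr1", 100_000_000),
        ("chr2", 100_000_000),
        ("chr3", 100_000_000),
        ("chr4", 100_000_000),
    )
    probes_per_chromosome: int = 500
    n_tumors: int = 6
    n_controls: int = 4
    planted_segments: Sequence[tuple[Sequence[str], str, int, int, float]] = ()
    probe_noise_sd: float = 0.1
    base_intensity: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for _, chrom, start, end, shift in self.planted_segments:
            if chrom not in lengths:
                raise ValidationError(f"planted segment on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValidationError("planted segment outside chromosome bounds")
            if not np.isfinite(shift):
                raise ValidationError("planted shift must be finite")


@dataclass
class TruthRecord:
    """Complete record of every planted effect in a synthetic dataset."""

    class_of_sample: dict[str, str] = field(default_factory=dict)
    signature_sites: dict[str, list[str]] = field(default_factory=dict)
    signature_directions: dict[str, list[int]] = field(default_factory=dict)
    class_means: dict[str, list[float]] | None = None
    bad_samples: list[str] = field(default_factory=list)
    planted_segments: dict[str, list[dict]] = field(default_factory=dict)
    mixture_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class MethylomeCohort(NamedTuple):
    betas: BetaMatrix
    intensities: IntensityMatrix
    sheet: SampleSheet
    manifest: ProbeManifest
    truth: TruthRecord


def _baseline_betas(spec: SimCohortSpec, rng: np.random.Generator) -> np.ndarray:
    low, high, w_low = spec.baseline_mix
    modes = np.where(rng.random(spec.n_probes) < w_low, low, high)
    return np.clip(modes + rng.normal(0, spec.baseline_sd, spec.n_probes), 0, 1)


def _make_manifest(
    probe_ids: Sequence[str],
    rng: np.random.Generator,
    promoter_fraction: float,
) -> ProbeManifest:
    n = len(probe_ids)
    n_chrom = MOUSE_AUTOSOME_COUNT
    chrom_idx = np.arange(n) % n_chrom
    per_chrom = np.bincount(chrom_idx, minlength=n_chrom)
    positions = np.empty(n, dtype=int)
    for c in range(n_chrom):
        members = np.flatnonzero(chrom_idx == c)
        positions[members] = 1 + np.arange(len(members)) * 10_000
    promoter = np.full(n, None, dtype=object)
    n_prom = int(round(promoter_fraction * n))
    prom_idx = rng.choice(n, size=n_prom, replace=False)
    for j, idx in enumerate(sorted(prom_idx)):
        promoter[idx] = f"Gene{j:05d}"
    table = pd.DataFrame(
        {
            "chromosome": [f"chr{c + 1}" for c in chrom_idx],
            "position": positions,
            "promoter_gene": promoter,
            "ortholog_id": pd.NA,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(table)


def gen_methylome_cohort(spec: SimCohortSpec) -> MethylomeCohort:
    """Simulate a class-structured beta matrix with planted signature CpGs.

    Each class shifts its own disjoint signature-site set by +/-
    ``signature_delta`` from a shared bimodal baseline (clipped to [0, 1]);
    replicates add truncated-Gaussian noise.  Planted QC failures get elevated
    missingness, depressed mean intensity and hence depressed probe success.
    """
    rng = np.random.default_rng(spec.seed)
    probe_ids = [f"mm_{i:06d}" for i in range(spec.n_probes)]
    classes = [f"class{k:02d}" for k in range(spec.n_classes)]

    baseline = _baseline_betas(spec, rng)
    sig_pool = rng.choice(
        spec.n_probes,
        size=spec.n_classes * spec.signature_sites_per_class,
        replace=False,
    )
    truth = TruthRecord()
    class_means = np.tile(baseline, (spec.n_classes, 1))
    for k, cls in enumerate(classes):
        sites = sig_pool[
            k * spec.signature_sites_per_class : (k + 1) * spec.signature_sites_per_class
        ]
        # signatures flip toward the opposite methylation mode so the planted
        # effect keeps its full size after clipping to [0, 1]
        directions = np.where(baseline[sites] < 0.5, 1, -1)
        class_means[k, sites] = np.clip(
            baseline[sites] + directions * spec.signature_delta, 0, 1
        )
        truth.signature_sites[cls] = [probe_ids[i] for i in sites]
        truth.signature_directions[cls] = [int(d) for d in directions]
    truth.class_means = {
        cls: class_means[k].tolist() for k, cls in enumerate(classes)
    }

    n_samples = spec.n_classes * spec.samples_per_class
    sample_ids = []
    values = np.empty((spec.n_probes, n_samples))
    labels = []
    col = 0
    for k, cls in enumerate(classes):
        for r in range(spec.samples_per_class):
            sid = f"{cls}_r{r:02d}"
            sample_ids.append(sid)
            labels.append(cls)
            noise = rng.normal(0, spec.noise_sd, spec.n_probes) if spec.noise_sd > 0 else 0.0
            values[:, col] = np.clip(class_means[k] + noise, 0, 1)
            truth.class_of_sample[sid] = cls
            col += 1

    # intensities: healthy samples near base level with mild sample effects
    base_int = 5000.0
    sample_level = base_int * np.exp(rng.normal(0, 0.05, n_samples))
    intens = sample_level[None, :] * np.exp(
        rng.normal(0, 0.1, size=(spec.n_probes, n_samples))
    )

    # planted QC failures: high missingness, low intensity
    bad_idx = rng.choice(n_samples, size=spec.n_bad_samples, replace=False)
    for b in bad_idx:
        n_miss = int(0.2 * spec.n_probes)
        miss = rng.choice(spec.n_probes, size=n_miss, replace=False)
        values[miss, b] = np.nan
        intens[:, b] *= 0.3
        truth.bad_samples.append(sample_ids[b])

    betas = BetaMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    )
    intensities = IntensityMatrix(
        pd.DataFrame(intens, index=probe_ids, columns=sample_ids)
    )
    sexes = np.where(np.arange(n_samples) % 2 == 0, "female", "male")
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "model": labels,
                "entity": labels,
                "family": ["sim" for _ in labels],
                "role": ["tumor" for _ in labels],
                "sex": sexes,
                "preservation": ["fresh" for _ in labels],
                "batch": ["b1" for _ in labels],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    manifest = _make_manifest(probe_ids, rng, spec.promoter_fraction)
    return MethylomeCohort(betas, intensities, sheet, manifest, truth)


def gen_mixtures(
    references: BetaMatrix,
    weights: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BetaMatrix, TruthRecord]:
    """Simulate bulk samples as weighted averages of pure population profiles.

    ``references`` holds one column per population; ``weights`` is samples x
    populations, rows non-negative and summing to 1.
    """
    if (weights.to_numpy() < 0).any():
        raise ValidationError("mixture weights must be non-negative")
    sums = weights.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValidationError("mixture weight rows must sum to 1")
    missing = weights.columns.difference(references.sample_ids)
    if len(missing):
        raise ValidationError(f"weights reference unknown populations: {list(missing)}")

    rng = np.random.default_rng(seed)
    R = references.values[weights.columns].to_numpy()  # probes x populations
    W = weights.to_numpy()  # samples x populations
    mix = R @ W.T
    if noise_sd > 0:
        mix = mix + rng.normal(0, noise_sd, mix.shape)
    mix = np.clip(mix, 0, 1)
    betas = BetaMatrix(
        pd.DataFrame(mix, index=references.probe_ids, columns=weights.index)
    )
    truth = TruthRecord(
        mixture_weights={
            sid: dict(zip(weights.columns, row)) for sid, row in weights.iterrows()
        }
    )
    return betas, truth


class CnaCohort(NamedTuple):
    intensities: IntensityMatrix
    sheet: SampleSheet
    manifest: ProbeManifest
    truth: TruthRecord


def gen_cna_cohort(spec: SimCnaSpec) -> CnaCohort:
    """Simulate probe intensities with planted segment-level copy-number shifts.

    Controls have flat expected log-intensity; each tumor adds its planted
    log2 shifts on the probes inside the planted segments; all probes carry
    multiplicative log-normal noise.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [c for c, _ in spec.chromosomes]
    probe_rows = []
    for chrom, length in spec.chromosomes:
        step = length // spec.probes_per_chromosome
        for i in range(spec.probes_per_chromosome):
            probe_rows.append((chrom, 1 + i * step))
    probe_ids = [f"cn_{i:06d}" for i in range(len(probe_rows))]
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chromosome": [c for c, _ in probe_rows],
                "position": [p for _, p in probe_rows],
                "promoter_gene": pd.NA,
                "ortholog_id": pd.NA,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    tumor_ids = [f"tumor{t:02d}" for t in range(spec.n_tumors)]
    control_ids = [f"control{c:02d}" for c in range(spec.n_controls)]
    sample_ids = tumor_ids + control_ids
    n_probes = len(probe_ids)

    shifts = pd.DataFrame(
        0.0, index=pd.Index(probe_ids), columns=pd.Index(sample_ids)
    )
    truth = TruthRecord()
    chrom_arr = manifest.table["chromosome"].to_numpy()
    pos_arr = manifest.table["position"].to_numpy()
    for samples, chrom, start, end, shift in spec.planted_segments:
        on = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
        for sid in samples:
            if sid not in shifts.columns:
                raise ValidationError(f"planted segment names unknown sample {sid!r}")
            shifts.loc[on, sid] += shift
            truth.planted_segments.setdefault(sid, []).append(
                {
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(end),
                    "log2_shift": float(shift),
                    "n_probes": int(on.sum()),
                }
            )

    log2_base = np.log2(spec.base_intensity)
    noise = (
        rng.normal(0, spec.probe_noise_sd, size=(n_probes, len(sample_ids)))
        if spec.probe_noise_sd > 0
        else np.zeros((n_probes, len(sample_ids)))
    )
    log2_int = log2_base + shifts.to_numpy() + noise
    intens = IntensityMatrix(
        pd.DataFrame(
            np.exp2(log2_int), index=probe_ids, columns=sample_ids
        )
    )
    roles = ["tumor"] * spec.n_tumors + ["control"] * spec.n_controls
    entities = ["sim_tumor"] * spec.n_tumors + ["normal_brain"] * spec.n_controls
    sexes = ["female" if i % 2 == 0 else "male" for i in range(len(sample_ids))]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "model": ["sim_cna"] * len(sample_ids),
                "entity": entities,
                "family": ["sim"] * len(sample_ids),
                "role": roles,
                "sex": sexes,
                "preservation": ["fresh"] * len(sample_ids),
                "batch": ["b1"] * len(sample_ids),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    for sid in sample_ids:
        truth.class_of_sample[sid] = "tumor" if sid in tumor_ids else "control"
    return CnaCohort(intens, sheet, manifest, truth)


def gen_synteny_map(
    mouse_chromosomes: Sequence[tuple[str, int]],
    human_chromosomes: Sequence[tuple[str, int]],
    block_count: int,
    seed: int = 0,
) -> SyntenyMap:
    """Partition mouse chromosomes into blocks mapped to disjoint human intervals.

    Blocks are distributed over mouse chromosomes proportionally to length (at
    least one each) and placed sequentially on the human chromosomes with gaps,
    so human coverage stays below the human genome size.
    """
    if block_count < len(mouse_chromosomes):
        raise ValidationError("need at least one block per mouse chromosome")
    rng = np.random.default_rng(seed)
    m_lengths = np.array([l for _, l in mouse_chromosomes], dtype=float)
    alloc = np.maximum(1, np.floor(block_count * m_lengths / m_lengths.sum()).astype(int))
    while alloc.sum() > block_count:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < block_count:
        alloc[np.argmin(alloc)] += 1

    human_total = sum(l for _, l in human_chromosomes)
    mouse_total = int(m_lengths.sum())
    if mouse_total >= human_total:
        raise ValidationError("human genome must exceed total mouse block length")

    # sequential human placement with modest inter-block gaps so the blocks
    # stay disjoint while still fitting the human chromosomes
    gap = max(1, (human_total - mouse_total) // (2 * block_count + 2))
    h_iter = iter(human_chromosomes)
    h_chrom, h_len = next(h_iter)
    h_cursor = 1

    rows = []
    for (m_chrom, m_len), n_blocks in zip(mouse_chromosomes, alloc):
        # split the mouse chromosome at sorted random internal cut points
        if n_blocks > 1:
            cuts = np.sort(rng.choice(np.arange(2, m_len), size=n_blocks - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = np.concatenate([[1], cuts, [m_len + 1]])
        for b in range(n_blocks):
            m_start, m_end = int(bounds[b]), int(bounds[b + 1] - 1)
            blen = m_end - m_start + 1
            while h_cursor + blen - 1 > h_len:
                try:
                    h_chrom, h_len = next(h_iter)
                except StopIteration as exc:
                    raise ValidationError("infeasible block geometry") from exc
                h_cursor = 1
            rows.append(
                (m_chrom, m_start, m_end, h_chrom, h_cursor, h_cursor + blen - 1)
            )
            h_cursor += blen + gap
    return SyntenyMap(
        pd.DataFrame(
            rows,
            columns=[
                "mouse_chromosome",
                "mouse_start",
                "mouse_end",
                "human_chromosome",
                "human_start",
                "human_end",
            ],
        )
    )


def gen_ortholog_map(
    mouse_manifest: ProbeManifest,
    human_manifest: ProbeManifest,
    fraction_shared: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair a random probe subset across the two array universes, injectively.

    Probes are paired positionally (the i-th mouse probe with the i-th human
    probe) on a uniformly sampled index subset, so planted class signatures
    survive the mapping at the same expected fraction.
    """
    if not (0 < fraction_shared <= 1):
        raise ValidationError("fraction_shared must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = min(len(mouse_manifest.probe_ids), len(human_manifest.probe_ids))
    k = int(round(fraction_shared * n))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return pd.DataFrame(
        {
            "query_probe": mouse_manifest.probe_ids[idx],
            "reference_probe": human_manifest.probe_ids[idx],
        }
    )


class CrossSpeciesFixture(NamedTuple):
    reference: BetaMatrix
    reference_labels: pd.Series
    query: BetaMatrix
    query_sheet: SampleSheet
    orthologs: pd.DataFrame
    truth: TruthRecord


def gen_cross_species_cohort(
    spec: SimCohortSpec,
    ortholog_fraction: float = 0.1,
    query_samples_per_class: int = 3,
    seed_offset: int = 7_777,
) -> CrossSpeciesFixture:
    """Build a paired human-reference / mouse-query fixture from one class model.

    The "human" reference cohort is generated from ``spec``; mouse query
    samples are drawn from the same per-class mean profiles with fresh noise
    and a renamed probe universe, linked back through a partial ortholog map.
    """
    ref = gen_methylome_cohort(spec)
    human_ids = [p.replace("mm_", "hs_") for p in ref.betas.probe_ids]
    ref_betas = BetaMatrix(
        pd.DataFrame(
            ref.betas.values.to_numpy(),
            index=human_ids,
            columns=ref.betas.sample_ids,
        )
    )
    human_manifest = ProbeManifest(
        ref.manifest.table.set_index(pd.Index(human_ids, name="probe_id"))
    )

    rng = np.random.default_rng(spec.seed + seed_offset)
    classes = sorted(ref.truth.signature_sites)
    class_means = np.array([ref.truth.class_means[c] for c in classes])
    q_ids, q_labels, cols = [], [], []
    truth = TruthRecord(signature_sites=ref.truth.signature_sites)
    for k, cls in enumerate(classes):
        for r in range(query_samples_per_class):
            sid = f"mouse_{cls}_q{r:02d}"
            q_ids.append(sid)
            q_labels.append(cls)
            cols.append(
                np.clip(class_means[k] + rng.normal(0, spec.noise_sd, spec.n_probes), 0, 1)
            )
            truth.class_of_sample[sid] = cls
    query = BetaMatrix(
        pd.DataFrame(np.column_stack(cols), index=ref.betas.probe_ids, columns=q_ids)
    )
    query_sheet = SampleSheet(
        pd.DataFrame(
            {
                "model": [f"model_{c}" for c in q_labels],
                "entity": q_labels,
                "family": ["sim"] * len(q_ids),
                "role": ["tumor"] * len(q_ids),
                "sex": ["unknown"] * len(q_ids),
                "preservation": ["fresh"] * len(q_ids),
                "batch": ["b1"] * len(q_ids),
            },
            index=pd.Index(q_ids, name="sample_id"),
        )
    )
    orthologs = gen_ortholog_map(
        ref.manifest, human_manifest, ortholog_fraction, seed=spec.seed + seed_offset + 1
    )
    ref_labels = pd.Series(
        [ref.truth.class_of_sample[s] for s in ref_betas.sample_ids],
        index=ref_betas.sample_ids,
        name="class",
    )
    return CrossSpeciesFixture(ref_betas, ref_labels, query, query_sheet, orthologs, truth)
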