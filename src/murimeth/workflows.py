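"""End-to-end study emulations built from the pipeline stages.

These compose the synthetic-cohort generator with the analysis stages into the
two headline procedures: construction of the 1,000-CpG deconvolution reference
(8 immune populations plus tumor- and brain-average pseudo-populations) and
its purity validation on an independently simulated pure-profile set.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import BetaMatrix
from .deconv import ReferenceMatrix, build_reference_matrix, evaluate_purity
from .simulate import MethylomeCohort, SimCohortSpec, gen_methylome_cohort


class ReferenceStudy(NamedTuple):
    cohort: MethylomeCohort
    immune_populations: list[str]
    reference: ReferenceMatrix


def reference_matrix_study(
    seed: int,
    n_probes: int = 50_000,
    signature_sites_per_class: int = 200,
    samples_per_class: int = 5,
    noise_sd: float = 0.05,
    top_n: int = 100,
) -> ReferenceStudy:
    """Build the deconvolution reference from a 10-population synthetic cohort.

    Ten populations are simulated (disjoint planted signatures, delta 0.5);
    eight serve as immune populations with replicates, the remaining two
    provide the tumor-average and brain-average pseudo-population profiles.
    """
    spec = SimCohortSpec(
        n_classes=10,
        samples_per_class=samples_per_class,
        n_probes=n_probes,
        signature_sites_per_class=signature_sites_per_class,
        signature_delta=0.5,
        noise_sd=noise_sd,
        seed=seed,
    )
    cohort = gen_methylome_cohort(spec)
    classes = sorted(cohort.truth.signature_sites)
    immune, tumor_cls, brain_cls = classes[:8], classes[8], classes[9]
    labels = pd.Series(cohort.truth.class_of_sample)
    immune_samples = labels.index[labels.isin(immune)]
    tumor_avg = cohort.betas.values[labels.index[labels == tumor_cls]].mean(axis=1)
    brain_avg = cohort.betas.values[labels.index[labels == brain_cls]].mean(axis=1)
    reference = build_reference_matrix(
        cohort.betas.select_samples(immune_samples),
        labels.loc[immune_samples],
        tumor_avg,
        brain_avg,
        top_n=top_n,
    )
    return ReferenceStudy(cohort, immune, reference)


class PurityStudy(NamedTuple):
    table: pd.DataFrame  # per-population mean/min self-weight
    min_mean_self_weight: float
    n_validation: int


def purity_validation_study(
    study: ReferenceStudy,
    validation_seed: int,
    replicates_per_population: int = 3,
    noise_sd: float = 0.05,
    method: str = "robust",
) -> PurityStudy:
    """Deconvolute freshly simulated pure profiles against the built reference.

    Validation profiles are drawn from the same true population means with an
    independent seed; the summary is the minimum over immune populations of
    the mean weight assigned back to the profile's own population.
    """
    rng = np.random.default_rng(validation_seed)
    probe_ids = study.cohort.betas.probe_ids
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for pop in study.immune_populations:
        mean = np.asarray(study.cohort.truth.class_means[pop])
        for r in range(replicates_per_population):
            sid = f"val_{pop}_r{r}"
            noise = rng.normal(0, noise_sd, len(mean)) if noise_sd > 0 else 0.0
            cols[sid] = np.clip(mean + noise, 0, 1)
            labels[sid] = pop
    validation = BetaMatrix(pd.DataFrame(cols, index=probe_ids))
    table = evaluate_purity(validation, pd.Series(labels), study.reference, method=method)
    return PurityStudy(
        table=table,
        min_mean_self_weight=float(table["mean_self_weight"].min()),
        n_validation=len(cols),
    )
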