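"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from murimeth.core import BetaMatrix
from murimeth.simulate import SimCohortSpec, gen_methylome_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 classes x 5 replicates, 3,000 probes, 50 signature sites per class."""
    spec = SimCohortSpec(
        n_classes=4,
        samples_per_class=5,
        n_probes=3000,
        signature_sites_per_class=50,
        signature_delta=0.5,
        noise_sd=0.05,
        seed=101,
    )
    return gen_methylome_cohort(spec)


@pytest.fixture(scope="session")
def cohort_labels(small_cohort):
    return pd.Series(small_cohort.truth.class_of_sample)


@pytest.fixture(scope="session")
def deconv_setup():
    """6 immune populations + tumor/brain pseudo-population source cohort."""
    spec = SimCohortSpec(
        n_classes=8,
        samples_per_class=5,
        n_probes=8000,
        signature_sites_per_class=80,
        signature_delta=0.5,
        noise_sd=0.05,
        seed=202,
    )
    cohort = gen_methylome_cohort(spec)
    classes = sorted(cohort.truth.signature_sites)
    immune = classes[:6]
    labels = pd.Series(cohort.truth.class_of_sample)
    immune_samples = labels.index[labels.isin(immune)]
    tumor_avg = cohort.betas.values[labels.index[labels == classes[6]]].mean(axis=1)
    brain_avg = cohort.betas.values[labels.index[labels == classes[7]]].mean(axis=1)
    return {
        "cohort": cohort,
        "immune": immune,
        "labels": labels,
        "pure": cohort.betas.select_samples(immune_samples),
        "pure_labels": labels.loc[immune_samples],
        "tumor_avg": tumor_avg,
        "brain_avg": brain_avg,
    }


@pytest.fixture()
def random_beta():
    rng = np.random.default_rng(7)
    X = rng.random((120, 8))
    return BetaMatrix(
        pd.DataFrame(
            X,
            index=[f"p{i:03d}" for i in range(120)],
            columns=[f"s{j}" for j in range(8)],
        )
    )
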