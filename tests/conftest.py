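"""Shared fixtures: small simulated cohorts and a trained cascade, reused
across test modules to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import methylcascade as mc


@pytest.fixture(scope="session")
def small_cohort():
    """2 tissues x (40 cancer + 40 normal), 300 probes, 10 planted/tissue."""
    config = mc.SimConfig(n_tissues=2, n_cancer_per_tissue=40,
                          n_normal_per_tissue=40, n_probes=300,
                          n_informative_per_tissue=10, effect_size_m=3.0,
                          seed=7)
    return mc.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    m = mc.beta_to_m(small_cohort.beta)
    labels = mc.labels_for_task(small_cohort.metadata, "multiclass")
    dataset = mc.LabeledDataset(m, labels)
    return mc.split_train_test(dataset, 0.25, seed=7)


@pytest.fixture(scope="session")
def small_cascade(small_dataset):
    """A quick multiclass cascade on the small cohort (reduced model sizes)."""
    boost = mc.BoostConfig(n_estimators=50, max_depth=3, objective="multiclass",
                           seed=7)
    dnn = mc.DNNConfig(hidden_layers=(32,), max_epochs=30, seed=7)
    return mc.train_cascade(small_dataset, boost, dnn)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def planted_probes(cohort) -> set[str]:
    out = set()
    for probes in cohort.truth.values():
        out |= set(probes)
    return out
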