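"""Shared fixtures: small seeded synthetic cohorts and their preprocessed
matrices, sized for fast unit tests."""

import numpy as np
import pytest

from rfaclust import SyntheticConfig, cluster_panel, generate_cohort, preprocess
from rfaclust.simulate import default_shift_matrix


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """180 participants, 16 markers (8 baseline + 2 informative candidates),
    3 clusters; compact version of the default cohort."""
    base = dict(
        n_participants=180, n_markers=16, n_baseline=8, k_true=3,
        cluster_proportions=(0.4, 0.4, 0.2), n_informative_candidates=2,
        shift_magnitude=2.0, n_batches=2, seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    processed, _ = preprocess(small_cohort.dataset, seed=11)
    return processed


@pytest.fixture(scope="session")
def small_solution(small_cohort, small_processed):
    return cluster_panel(small_processed.values, small_cohort.dataset.baseline_panel)


@pytest.fixture(scope="session")
def small_labels(small_solution):
    return small_solution.assignments.to_numpy()
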