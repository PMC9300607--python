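import numpy as np
import pytest

from nodesphere.simulate import CohortConfig, ShapeClassParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def default_config():
    return CohortConfig(seed=7)


@pytest.fixture
def small_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture
def separated_params():
    """Well-separated shape classes for classifier tests."""
    return {
        "non_metastatic": ShapeClassParams(0.55, 0.05, 10.0, 3.0),
        "metastatic": ShapeClassParams(0.90, 0.05, 14.0, 4.0),
    }


def two_class_scores(rng, n_pos, n_neg, mu_pos=0.85, mu_neg=0.60, sd=0.08):
    """Sampled scores + labels from two Gaussians, clipped to (0, 1]."""
    pos = np.clip(rng.normal(mu_pos, sd, n_pos), 1e-6, 1.0)
    neg = np.clip(rng.normal(mu_neg, sd, n_neg), 1e-6, 1.0)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return scores, labels
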