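import numpy as np
import pytest

from cdr3boost.evaluation import loo_classify
from cdr3boost.simulate import SyntheticConfig, generate_cohort, strong_signal_config


@pytest.fixture(scope="session")
def signal_cohort():
    """A strong-signal benchmark cohort with its ground truth and config."""
    cfg = strong_signal_config(seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def signal_loo(signal_cohort):
    """Leave-one-out run on the benchmark cohort, with per-fold models."""
    cohort, _, _ = signal_cohort
    result, models = loo_classify(cohort, seed=3, collect_models=True)
    return result, models


@pytest.fixture(scope="session")
def small_null_cohort():
    """A small no-signal cohort (classes exchangeable)."""
    cfg = SyntheticConfig(
        seed=5,
        n_pos=3,
        n_neg=3,
        clones_per_mouse=400,
        universe_size=5_000,
        n_public=20,
        n_private_expanded=30,
        reads_per_mouse=4_000,
        expansion_factor=16.0,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
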