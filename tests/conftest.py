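"""Shared fixtures: the reference study condition and simulated datasets."""

import numpy as np
import pytest

from satiety import DEFAULT_PARAMS, GutModel, ModelParams, simulate
from satiety.hierarchical import HyperPriorConfig


@pytest.fixture(scope="session")
def gut():
    return GutModel()


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def narrow_hyper():
    """Well-behaved group hyperprior centred on the reference condition.

    Used for synthetic multi-subject datasets: ~30-40% interindividual
    spread, moderate correlations.
    """
    return HyperPriorConfig(
        mu_star=tuple(DEFAULT_PARAMS.to_transformed()),
        mu_prior_sd=0.15, tau_scale=0.1, lkj_eta=2.0)


@pytest.fixture(scope="session")
def day_sequence(gut, params):
    """One simulated day of labelled events (ground-truth pause classes)."""
    rng = np.random.default_rng(42)
    seq, _ = simulate(params, gut, (0.0, 24 * 3600.0), rng=rng)
    return seq


@pytest.fixture(scope="session")
def long_sequence(gut, params):
    """Fourteen simulated days: >500 meals, for recovery experiments."""
    rng = np.random.default_rng(7)
    seq, _ = simulate(params, gut, (0.0, 14 * 24 * 3600.0), rng=rng)
    return seq
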