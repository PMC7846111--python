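"""Shared fixtures: the default model, a synthetic mutation-frequency table,
and a scaled-down strain survey reused by the statistical property tests."""

from __future__ import annotations

import numpy as np
import pytest

from fluxscape.landscape import CENTRAL_REACTIONS
from fluxscape.model import Condition, build_default_model, solve_growth
from fluxscape.sampling import SamplerConfig, sample_strains
from fluxscape.synth import make_expression_fixture, make_mutation_frequency_table


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def freq():
    return make_mutation_frequency_table(seed=1)


@pytest.fixture(scope="session")
def wt37(model):
    return solve_growth(model, Condition(temperature=37.0))


@pytest.fixture(scope="session")
def mini_run(model, freq):
    """Scaled strain survey: 10 strains at each of the 22 temperatures."""
    cfg = SamplerConfig(n_per_temperature=10, master_seed=7)
    return sample_strains(model, freq, cfg, flux_columns=CENTRAL_REACTIONS)


@pytest.fixture(scope="session")
def expression_fixture():
    return make_expression_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
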