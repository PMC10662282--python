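"""Shared fixtures: the frozen synthetic testbed and cheap short-horizon variants."""

from dataclasses import replace

import numpy as np
import pytest

import codeal as cd


@pytest.fixture(scope="session")
def default_testbed():
    """The package's frozen 12-year scenario (spec, params, config, forcing)."""
    spec, params, config = cd.default_scenario()
    forcing = cd.make_forcing(spec)
    return spec, params, config, forcing


@pytest.fixture(scope="session")
def short_testbed():
    """Two-year variant of the frozen scenario for cheap unit tests."""
    spec, params, config = cd.default_scenario()
    spec = replace(spec, years=2.0)
    config = replace(config, t1=365.0 * 2)
    forcing = cd.make_forcing(spec)
    return spec, params, config, forcing


@pytest.fixture(scope="session")
def short_trajectory(short_testbed):
    _, params, config, forcing = short_testbed
    return cd.run_simulation(config, params, forcing)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
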