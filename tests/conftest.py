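"""Shared fixtures: the ground-truth complex and its noise-free peak list
are expensive, so they are built once per session."""

import numpy as np
import pytest

from noefold.restraints import calibrate, make_hbond_restraints
from noefold.synthetic import (make_ground_truth, tff1_complex_spec,
                               simulate_noesy)
from noefold.topology import TFF1_ERE_SENSE, build_duplex


@pytest.fixture(scope="session")
def tff1_topology():
    return build_duplex(TFF1_ERE_SENSE)


@pytest.fixture(scope="session")
def complex_spec():
    return tff1_complex_spec(seed=0)


@pytest.fixture(scope="session")
def ground_truth(complex_spec):
    return make_ground_truth(complex_spec)


@pytest.fixture(scope="session")
def noiseless_peaks(ground_truth, complex_spec):
    return simulate_noesy(ground_truth, complex_spec.topology, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def full_restraints(noiseless_peaks, complex_spec):
    rs = calibrate(noiseless_peaks, complex_spec.topology)
    return rs.extend(make_hbond_restraints(complex_spec.topology))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
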