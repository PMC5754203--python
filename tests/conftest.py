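"""Shared fixtures: a small simulated clade and helpers."""

import numpy as np
import pytest

from promevo.synth import CladeSpec, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """A modest 5-species clade reused by read-only tests."""
    spec = CladeSpec(n_tscs=150, depth=4e4, seed=7)
    return simulate_clade(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
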