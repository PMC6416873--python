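"""Shared fixtures: small simulated cohorts, generated at test time."""

import logging

import pytest

from diffgc import SimulationConfig, normalize_rnaseq, simulate_cohorts
from diffgc.containers import SUBTYPES

logging.getLogger("diffgc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """Compact 4-subtype study: 400 genes, 40 signature genes/subtype, 8/subtype."""
    return SimulationConfig(n_genes=400, n_signature_genes_per_subtype=40,
                            cohorts={"a": {s: 8 for s in SUBTYPES}}, seed=7)


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return simulate_cohorts(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_fixture):
    return normalize_rnaseq(small_fixture.expression)


@pytest.fixture(scope="session")
def strong_fixture():
    """Study-scale fixture: 2,000 genes, 200 signature genes/subtype,
    2.0 log2-fold effect, 30 samples/subtype."""
    return simulate_cohorts(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def strong_normalized(strong_fixture):
    return normalize_rnaseq(strong_fixture.expression)
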