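"""Shared fixtures: small synthetic references and libraries."""

import pytest

from crownkit.simulate import make_reference, simulate_library
from crownkit.types import SimConfig


@pytest.fixture(scope="session")
def small_ref():
    """Ten genes, three TSNs each, A-rich starts."""
    return make_reference(10, tsns_per_gene=3, seed=7, a_fraction=0.6)


@pytest.fixture(scope="session")
def small_library(small_ref):
    cfg = SimConfig(depth=3000, seed=1)
    reads, truth = simulate_library(small_ref, cfg)
    return small_ref, cfg, reads, truth


@pytest.fixture(scope="session")
def clean_library():
    """Error-free, background-free library on distinct gene sequences."""
    ref = make_reference(8, tsns_per_gene=2, seed=3, a_fraction=0.7)
    cfg = SimConfig(depth=2000, seed=5, background_rate=0.0, seq_error_rate=0.0)
    reads, truth = simulate_library(ref, cfg)
    return ref, cfg, reads, truth
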