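"""Shared fixtures: a small simulated screen reused across test modules."""

import pytest

from utrscreen import simulate


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimConfig(seed=11, n_variants=12, frac_functional=0.5)


@pytest.fixture(scope="session")
def small_library(small_cfg):
    """(utrs, variants, truth, oligos) for a 12-variant screen."""
    return simulate.build_library(small_cfg)


@pytest.fixture(scope="session")
def small_counts(small_cfg, small_library):
    _, _, truth, oligos = small_library
    return simulate.simulate_counts(oligos, truth, small_cfg)


@pytest.fixture()
def toy_genome():
    # 400-nt deterministic sequence with a known base at 1-based pos 200
    base = "ACGT" * 100
    return {"chr1": base}
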