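"""Shared fixtures: a toy plastome, a WGS-like read mixture, configs.

Everything is generated programmatically; the toy plastome (LSC 20 kb,
IR 5 kb, SSC 4 kb) at 100x single-copy coverage with 1% substitution errors
over a 100 kb nuclear background at 2x is the standard study condition used
throughout the suite.
"""

from __future__ import annotations

import pytest

from plastokmer import (
    PipelineConfig,
    ReadSimParams,
    count_kmers,
    make_nuclear,
    make_plastome,
    simulate_reads,
    toy_config,
)

TOY_LSC, TOY_IR, TOY_SSC = 20_000, 5_000, 4_000


@pytest.fixture(scope="session")
def truth():
    return make_plastome(TOY_LSC, TOY_IR, TOY_SSC, seed=1)


@pytest.fixture(scope="session")
def nuclear():
    return make_nuclear(100_000, (), seed=2)


@pytest.fixture(scope="session")
def mixture_reads(truth, nuclear):
    """Plastome at 100x SC coverage + nuclear at 2x, 1% substitution errors."""
    return simulate_reads(truth, nuclear, ReadSimParams(seed=3))


@pytest.fixture(scope="session")
def mixture_table(mixture_reads):
    return count_kmers(mixture_reads, 31)


@pytest.fixture(scope="session")
def plastome_reads(truth):
    """Error-free plastome-only reads (for exactness-sensitive tests)."""
    return simulate_reads(truth, None,
                          ReadSimParams(seed=5, substitution_error_rate=0.0))


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return toy_config(seed=3)
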