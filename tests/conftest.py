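"""Shared fixtures: a desk-scale founder set and representative runs.

Everything is generated programmatically; session scope keeps the expensive
simulation fixtures to one execution per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from gxebreed import engine, founders
from gxebreed.rng import stream

DESK_FOUNDER_KW = dict(n_chromosomes=5, n_snp=2_000, n_qtl=200,
                       n_tracer_per_chrom=100, n_hist_generations=100,
                       n_males=100, n_females=100, oversample=1.5,
                       maf_min=0.05)


@pytest.fixture(scope="session")
def desk_founders():
    return founders.simulate_founders(stream(11, "founders"),
                                      **DESK_FOUNDER_KW)


@pytest.fixture(scope="session")
def wp_run(desk_founders):
    """One desk-scale WP-WS (independent, pedigree-based) replicate."""
    return engine.run_scenario(engine.desk_config("WP-WS", h2=0.3, rg=0.9),
                               desk_founders, seed=11)


@pytest.fixture(scope="session")
def ag_run(desk_founders):
    """One desk-scale AG-AS (cooperative, genomic) replicate."""
    return engine.run_scenario(engine.desk_config("AG-AS", h2=0.3, rg=0.9),
                               desk_founders, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
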