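"""Shared fixtures: default config, synthetic databases, simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from stitch16s import simulate
from stitch16s.config import PipelineConfig
from stitch16s.panel import canonical_anchor, default_panel, full_length_pair


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def panel():
    return list(default_panel())


@pytest.fixture(scope="session")
def anchor() -> str:
    return canonical_anchor()


@pytest.fixture(scope="session")
def refdb_meta():
    """Default synthetic reference database (8 genera x 3 species)."""
    return simulate.make_refdb(seed=11)


@pytest.fixture(scope="session")
def refdb(refdb_meta):
    return refdb_meta[0]


@pytest.fixture(scope="session")
def community(refdb_meta):
    refdb, meta = refdb_meta
    return simulate.make_community(refdb, 4, "uniform", seed=11, meta=meta)


@pytest.fixture(scope="session")
def simulated_run(community, panel):
    """A moderate simulated sequencing run shared across tests."""
    eff = simulate.default_efficiency_matrix(len(community.taxa), len(panel), seed=11)
    reads, truth = simulate.simulate_reads(
        community, panel, eff, simulate.ErrorModel(), n_reads=1200, seed=11
    )
    return reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
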