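"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from omicsfunnel import (
    DEFAULT_DESIGN,
    PipelineConfig,
    SimulationParams,
    simulate_multiomics,
)


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    params = SimulationParams(n_genes=200, n_pathways=12)
    return simulate_multiomics(params, seed=7), params


@pytest.fixture(scope="session")
def default_sim():
    """One default-sized simulated dataset shared by read-only tests."""
    params = SimulationParams()
    return simulate_multiomics(params, seed=11), params


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t").replace("|", "\t"))
    return path
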