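"""Shared fixtures: one small seeded synthetic experiment per session."""

from __future__ import annotations

import pytest

from srnapipe.annotate import CategoryReferences, GenomeIndex
from srnapipe.experiments import simulate_to_library
from srnapipe.simulate import SimulationConfig, generate_precursors


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    return SimulationConfig(
        seed=101,
        library_depth=20_000,
        fold_change_map={"syn-miR1": 4.0, "syn-miR2": 0.25},
    )


@pytest.fixture(scope="session")
def refs(base_config):
    return generate_precursors(base_config)


@pytest.fixture(scope="session")
def sim_library(refs, base_config):
    """(TagLibrary, SimulatedData) for the session's default experiment."""
    return simulate_to_library(refs, base_config)


@pytest.fixture(scope="session")
def genome_index(refs):
    return GenomeIndex(refs.genome)


@pytest.fixture(scope="session")
def category_refs(refs):
    return CategoryReferences(refs.category_seqs, refs.known)
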