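"""Shared fixtures: one small synthetic corpus reused across test modules."""

from __future__ import annotations

import pytest

from gocensus.annotations import filter_organisms
from gocensus.census import build_census
from gocensus.ontology import terminal_mf_terms
from gocensus.simulate import SimulationConfig, generate_ontology, simulate_genomes


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_corpus(sim_config):
    """(graph, annotation_sets, metadata, hgt_lists, truth) at the default
    desk-scale study conditions."""
    graph = generate_ontology(sim_config)
    sets, metadata, hgt_lists, truth = simulate_genomes(graph, sim_config)
    return graph, sets, metadata, hgt_lists, truth


@pytest.fixture(scope="session")
def sim_census(sim_corpus):
    """Census over the retained organisms of the shared corpus."""
    graph, sets, metadata, _hgt, _truth = sim_corpus
    terminal = terminal_mf_terms(graph)
    retained, _covs, _log = filter_organisms(metadata, sets, terminal)
    return build_census(sets, terminal, retained, metadata)
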