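"""Shared fixtures: a small simulated dataset reused across test modules."""

from __future__ import annotations

import pytest

from levitax.classify import DemarcationConfig
from levitax.hmm import build_library
from levitax.simulate import simulate_reference_set


@pytest.fixture(scope="session")
def mini_dataset():
    """2 orders × 1 family × 2 genera × 2 species × 2 members = 16 genomes."""
    return simulate_reference_set(
        n_orders=2,
        families_per_order=1,
        genera_per_family=2,
        species_per_genus=2,
        members_per_species=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_library(mini_dataset):
    return build_library(mini_dataset.msas)


@pytest.fixture(scope="session")
def mini_config(mini_dataset):
    return DemarcationConfig(cluster_taxon_map=mini_dataset.taxon_map)
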