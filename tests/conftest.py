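"""Shared fixtures: simulated families are generated once per session."""

from __future__ import annotations

from collections import defaultdict

import pytest

from immikit.synthetic_family import (
    SimulationConfig,
    simulate_family,
    family_from_product,
)


@pytest.fixture(scope="session")
def family():
    """The default study-condition family: 12 genomes, 3 genera, 7 species."""
    return simulate_family(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def family_b():
    """An independent second family for cross-family (super-)tests."""
    return simulate_family(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def small_uniform_family():
    """A family with no accessory genes, so same-species genomes share gene
    content, architecture and integrase type and whole-genome Hamming
    distance is a valid similarity oracle."""
    cfg = SimulationConfig(
        genus_species_sizes=((2, 1, 1), (2,)),
        n_core=20,
        n_flexible=0,
        n_unique=0,
        seed=5,
    )
    return simulate_family(cfg)


def partition(assignment: dict[str, str]) -> set[frozenset[str]]:
    """Label-free view of a clustering for comparing partitions."""
    blocks = defaultdict(set)
    for item, label in assignment.items():
        blocks[label].add(item)
    return {frozenset(b) for b in blocks.values()}


def truth_family_membership(result) -> dict[str, frozenset]:
    """Planted family -> {(genome, rank)} sets, read off the emitted tables."""
    out = {}
    for fam, members in result.truth.family_members.items():
        s = set()
        for g in result.genomes:
            if g.id not in members:
                continue
            for gene in g.genes:
                if family_from_product(gene.product) == fam:
                    s.add((g.id, gene.rank))
    # one gene per genome per family in the simulator
        out[fam] = frozenset(s)
    return out
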