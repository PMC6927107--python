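"""Shared fixtures: small hand-built and randomized gene–phenotype networks."""

from __future__ import annotations

import random

import pytest

from multipath2vec import GPNetwork, SyntheticConfig, assemble_network, generate_planted_network


@pytest.fixture
def toy_network() -> GPNetwork:
    """g1–g2, p1–p2, g1–p1: one edge of each relation, 4 vertices."""
    return assemble_network({("g1", "g2")}, {("p1", "p2")}, {("g1", "p1")})


@pytest.fixture
def small_planted() -> GPNetwork:
    """A small but non-trivial planted network (2 blocks)."""
    net, _ = generate_planted_network(
        SyntheticConfig(blocks=2, genes_per_block=5, phens_per_block=4, seed=11)
    )
    return net


def random_hetero_network(seed: int, n_genes: int = 6, n_phens: int = 5,
                          p_edge: float = 0.35) -> GPNetwork:
    """Erdős–Rényi-style typed graph for property tests (seeded)."""
    rng = random.Random(seed)
    genes = [f"rg{i}" for i in range(n_genes)]
    phens = [f"rp{i}" for i in range(n_phens)]
    gene_edges, phen_edges, assocs = set(), set(), set()
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p_edge:
                gene_edges.add((genes[i], genes[j]))
    for i in range(n_phens):
        for j in range(i + 1, n_phens):
            if rng.random() < p_edge:
                phen_edges.add((phens[i], phens[j]))
    for g in genes:
        for p in phens:
            if rng.random() < p_edge / 2:
                assocs.add((g, p))
    return assemble_network(gene_edges, phen_edges, assocs)
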