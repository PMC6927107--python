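"""Planted gene–phenotype networks for end-to-end testing.

Real inputs for this task are large curated resources (a PPI database, an
OMIM-style association catalogue, a phenotype-similarity matrix) that cannot
be bundled. This module generates a stochastic-block-model stand-in with the
same three file shapes: genes and phenotypes fall into B paired blocks,
within-block edges are denser than between-block edges, and each gene gains
an association with a phenotype of its paired block (plus rare noise
associations across blocks). A pipeline that embeds the network well should
rank a held-out gene's block phenotypes highly — that recovery property is
what the acceptance suite measures.

The generated raw edge sets are passed through the same filter/assembly
pipeline as parsed files, so ``write_fixture_files`` round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gpnet import FilterConfig, GPNetwork, apply_filters, assemble_network

# fixture similarity score for planted phenotype links; anything strictly
# above the default 0.6 threshold works, 1.0 keeps the files trivial to read
_FIXTURE_SCORE = "1.0"


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted-partition generator settings.

    Defaults define the study conditions used throughout the acceptance
    suite: 5 blocks of 10 genes and 6 phenotypes, dense within-block
    structure (p_in >> p_out), an association rate q=0.5 from each gene to a
    uniformly chosen phenotype of its paired block, and a 2% cross-block
    noise-association rate.
    """

    blocks: int = 5
    genes_per_block: int = 10
    phens_per_block: int = 6
    p_gg_in: float = 0.3
    p_gg_out: float = 0.01
    p_pp_in: float = 0.4
    p_pp_out: float = 0.01
    q: float = 0.5
    q_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_gg_in", "p_gg_out", "p_pp_in", "p_pp_out", "q", "q_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.blocks < 1 or self.genes_per_block < 1 or self.phens_per_block < 1:
            raise ValueError("blocks and per-block sizes must be >= 1")
        if self.blocks * self.genes_per_block < 2 or self.blocks * self.phens_per_block < 2:
            raise ValueError("need at least 2 genes and 2 phenotypes overall")


def _block_edges(rng, ids, block_of, p_in, p_out):
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            p = p_in if block_of[i] == block_of[j] else p_out
            if rng.random() < p:
                edges.add((ids[i], ids[j]))
    return edges


def sample_raw_inputs(
    config: SyntheticConfig,
) -> tuple[set[tuple[str, str]], dict[tuple[str, str], float], set[tuple[str, str]]]:
    """Draw the raw (unfiltered) PPI pairs, similarity scores and associations.

    Exposed separately so the generator's edge-count statistics can be
    checked against their binomial expectations before filtering.
    """
    rng = np.random.default_rng(config.seed)
    B, m, r = config.blocks, config.genes_per_block, config.phens_per_block
    genes = [f"G{i:04d}" for i in range(B * m)]
    phens = [f"P{i:04d}" for i in range(B * r)]
    g_block = [i // m for i in range(B * m)]
    p_block = [i // r for i in range(B * r)]

    gene_edges = _block_edges(rng, genes, g_block, config.p_gg_in, config.p_gg_out)
    phen_edges = _block_edges(rng, phens, p_block, config.p_pp_in, config.p_pp_out)

    assocs = set()
    for i, g in enumerate(genes):
        b = g_block[i]
        if rng.random() < config.q:
            j = int(rng.integers(r))
            assocs.add((g, phens[b * r + j]))
        if B > 1 and rng.random() < config.q_noise:
            other = int(rng.integers(B - 1))
            if other >= b:
                other += 1
            j = int(rng.integers(r))
            assocs.add((g, phens[other * r + j]))
    return gene_edges, {e: 1.0 for e in phen_edges}, assocs


def block_of(vertex_id: str, config: SyntheticConfig) -> int:
    """Ground-truth block of a generated vertex (namespaced or raw id)."""
    raw = vertex_id.split(":", 1)[-1]
    idx = int(raw[1:])
    per = config.genes_per_block if raw[0] == "G" else config.phens_per_block
    return idx // per


def generate_planted_network(
    config: SyntheticConfig,
) -> tuple[GPNetwork, dict[str, int]]:
    """Draw a planted network; returns it with the ground-truth block map.

    The raw edge sets pass through the same filter/assembly pipeline as
    parsed input files, so the returned network satisfies every GPNetwork
    invariant and is stable under re-filtering (which is what makes
    ``write_fixture_files`` round-trip exactly). The block map covers all
    generated vertices by their namespaced ids, including any removed by
    filtering.
    """
    gene_edges, scores, assocs = sample_raw_inputs(config)
    ge, pe, av = apply_filters(gene_edges, scores, assocs, FilterConfig())
    net = assemble_network(ge, pe, av)
    B, m, r = config.blocks, config.genes_per_block, config.phens_per_block
    block_map = {f"g:G{i:04d}": i // m for i in range(B * m)}
    block_map.update({f"p:P{i:04d}": i // r for i in range(B * r)})
    return net, block_map


def write_fixture_files(network: GPNetwork, directory: str | Path) -> tuple[Path, Path, Path]:
    """Emit ppi.tsv, phen_sim.tsv (triples, score 1.0) and assoc.tsv.

    Parsing, filtering (threshold 0.6) and assembling these files
    reconstructs *network* exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ppi = directory / "ppi.tsv"
    sim = directory / "phen_sim.tsv"
    assoc = directory / "assoc.tsv"
    from .gpnet import EdgeRelation  # local to avoid a circular-feel at top

    gg, pp, gp = [], [], []
    for u, v, rel in network.edges():
        if rel is EdgeRelation.GENE_GENE:
            gg.append((u[2:], v[2:]))
        elif rel is EdgeRelation.PHEN_PHEN:
            pp.append((u[2:], v[2:]))
        else:
            g, p = (u, v) if u.startswith("g:") else (v, u)
            gp.append((g[2:], p[2:]))
    ppi.write_text("".join(f"{a}\t{b}\n" for a, b in sorted(gg)), encoding="utf-8")
    sim.write_text(
        "".join(f"{a}\t{b}\t{_FIXTURE_SCORE}\n" for a, b in sorted(pp)),
        encoding="utf-8",
    )
    assoc.write_text("".join(f"{g}\t{p}\n" for g, p in sorted(gp)), encoding="utf-8")
    return ppi, sim, assoc
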