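"""Random-walk corpus generation over the GP-network.

Three walk strategies share one sampler:

* ``MULTIPATH`` — the multi-path constrained walk: no three consecutive
  vertices may share a type. With no two-step same-type history both vertex
  types are eligible, and the next vertex is drawn uniformly from the union
  of eligible neighbours (so gene–gene, phenotype–phenotype and
  gene–phenotype relations all enter the corpus).
* ``METAPATH_GPG`` — a fixed alternating gene–phenotype meta-path: the next
  vertex must always be of the other type.
* ``UNIFORM`` — a type-blind uniform walk over all neighbours (DeepWalk
  style).

Sampling is cumulative-probability inversion over candidates sorted by id,
realized for the uniform-over-candidates case as ``idx = floor(r * n)``. A
dead end (no eligible neighbour) terminates the walk early; length-1 walks
are discarded at the corpus level since they yield no skip-gram pairs.

``generate_corpus`` runs a numba-jitted kernel by default; the pure-Python
path (``fast=False``) consumes the identical PCG32 stream and produces the
identical corpus, and serves as the oracle in tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .gpnet import GPNetwork, VertexType
from .rng import HAVE_NUMBA, PCG32, STREAM_WALK, njit, pcg32_random, pcg32_state


class WalkStrategy(Enum):
    MULTIPATH = "multipath"
    METAPATH_GPG = "metapath"
    UNIFORM = "uniform"


_STRATEGY_CODE = {
    WalkStrategy.MULTIPATH: 0,
    WalkStrategy.METAPATH_GPG: 1,
    WalkStrategy.UNIFORM: 2,
}


@dataclass(frozen=True)
class WalkConfig:
    """Corpus-generation settings (defaults follow the method's t=500, l=100)."""

    walks_per_vertex: int = 500
    walk_length: int = 100
    strategy: WalkStrategy = WalkStrategy.MULTIPATH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_vertex < 1:
            raise ValueError("walks_per_vertex must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


Walk = tuple[str, ...]


@dataclass
class WalkCorpus:
    """Ordered collection of walks plus per-vertex occurrence counts."""

    walks: list[Walk]
    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.counts:
            for w in self.walks:
                self.counts.update(w)

    def __len__(self) -> int:
        return len(self.walks)

    def vocabulary(self) -> list[str]:
        return sorted(self.counts)


def eligible_next_types(
    prev_type: VertexType | None, curr_type: VertexType
) -> frozenset[VertexType]:
    """Vertex types allowed at the next step under the multi-path constraint.

    Only a two-step same-type history restricts the walk: after two genes the
    next vertex must be a phenotype, and vice versa. With no history (walk
    start) or mixed history, both types are eligible.
    """
    if prev_type is curr_type:
        return frozenset({curr_type.other})
    return frozenset({VertexType.GENE, VertexType.PHENOTYPE})


def transition_distribution(
    network: GPNetwork,
    prev: str | None,
    curr: str,
    strategy: WalkStrategy = WalkStrategy.MULTIPATH,
) -> dict[str, float]:
    """One-step transition probabilities from *curr* given the previous vertex.

    Eligible neighbours are equiprobable (1/|candidates|); ineligible or
    non-adjacent vertices have probability zero and are omitted. Returns an
    empty map at a dead end.
    """
    if curr not in network:
        raise KeyError(f"vertex {curr!r} not in network")
    curr_type = network.vertex_type(curr)
    if strategy is WalkStrategy.MULTIPATH:
        prev_type = network.vertex_type(prev) if prev is not None else None
        elig = eligible_next_types(prev_type, curr_type)
        cands: set[str] = set()
        for t in elig:
            cands |= network.neighbors(curr, t)
    elif strategy is WalkStrategy.METAPATH_GPG:
        cands = network.neighbors(curr, curr_type.other)
    else:
        cands = network.neighbors(curr)
    if not cands:
        return {}
    p = 1.0 / len(cands)
    return {v: p for v in sorted(cands)}


def generate_walk(
    network: GPNetwork,
    start: str,
    length: int,
    strategy: WalkStrategy,
    rng: PCG32,
) -> Walk:
    """One random walk from *start*; terminates early at a dead end."""
    if start not in network:
        raise KeyError(f"start vertex {start!r} not in network")
    walk = [start]
    prev: str | None = None
    while len(walk) < length:
        dist = transition_distribution(network, prev, walk[-1], strategy)
        if not dist:
            break
        cands = sorted(dist)  # already sorted by construction; keep explicit
        idx = int(rng.random() * len(cands))
        if idx == len(cands):  # guard the r == 1.0-ulp boundary
            idx -= 1
        prev = walk[-1]
        walk.append(cands[idx])
    return tuple(walk)


# ---------------------------------------------------------------------------
# fast path: CSR view of the network + jitted corpus kernel


class _GraphIndex:
    """Integer CSR view of a GPNetwork.

    Vertices are numbered in ascending id order; because ``g:`` sorts before
    ``p:``, indices ``< n_genes`` are genes. Each vertex's neighbour slice is
    sorted ascending, so its gene neighbours form a prefix whose length is
    stored in ``gene_counts``.
    """

    def __init__(self, network: GPNetwork) -> None:
        self.ids: list[str] = network.vertices()
        self.index = {v: i for i, v in enumerate(self.ids)}
        self.n_genes = sum(1 for v in self.ids if network.vertex_type(v) is VertexType.GENE)
        offsets = [0]
        flat: list[int] = []
        gene_counts: list[int] = []
        for v in self.ids:
            nbrs = sorted(self.index[u] for u in network.neighbors(v))
            flat.extend(nbrs)
            offsets.append(len(flat))
            gene_counts.append(sum(1 for u in nbrs if u < self.n_genes))
        self.nbr_flat = np.asarray(flat, dtype=np.int32)
        self.nbr_off = np.asarray(offsets, dtype=np.int64)
        self.gene_counts = np.asarray(gene_counts, dtype=np.int64)


@njit(cache=True)
def _corpus_kernel(
    nbr_flat, nbr_off, gene_counts, n_genes, n_vertices,
    walks_per_vertex, walk_length, strategy, state
):  # pragma: no cover - exercised via generate_corpus
    n_walks = n_vertices * walks_per_vertex
    tokens = np.empty(n_walks * walk_length, dtype=np.int32)
    lengths = np.empty(n_walks, dtype=np.int64)
    pos = 0
    w = 0
    for v in range(n_vertices):
        for _ in range(walks_per_vertex):
            cur = v
            prev = -1
            tokens[pos] = cur
            pos += 1
            wl = 1
            while wl < walk_length:
                s = nbr_off[cur]
                e = nbr_off[cur + 1]
                gsplit = s + gene_counts[cur]
                cur_is_gene = cur < n_genes
                if strategy == 0:  # multipath
                    lo, hi = s, e
                    if prev >= 0 and (prev < n_genes) == cur_is_gene:
                        if cur_is_gene:
                            lo = gsplit  # two genes: phenotypes only
                        else:
                            hi = gsplit  # two phenotypes: genes only
                elif strategy == 1:  # metapath g-p-g: always switch type
                    if cur_is_gene:
                        lo, hi = gsplit, e
                    else:
                        lo, hi = s, gsplit
                else:  # uniform
                    lo, hi = s, e
                n = hi - lo
                if n <= 0:
                    break
                idx = int(pcg32_random(state) * n)
                if idx == n:
                    idx -= 1
                prev = cur
                cur = nbr_flat[lo + idx]
                tokens[pos] = cur
                pos += 1
                wl += 1
            lengths[w] = wl
            w += 1
    return tokens[:pos], lengths


def generate_corpus(
    network: GPNetwork, config: WalkConfig, fast: bool = True
) -> WalkCorpus:
    """Generate ``walks_per_vertex`` walks from every vertex, in ascending
    id order, with one seeded generator for the whole corpus.

    Walks that terminate with fewer than two vertices are discarded. The
    jitted and pure-Python paths consume the same PCG32 stream and produce
    identical corpora.
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    if fast and HAVE_NUMBA:
        gi = _GraphIndex(network)
        state = pcg32_state(config.seed, STREAM_WALK)
        tokens, lengths = _corpus_kernel(
            gi.nbr_flat, gi.nbr_off, gi.gene_counts, gi.n_genes, len(gi.ids),
            config.walks_per_vertex, config.walk_length,
            _STRATEGY_CODE[config.strategy], state,
        )
        ids = np.asarray(gi.ids, dtype=object)
        walks: list[Walk] = []
        pos = 0
        for wl in lengths:
            wl = int(wl)
            if wl >= 2:
                walks.append(tuple(ids[tokens[pos : pos + wl]]))
            pos += wl
        return WalkCorpus(walks)
    rng = PCG32(config.seed, STREAM_WALK)
    walks = []
    for v in network.vertices():
        for _ in range(config.walks_per_vertex):
            w = generate_walk(network, v, config.walk_length, config.strategy, rng)
            if len(w) >= 2:
                walks.append(w)
    return WalkCorpus(walks)


# ---------------------------------------------------------------------------
# corpus I/O (one walk per line, space-separated namespaced ids)


def write_corpus(corpus: WalkCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in corpus.walks:
            fh.write(" ".join(w) + "\n")


def read_corpus(path: str | Path) -> WalkCorpus:
    walks: list[Walk] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            toks = line.split()
            if toks:
                walks.append(tuple(toks))
    return WalkCorpus(walks)
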