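"""Gene–phenotype heterogeneous network: parsing, filtering, assembly.

The GP-network is an undirected simple graph over two vertex types — genes
(proteins) and disease phenotypes — with three edge relations: protein–
protein interactions (gene–gene), thresholded phenotype–similarity links
(phenotype–phenotype), and known gene–phenotype associations. Inputs are
the three generic text shapes used by the field's public resources: a
two-column PPI edge list, a phenotype similarity matrix (labelled square
matrix or sparse triples), and a two-column association list.

Raw identifiers are namespaced internally with ``g:`` / ``p:`` prefixes so a
token that happens to occur both as a gene symbol and a phenotype accession
yields two distinct vertices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

GENE_PREFIX = "g:"
PHEN_PREFIX = "p:"

_SYMMETRY_TOL = 1e-6  # |M[i,j]-M[j,i]| above this is an error, below is averaged


class VertexType(Enum):
    GENE = "gene"
    PHENOTYPE = "phenotype"

    @property
    def prefix(self) -> str:
        return GENE_PREFIX if self is VertexType.GENE else PHEN_PREFIX

    @property
    def other(self) -> "VertexType":
        return VertexType.PHENOTYPE if self is VertexType.GENE else VertexType.GENE


class EdgeRelation(Enum):
    GENE_GENE = "gene-gene"
    PHEN_PHEN = "phen-phen"
    GENE_PHEN = "gene-phen"


def relation_for(tu: VertexType, tv: VertexType) -> EdgeRelation:
    """Edge relation is fully determined by the endpoint types."""
    if tu is VertexType.GENE and tv is VertexType.GENE:
        return EdgeRelation.GENE_GENE
    if tu is VertexType.PHENOTYPE and tv is VertexType.PHENOTYPE:
        return EdgeRelation.PHEN_PHEN
    return EdgeRelation.GENE_PHEN


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


class NamespaceCollisionError(ValueError):
    """An internal vertex id was registered under both vertex types."""


@dataclass(frozen=True)
class FilterConfig:
    """Pre-assembly filtering rules.

    similarity_threshold
        Phenotype pairs are linked only when their similarity score is
        *strictly* greater than this value (default 0.6).
    drop_self_only
        Remove proteins whose only PPI record is a self-interaction.
        Self-loop edges themselves are always discarded (simple graph);
        with this flag off, such proteins stay in the gene vertex set and
        may survive through their associations.
    prune_distance1
        Remove genes with no association and no PPI neighbour holding an
        association (and symmetrically for phenotypes).
    """

    similarity_threshold: float = 0.6
    drop_self_only: bool = True
    prune_distance1: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError(
                f"similarity_threshold must be in [0,1], got {self.similarity_threshold}"
            )


# ---------------------------------------------------------------------------
# parsing


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace tokens), skipping blanks and '#'."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def parse_ppi(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column protein–protein interaction edge list.

    Returns deduplicated unordered pairs, each normalized lexicographically.
    Self-interactions are retained as pairs ``(x, x)``; the filtering stage
    decides their fate.
    """
    pairs: set[tuple[str, str]] = set()
    for lineno, toks in _data_lines(path):
        if len(toks) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(toks)}")
        pairs.add(_norm_pair(toks[0], toks[1]))
    return pairs


def parse_associations(path: str | Path) -> set[tuple[str, str]]:
    """Read gene–phenotype association pairs (gene column first)."""
    pairs: set[tuple[str, str]] = set()
    for lineno, toks in _data_lines(path):
        if len(toks) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(toks)}")
        pairs.add((toks[0], toks[1]))
    return pairs


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def parse_phenotype_similarity(path: str | Path) -> dict[tuple[str, str], float]:
    """Read phenotype–phenotype similarity scores.

    Two dialects are auto-detected from the first data row's column count:
    exactly three columns means sparse triples ``phen1 phen2 score``; any
    other width means a labelled square matrix (first row = column ids,
    first column = row ids, with an optional corner label). Diagonal entries
    are discarded. Asymmetric matrix cells beyond 1e-6 raise; smaller
    discrepancies are averaged.
    """
    rows = list(_data_lines(path))
    if not rows:
        return {}
    if len(rows[0][1]) == 3:
        return _parse_triples(path, rows)
    return _parse_matrix(path, rows)


def _parse_triples(path, rows) -> dict[tuple[str, str], float]:
    scores: dict[tuple[str, str], float] = {}
    for lineno, toks in rows:
        if len(toks) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(toks)}")
        a, b, s = toks
        if not _is_number(s):
            raise ParseError(f"{path}:{lineno}: non-numeric score {s!r}")
        if a == b:
            continue  # diagonal
        key = _norm_pair(a, b)
        val = float(s)
        if key in scores:
            if abs(scores[key] - val) > _SYMMETRY_TOL:
                raise ParseError(
                    f"{path}:{lineno}: asymmetric scores for {key}: "
                    f"{scores[key]} vs {val}"
                )
            scores[key] = (scores[key] + val) / 2.0
        else:
            scores[key] = val
    return scores


def _parse_matrix(path, rows) -> dict[tuple[str, str], float]:
    (header_lineno, header), body = rows[0], rows[1:]
    n = len(body)
    if len(header) == n + 1:
        col_ids = header[1:]  # corner label present
    elif len(header) == n:
        col_ids = header
    else:
        raise ParseError(
            f"{path}:{header_lineno}: labelled matrix is not square "
            f"({len(header)} header columns, {n} data rows)"
        )
    row_ids: list[str] = []
    values: list[list[float]] = []
    for lineno, toks in body:
        if len(toks) != n + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {n + 1} columns, got {len(toks)}"
            )
        row_ids.append(toks[0])
        vals = []
        for tok in toks[1:]:
            if not _is_number(tok):
                raise ParseError(f"{path}:{lineno}: non-numeric score {tok!r}")
            vals.append(float(tok))
        values.append(vals)
    if row_ids != col_ids:
        raise ParseError(f"{path}: row labels do not match column labels")
    scores: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = values[i][j], values[j][i]
            if abs(a - b) > _SYMMETRY_TOL:
                raise ParseError(
                    f"{path}: asymmetric cell ({row_ids[i]},{row_ids[j]}): {a} vs {b}"
                )
            scores[_norm_pair(row_ids[i], row_ids[j])] = (a + b) / 2.0
    return scores


# ---------------------------------------------------------------------------
# filtering


def apply_filters(
    ppi_pairs: Iterable[tuple[str, str]],
    phen_scores: Mapping[tuple[str, str], float],
    assoc_pairs: Iterable[tuple[str, str]],
    config: FilterConfig | None = None,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]], set[tuple[str, str]]]:
    """Apply the pre-assembly filters; returns (gene edges, phen edges, assocs).

    The sequence is deterministic:

    1. drop self-loop edges and (by default) proteins whose only interaction
       was a self-loop;
    2. keep phenotype pairs with score strictly above the threshold, as
       unweighted edges;
    3. drop associations whose gene or phenotype is missing from the
       surviving vertex sets;
    4. single-pass distance-1 prune: drop genes with no association and no
       neighbour holding one, symmetrically for phenotypes;
    5. re-apply step 3.
    """
    cfg = config or FilterConfig()

    # 1. self-loop handling
    gene_edges = {_norm_pair(*p) for p in ppi_pairs if p[0] != p[1]}
    genes = {x for e in gene_edges for x in e}
    if not cfg.drop_self_only:
        genes |= {a for a, b in ppi_pairs if a == b}

    # 2. similarity threshold (strict >)
    phen_edges = {
        _norm_pair(*pair)
        for pair, s in phen_scores.items()
        if s > cfg.similarity_threshold and pair[0] != pair[1]
    }
    phens = {x for e in phen_edges for x in e}

    # 3. associations restricted to surviving vertices
    assocs = {(g, p) for g, p in assoc_pairs if g in genes and p in phens}

    # 4. distance-1 prune (single pass, not iterated to fixpoint)
    if cfg.prune_distance1:
        gene_edges, genes = _prune_distance1(gene_edges, genes, {g for g, _ in assocs})
        phen_edges, phens = _prune_distance1(phen_edges, phens, {p for _, p in assocs})

    # 5. re-apply step 3
    assocs = {(g, p) for g, p in assocs if g in genes and p in phens}
    return gene_edges, phen_edges, assocs


def _prune_distance1(
    edges: set[tuple[str, str]], vertices: set[str], anchored: set[str]
) -> tuple[set[tuple[str, str]], set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in vertices}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    keep = {
        v for v in vertices if v in anchored or any(n in anchored for n in adj[v])
    }
    return {e for e in edges if e[0] in keep and e[1] in keep}, keep


# ---------------------------------------------------------------------------
# the network container


class GPNetwork:
    """Typed, undirected, simple heterogeneous graph over genes and phenotypes.

    Vertex ids are namespaced (``g:``/``p:``). Adjacency is held partitioned
    by neighbour type, which is what the constrained walk needs at every
    step.
    """

    def __init__(self) -> None:
        self._types: dict[str, VertexType] = {}
        self._adj: dict[str, dict[VertexType, set[str]]] = {}

    # -- construction -------------------------------------------------------

    def add_vertex(self, vid: str, vtype: VertexType) -> None:
        existing = self._types.get(vid)
        if existing is not None:
            if existing is not vtype:
                raise NamespaceCollisionError(
                    f"vertex {vid!r} registered as both {existing.value} and {vtype.value}"
                )
            return
        self._types[vid] = vtype
        self._adj[vid] = {VertexType.GENE: set(), VertexType.PHENOTYPE: set()}

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop {u!r} not allowed")
        for x in (u, v):
            if x not in self._types:
                raise KeyError(f"unknown vertex {x!r}")
        self._adj[u][self._types[v]].add(v)
        self._adj[v][self._types[u]].add(u)

    # -- queries ------------------------------------------------------------

    def __contains__(self, vid: str) -> bool:
        return vid in self._types

    def __len__(self) -> int:
        return len(self._types)

    def vertex_type(self, vid: str) -> VertexType:
        return self._types[vid]

    def vertices(self) -> list[str]:
        return sorted(self._types)

    def genes(self) -> list[str]:
        return sorted(v for v, t in self._types.items() if t is VertexType.GENE)

    def phenotypes(self) -> list[str]:
        return sorted(v for v, t in self._types.items() if t is VertexType.PHENOTYPE)

    def neighbors(self, vid: str, vtype: VertexType | None = None) -> set[str]:
        if vtype is None:
            return self._adj[vid][VertexType.GENE] | self._adj[vid][VertexType.PHENOTYPE]
        return set(self._adj[vid][vtype])

    def degree(self, vid: str) -> int:
        return len(self._adj[vid][VertexType.GENE]) + len(
            self._adj[vid][VertexType.PHENOTYPE]
        )

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u][self._types[v]]

    def edges(self) -> Iterator[tuple[str, str, EdgeRelation]]:
        for u in sorted(self._adj):
            for t in VertexType:
                for v in sorted(self._adj[u][t]):
                    if u < v:
                        yield u, v, relation_for(self._types[u], t)

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def associations(self) -> list[tuple[str, str]]:
        """All gene–phenotype edges as (gene, phenotype), sorted."""
        out = []
        for u, v, rel in self.edges():
            if rel is EdgeRelation.GENE_PHEN:
                g, p = (u, v) if self._types[u] is VertexType.GENE else (v, u)
                out.append((g, p))
        return sorted(out)

    # -- mutation-by-copy ---------------------------------------------------

    def copy(self) -> "GPNetwork":
        new = GPNetwork()
        new._types = dict(self._types)
        new._adj = {
            v: {t: set(s) for t, s in part.items()} for v, part in self._adj.items()
        }
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GPNetwork):
            return NotImplemented
        return self._types == other._types and self._adj == other._adj

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        vertices = [
            {"id": v, "type": self._types[v].value} for v in sorted(self._types)
        ]
        edges = [
            {"u": u, "v": v, "relation": rel.value} for u, v, rel in self.edges()
        ]
        return json.dumps(
            {"vertices": vertices, "edges": edges}, indent=1, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "GPNetwork":
        data = json.loads(text)
        net = cls()
        for rec in data["vertices"]:
            net.add_vertex(rec["id"], VertexType(rec["type"]))
        for rec in data["edges"]:
            net.add_edge(rec["u"], rec["v"])
        return net

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GPNetwork":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def assemble_network(
    gene_edges: Iterable[tuple[str, str]],
    phen_edges: Iterable[tuple[str, str]],
    associations: Iterable[tuple[str, str]],
) -> GPNetwork:
    """Build a GPNetwork from filtered edge sets; ids get ``g:``/``p:`` prefixes.

    The vertex set is the union of all edge endpoints, so the same raw token
    used as a gene and as a phenotype yields two distinct vertices.
    """
    net = GPNetwork()
    for a, b in sorted(gene_edges):
        net.add_vertex(GENE_PREFIX + a, VertexType.GENE)
        net.add_vertex(GENE_PREFIX + b, VertexType.GENE)
        net.add_edge(GENE_PREFIX + a, GENE_PREFIX + b)
    for a, b in sorted(phen_edges):
        net.add_vertex(PHEN_PREFIX + a, VertexType.PHENOTYPE)
        net.add_vertex(PHEN_PREFIX + b, VertexType.PHENOTYPE)
        net.add_edge(PHEN_PREFIX + a, PHEN_PREFIX + b)
    for g, p in sorted(associations):
        net.add_vertex(GENE_PREFIX + g, VertexType.GENE)
        net.add_vertex(PHEN_PREFIX + p, VertexType.PHENOTYPE)
        net.add_edge(GENE_PREFIX + g, PHEN_PREFIX + p)
    return net


def build_network(
    ppi_path: str | Path,
    phen_sim_path: str | Path,
    assoc_path: str | Path,
    config: FilterConfig | None = None,
) -> GPNetwork:
    """Parse the three input files, filter, and assemble in one call."""
    gene_edges, phen_edges, assocs = apply_filters(
        parse_ppi(ppi_path),
        parse_phenotype_similarity(phen_sim_path),
        parse_associations(assoc_path),
        config,
    )
    return assemble_network(gene_edges, phen_edges, assocs)


def remove_association(network: GPNetwork, gene_id: str, phen_id: str) -> GPNetwork:
    """Return a copy of *network* with one gene–phenotype edge removed.

    Both endpoints are retained even if isolated afterwards (a held-out
    evaluation fold must still be able to refer to them). Ids are the
    namespaced forms.
    """
    if gene_id not in network or phen_id not in network:
        raise KeyError(f"association ({gene_id}, {phen_id}): vertex not in network")
    if network.vertex_type(gene_id) is not VertexType.GENE:
        raise ValueError(f"{gene_id!r} is not a gene vertex")
    if network.vertex_type(phen_id) is not VertexType.PHENOTYPE:
        raise ValueError(f"{phen_id!r} is not a phenotype vertex")
    if not network.has_edge(gene_id, phen_id):
        raise KeyError(f"association ({gene_id}, {phen_id}) not present")
    new = network.copy()
    new._adj[gene_id][VertexType.PHENOTYPE].discard(phen_id)
    new._adj[phen_id][VertexType.GENE].discard(gene_id)
    return new
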