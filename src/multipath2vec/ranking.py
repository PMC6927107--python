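"""Candidate-gene prioritization by cosine similarity to a target phenotype.

Genes and phenotypes are compared through their center (Φ) vectors. For a
target phenotype, every embedded gene is scored with

    sim(g, p) = Σ x_n y_n / (sqrt(Σ x_n²) · sqrt(Σ y_n²)),

except genes that still hold a known association edge to the target (the
prioritization task asks for *new* candidates). Ties are broken by ascending
gene id, and a vector of all zeros scores 0, so the ranking is a total,
deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gpnet import GENE_PREFIX, GPNetwork
from .sgns import EmbeddingModel


def cosine_similarity(g: np.ndarray, p: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either is all-zero."""
    g = np.asarray(g, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if g.shape != p.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {p.shape}")
    ng = float(np.linalg.norm(g))
    np_ = float(np.linalg.norm(p))
    if ng == 0.0 or np_ == 0.0:
        return 0.0
    return float(g @ p / (ng * np_))


@dataclass
class RankedCandidates:
    """Ranked (gene, score) list for one target phenotype; ranks are 1-based."""

    target: str
    scores: list[tuple[str, float]]

    def __len__(self) -> int:
        return len(self.scores)

    def rank_of(self, gene: str) -> int | None:
        for r, (g, _) in enumerate(self.scores, start=1):
            if g == gene:
                return r
        return None

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.scores[:k]


def rank_candidates(
    model: EmbeddingModel, network: GPNetwork, phenotype: str
) -> RankedCandidates:
    """Score and rank all embedded genes against *phenotype*.

    Candidates are every gene with an embedding except those holding a
    retained association edge to the target in *network*. Sorted by
    descending score, ties by ascending gene id.
    """
    if phenotype not in model:
        raise KeyError(f"phenotype {phenotype!r} has no embedding")
    known = {
        g for g in (network.neighbors(phenotype) if phenotype in network else set())
        if g.startswith(GENE_PREFIX)
    }
    genes = [v for v in model.ids if v.startswith(GENE_PREFIX) and v not in known]
    p_vec = model.phi_of(phenotype)
    scored = [(g, cosine_similarity(model.phi_of(g), p_vec)) for g in genes]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return RankedCandidates(phenotype, scored)


def write_ranking_tsv(
    ranked: RankedCandidates, path: str | Path, top: int | None = None
) -> None:
    """TSV with columns rank, gene, score (6 decimals)."""
    rows = ranked.scores if top is None else ranked.scores[:top]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene\tscore\n")
        for r, (g, s) in enumerate(rows, start=1):
            fh.write(f"{r}\t{g}\t{s:.6f}\n")
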