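"""Leave-one-out cross-validation with Top-K precision.

Every known gene–phenotype association becomes one fold: its edge is removed
from the network, walks are regenerated and the embedding retrained from
scratch (a shared embedding would leak the held-out edge through the walk
corpus), candidates are ranked for the fold's phenotype, and the held-out
gene's 1-based rank is recorded. A fold whose phenotype or gene never enters
the walk corpus (hence has no embedding) counts as a MISS rather than being
skipped, so precision is not inflated.

Folds are stratified by the phenotype's number of associated genes in the
full association set: SINGLE (exactly one causative gene) versus MANY.
Precision@K is the fraction of folds whose held-out gene ranks within the
top K. Viewing each fold as a binary detection, a hit is simultaneously a
true positive (the cut link is recovered) and a true negative (its absence
elsewhere is confirmed), so TP = TN and FP = FN by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

from .gpnet import GPNetwork, remove_association
from .ranking import rank_candidates
from .sgns import TrainConfig, train
from .walks import WalkConfig, generate_corpus

logger = logging.getLogger(__name__)

DEFAULT_KS = (1, 5, 10, 30, 50, 100)


class Stratum(Enum):
    SINGLE = "single"
    MANY = "many"


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one leave-one-out fold; ``rank`` is None on a MISS."""

    gene: str
    phenotype: str
    rank: int | None
    pool_size: int
    stratum: Stratum

    @property
    def miss(self) -> bool:
        return self.rank is None


@dataclass
class LOOCVReport:
    folds: list[FoldResult]

    def strata(self) -> dict[Stratum, list[FoldResult]]:
        out: dict[Stratum, list[FoldResult]] = {s: [] for s in Stratum}
        for f in self.folds:
            out[f.stratum].append(f)
        return out


def stratify_associations(network: GPNetwork) -> dict[tuple[str, str], Stratum]:
    """SINGLE when the phenotype has exactly one associated gene, else MANY."""
    assocs = network.associations()
    if not assocs:
        raise ValueError("network has no associations")
    per_phen: dict[str, int] = {}
    for _, p in assocs:
        per_phen[p] = per_phen.get(p, 0) + 1
    # the alternative reading (genes with exactly one phenotype) is logged
    # for comparison but does not drive the report
    per_gene: dict[str, int] = {}
    for g, _ in assocs:
        per_gene[g] = per_gene.get(g, 0) + 1
    n_single_by_gene = sum(1 for g, _ in assocs if per_gene[g] == 1)
    n_single = sum(1 for _, p in assocs if per_phen[p] == 1)
    logger.info(
        "stratification: %d/%d SINGLE by phenotype gene-count "
        "(%d would be SINGLE under the by-gene reading)",
        n_single, len(assocs), n_single_by_gene,
    )
    return {
        (g, p): Stratum.SINGLE if per_phen[p] == 1 else Stratum.MANY
        for g, p in assocs
    }


def run_loocv(
    network: GPNetwork,
    walk_config: WalkConfig,
    train_config: TrainConfig,
    base_seed: int,
) -> LOOCVReport:
    """One fold per association, in ascending (gene, phenotype) order.

    Fold *i* uses seed ``base_seed + i`` for both walk generation and
    training, so the whole report is reproducible from one integer.
    """
    strata = stratify_associations(network)
    folds: list[FoldResult] = []
    for fold_index, (g, p) in enumerate(sorted(strata)):
        held_out = remove_association(network, g, p)
        seed = base_seed + fold_index
        corpus = generate_corpus(held_out, replace(walk_config, seed=seed))
        rank: int | None = None
        pool = 0
        if corpus.walks:
            model = train(corpus, replace(train_config, seed=seed))
            if p in model and g in model:
                ranked = rank_candidates(model, held_out, p)
                pool = len(ranked)
                rank = ranked.rank_of(g)
        folds.append(FoldResult(g, p, rank, pool, strata[(g, p)]))
        logger.debug("fold %d (%s, %s): rank=%s/%d", fold_index, g, p, rank, pool)
    return LOOCVReport(folds)


def _select(report: LOOCVReport, stratum: Stratum | str | None) -> list[FoldResult]:
    if stratum is None or stratum == "ALL":
        return report.folds
    if isinstance(stratum, str):
        stratum = Stratum(stratum.lower())
    return [f for f in report.folds if f.stratum is stratum]


def topk_precision(
    report: LOOCVReport, K: int, stratum: Stratum | str | None = None
) -> float:
    """TP/(TP+FP): the fraction of folds whose held-out gene ranks within K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    folds = _select(report, stratum)
    if not folds:
        raise ValueError(f"no folds in stratum {stratum!r}")
    hits = sum(1 for f in folds if f.rank is not None and f.rank <= K)
    return hits / len(folds)


def confusion_counts(
    report: LOOCVReport, K: int, stratum: Stratum | str | None = None
) -> dict[str, int]:
    """TP/FP/TN/FN under the fold-as-binary-detection reading (TP=TN, FP=FN)."""
    folds = _select(report, stratum)
    tp = sum(1 for f in folds if f.rank is not None and f.rank <= K)
    fp = len(folds) - tp
    return {"TP": tp, "FP": fp, "TN": tp, "FN": fp}


def write_report_tsv(
    report: LOOCVReport, path: str | Path, ks: Sequence[int] = DEFAULT_KS
) -> None:
    """One row per stratum plus ALL; hits@K and precision@K columns."""
    rows: list[tuple[str, list[FoldResult]]] = [
        (s.value, fs) for s, fs in report.strata().items() if fs
    ]
    rows.append(("ALL", report.folds))
    with open(path, "w", encoding="utf-8") as fh:
        header = ["stratum", "n"]
        for k in ks:
            header += [f"hits@{k}", f"precision@{k}"]
        fh.write("\t".join(header) + "\n")
        for name, folds in rows:
            cells = [name, str(len(folds))]
            for k in ks:
                hits = sum(1 for f in folds if f.rank is not None and f.rank <= k)
                cells += [str(hits), f"{hits / len(folds):.6f}"]
            fh.write("\t".join(cells) + "\n")


def write_folds_tsv(report: LOOCVReport, path: str | Path) -> None:
    """Per-fold detail: gene, phenotype, stratum, rank (MISS if unranked), pool."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tphenotype\tstratum\trank\tpool_size\n")
        for f in report.folds:
            rank = "MISS" if f.rank is None else str(f.rank)
            fh.write(f"{f.gene}\t{f.phenotype}\t{f.stratum.value}\t{rank}\t{f.pool_size}\n")
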