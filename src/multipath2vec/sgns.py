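"""Skip-gram with negative sampling over walk corpora.

Each vertex carries two d-dimensional vectors: a center vector Φ(v) (the
embedding proper) and a context vector Ψ(v). For every (center, context)
pair within a window of size k the per-pair loss is the standard
negative-sampling objective

    O = −log σ(Ψ(ctx)·Φ(c)) − Σ_{m=1..M} log σ(−Ψ(neg_m)·Φ(c)),

minimized by per-pair SGD, Φ ← Φ − α ∂O/∂Φ and Ψ ← Ψ − α ∂O/∂Ψ, with α
decayed linearly across the total number of processed pairs. Negatives are
drawn from the corpus unigram distribution raised to the 3/4 power,
resampling on collision with the context vertex; the distribution spans the
whole vocabulary by default, or only the context vertex's own type in the
type-restricted mode.

``train`` runs a numba-jitted kernel; a pure-Python reference trainer
consuming the identical PCG32 stream exists for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gpnet import GENE_PREFIX
from .rng import (
    HAVE_NUMBA,
    PCG32,
    STREAM_INIT,
    STREAM_TRAIN,
    njit,
    pcg32_random,
    pcg32_state,
)
from .walks import Walk, WalkCorpus

_SIGMOID_CLIP = 40.0  # |x| >= 40: sigmoid indistinguishable from 0/1 in float64
_NEG_POWER = 0.75


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults follow the method: d=128, k=7, M=5)."""

    dimension: int = 128
    window: int = 7
    negatives: int = 5
    alpha_init: float = 0.025
    alpha_final: float = 1e-4
    epochs: int = 1
    seed: int = 0
    same_type_negatives: bool = False  # restrict negatives to the context's type

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")
        if not self.alpha_init > self.alpha_final > 0:
            raise ValueError("need alpha_init > alpha_final > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class EmbeddingModel:
    """Center (Φ) and context (Ψ) vector tables over a shared vocabulary."""

    def __init__(self, ids: Sequence[str], phi: np.ndarray, psi: np.ndarray) -> None:
        ids = list(ids)
        if sorted(ids) != ids:
            raise ValueError("ids must be sorted ascending")
        if phi.shape != psi.shape or phi.shape[0] != len(ids):
            raise ValueError("table shapes do not match the id list")
        if not (np.isfinite(phi).all() and np.isfinite(psi).all()):
            raise ValueError("non-finite entries in embedding tables")
        self.ids: list[str] = ids
        self.index: dict[str, int] = {v: i for i, v in enumerate(ids)}
        self.phi = phi
        self.psi = psi

    @property
    def d(self) -> int:
        return self.phi.shape[1]

    def __contains__(self, vid: str) -> bool:
        return vid in self.index

    def __len__(self) -> int:
        return len(self.ids)

    def phi_of(self, vid: str) -> np.ndarray:
        return self.phi[self.index[vid]]

    def psi_of(self, vid: str) -> np.ndarray:
        return self.psi[self.index[vid]]

    # word2vec-style text format: header "<count> <dim>", then one vertex/line
    def save(self, path: str | Path, table: str = "phi") -> None:
        mat = self.phi if table == "phi" else self.psi
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)} {self.d}\n")
            for i, vid in enumerate(self.ids):
                fh.write(vid + " " + " ".join(f"{x:.6f}" for x in mat[i]) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            n, d = map(int, fh.readline().split())
            recs = []
            for line in fh:
                toks = line.split()
                if toks:
                    recs.append((toks[0], np.array([float(x) for x in toks[1:]])))
        if len(recs) != n or any(len(v) != d for _, v in recs):
            raise ValueError(f"{path}: malformed embedding file")
        recs.sort(key=lambda r: r[0])
        ids = [r[0] for r in recs]
        phi = np.vstack([r[1] for r in recs])
        return cls(ids, phi, np.zeros_like(phi))


def init_model(vertex_ids: Iterable[str], d: int, seed: int) -> EmbeddingModel:
    """Fresh model: Φ uniform in the open interval (−0.5/d, +0.5/d), Ψ zero."""
    ids = sorted(set(vertex_ids))
    if not ids:
        raise ValueError("empty vertex id set")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = PCG32(seed, STREAM_INIT)
    phi = np.empty((len(ids), d))
    for i in range(len(ids)):
        for j in range(d):
            # (u32+0.5)/2^32 lies strictly inside (0,1), so entries are
            # strictly inside (-0.5/d, 0.5/d)
            u = (rng.next_uint32() + 0.5) / 4294967296.0
            phi[i, j] = (u - 0.5) / d
    return EmbeddingModel(ids, phi, np.zeros((len(ids), d)))


def context_pairs(walk: Walk, k: int) -> list[tuple[str, str]]:
    """(center, context) pairs within window k, truncated at walk boundaries.

    Deterministic order: increasing center position, then increasing context
    position.
    """
    if k < 1:
        raise ValueError("window must be >= 1")
    L = len(walk)
    out = []
    for i in range(L):
        for j in range(max(0, i - k), min(L, i + k + 1)):
            if j != i:
                out.append((walk[i], walk[j]))
    return out


def _pair_count(length: int, k: int) -> int:
    return sum(min(length - 1, i + k) - max(0, i - k) for i in range(length))


def _bisect_right(cum: np.ndarray, r: float) -> int:
    lo, hi = 0, len(cum)
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] > r:
            hi = mid
        else:
            lo = mid + 1
    return lo


def _noise_cum(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=np.float64) ** _NEG_POWER
    cum = np.cumsum(p)
    return cum / cum[-1]


def negative_sample(
    frequency_table: Mapping[str, int], M: int, exclude: str, rng: PCG32
) -> list[str]:
    """Draw M negatives from unigram^0.75, resampling on hitting *exclude*."""
    vocab = sorted(frequency_table)
    if vocab == [exclude]:
        raise ValueError("vocabulary contains only the excluded vertex")
    cum = _noise_cum([frequency_table[v] for v in vocab])
    out = []
    while len(out) < M:
        idx = _bisect_right(cum, rng.random())
        if vocab[idx] != exclude:
            out.append(vocab[idx])
    return out


def _sigmoid(x: float) -> float:
    if x >= _SIGMOID_CLIP:
        return 1.0
    if x <= -_SIGMOID_CLIP:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class PairLoss:
    """Loss and exact gradients for one (center, context, negatives) instance."""

    loss: float
    grad_phi: dict[str, np.ndarray] = field(default_factory=dict)
    grad_psi: dict[str, np.ndarray] = field(default_factory=dict)


def pair_loss_and_gradients(
    model: EmbeddingModel, center: str, context: str, negatives: Sequence[str]
) -> PairLoss:
    """Negative-sampling loss O and its analytic gradients.

    O = −log σ(Ψ(ctx)·Φ(c)) − Σ_m log σ(−Ψ(neg_m)·Φ(c)). Gradients for a
    negative sampled more than once are summed.
    """
    for vid in (center, context, *negatives):
        if vid not in model:
            raise KeyError(f"unknown vertex {vid!r}")
    phi_c = model.phi_of(center)
    psi_ctx = model.psi_of(context)
    sp = float(psi_ctx @ phi_c)
    # -log sigmoid(x) = log(1 + exp(-x)), computed stably
    loss = float(np.logaddexp(0.0, -sp))
    a_pos = _sigmoid(sp) - 1.0
    grad_phi = a_pos * psi_ctx.copy()
    grad_psi: dict[str, np.ndarray] = {context: a_pos * phi_c.copy()}
    for neg in negatives:
        psi_n = model.psi_of(neg)
        sn = float(psi_n @ phi_c)
        loss += float(np.logaddexp(0.0, sn))
        a_n = _sigmoid(sn)
        grad_phi += a_n * psi_n
        g = a_n * phi_c
        if neg in grad_psi:
            grad_psi[neg] = grad_psi[neg] + g
        else:
            grad_psi[neg] = g.copy()
    return PairLoss(loss, {center: grad_phi}, grad_psi)


def sgd_step(model: EmbeddingModel, pair: PairLoss, alpha: float) -> EmbeddingModel:
    """In-place SGD update v ← v − α ∂O/∂v on every touched row."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    for vid, g in pair.grad_phi.items():
        model.phi[model.index[vid]] -= alpha * g
    for vid, g in pair.grad_psi.items():
        model.psi[model.index[vid]] -= alpha * g
    return model


def softmax_probability(model: EmbeddingModel, center: str, target: str) -> float:
    """Full-softmax Pr(target | Φ(center)); diagnostic oracle, not used in training."""
    if center not in model or target not in model:
        raise KeyError("unknown vertex id")
    scores = model.psi @ model.phi_of(center)
    scores -= scores.max()  # stability shift
    ex = np.exp(scores)
    return float(ex[model.index[target]] / ex.sum())


# ---------------------------------------------------------------------------
# training


def _encode_corpus(corpus: WalkCorpus) -> tuple[list[str], np.ndarray, np.ndarray]:
    vocab = corpus.vocabulary()
    index = {v: i for i, v in enumerate(vocab)}
    tokens = np.empty(sum(len(w) for w in corpus.walks), dtype=np.int32)
    offsets = np.empty(len(corpus.walks) + 1, dtype=np.int64)
    offsets[0] = 0
    pos = 0
    for wi, w in enumerate(corpus.walks):
        for v in w:
            tokens[pos] = index[v]
            pos += 1
        offsets[wi + 1] = pos
    return vocab, tokens, offsets


@njit(cache=True)
def _train_kernel(
    tokens, offsets, phi, psi, k, M, noise_cum, type_lo, type_hi,
    alpha_init, alpha_final, epochs, total_pairs, state
):  # pragma: no cover - exercised via train()
    d = phi.shape[1]
    gphi = np.empty(d)
    negs = np.empty(M, dtype=np.int64)
    coef = np.empty(M)
    t = 0
    denom = total_pairs - 1 if total_pairs > 1 else 1
    for _ in range(epochs):
        for wi in range(len(offsets) - 1):
            s = offsets[wi]
            L = offsets[wi + 1] - s
            for i in range(L):
                c = tokens[s + i]
                jlo = i - k if i - k > 0 else 0
                jhi = i + k + 1 if i + k + 1 < L else L
                for j in range(jlo, jhi):
                    if j == i:
                        continue
                    ctx = tokens[s + j]
                    alpha = alpha_init + (alpha_final - alpha_init) * (t / denom)
                    t += 1
                    # sample M negatives from unigram^0.75, excluding ctx;
                    # in same-type mode the cumulative table spans only the
                    # context's type slice [type_lo, type_hi)
                    lo = type_lo[ctx]
                    hi = type_hi[ctx]
                    off = noise_cum[lo - 1] if lo > 0 else 0.0
                    scale = noise_cum[hi - 1] - off
                    for m in range(M):
                        while True:
                            r = off + pcg32_random(state) * scale
                            a, b = lo, hi
                            while a < b:
                                mid = (a + b) // 2
                                if noise_cum[mid] > r:
                                    b = mid
                                else:
                                    a = mid + 1
                            if a >= hi:
                                a = hi - 1
                            if a != ctx:
                                negs[m] = a
                                break
                    # read phase: scores and phi-gradient at pre-update values
                    sp = 0.0
                    for dd in range(d):
                        sp += psi[ctx, dd] * phi[c, dd]
                    if sp >= 40.0:
                        a_pos = 0.0
                    elif sp <= -40.0:
                        a_pos = -1.0
                    else:
                        a_pos = 1.0 / (1.0 + np.exp(-sp)) - 1.0
                    for dd in range(d):
                        gphi[dd] = a_pos * psi[ctx, dd]
                    for m in range(M):
                        n_idx = negs[m]
                        sn = 0.0
                        for dd in range(d):
                            sn += psi[n_idx, dd] * phi[c, dd]
                        if sn >= 40.0:
                            a_n = 1.0
                        elif sn <= -40.0:
                            a_n = 0.0
                        else:
                            a_n = 1.0 / (1.0 + np.exp(-sn))
                        coef[m] = a_n
                        for dd in range(d):
                            gphi[dd] += a_n * psi[n_idx, dd]
                    # write phase
                    for dd in range(d):
                        psi[ctx, dd] -= alpha * a_pos * phi[c, dd]
                    for m in range(M):
                        n_idx = negs[m]
                        for dd in range(d):
                            psi[n_idx, dd] -= alpha * coef[m] * phi[c, dd]
                    for dd in range(d):
                        phi[c, dd] -= alpha * gphi[dd]
    return t


def _type_slices(
    vocab: list[str], same_type: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex noise-table slice; whole vocabulary unless type-restricted."""
    V = len(vocab)
    n_genes = sum(1 for v in vocab if v.startswith(GENE_PREFIX))
    lo = np.zeros(V, dtype=np.int64)
    hi = np.full(V, V, dtype=np.int64)
    if same_type:
        for i in range(V):
            if i < n_genes:
                lo[i], hi[i] = 0, n_genes
            else:
                lo[i], hi[i] = n_genes, V
    return lo, hi


def train(
    corpus: WalkCorpus, config: TrainConfig, fast: bool = True
) -> EmbeddingModel:
    """Train an embedding model on a walk corpus.

    Single-threaded, deterministic pass(es) over all context pairs in corpus
    order; the vocabulary is exactly the set of vertices occurring in the
    corpus. The jitted and reference paths consume the same PCG32 stream.
    """
    if not corpus.walks:
        raise ValueError("empty corpus")
    vocab, tokens, offsets = _encode_corpus(corpus)
    total_pairs = config.epochs * sum(
        _pair_count(len(w), config.window) for w in corpus.walks
    )
    if total_pairs < 1:
        raise ValueError("corpus yields no context pairs")
    if config.negatives > 0:
        if len(vocab) < 2:
            raise ValueError("need at least two vertices to sample negatives")
        if config.same_type_negatives:
            n_genes = sum(1 for v in vocab if v.startswith(GENE_PREFIX))
            if 0 < n_genes < 2 or 0 < len(vocab) - n_genes < 2:
                raise ValueError(
                    "same-type negative sampling needs >= 2 vertices per type"
                )
    model = init_model(vocab, config.dimension, config.seed)
    counts = np.array([corpus.counts[v] for v in vocab], dtype=np.float64)
    noise_cum = np.cumsum(counts**_NEG_POWER)
    noise_cum /= noise_cum[-1]
    type_lo, type_hi = _type_slices(vocab, config.same_type_negatives)
    if fast and HAVE_NUMBA:
        state = pcg32_state(config.seed, STREAM_TRAIN)
        _train_kernel(
            tokens, offsets, model.phi, model.psi, config.window, config.negatives,
            noise_cum, type_lo, type_hi, config.alpha_init, config.alpha_final,
            config.epochs, total_pairs, state,
        )
        return model
    return _train_reference(
        model, tokens, offsets, noise_cum, type_lo, type_hi, config, total_pairs
    )


def _train_reference(
    model, tokens, offsets, noise_cum, type_lo, type_hi, config, total_pairs
):
    """Pure-Python trainer mirroring the kernel's arithmetic and RNG draws."""
    rng = PCG32(config.seed, STREAM_TRAIN)
    phi, psi = model.phi, model.psi
    d, k, M = config.dimension, config.window, config.negatives
    t = 0
    denom = total_pairs - 1 if total_pairs > 1 else 1
    for _ in range(config.epochs):
        for wi in range(len(offsets) - 1):
            s = int(offsets[wi])
            L = int(offsets[wi + 1]) - s
            for i in range(L):
                c = int(tokens[s + i])
                for j in range(max(0, i - k), min(L, i + k + 1)):
                    if j == i:
                        continue
                    ctx = int(tokens[s + j])
                    alpha = config.alpha_init + (
                        config.alpha_final - config.alpha_init
                    ) * (t / denom)
                    t += 1
                    lo, hi = int(type_lo[ctx]), int(type_hi[ctx])
                    off = float(noise_cum[lo - 1]) if lo > 0 else 0.0
                    scale = float(noise_cum[hi - 1]) - off
                    negs = []
                    while len(negs) < M:
                        r = off + rng.random() * scale
                        a = lo + _bisect_right(noise_cum[lo:hi], r)
                        if a >= hi:
                            a = hi - 1
                        if a != ctx:
                            negs.append(a)
                    sp = 0.0
                    for dd in range(d):
                        sp += psi[ctx, dd] * phi[c, dd]
                    a_pos = _sigmoid(sp) - 1.0
                    gphi = [a_pos * psi[ctx, dd] for dd in range(d)]
                    coefs = []
                    for n_idx in negs:
                        sn = 0.0
                        for dd in range(d):
                            sn += psi[n_idx, dd] * phi[c, dd]
                        a_n = _sigmoid(sn)
                        coefs.append(a_n)
                        for dd in range(d):
                            gphi[dd] += a_n * psi[n_idx, dd]
                    for dd in range(d):
                        psi[ctx, dd] -= alpha * a_pos * phi[c, dd]
                    for n_idx, a_n in zip(negs, coefs):
                        for dd in range(d):
                            psi[n_idx, dd] -= alpha * a_n * phi[c, dd]
                    for dd in range(d):
                        phi[c, dd] -= alpha * gphi[dd]
    return model


def mean_pair_loss(
    model: EmbeddingModel,
    eval_pairs: Sequence[tuple[str, str]],
    negatives: Sequence[Sequence[str]],
) -> float:
    """Mean negative-sampling loss over a frozen evaluation set."""
    total = 0.0
    for (c, ctx), negs in zip(eval_pairs, negatives):
        total += pair_loss_and_gradients(model, c, ctx, negs).loss
    return total / len(eval_pairs)
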