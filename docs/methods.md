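# Methods

## Problem and model

Known disease-causing genes are scarce; most phenotype entries in curated
catalogues have at most a handful of confirmed causative genes, while the
protein interaction neighbourhood of those genes is rich. The method
implemented here predicts new gene–phenotype associations by embedding a
heterogeneous **GP-network** — genes G and phenotypes P with three edge
relations: protein–protein interactions (g–g), thresholded phenotype
similarity (p–p), and known associations (g–p) — into a common d-dimensional
space, then ranking candidate genes for a phenotype by cosine similarity of
their vectors.

The embedding is produced by skip-gram with negative sampling over a corpus
of **multi-path constrained random walks**. The constraint is the defining
ingredient: in a walk v₁…v_l, no three consecutive vertices may share a
type. With two same-type vertices behind it the walker must switch type;
otherwise both types are eligible and the next vertex is drawn uniformly
from the union of eligible neighbours,

    Pr(v⁺ | prev, curr) = 1/|N_elig(curr)|   if (v⁺, curr) ∈ E and φ(v⁺) eligible,
                          0                  otherwise.

This lets one walk mix g–g, p–p and g–p relations (unlike a fixed
gene–phenotype–gene meta-path, which captures only co-association), while
still preventing the walk from drifting indefinitely inside one
single-type subnetwork. Two baselines share the sampler: a strict
alternating meta-path walk (`METAPATH_GPG`) and a type-blind uniform walk
(`UNIFORM`, DeepWalk-style).

### Skip-gram with negative sampling

Each vertex has a center vector Φ(v) (the embedding) and a context vector
Ψ(v). For every ordered pair (v_i, v_j) with |i−j| ≤ k inside a walk, the
per-pair loss is

    O_ij = −log σ(Ψ(v_j)·Φ(v_i)) − Σ_{m=1..M} log σ(−Ψ(v_jm)·Φ(v_i)),

minimized by per-pair SGD: Φ ← Φ − α ∂O/∂Φ, Ψ ← Ψ − α ∂O/∂Ψ. Negatives
v_jm are drawn from the corpus unigram distribution raised to the 3/4
power, resampling on collision with v_j. By default the noise distribution
spans the whole mixed-type vocabulary (the full-softmax form this
approximates normalizes over all vertices); a type-restricted mode
(negatives only from the context's own type, metapath2vec++-style) is
available via `TrainConfig(same_type_negatives=True)` because the
type-specific variant is an equally defensible reading — the two modes give
similar results on the planted benchmarks.

Within one pair update, all dot products are evaluated at the pre-update
parameter values and the writes are applied afterwards, so the update is
exactly one SGD step on the analytic gradient (a negative drawn twice
contributes its gradient twice).

### Scoring and evaluation

For a target phenotype p, every embedded gene g (except genes that still
hold a known association edge to p) is scored with cos(Φ(g), Φ(p)); Ψ is
never used for scoring. Ties break by ascending gene id and an all-zero
vector scores 0, making the ranking a total deterministic order.

Evaluation is leave-one-out over associations: each fold removes one g–p
edge, regenerates walks and retrains **from scratch** (a shared embedding
would leak the held-out edge through the walk corpus), then records the
held-out gene's rank among the candidates. Precision@K is the fraction of
folds whose gene ranks within the top K. Folds are stratified by the
phenotype's number of causative genes: SINGLE (exactly one) vs MANY. The
alternative stratification (genes with exactly one phenotype) is emitted in
the log for comparison but does not drive the report. Folds whose phenotype
or gene has no embedding count as misses rather than being skipped, so
precision is never inflated. A fold viewed as binary detection makes each
hit simultaneously a true positive and a true negative, so TP = TN and
FP = FN identically — the `confusion_counts` helper exposes this.

## Parameters

| parameter | default | meaning |
|---|---|---|
| similarity threshold | 0.6 | p–p edges kept when score **strictly** exceeds it |
| walks per vertex t | 500 | walks started from every vertex (both types) |
| walk length l | 100 | maximum walk length; dead ends terminate early |
| dimension d | 128 | embedding size |
| window k | 7 | skip-gram context half-width |
| negatives M | 5 | noise samples per pair |
| α init → final | 0.025 → 1e-4 | linear decay across all processed pairs (word-embedding convention; the learning rate is otherwise unspecified) |
| epochs | 1 | passes over the corpus |

Network filtering is a fixed five-step sequence: (1) drop self-loop edges
and proteins whose only interaction is a self-loop; (2) threshold phenotype
similarities (strict >); (3) drop associations with a missing endpoint; (4)
a single-pass distance-1 prune removing genes (phenotypes) with no
association and no neighbour holding one; (5) re-apply (3). The prune is
deliberately single-pass, not iterated to fixpoint: the filtering rules
describe direct links only, and a fixed order resolves the circular
dependency between pruning and association filtering deterministically.
The sequence is idempotent (property-tested). Phenotype edges are
unweighted after thresholding because the transition law is uniform over
neighbours — weights would never be read.

## Synthetic data

`synthdata` draws a planted-partition (stochastic block model) network: B
paired blocks of m genes and r phenotypes, within-block edge probabilities
p_gg_in/p_pp_in well above the between-block rates, each gene associated
with probability q to a uniform phenotype of its paired block and with
probability q_noise to a phenotype of another block. Defaults (B=5, m=10,
r=6, p_gg_in=0.3, p_gg_out=0.01, p_pp_in=0.4, p_pp_out=0.01, q=0.5,
q_noise=0.02) define the study conditions used by the acceptance suite.
The raw draws pass through the standard filter pipeline before assembly, so
written fixture files round-trip exactly through parse → filter → assemble.

What it does and does not emulate: block structure gives the embedding a
recoverable signal with a computable random baseline, but real PPI networks
are scale-free with hubs, phenotype similarity is a dense continuous matrix
rather than planted binary links, and real association counts per phenotype
are heavily skewed. Passing the recovery tests therefore demonstrates that
the pipeline recovers planted modular signal at small scale, not that it
reproduces performance numbers on curated human data.

## Numerical and design choices

- **Determinism.** All stochastic stages run on an explicit PCG32 stream
  (one generator per corpus / per training run, separate stream selectors
  for walks, initialization and training). Vertices are visited in
  ascending id order, and candidate sampling is cumulative-probability
  inversion over id-sorted candidates (`floor(r·n)` in the uniform case).
  Identical seeds give byte-identical corpus, embedding and report files.
  PCG32 is implemented twice — pure Python and inside the numba kernels —
  so the fast paths and the reference paths consume identical streams; the
  test suite asserts the two trainers and the two walk generators agree to
  the last bit/ulp.
- **Initialization.** Φ entries uniform strictly inside (−0.5/d, +0.5/d),
  Ψ zero — the standard stable word-embedding start.
- **Sigmoid clipping.** σ(x) is clamped for |x| ≥ 40, where 1/(1+e^(−x))
  is 0 or 1 to double precision anyway; losses use `logaddexp` for
  stability. The full-softmax diagnostic subtracts the max score before
  exponentiating.
- **Walk starts and dead ends.** Every vertex of both types seeds walks
  (the constraint only restricts triples, so the first step is free). A
  vertex with no eligible neighbour ends the walk; single-vertex walks are
  discarded because they yield no pairs.
- **Degenerate inputs.** Empty filtered outputs are legal; an empty network
  or corpus raises; an isolated phenotype in a fold is a MISS; a ranking
  for an unembedded phenotype is an error rather than an empty list.
- **Matrix dialect detection.** A similarity file whose first data row has
  exactly three columns is read as sparse triples; consequently a labelled
  2×2 matrix *with* a corner label is misread — real similarity matrices
  are far larger, and the matrix dialect is exercised with n ≥ 3 in tests.

## Problem sizes

The acceptance suite and `scripts/acceptance.py` run the recovery study at
reduced training cost — 50 walks of length 40 per vertex, d=32, k=5, M=5, 3
epochs, 5 generator seeds, both multi-path and uniform strategies, one
LOOCV fold per association (~25 per network) — which completes in a few
minutes on one core while leaving a wide margin over the ~0.2 random
baseline. The exhaustive transition-law check enumerates every connected
heterogeneous graph on ≤ 5 vertices (>100,000 (graph, history) cases).

## Known limitations

- The per-fold retraining protocol is O(|associations|) full pipelines; at
  the scale of curated human catalogues (hundreds of associations, 10⁴
  vertices, t=500, l=100, d=128) a LOOCV sweep is a batch-compute job, not
  an interactive run.
- Walk generation and training are single-threaded by design; determinism
  is the contract and any parallel mode would have to be explicitly
  non-deterministic.
- Two published baselines for this task (a path-count-feature bagging SVM
  and a label-propagation method) are out of scope: their printed
  descriptions are not self-contained enough to implement faithfully.
  The uniform-walk and meta-path baselines share the skip-gram core and are
  included.
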