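# Methods

## Model overview

The package treats miRNA–disease association prediction as transductive
bipartite link prediction. All information enters through similarity
kernels: three per entity axis, fused into one kernel per axis, on which a
closed-form kernel regression with a graph-smoothness penalty scores every
pair. The method's core assumption is the guilt-by-association principle:
miRNAs that are functionally, sequence-wise, or profile-wise similar tend to
associate with semantically, functionally, or profile-wise similar diseases.

## Similarity kernels

**Disease semantic kernel.** Each disease maps to one or more ontology terms
organised in a DAG (MeSH-style tree numbers are converted to parent links by
truncating the final dotted component). The contribution of an ancestor term
`t` to disease `d` is `D_d(t) = Δ^(shortest upward distance from d's terms)`,
implemented as the fixpoint of `D_d(t) = max over in-closure children t' of
Δ·D_d(t')` with `D_d = 1` on the disease's own terms. The pairwise kernel
sums contributions over shared ancestors and normalises by the two semantic
values `DV`. Δ defaults to 0.5 and is exposed as a parameter; larger Δ makes
distant ancestry count more.

**Disease functional kernel.** Gene–gene functional similarity is 1 for
identical genes, the min–max normalised log-likelihood score for network
edges, 0 otherwise. Min and max are taken over the whole network, so a
network whose edges all carry the same score has no usable contrast and is
rejected. A gene's similarity to a gene set is its best match; the disease
pair score averages best matches in both directions over the two gene sets.

**Hamming profile kernels.** One minus the normalised Hamming distance
between interaction profiles (columns of Y for diseases, rows for miRNAs),
with the full profile lengths `p` and `q` as denominators. These are the only
kernels that depend on Y, besides the MISIM kernel below.

**MISIM miRNA functional kernel.** Best-match average of disease semantic
similarities between the two miRNAs' associated disease sets, mirroring the
functional-kernel template. Because it reads Y, it is rebuilt inside
cross-validation folds (see below).

**Sequence kernel.** Global Needleman–Wunsch alignment with match +1,
mismatch −1, linear gap −1 (via Biopython's `PairwiseAligner`), normalised by
the larger of the two self-scores and clipped at zero. This choice of scoring
and normalisation guarantees a symmetric kernel in [0, 1] with unit diagonal;
the alignment itself fixes only relative order, and any affine rescaling of
the scoring would change values smoothly without changing the qualitative
structure.

**Missing-entity fallback.** Entities missing from an auxiliary source (no
ontology term, empty gene set, no sequence, or an empty disease set after
masking) keep their row: 1 on the diagonal, 0 elsewhere. This keeps every
kernel well defined without inventing similarity, at the cost of isolating
such entities in the fused graph.

## Kernel fusion

SKF column-normalises each kernel (`P_l`, zero columns fall back to unit
columns) and builds a k-nearest-neighbour sparsified, row-stochastic version
(`S_l`; the self index is always a neighbour, ties at the k-th rank break
toward the lower index for determinism). The update

    P_l(t+1) = α · S_l (mean of the other P_r(t)) S_l^T
               + (1−α) · (mean of the other P_r(0))

is run for T iterations with `S_l` and `P_l(0)` computed once from the
original kernels and never refreshed — the anchor term is what distinguishes
SKF from pure cross-diffusion and bounds the iterates, giving geometric
convergence at rate ~α. The per-kernel relative error
`E_t = ‖P(t+1)−P(t)‖_F / ‖P(t)‖_F` is recorded every iteration; at α = 0.1
and T = 10 the final error is far below 1e−5 (the α = 0 limit reproduces the
plain mean of the normalised kernels exactly, a useful algebraic check).

The fused kernel (mean of the final iterates) is multiplied element-wise by
a weight matrix computed from the fused kernel's own k-NN neighbourhoods:
1 for mutual neighbours, 0.5 when only one direction holds, 0 when neither.
Because column normalisation breaks symmetry, the weighted kernel is
symmetrised as `(K* + K*ᵀ)/2` before the Laplacian is formed; this is the
minimal repair that leaves mutual-neighbour values untouched.

Two comparators are included. AVG is the element-wise mean. SNF follows the
classical similarity-network-fusion construction: the same k-NN operator,
but a diagonal-reinforced normalisation (1/2 on the diagonal, off-diagonal
mass row-normalised to 1/2, symmetrised) re-applied after every
cross-diffusion step. Without that diagonal reinforcement pure
cross-diffusion converges toward a near rank-one consensus and loses the
signal, which is why the package uses the classical normalisation for the
comparator rather than re-using the SKF column normalisation.

Fusion is defined for exactly three kernels per axis (the cross-kernel mean
divides by 2); an `allow_two` flag generalises to other counts by averaging
over the remaining kernels.

## LapRLS

With `D` the diagonal of row sums of the fused kernel and
`L = D^(−1/2)(D−K*)D^(−1/2)` (zero-degree rows get zero Laplacian rows), the
miRNA-subspace solution is `F_m = K*(K* + β L K*)^{-1} Y`, computed by a
linear solve, never an explicit inverse; a singular system receives 1e−12
ridge jitter with a warning (this only arises for degenerate inputs such as
duplicated rows in noiseless toys). The disease subspace solves the same
system against `Yᵀ`, and the final score matrix is the element-wise mean
`F* = (F_m + F_dᵀ)/2`. β = 0 reproduces Y exactly for a well-conditioned
kernel; growing β shrinks scores toward graph-smooth functions. β is kept
equal in both subspaces by default.

Default parameters: α = 0.1, T = 10, k = 36, β = 2⁻⁵; the local leave-one-out
protocol defaults to k = 192 and β = 2⁻¹, reflecting that a disease with all
its associations removed needs information from a wider similarity
neighbourhood. k is clamped to the axis size when the graph is smaller than
the neighbourhood. Which β best suits global leave-one-out is genuinely
open; the package mirrors the k-fold choice since the two protocols mask
comparable fractions of the data.

## Cross-validation protocols

* **Global LOOCV** masks each known pair in turn and ranks it against all
  pairs unknown in the masked matrix.
* **Local LOOCV** masks one disease's whole column and ranks all miRNAs for
  it; AUC/AUPR are computed per disease and averaged (diseases with no
  positives, or with every miRNA positive, are skipped). Averaging rather
  than pooling was chosen so that every disease counts equally regardless of
  its degree.
* **k-fold** partitions the known pairs uniformly at random by seed
  (unstratified) and scores each fold's held-out positives against all
  never-known pairs.

Pooled metrics concatenate each fold's positive and negative scores and
evaluate a single ranking; per-fold and per-disease values are reported
alongside. AUC is the Mann–Whitney statistic (ties count one half), AUPR is
step-wise average precision, both via scikit-learn.

All protocols operate on copies: the input dataset is bit-identical after a
run. The Y-derived kernels (both Hamming kernels and MISIM) are rebuilt from
the masked matrix inside every fold by default, so a masked positive cannot
leak through the similarity structure; a `fast` mode rebuilds only the cheap
Hamming kernels and reuses the full-data MISIM kernel, trading a small,
documented leak for speed at leave-one-out granularity.

## Synthetic benchmark

The generator emulates the five input files with a shared planted block
structure: entities are assigned to `n_blocks` blocks round-robin;
associations are Bernoulli(`d_in`) within blocks and Bernoulli(`d_out`)
across (any entity left without an association receives one inside its block
so the association file defines the full universe); the ontology nests each
disease inside its block's subtree; genes form per-block cliques with high
log-likelihood scores plus sparse weak cross edges, and disease gene sets
draw from the block clique; sequences mutate from a per-block length-22
ancestor at rate `mut_rate`. One seeded generator stream makes regeneration
byte-identical.

Because associations within a block are i.i.d., the block identity is the
only pair-level signal, and the best achievable ranking is that of an oracle
that knows the block labels: with within fraction `w = 1/n_blocks`,
`a = w·d_in / (w·d_in + (1−w)·d_out)` of positives and
`b = w(1−d_in) / (w(1−d_in) + (1−w)(1−d_out))` of negatives inside blocks,
the oracle AUC is `a(1−b) + (ab + (1−a)(1−b))/2`. The defaults (p = 60,
q = 40, 3 blocks, d_in = 0.7, d_out = 0.02, mut_rate = 0.1) put this ceiling
near 0.91, and the full pipeline lands within about 0.01 of it, so the
planted signal is recovered essentially completely while the full
leave-one-out suite runs in seconds.

What the benchmark does **not** emulate: the heavy-tailed degree
distribution of curated catalogues, correlated (non-i.i.d.) associations
within a block, diseases annotated in multiple ontology subtrees, gene
networks with hubs, or sequence families with indels (point mutations only).
Passing tests therefore demonstrate correctness of the machinery and
recovery of homogeneous block structure, not performance on real curated
data.

## Numerical conventions

* Canonical entity order: lexicographic sort of identifiers from the
  association file; all matrices and kernels share it.
* Zero columns in normalisation become unit columns; zero-mass k-NN rows
  become unit rows; neighbour ties break toward lower index.
* Kernel TSVs are written at 17 significant digits and parsed with
  round-trip float precision, so write/read is exact.
* Everything is deterministic given the input files and seeds; the only
  randomness is in the synthetic generator and the k-fold partition.

## Known limitations

* All-pairs Needleman–Wunsch is quadratic in the number of miRNAs with
  length-squared alignment cost; fine at hundreds of sequences, slow at tens
  of thousands.
* Full per-fold MISIM recomputation at leave-one-out granularity is the
  dominant evaluation cost; `fast` mode exists for exploration.
* The fused kernel is not guaranteed positive semi-definite (the weight
  matrix is an element-wise product followed by symmetrisation); LapRLS only
  needs the linear system to be solvable, and the ridge jitter covers the
  degenerate cases.
* Scores are relative rankings, not calibrated probabilities.
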