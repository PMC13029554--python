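# Methods

This note documents the modelling, protocol and numerical choices behind
`gnnma`, in the spirit of a model-description appendix: what is computed,
under which assumptions, which knobs matter, and what the synthetic
experiments do and do not demonstrate.

## Problem formulation

Ligand-based virtual screening is cast as pairwise scoring: for a target
with known actives, every library candidate is scored against query actives
and ranked by its best (default) or mean pair score.  Labels are
pair-level: (active, active) pairs within a target are positives,
(active, decoy) pairs negatives.  The operative quality measure is early
enrichment — how many actives land in the top 1–20% of the ranking — not
global classification accuracy.

## Molecular representation

Molecules are 2D heavy-atom graphs from SMILES (RDKit).  Multi-fragment
inputs keep the largest fragment; no other standardization, no 3D
conformers, no stereochemistry features.

Atom features (d_n = 20 with the default element vocabulary
{C, N, O, S, F, Cl, Br, I, P, other}): element one-hot;
Murcko-scaffold membership (scaffold atom vs. side chain; acyclic
molecules are all side chain); scaffold type (aromatic vs. aliphatic
scaffold atom); aromaticity; ring membership; and four pharmacophoric
flags.  The pharmacophore rules are deliberately simple Lipinski-style
SMARTS, documented in `gnnma.molgraph`:

* donor `[#7,#8;!H0]`, acceptor `[#7,#8]`,
  hydrophobic `[#6;!$([#6]~[!#6;!#1])]` (carbon with no heteroatom
  neighbour); the aromatic-ring flag duplicates the aromaticity bit so the
  pharmacophore block is self-contained.

Bond features (d_e = 7): bond-order one-hot {single, double, triple,
aromatic} plus aromatic, conjugated (RDKit perception) and in-ring flags.
The bond tensor is dense N×N×d_e; for drug-like sizes (N < 70) the memory
cost is trivial and the dense layout keeps masking simple.  Unknown
elements map to a reserved "other" slot rather than failing, so screening
files with exotic atoms degrade gracefully.

## Architecture choices

Defaults: hidden dim 64, 3 message-passing layers, mean pooling, head MLP
[128, 64] with dropout 0.2 (train-time only, in the head).

Where the general design left detail open, the package's choices are:

* ψ is a one-hidden-layer ReLU MLP on [v_i ‖ v_j ‖ e_ij]; φ is linear on
  [v_i ‖ m_i].  The residual update is **post-normalized**:
  v ← LayerNorm(v + φ(·)).  Normalizing the sum (rather than only the
  update) keeps node-embedding norms bounded across layers; with unbounded
  norms the downstream attention softmax saturates to near-one-hot weights
  at initialization and the alignment module receives no gradient.
* Cross-attention is applied once, after the final message-passing layer
  (sequential stages, not interleaved).  Each direction (query→candidate,
  candidate→query) has its own projection pair, at both atom and bond
  level.
* Bond tokens: each undirected bond appears once; its embedding is a
  symmetrized fused-edge vector, the average of the fusion MLP applied to
  (i, j) and (j, i) orderings, so ê_ij = ê_ji by construction.  The
  bond-level cross context feeds into the second-stage edge fusion rather
  than a separate pooled term.
* Edge-to-node aggregation is per-atom: v_i^{(e→v)} = η(g_i) with
  g_i the sum of incident fused edges.  (A graph-level sum would be
  dimensionally incompatible with the per-atom residual combination.)
  η's output is layer-normalized so the three residual terms entering
  pooling — intra embeddings, cross context, bond aggregation — share the
  same scale; without this the non-negative bond term dominates the pooled
  representation and measurably hurts the full model.
* Pooling is a masked mean by default (robust to molecule size); sum
  pooling is available via config.
* The score S is an unbounded logit; the sigmoid lives in the loss.

The intra-only ablation (`use_cross_attention=False`) removes both
attention stages; molecules are embedded independently and only the joint
MLP head sees the pair.  Its candidate embedding is provably independent of
the query (asserted in tests).

## Splitting, pairing, batching

Per target, molecules are split train/val/test at ratio 8:1:1 at the
molecule level, independently per class (actives, decoys), deterministic
given (target id, seed) and independent of listing order.  Validation and
test receive floor(n/10) molecules per class, remainder to train, with two
small-class guards: a class with ≥ 5 molecules places at least 2 in test,
and with ≥ 10 at least 2 in validation.  The test guard exists because the
within-test pairwise protocol excludes self-pairs: a lone test active has
no same-subset query, leaving its candidate score — and hence per-target
AUC/EF — undefined.  The validation guard keeps checkpoint selection
operative.  Targets with fewer than 3 actives are flagged unusable for
pair evaluation.

Pairs never cross subsets or targets.  Positives are unordered pairs of
distinct same-subset actives, emitted in fixed (query, candidate) role
order; negatives pair a same-subset active with a same-subset decoy,
subsampled at 3:1 negatives:positives for training.  Validation pairs use
*all* available negatives — subsampling is a training budget, and model
selection wants a low-variance AUC.  Mini-batches (size 32) are always
single-target, a precondition of the within-batch hard-negative ranking
term.

## Objective and optimization

L = L_BCE + λ·L_rank.  L_BCE is mean sigmoid cross-entropy over all batch
pairs (computed in the stable softplus form).  L_rank selects the
K = 10 highest-scoring negatives of the batch (by current score, stable
sort) and averages the margin hinge max(0, 1 − s_pos + s_neg) over all
(positive, hard-negative) combinations; a logistic surrogate is available
via config.  The hinge depends on scores only through differences
s_pos − s_neg (shift-invariant).  Batches lacking either class contribute
zero and are counted.  λ = 0 for epochs 1–2, 0.05 afterwards.

Adam, learning rate 1e-3, weight decay 1e-4, gradient clipping at global
norm 5.0, 20 epochs.  The checkpoint with the best validation pair ROC-AUC
is kept (earliest epoch on ties).  All randomness — initialization,
negative sampling, batch shuffling, dropout — derives from a single seed;
two runs with the same seed are bit-identical.  A non-finite loss aborts
with the offending target, epoch and batch scores in the message.

The network runs on `gnnma.autodiff`, a small reverse-mode automatic
differentiation core over NumPy (broadcast-aware arithmetic, batched
matmul, reductions, masked softmax, gather/scatter for edge-list message
passing).  Every operation is checked against central finite differences,
gather/scatter against the adjoint identity, and the full batched forward
against an explicit loop-over-atoms oracle (agreement ~1e-15).

## Metrics and statistics

Candidate score = max (default; mean available) over test-active queries,
self-pairs excluded.  ROC-AUC uses the rank-based estimator with 0.5 tie
credit (scikit-learn; the test oracle counts active–inactive pairs
exhaustively).  EF@k% uses cutoff n = max(1, round_half_up(k/100·N)) and
stable tie-breaking by (−score, mol_id); EF is tie-sensitive at small n,
which is why the rule is pinned.  EF@100% ≡ 1 and EF@k ≤ N/A are asserted
as invariants.

Aggregation views: pooled (scores concatenated across targets; pooled EF
sums per-target a_k and n_k before the ratio), macro (equal-weight mean),
weighted macro (weights = per-target molecule counts), macro-target
(distribution summaries).  Pooled values mix uncalibrated score scales
across targets and can diverge from macro views; reports carry that
caveat.  Paired comparisons use per-target deltas Δ_t: percentile
bootstrap over targets (B = 20,000, 95% CI, seeded) and a two-sided
Wilcoxon signed-rank test on nonzero deltas (wins Δ>0, losses Δ<0, ties
Δ=0; all-zero deltas report p = NA).

## Synthetic libraries

The generator emulates the *shape* of target-organized screening
benchmarks.  Each target owns a scaffold from a pool of eight
pairwise-non-contained templates (benzene, pyridine, pyrimidine, pyrrole,
furan, thiophene, piperidine, morpholine) with 2–3 attachment sites;
actives attach 1–3 random decorations from a 12-fragment pool; decoys are
decorated molecules on the other scaffolds, rejected if they contain the
target scaffold.  Assembly zips dummy-labelled attachment points, so every
SMILES is valid by construction; molecules are unique within a target;
optional label noise flips labels at a configurable rate (default 0).
Default study conditions: 3 targets × (15 actives + 150 decoys), giving
per-target test sets of 2 actives + 15 decoys.

What this does *not* emulate: property-matched decoys (the defining
difficulty of curated benchmarks), assay noise, activity cliffs, or
chemotype diversity within a target's actives.  The scaffold signal is
clean and fully recoverable from a single molecule — by design the task
validates the machinery (featurization, training, protocol, metrics), not
real-world screening difficulty.  A direct consequence, measured by the
acceptance experiment: the intra-only ablation solves the default task at
or near the EF ceiling, and the full model's cross-graph terms — whose
value lies in relational matching that per-molecule embeddings cannot
express — offer no advantage there and can cost a little test-set EF at
this sample size (2 test actives per target).  Passing synthetic tests
therefore demonstrates correctness of the implementation and protocol, not
superiority of cross-graph attention on real benchmarks.

The ECFP4 baseline (Morgan radius 2, 2048 bits, max Tanimoto to test
actives) runs through the identical split and metric pipeline and
enriches strongly on zero-noise libraries, confirming the scaffold signal
is fingerprint-recoverable.

## Throughput benchmark

`gnnma bench` times pair scoring in two scopes — forward-only (model
compute ceiling) and end-to-end (disk-to-score, including SMILES reading
and graph construction) — with online or cached compound preparation.  The
cache flat-packs each featurized graph into a single `.npy` record keyed
by canonical SMILES + schema hash and memoizes loads in process memory, so
a molecule appearing in many pairs touches disk once.  The first 10
batches are warm-up and excluded.  Reports: pairs/s, ms/pair = 1000/(pairs/s),
and extrapolations T(N) = N/throughput for N = 1e5, 1e6.  Only CPU
execution is supported; requesting another device falls back with a
notice.  Absolute numbers are hardware-dependent; only the internal
identities and qualitative orderings (forward-only ≥ end-to-end; cached ≥
online) are meaningful.

## Reported experiment sizes

The acceptance script and the learnability tests run the default study
conditions (3 targets × 165 molecules, 3 seeds, 20 epochs, full model and
ablation) — about 3 minutes on one CPU core.  Unit and property tests use
smaller libraries (2–5 targets, 8–12 actives) and low-dimensional scorers
(hidden 8–16) where exact numeric oracles are compared.

## Known limitations

* 2D topology only; no stereochemistry, tautomers, or 3D geometry.
* The evaluation protocol scores candidates only against *test-subset*
  actives; with very few test actives the per-target metrics are coarse
  (AUC granularity 1/30 at 2 actives × 15 decoys).
* Dense edge tensors and the Python-level autodiff graph are sized for
  drug-like molecules and desk-scale experiments, not for screening
  millions of pairs; the benchmark harness quantifies exactly what a
  deployment would pay.
* The synthetic generator's clean scaffold signal makes per-molecule
  classification sufficient; conclusions about the relative merit of
  cross-graph attention require property-matched real benchmarks.
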