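# Methods

This note documents the models and procedures implemented in `perturbcast`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The prediction model

The core predictor maps a (drug, cell, dose) triple to the differential
expression of a fixed gene panel (978 landmark genes at full scale; smaller
panels at desk scale) and, through separate heads, to binary up/down gene
calls and a scalar cell viability. Four input components are fused:

1. **Chemical graph fingerprint.** A SMILES string is parsed (RDKit) into a
   heavy-atom graph with per-atom features (element one-hot over
   {C,N,O,S,F,Cl,Br,I,P,other}, degree one-hot to 5, aromaticity flag,
   formal charge; featurization id `element10-degree6-aromatic-charge-v1`).
   Each graph-convolution layer computes `act(D⁻¹(A+I) Hˡ Wˡ)` where `A` is
   the adjacency, `I` adds self-loops and `D` is the degree matrix of
   `A+I`. The default activation is a row-wise softmax over the feature
   axis, which keeps each atom embedding on the probability simplex; a
   conventional ReLU is available (`activation="relu"`). The molecule
   fingerprint is the atom-sum (config: mean/max), and the per-atom
   embeddings are retained as attention keys/values.
2. **Drug–gene attention.** Each panel gene's embedding vector (consumed as
   a precomputed table; random near-orthogonal vectors in synthetic runs,
   with a pluggable interface for network-walk embeddings) queries the atom
   embeddings with scaled dot-product attention, giving a per-gene context
   matrix. Its gene-average joins the fused vector; the full matrix feeds
   the per-gene output layer.
3. **Cell embedding.** The basal expression profile is encoded by an
   attention autoencoder: per-gene tokens (scalar expression × learned
   per-gene identity vector, no positional encoding), Gaussian noise (σ =
   0.1 on standardized inputs) and dropout (0.1) applied only during
   training, one transformer block (4 heads, model dim 32, feed-forward
   64), max-pool over genes, and a linear projection plus a linear skip
   path from the standardized profile. The embedding is L2-normalized to
   radius √d. The normalization replaces a squashing nonlinearity: bounded
   scale keeps the downstream fusion stable while the encoder is
   co-trained, and, unlike tanh, cannot saturate to indistinguishable
   sign patterns (observed as a total loss of context sensitivity in early
   experiments). Inputs are standardized per gene against the autoencoder
   corpus. The decoder (fully connected, one hidden layer) reconstructs the
   standardized profile; the reconstruction loss is mean squared error.
4. **Dosage embedding.** Doses form a finite vocabulary (one-hot), looked
   up in a learned embedding matrix. Exact match is required by default; a
   log-nearest mode serves curve sweeps over the grid.

**Fusion and heads.** The concatenation [fingerprint ‖ attention mean ‖
cell embedding ‖ dose embedding ‖ bilinear term] passes through one tanh
layer (width 64). The bilinear term is a factorized product of a drug-side
and a cell-side projection (32 dims); it makes drug-by-cell interactions
directly representable at first order instead of relying on deep mixing —
without it the context signal trains far too slowly at desk scale.
Expression heads end in a per-gene output layer (hidden → G) plus a
per-gene readout of the attention context; the binary classifier applies
the logistic function to its per-gene scores (so P(up) + P(down) = 1 by
construction) and trains with cross-entropy against top/bottom-5% labels
(`n_pos = floor(0.05·G)`, stable tie-break by panel order); viability uses
a two-layer scalar head trained with MSE.

All numerics run on a compact reverse-mode autodiff core (`_autodiff.py`,
float64 numpy, Adam) — deliberately dependency-free and verified against
finite differences in the test suite.

## Training procedures

Both procedures share the encoder E between the autoencoder (E, D) and the
supervised components S:

- **Pretrain/fine-tune**: `epoch_max` epochs of autoencoder training, then
  `epoch_max` supervised epochs updating (E, S) from the pretrained E.
- **Joint**: each epoch runs one full autoencoder pass (E, D) then one full
  supervised pass (E, S). Alternation granularity is per-epoch.

Optimizer: Adam, lr 1e-3 default (3e-3 in the benchmarks), separate moment
state per phase. Supervised samples are grouped by (drug, cell) so the
fingerprint, attention and cell embedding are computed once per group; one
optimizer step per group. Optional early stopping snapshots the best
dev-set Pearson; the dev split is cluster-respecting (≈10% of training
clusters).

**Teacher–student augmentation.** A teacher trained on the high-reliability
pool predicts every low-reliability record; records whose prediction
correlates with their experimental consensus above a similarity gate are
added with the *prediction* as pseudo label (never the noisy measurement);
a student retrains on the union and becomes the next teacher, iterated 4
times by default. Keys are unique: re-selected records replace their pseudo
label with the newer prediction. Every student shares the same
initialization and schedule, so iterations differ only by the growing
dataset — with freshly re-initialized students, initialization noise
swamped the augmentation effect at desk scale. The gate defaults to 0.7
(mirroring the reliability cutoff) at full scale; the benchmark uses 0.3
because the attainable prediction-vs-corrupted-consensus correlation
shrinks with panel size and noise at desk scale, so the gate is scaled down
with the problem, as the permutation count is.

## Replicate reliability

Replicates of one (drug, cell, dose, time) condition are scored by the mean
Pearson correlation over unordered pairs; sets strictly above 0.7 are
high-quality (training labels = replicate mean), the rest feed only the
augmentation loop. Single-replicate sets cannot attest quality and are
routed low. Pearson is computed by the centered-sum formula, which is exact
for the integer fixtures used to probe the strict boundary. Constant
replicate vectors raise instead of returning 0 — silent zeros would mask
degenerate fixtures.

## Dose–response harmonization

Viability follows `E(C) = E0 + (Einf − E0)/(1 + (EC50/C)^H)`. Fitting is
nonlinear least squares on log10-dose with multi-start over H ∈ {0.5, 1, 2},
E0/Einf seeded from the observed extremes, EC50 from the dose nearest the
half-response, bounds EC50 ∈ [min_dose/100, max_dose·100] and H ∈ [0.1, 10].
Non-convergence or EC50 at a bound marks the series unfittable and it is
dropped. Harmonization re-evaluates each fitted curve on a common log grid;
curves whose range over the grid is < 0.01 (config) contribute only the
extreme-dose points. The toxicity filter declares a drug safe iff viability
at 1 µM is strictly greater than 0.9.

## Evaluation protocol

Cells are clustered by affinity propagation on standardized basal profiles
(damping 0.9, median-similarity preference); whole clusters are assigned to
k = 3 folds greedily (largest cluster into the smallest fold, seeded
tie-breaks), so test cells are dissimilar from all training cells. One role
map per round governs both the supervised task and the autoencoder corpus,
making the two partitions aligned by construction. Drug-centric tasks use
an analogous drugs-stay-together splitter. Metrics: per-sample
Pearson/Spearman (averaged), per-drug/per-cell group averages, precision@K
for the top-K up/down genes (stable tie-break), macro/micro ROC-AUC and
PR-AUC.

## Screening statistic and significance

For a ranked drug profile L of m genes and query set G_q (n_q genes), the
running statistic at query gene i is
`D_q(i) = #{j∈L: g_j < g_i}/m − #{j∈G_q: g_j < g_i}/n_q`
(strict inequalities; ties contribute 0), and ES_q is the sup or inf over
i ∈ G_q, whichever has larger magnitude. The reverse-similarity score is
`S = −(ES_up + ES_down)` when the two scores have opposite signs, else 0;
drugs are ranked by ascending permutation p-value, then descending S.

The permutation null histograms the statistic of random gene groups into
2,000 equal bins on [−1, 1] (100,000 permutations at full scale; 1,000–2,000
in the desk benchmarks). Two statistics are supported: the single-set
enrichment score (continuous; used for calibration work) and the
reverse-similarity of disjoint random pairs (carries a point mass at 0 from
same-sign pairs, hence conservative p-values whose ties the S tie-break
resolves; used for screening ranking). The histogram is smoothed by local
log-quadratic fits `exp(a + bx + cx²)` over 0.015-wide windows, fit only on
positive-count bins — the enrichment statistic lives on a value lattice
coarser than the bin width, so empty bins carry no information about the
local level, and including them (e.g. with a half-count floor) flattens the
density and mis-calibrates the tail integral. Windows with fewer than three
positive bins fall back to their mean level; all-empty windows smooth to
zero. The p-value of a score x is the renormalized density integrated from
x to 1 (partial first bin; floored at 1/(n_perms+1)).

Patient clustering encodes signatures as ±1/0 vectors and runs a flat-kernel
mean shift under Manhattan distance (hand-rolled; no installed
implementation offers an L1 metric), bandwidth defaulting to half the
median pairwise distance. Drug-set and target enrichment use the upper-tail
hypergeometric test.

## Synthetic worlds

`WorldSpec` defaults define the desk-scale study conditions: 150 genes, 40
cells in 8 latent clusters (centers ~ N(0, 2.5²·I) in a 6-dim latent space,
within-cluster σ = 0.5), 30 drugs from a packaged 100-molecule SMILES
library, dose grid {0.1, 0.5, 1, 5, 10} µM. Basal profiles are a linear
map of the cell latent plus N(0, 0.3²) noise on a log2-TPM-like offset.
Drug latent factors are normalized projections of molecular-graph
invariants (atom/bond/ring counts, element counts, mean degree), so the
chemical branch has real signal. Differential expression is
`s_d(dose) · (U a_d + V (a_d ⊙ b_c))` — a drug main effect plus a
drug-by-cell interaction — with a saturating dose factor
`s_d = dose^h/(dose^h + k^h)`; replicates add i.i.d. noise (σ = 0.3), and
a 25% fraction of conditions receives corruption noise (σ = 1.5) that
drives their average replicate correlation below 0.7. Viability curves are
Hill with asymptotes tied to the drug–cell latent compatibility. Patient
cohorts perturb cell profiles and build signatures from a planted library
drug: the up-set is that drug's most-suppressed genes (deep-negative
enrichment), the down-set is spread slightly above the uniform ranking
diagonal (mildly positive, sign-stable enrichment) — a partial reversal
whose score stands far above the null. A small factor jitter separates
isomer-like library molecules whose graph invariants coincide.

What the generator does **not** emulate: realistic transcriptomic
covariance beyond cluster + low-rank structure, chemical-series structure,
batch effects, or non-Gaussian measurement noise. Passing benchmarks
demonstrate the machinery recovers planted structure under these idealized
conditions, not performance on real perturbational atlases.

## Benchmark problem sizes

`perturbcast.benchmarks` fixes the experiment scales: 100 Hill curves
(8 points each); 1,000 random enrichment instances (m ≤ 50); 10,000
reverse-similarity pairs; a 2,000-permutation null with 300 fresh query
sets; a 60-cell/6-cluster split check; the default world with 20 cells per
drug × 3 doses sampled and 120 extra unlabeled autoencoder profiles, 20
epochs × 5 seeds for the context-dependence contrast; a 60-gene world, 10
epochs × 5 seeds × 2 augmentation iterations for the teacher-student trend;
20 screening replicates against 50-drug libraries with 1,000-permutation
nulls. `scripts/acceptance.py --seed N --out f.json` recomputes all of it.

## Known limitations

- The desk-scale transformer is one block; depth/width at full scale are
  config but untested here.
- Dose is categorical; continuous-dose interpolation is available only as
  the log-nearest lookup.
- The screening p-value under the reverse-similarity null is conservative
  (point mass at 0); calibrated p-values are available under the
  enrichment-score null.
- Viability and expression heads share the fused trunk; task interference
  at very small data sizes has not been characterized.
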