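# Methods

## Problem and data model

The classifier separates antioxidant from non-antioxidant proteins. Each
protein is represented by two precomputed profiles: an L×20 position-specific
scoring matrix (PSSM) from iterative profile search, whose entry (i, j) is
the log-odds score for residue i mutating to amino-acid type j, and a
3-state secondary-structure track (helix H, strand E, coil C) with an L×3
per-residue probability matrix. Sequences containing the ambiguous letters
B, X, Z, O, U or J are dropped outright during benchmark construction, not
repaired; there is no defensible imputation for them.

All 20-column matrices use the fixed alphabetical amino-acid order
ACDEFGHIKLMNPQRSTVWY internally; file column orders (e.g. the
ARNDCQEGHILKMFPSTWYV order the profile-search tool emits) are permuted on
read. The structure probability columns are ordered (C, H, E).

## Feature extraction (473 = 440 + 33)

**PSSM block (440).** The 20 column means of the score matrix, then 420
n-gram features of the consensus sequence. The consensus keeps, per row i,
the amino acid j maximizing 2^(score·BF_j); ties resolve to the earliest
amino acid alphabetically, making the map deterministic. BF defaults to the
Robinson–Robinson amino-acid background frequencies normalized to sum 1 and
is configurable (`background_frequencies`, 20 positive floats): any positive
vector preserves the structure of the method, and different choices change
which residue wins a row, so consensus sequences are only comparable across
runs using the same BF. The n-gram block is 20 monomer frequencies
O(P_i)/L weighted by 20/420 followed by 400 ordered adjacent-pair
frequencies O(P_i P_j)/L weighted by 400/420 (row-major, first residue =
row). The pair denominator is L, so raw pair frequencies sum to (L−1)/L
rather than 1; the weighting scheme is defined on that convention and we
keep it.

**Secondary-structure block (33).** Composition moment vectors
D_X = (Σ 1-based positions of state X)/(L(L−1)) for X ∈ {H, E, C} — 1-based
indexing makes a single-state sequence saturate its moment at exactly 1;
normalized maximum run lengths maxE/L and maxH/L; and a fold-architecture
motif count: collapse each maximal H run to α, each maximal E run to β,
delete C entirely, and count overlapping strand–helix–strand (βαβ)
occurrences in the fragment string, normalized by L−2. A switch
(`motif: aba`) counts helix–strand–helix instead, since either convention
appears in the composition-moment literature. The probability matrix
contributes its 3 column means globally and the column means of 8
contiguous row blocks (np.array_split semantics: earlier blocks absorb the
remainder, so block sizes differ by at most one row). Sequences shorter
than 8 residues are rejected — the 8-way partition is undefined and real
proteins are far longer. The size-weighted mean of the 8 local means equals
the global means exactly, which the tests exploit as an internal
consistency oracle.

## SMOTE rebalancing

Classic SMOTE with Euclidean nearest neighbours on the raw 473-dim
features: a synthetic minority point is x + u(x_nn − x) with u uniform on
[0, 1] and x_nn one of the M = 5 nearest minority neighbours of x (self
excluded). Parents are drawn uniformly **with replacement** so that
non-integer amplification factors (e.g. 253 → 1552) hit the target count
exactly. Original rows are preserved unchanged and first; majority rows are
never touched. Two orderings relative to cross-validation are first-class:

* `paper` — rebalance the full dataset once, then split. This matches the
  protocol under which a 253/1552 benchmark becomes 3104 samples before
  evaluation, but synthetic points interpolate between folds, so validation
  scores are optimistic.
* `fold-safe` (default) — rebalance each training fold only; validation
  folds contain only original samples. All headline numbers in this
  repository are produced in this mode.

## Variational feature compressor

The compressor optimizes the information-bottleneck trade-off
max M(C, P) − λ·M(R, P) between compressing the 473-dim input R and
preserving the label C in the latent code P, through the standard
variational bound: a diagonal-Gaussian encoder q(p|r) = N(E(r), diag D(r)²),
a standard-normal prior s(p), and a logistic classifier head t(c|p). The
per-batch training loss is

    mean_i [ −log t(c_i|z_i) ] + λ · mean_i KL(q(p|r_i) ‖ s(p)),
    z_i = E(r_i) + ε·D(r_i),  ε ~ N(0, I),

with the KL in closed form, ½ Σ_k (σ² + μ² − 1 − 2 log σ). Architecture:
inputs standardized with training-split statistics (stored in the model;
the Gaussian prior presumes commensurate scales), two rectified-linear
hidden layers (256, 64), a K-dim mean head, a K-dim scale head through
softplus plus a 1e-6 floor, K = 15. Training is hand-derived
backpropagation with Adam (lr 1e-3, batch 64, 200 epochs) plus decoupled
weight decay 1e-2 on the weight matrices; the decay enters the update only,
so the reported loss components remain the pure bound. Gradients are
verified against central finite differences in the test suite.

Parameter defaults that matter:

* **λ = 1e-2.** At 1e-3 the bottleneck pressure is too weak at desk-scale
  sample sizes: the encoder memorizes the training set, training
  cross-entropy collapses while held-out points land between the two tight
  latent clusters. 1e-2 keeps posterior scales large enough that the latent
  geometry generalizes. Larger values trade accuracy for compression;
  λ → ∞ collapses the posterior onto the prior (verified as a limiting-case
  test).
* **Weight decay = 1e-2.** The first layer has 473×256 weights; without
  decay it can separate small training sets using noise directions alone.
* **Transform output = posterior mean E(r)**, never a sample: downstream
  tree training needs stable features.

Because initialization and sampling are stochastic, repeated fits give
different latent feature sets. `select_compressor` trains `n_runs`
candidates (run r seeded seed + r), scores each by the Matthews correlation
of the downstream classifier on a stratified held-out split
(`val_fraction` 0.2), and keeps the best; ties go to the lowest run index.
The latent width is treated as fixed at 15; sweeping it is left to the
user via the config rather than automated.

## Classifier and evaluation

Tree boosting is delegated to xgboost with the logistic objective and the
γT + ½λ‖ω‖² regularizer (defaults: 300 trees, learning rate 0.1, depth 4,
γ = 0, λ = 1); predictions threshold the logistic output at 0.5, appropriate
for the post-SMOTE balanced classes. Row and column subsampling at 0.7
(stochastic gradient boosting) is on by default: when the latent classes
form well-separated clusters, deterministic boosting places every tree's
split at the same arbitrary point inside the wide empty margin, and points
falling mid-gap are classified by that accident; subsampling diversifies
the thresholds and the ensemble vote approximates a centered boundary.

Metrics: ACC, SN = TP/(TP+FN), SP = TN/(TN+FP),
MCC = (TN·TP − FN·FP)/√((TN+FP)(FN+TP)(TN+FN)(TP+FP)), F1 = 2TP/(2TP+FP+FN),
with positives = antioxidant. Any 0/0 denominator yields 0 with a warning
flag so fold averaging stays defined. Cross-validation uses stratified
near-equal folds with a seeded shuffle; the report carries per-fold metrics
and their arithmetic means.

## Synthetic data

The generator stands in for a real benchmark (curated positive/negative
sequence sets with externally computed profiles) and emulates both file
dialects exactly. Per record: length uniform on 30–80 residues; integer
PSSM scores from a rounded N(0, 2) base clipped to −10..12, with the
positive class shifted by `effect_size` on five fixed columns; structure
probabilities row-wise Dirichlet(3, 3, 3), the positive class's helix
concentration raised by `effect_size`; states are the argmax of each row;
the residue sequence is the PSSM consensus under uniform background. The
signal therefore lives in both modalities, so the compressor must integrate
them. At `effect_size = 0` the class-conditional distributions coincide and
downstream MCC is at chance. Default study conditions used by the
end-to-end tests: 60 positives / 140 negatives (n = 200), effect size 3,
three generator seeds, 5-fold fold-safe CV — sized to finish in minutes on
one CPU while leaving the recovery thresholds (mean ACC ≥ 0.90,
MCC ≥ 0.80; |MCC| ≤ 0.15 under the null) a comfortable margin.

What the generator does **not** emulate: homology between records, realistic
amino-acid covariance in PSSM columns, protein-length/feature correlations,
and the 20 %-identity redundancy screening of real benchmarks. Passing the
recovery tests shows the pipeline recovers a planted two-modality signal at
desk scale; it does not certify performance on real antioxidant data.

## Known limitations

* The benchmark numbers reported for the original antioxidant dataset
  (five-fold ACC ≈ 0.96, MCC ≈ 0.92 on 3104 balanced samples) require that
  external dataset plus profile-search and structure-prediction runs
  against large sequence databases; they are out of scope here and nothing
  in this repository claims to reproduce them.
* Information retention holds for signals *embedded* across many
  coordinates (a low-rank factor model): with 1000 training samples the
  latent-15 classifier tracks the full-473 classifier within 0.05 MCC.
  For an axis-aligned needle (a few shifted columns among hundreds) at a
  few hundred samples, greedy tree splits find the needle while the dense
  encoder memorizes noise directions instead — a small-sample estimation
  effect inherent to dense encoders, not a property of the bound.
* The exact consensus sequences depend on the BF vector; published
  consensus-based feature values are reproducible only with the original
  (unpublished) background table.
* SMOTE's random draws make exact replication of any particular balanced
  dataset impossible without the original seed and neighbour count.
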