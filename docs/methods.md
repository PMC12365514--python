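# Methods

## Model overview

`ptmfusion` couples two graph convolutional models.

**Stage 1 — PTM potentiality scoring (LAGCN).** The inputs are a binary
protein×disease association matrix *A*, protein sequences, and nothing
else. Protein similarity is the elementwise sum (weights α₁ = α₂ = 1) of

* normalized best local-alignment scores (Smith–Waterman with affine
  gaps; match 2, mismatch −1, gap open −0.5, gap extension −0.1; the
  whole matrix is divided by its global maximum, self-scores included,
  so the longest self-alignment maps to 1), and
* the Gaussian interaction profile kernel
  K(i,j) = exp(−ρ‖I(i)−I(j)‖²) over the rows of *A*, with
  ρ = ρ′ / mean‖I(i)‖² and initial bandwidth ρ′ = 1.

Disease similarity is the GIP kernel over the columns of *A*. The
heterogeneous matrix A_H places degree-normalized similarities
(D^{-1/2} S D^{-1/2}) on the diagonal blocks and *A* / *A*ᵀ off-diagonal;
the model input G_pd multiplies both similarity blocks by Ψ (default 6).
The factor is applied exactly as a multiplier: values above 1 *amplify*
similarity edges relative to association edges, and Ψ is exposed in the
configuration for users who want the attenuating regime (Ψ < 1).

The initial node embedding is H⁽⁰⁾ = A_H itself — each node is described
by its row of the heterogeneous matrix. This is the standard construction
for layer-attention GCN link predictors on a single combined graph; a
block form that stacks A_H against its transpose would double the node
count and is dimensionally inconsistent with an (n_p+n_d)-node network.

Propagation: H⁽ˡ⁺¹⁾ = ReLU(D^{-1/2} G_pd D^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾) for
l = 1..L (L = 3, embedding width k = 64). The final embedding is
Σ_l θ_l H⁽ˡ⁾ over the **hidden layers only** (H⁽⁰⁾ is excluded; its
dimension differs from k and the attention index runs from 1), with θ_l
trainable and initialized to 1/(l+1). The decoder is
A′ = sigmoid(H_p W′ H_dᵀ) with W′ a trainable k×k matrix.

Loss: class-weighted cross-entropy over all n_p·n_d pairs,
scaled by 1/(P·D), with the positive terms weighted by |T−|/|T+|. All
unobserved pairs are negatives. Scores of exactly 0/1 are clamped at
ε = 1e−7 when evaluating the loss (gradients are computed from the
unclamped sigmoid).

Optimization: full-batch Adam, analytic NumPy gradients (verified against
finite differences to ~1e−10 in the test suite). Two learning profiles
are shipped: the grid-selected optimum `grid` (lr 0.01, 800 epochs, the
default) and the alternative `text` profile (lr 0.001, 400 epochs).
Dropout: node dropout φ = 0.6 on each hidden embedding and symmetric
random edge dropout ω = 0.4 on G_pd (inverted scaling, graph
re-normalized each epoch). Both are inverted-dropout masks drawn from the
seeded generator, so training is bit-reproducible. Weight matrices use
Glorot-uniform initialization.

**Stage 2 — feature-weighted classification (FWGCN).** Shared-protein
expression columns are transformed by p′ = 2·p·a·exp(δ·|p|), where a is
the protein's potentiality score for the cohort's disease. The transform
is the identity at (a = 0.5, δ = 0) and strictly monotone in a for
p > 0. The exponent grows with δ as written; since some users expect a
shrinkage regularizer, an alternative `shrink` mode using exp(−δ·|p|) is
available behind `weight_mode`. δ defaults to 1e−4 and can be selected
from the canonical grid {1e−4 … 3} by internal stratified 5-fold CV
(`select_delta`); γ ∈ {2, 5, 10} is likewise chosen on training data,
with 5 as the package default.

The sample graph retains off-diagonal cosines ≥ ϵ, where ϵ is the largest
candidate threshold (the sorted unique non-negative off-diagonal cosines,
plus 0) whose mean retained edges per node — counting the unit self-loops
that are always added — reaches γ. Only non-negative cosines are ever
retained: negative-cosine edges would break the non-negativity assumed by
symmetric degree normalization. If γ is unreachable with ϵ = 0 the
achieved degree is reported with a warning. All-zero feature rows keep a
self-loop only. Ties break toward the larger ϵ, and the whole search is
an exhaustive scan (instances are a few hundred samples at most).

The classifier is a two-layer GCN (hidden width 64, ReLU, Adam lr 0.001,
400 epochs) using the same symmetric-normalized propagation; the loss is
the mean softmax cross-entropy over labeled samples (the mean rather than
the sum keeps the effective learning rate independent of cohort size).
Prediction is transductive with frozen weights: test samples are appended
to the training features, the cosine graph is rebuilt over the union with
the training γ, and one forward pass yields their probabilities. The
default appends all test samples of a fold at once (`batch`); a
one-at-a-time `single` mode is available and agrees with `batch` on
separable data in ≥ 95% of argmax labels.

## Evaluation protocols

**Masked ranking CV (link prediction).** Known associations are split
into 5 near-equal folds. Per fold, test positives are set to 0 in *A*
*before* the GIP kernels are computed (sequence similarity does not
depend on *A* and is computed once), the model is retrained, and the
held-out positives are ranked among all pairs unknown to the full
dataset. The AUC of this ranking equals the Mann–Whitney statistic; the
implementation uses `sklearn.roc_auc_score` and is checked against a
brute-force pair-counting oracle.

**Biomarker screening.** Within a stratified 5-fold loop, the unweighted
GCN sets the fold's baseline validation accuracy; each shared protein is
then weighted *alone* and retrained with the same seed (a paired
comparison, so identity weighting produces exactly zero deltas), and a
protein is recorded for the fold if accuracy strictly improves — ties do
not count. Proteins are ranked by fold frequency, ties by mean accuracy
improvement, then ID. Screening runs use 150 training epochs — improvement
deltas stabilize well before full convergence and the screen retrains one
model per shared protein per fold. When screens are replicated over
several seeds, fold frequencies are pooled across replicates before
ranking; frequency pooling is the same aggregation the per-fold counting
already performs, extended over replicates.

**Classification metrics.** Binary cohorts report accuracy, positive-class
F1 and the AUC of the class-1 probability; multiclass cohorts report
accuracy, weighted F1 and macro F1. Classification CV is stratified by
subtype to avoid degenerate folds on imbalanced cohorts. A guidance
threshold is enforced with a warning: with ≤ 10 shared proteins,
weighting gains are dominated by stochastic error and the plain GCN may
do better.

## Synthetic study

The generator plants exactly the structure each stage assumes:

* **Associations** — proteins and diseases are assigned to 5 latent
  blocks; within-block pairs link with density 0.6, off-block with 0.02
  (defaults; 100×40). The blocks are recoverable by spectral
  co-clustering at these settings, which anchors the link-prediction
  recovery experiments.
* **Sequences** — random 80–120-residue strings with a conserved
  15-residue block motif embedded, so within-block alignment similarity
  exceeds between-block similarity.
* **Expression** — 300 samples × 200 proteins of standard Gaussian noise;
  the first 30 columns are shared with the association vocabulary, and
  the first 15 of those get per-subtype mean shifts of 1.5 feature SDs
  (2 subtypes by default). Tables are robust-scaled (median/IQR).
* **Truth scores** — informative shared proteins score 0.9 for the
  cohort's disease, other shared proteins 0.1 (mirroring the low decoded
  scores of non-associated proteins), everything else 0.5.

What the generator does *not* emulate: mass-spectrometry intensity
distributions, missingness, batch effects, correlated protein modules,
PTM-site-level annotation, or disease ontology structure. Passing tests
therefore demonstrate that the algorithms recover the structure they
assume at realistic sparsity and effect sizes — not clinical performance.

## Problem sizes and replication

The validation experiments run the full pipeline at the default synthetic
scale: link prediction over 100×40 associations (≈ 550 positives,
5 folds, 3 seeded replicates), classification over 300×200 expression
tables (5 folds, 5 replicates in the tests, 3 in the acceptance script),
and screening of 30 shared proteins (≈ 150 GCN retrainings per
replicate). These sizes keep each experiment well-powered for the
properties asserted while remaining desk-scale.

## Numerical choices

* Degrees are floored at 1e−12 in symmetric normalization (isolated
  nodes).
* Sigmoid/softmax are computed in numerically stable forms; CE
  probabilities are clamped before logs.
* The GIP kernel is evaluated via the expanded squared-distance identity
  with a non-negativity clamp, and matches a naive double loop to 1e−12.
* A zero-similarity row (degree 0) in the heterogeneous network is
  rejected by name rather than floored: it indicates a malformed
  similarity input rather than an isolated-but-valid graph node.
* `build_input_graph` refuses to scale a graph twice.

## Known limitations

* Dense matrices throughout: graphs beyond a few thousand nodes would
  need sparse propagation.
* The transductive `single` extension mode re-thresholds the graph per
  test sample, which is quadratic in cohort size when applied to many
  samples.
* Scores feed classification only through one disease column; cohorts
  mapping to several related disease terms are not modeled.
* The screen weights one protein at a time; synergistic subsets whose
  members only help jointly will be under-counted.
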