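# ptmfusion

Graph learning for proteomics-driven disease subtyping: predict which
proteins are likely to carry a disease-relevant post-translational
modification (PTM), then use those predictions to re-weight protein
expression features before classifying disease subtypes.

## The problem

Curated PTM–disease associations (PhosphoSitePlus- or PTMD-style tables)
are sparse: a few thousand known pairs over ~1,000 proteins and a few
hundred diseases. Clinical proteomics cohorts, on the other hand, measure
expression for hundreds of proteins per patient but say nothing about
which of those proteins' modifications matter for the disease at hand.
`ptmfusion` bridges the two resources in two stages:

1. **Link prediction (LAGCN).** Known associations *A* ∈ {0,1}^{n_p×n_d}
   are combined with protein sequence similarity (Smith–Waterman local
   alignment, affine gaps) and Gaussian interaction profile (GIP) kernel
   similarities into one heterogeneous network

   A_H = [ D_p^{-1/2} S_P D_p^{-1/2} , A ; Aᵀ , D_d^{-1/2} S_D D_d^{-1/2} ],

   whose similarity blocks are scaled by a factor Ψ before being fed into
   a layer-attention graph convolutional network. Each layer propagates
   H^{(l+1)} = σ(D^{-1/2} G_pd D^{-1/2} H^{(l)} W^{(l)}); the layer outputs
   are mixed with learned scalars θ_l (initialized 1/(l+1)) and decoded by
   a bilinear decoder A′ = sigmoid(H_p W′ H_dᵀ). Training minimizes a
   class-weighted cross-entropy in which the sparse positive set is
   up-weighted by |T−|/|T+|. The entries a′_{ij} ∈ (0,1) are *PTM
   potentiality scores*.

2. **Feature-weighted classification (FWGCN).** For an expression cohort
   mapped to one disease, every protein present in both resources
   ("shared protein") has its expression values re-scaled by its score a:

   p′ = 2 · p · a · exp(δ·|p|),

   so scores above 0.5 amplify and below 0.5 attenuate. A cosine-similarity
   graph over patients is thresholded so that the mean number of retained
   edges per node (self-loops included) reaches a target γ, and a GCN is
   trained transductively: test patients are appended to the graph and
   classified by a forward pass of the frozen model. Screening the shared
   proteins one at a time for weighting-driven accuracy improvements, and
   ranking them by their frequency across cross-validation folds, yields
   candidate PTM biomarkers.

Both networks are implemented in NumPy with analytic gradients and Adam,
so every fit is exactly reproducible from a seed.

## Worked example

Simulate a small study, score PTM–disease pairs, and classify subtypes:

```sh
ptmfusion simulate --seed 7 --out-dir demo --n-proteins 40 --n-diseases 16 --n-samples 120
ptmfusion predict-ptm --assoc demo/associations.tsv --fasta demo/sequences.fasta \
    --out demo/scores.tsv --preset grid --seed 7
ptmfusion classify --expr demo/expression.tsv --scores demo/truth_scores.tsv \
    --disease-key D000 --out-dir demo/cls --seed 7
```

The second command prints the fitted link predictor's summary:

```
Layer-Attention GCN link predictor
==================================
nodes: 34 proteins x 16 diseases
layers L=3, embed k=64, psi=6.0
lr=0.01, epochs=800, seed=7
loss: 1.1779 -> 0.4151
attention weights: theta_1=0.5679, theta_2=0.1649, theta_3=-0.0006
```

The weighted cross-entropy drops from 1.18 to 0.42 over training, and the
attention weights show the first (shallow) convolution layer dominating
the final embedding — similarity structure carries most of the signal.
The third command runs 5-fold cross-validated classification and prints

```
weighted CV accuracy 0.9583 vs unweighted 0.8917 (30 shared proteins)
```

— on this fixture, score-weighting the 30 shared proteins lifts subtype
accuracy by about 6.7 percentage points over the plain GCN.

The same objects are available as a library: build a
`LayerAttentionGCN(hetero, assoc, config)` and call `.fit(seed)` for a
results object with `.scores`, `.attention` and `.summary()`; build a
`FeatureWeightedGCN.from_dataset(expr, scores, config)` and call
`.fit(seed)` for a classifier whose `.predict_transductive(x_te)` returns
per-sample subtype probabilities. `ptmfusion screen` / 
`ptmfusion.evaluation.screen_biomarkers` produce the frequency-ranked
biomarker table.

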