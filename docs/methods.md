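# Methods notes

## Model and assumptions

The pipeline assumes that drugs that are similar across several annotation
sources tend to interact with other drugs in the same way, and that the
*type* of an interaction is largely determined by the pair of "behavioral
neighborhoods" the two drugs occupy. It therefore (1) measures pairwise
similarity per source, (2) replaces raw similarity with a network-context
representation (random walk with restart + positive PMI) so that two drugs
sharing a neighborhood score as related even without direct feature
overlap, (3) compresses the five network views into one embedding with a
multimodal autoencoder, and (4) treats type prediction as flat multiclass
classification over pair features. Interaction types are assumed mutually
exclusive per pair (input tables carrying two types for one unordered pair
are rejected), and pairs are unordered throughout.

## Stage-by-stage choices

**Similarity.** Jaccard over binary descriptor vectors; two all-zero
vectors get similarity 0 off-diagonal (absent annotation is not evidence of
similarity) while the diagonal is forced to 1. ATC similarity parses the
7-character code into the standard 5 levels (anatomical letter | 2-digit
therapeutic | pharmacological letter | chemical letter | 2-digit substance)
and scores the shared-prefix depth k/5; when a drug carries several codes
the maximum over code pairs is used (the most permissive standard choice);
drugs with no code are 0-similar to everything. All ATC values therefore
lie on the grid {0, 0.2, 0.4, 0.6, 0.8, 1}.

**Diffusion.** The restart probability defaults to α = 0.8 and the L1
stopping tolerance to ε = 1e-9. All m one-hot starts are propagated
simultaneously as a matrix iteration (identical per row to the vector
form); convergence is declared when the worst row's L1 change falls below
ε, the strictest per-row criterion. α < 1 guarantees geometric convergence,
so the max_iter = 1000 guard only catches non-finite pathologies. PPMI uses
row sums for rᵢ and column sums for cⱼ (standard convention; for the
symmetric matrices produced here the transpose convention would differ only
through floating error, and the final averaging with the transpose absorbs
asymmetry either way).

**Autoencoder.** The reconstruction loss is mean squared error summed over
the five networks. Sigmoid outputs live in (0, 1), so inputs are min–max
scaled to [0, 1] per network first; the scaling parameters are recorded
with the run. This scaling choice changes absolute reconstruction numbers
relative to any other normalization and is the main numerical freedom in
the stage. One shared integration layer per side is the default (concat →
bottleneck → concat); deeper integration stacks are supported via
`integration_layers`, with widths interpolated geometrically. Weights are
Glorot-uniform from the run seed; batching is over drugs, each sample being
the drug's five concatenated network rows. Defaults: learning rate 0.01, 80
epochs, dropout 0, batch 64, per-network embedding 256 and unified
dimension 640 at full scale (16/32 in the bundled `test_scale`
configuration). The extractor trains for the fixed epoch budget; early
stopping applies only to the classifier.

**Classifier.** Hidden layers are linear → batch-norm → ReLU → dropout;
output linear → softmax; cross-entropy with Adam (defaults: lr 0.001, 100
epochs, dropout 0.2, batch 128, hidden 640/320/160 full scale, 64/32 test
scale). Input pair features are standardized per column with training-set
statistics stored on the model: embedding coordinates can differ in scale
by orders of magnitude, and without standardization the mismatch between
batch statistics during training and running statistics at inference is
large enough to destroy generalization. Early stopping holds out a
stratified 10% of the training pairs, watches validation cross-entropy with
patience 10, and restores the best weights. Unordered pairs are stored
once; concatenation is orientation-dependent, so training materializes both
orientations as augmented samples and inference averages the two
orientations' probability vectors and renormalizes — reported scores are
exactly orientation-invariant. Product and sum operators are invariant by
construction. Argmax ties break toward the lowest label index. No class
re-weighting or resampling is applied.

**Evaluation.** Accuracy is the per-class one-vs-rest average
(TPᵢ+TNᵢ)/n, which exceeds plain multiclass accuracy when classes are
imbalanced; plain accuracy is reported alongside. F1 is the harmonic mean
of macro precision and macro recall; the average-of-per-class-F1 variant is
also reported. Micro AUPR/AUC flatten the n × l one-vs-rest label matrix
against the flattened probabilities. Classes absent from a test fold use
the 0/0 → 0 convention inside macro averages. Fold aggregates are
unweighted means; per-fold values are always kept. Similarities, diffusion
and the autoencoder consume no interaction labels and are computed once on
all drugs; only the classifier is refit per fold, which keeps the S2/S3
cold-start scenes honest because held-out drugs contribute no labels
anywhere.

## Synthetic benchmark

The generator plants `n_groups` latent groups: each feature source reserves
one descriptor block per group, with bits firing at `p_in = 0.5` inside the
drug's own block and `p_out = 0.02` elsewhere; ATC codes share their first
4 of 5 levels within a group (distinct first letters across groups); each
sampled pair's type is a fixed function of the two groups, flipped to a
uniform other type with probability `label_noise`. Defaults: 80 drugs, 4
groups, source widths (120, 100, 80, 40), 5 types, pair density 0.6, label
noise 0.05 — sized so the complete pipeline, all three scenes, runs in
well under a minute on one CPU. One integer seed drives an independent
named stream per artifact, so changing e.g. `pair_density` never perturbs
the feature draw.

What the benchmark does *not* emulate: the long-tailed descriptor
frequency spectrum of real fingerprints, heavily imbalanced type
frequencies, and — importantly — drugs whose features only weakly predict
their interaction behavior. Because group membership is recoverable from
features alone, held-out drugs are nearly as predictable as training drugs,
so cold-start degradation (S2/S3 below S1) is present only as a small
training-set-size effect: across-seed mean macro-F1 orders S1 ≥ S2 ≥ S3,
but per-seed differences between S1 and S2 sit inside fold-composition
noise. Passing recovery tests on this benchmark demonstrates that the
pipeline wiring preserves and transports the planted signal; it does not
certify real-data accuracy levels or the magnitude of cold-start drops.

## Numerical details

- Diffusion validity is cross-checked against the closed form
  (1−α)·eᵢ·(I−αW)⁻¹; PPMI against an entrywise scalar loop; metrics
  against brute-force confusion counting and explicit threshold sweeps.
- Jaccard 0/0, PPMI at P(i,j)=0, and macro terms at 0/0 all use the
  "undefined → 0" convention (diagonals forced to 1 where identity demands
  it).
- A constant network min–max scales to all zeros with a warning rather
  than an error.
- Batch-norm uses momentum 0.9 running statistics and eps 1e-5; dropout is
  inverted (identity at inference).
- All training is deterministic given the run seed; per-stage seeds are
  derived from the global seed by a named-stream hash, so stages are
  independently reproducible.

## Using the published-scale configuration

`PipelineConfig()` defaults to the full-scale dimensions (256 per-network,
640 unified, hidden 640/320/160). For a real corpus exported as the
documented CSV formats (drug catalog, four feature tables, ATC pair list,
typed pair table), `ddifuse evaluate --datadir ... --config full.yaml`
runs the identical code path; with a few hundred drugs expect minutes per
fold on one CPU. No downloader is included, and database-specific export
(e.g. from SQLite event stores) is left to the user.

## Known limitations

- Type imbalance is not addressed (no re-weighting/resampling); macro
  metrics on rare types will be noisy.
- Probabilities are not calibrated.
- The autoencoder trains full-batch epochs for a fixed budget; no
  per-branch pretraining or denoising variants.
- The synthetic benchmark's ceiling behavior (see above) limits what
  ordering comparisons between variants can show: near the label-noise
  ceiling, the fused pipeline and the averaged-similarity baseline often
  make identical predictions and tie exactly.
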