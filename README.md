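# ddifuse

Multiclass prediction of drug–drug interaction (DDI) *types* — not just
whether two drugs interact, but how (e.g. "metabolism decreased", "risk of
adverse effects increased") — from heterogeneous drug annotations. The
package is aimed at computational pharmacology researchers who have, for a
set of `m` drugs, binary descriptor vectors over several feature spaces
(chemical substructures, protein targets, pathways, enzymes), WHO ATC codes,
and a partially observed table of typed interactions, and who want to
classify the unobserved pairs — including pairs involving drugs with no
known interactions at all (cold start).

## Method

The pipeline has four stages.

1. **Similarity matrices.** For each binary feature space, pairwise Jaccard
   similarity `s(dᵢ, dⱼ) = |fᵢ ∩ fⱼ| / |fᵢ ∪ fⱼ|`; for ATC codes, the
   shared-prefix depth `k/N` over the `N = 5` hierarchy levels (maximum over
   code pairs when a drug carries several codes). This yields five `m × m`
   similarity matrices.
2. **Topological networks.** Each similarity matrix `S` is row-normalized
   to `W = D⁻¹S` and diffused by random walk with restart,
   `pₜ = α pₜ₋₁ W + (1 − α) p₀` (restart probability `α = 0.8`, iterated to
   an L1 tolerance of `1e-9`), started from every drug. The stacked
   diffusion states `P` are re-weighted entrywise by positive pointwise
   mutual information, `X(i,j) = max(0, log₂ (P(i,j)·T) / (rᵢ·cⱼ))`, and
   symmetrized by averaging with the transpose, giving networks `N₁…N₅`
   that encode each drug's global network context.
3. **Multimodal autoencoder fusion.** The five networks (min–max scaled to
   [0, 1]) enter a multimodal deep autoencoder: one sigmoid encoder branch
   per network (`m → d`), concatenation, a shared integration layer to the
   unified bottleneck (`5d → d_u`), and a mirrored decoder, trained jointly
   by Adam on the summed per-network reconstruction MSE. The bottleneck
   activations are the unified drug embedding.
4. **Pair classifier.** Drug-pair features (concatenation `[hᵢ, hⱼ]` by
   default; elementwise product and sum are also available) feed a
   feed-forward softmax network (ReLU hidden layers with batch
   normalization and dropout, cross-entropy loss, Adam, early stopping)
   that outputs a probability per interaction type.

Evaluation uses fivefold cross-validation in three scenes: **S1** splits
labeled pairs (both drugs seen in training), **S2** holds out drugs and
tests known–new pairs, **S3** tests new–new pairs. Accuracy is the
one-vs-rest per-class average, precision/recall/F1 are macro-averaged, and
AUPR/AUC are micro-averaged over the flattened one-vs-rest construction.

Because labeled DDI corpora derive from restricted-access databases, the
package ships a synthetic data generator (`ddifuse.synth`) that plants
latent drug groups into every feature source and derives pair labels from a
group-pair rule with configurable label noise — every stage is testable
end to end without downloads. Real data in the documented CSV/TSV formats
drop into the same pipeline.

## Worked example

```python
from ddifuse import (PipelineConfig, SynthConfig, chance_macro_f1,
                     generate_dataset, run_cv)

dataset = generate_dataset(SynthConfig(seed=1))     # 80 drugs, 4 groups, 5 types
config = PipelineConfig.test_scale(seed=1)          # small-network configuration
result = run_cv(dataset, config)                    # S1 fivefold CV
for k in ("acc", "aupr_micro", "auc_micro", "f1_macro",
          "precision_macro", "recall_macro"):
    print(f"{k:16s} {result.aggregate[k]:.4f}")
print(f"{'chance f1_macro':16s} {chance_macro_f1(dataset.ddis):.4f}")
```

prints

```
acc              0.9778
aupr_micro       0.9144
auc_micro        0.9648
f1_macro         0.9422
precision_macro  0.9433
recall_macro     0.9411
chance f1_macro  0.1999
```

The pipeline recovers the planted group-pair rule almost up to the 5%
label-noise ceiling: macro-F1 0.94 against a frequency-matched chance level
of 0.20. The same run is available from the shell:

```bash
ddifuse evaluate --datadir data/ --outdir runs/s1 --seed 1 --scene s1 --simulate
```

Every stage is also exposed as its own subcommand (`simulate`, `featurize`,
`embed-networks`, `fuse`, `train`, `predict`, `rank-novel`, `ablate`) so a
run can be resumed from any saved artifact.

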