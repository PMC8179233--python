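# pistack

One-class classification workflow for ranking candidate π–π co-crystal
co-former pairs. Known co-crystal pairs (positive examples only) are used to
learn a description of the "co-crystal-forming" class; candidate molecule
pairs are then scored by their conformity to that description.

## Pipeline

1. **`pistack.data_model`** — parse multi-component (dotted) SMILES with
   stoichiometric multiplicities, filter molecules with acidic hydrogens
   (SMARTS), drop pairs containing non-aromatic solvents (aromatic solvents
   like benzene are kept), Tanimoto fingerprint similarity search, and
   enumeration of all n(n−1)/2 candidate pairs.
2. **`pistack.featurization`** — descriptor pruning (|r| > 0.92 or variance
   < 0.4 removed), molecular-complementarity feature selection (keep
   descriptors whose values correlate between the two co-formers across known
   pairs: Pearson and Spearman > 0.4, p < 1e−3), min–max scaling fitted on the
   labelled molecules only, and bidirectional pair-vector construction.
3. **`pistack.occ_traditional`** — eight one-class detectors (GMM density,
   LOF, kNN distance, isolation forest, one-class SVM, histogram density,
   cluster-based LOF, feature-bagged LOF) under a single contract: oriented
   scores (higher = more inlier), threshold at the contamination quantile
   (default 0.05 ⇒ 95% of training pairs flagged inliers), min–max score
   normalization to [0,1] and ensemble averaging. Group-aware 5-fold CV (both
   orientations of a pair share a fold) and a seeded sequential model-based
   hyperparameter search (`pistack.tuning`).
4. **`pistack.occ_deep`** — permutation-invariant set encoder (shared
   per-molecule MLP, symmetric pooling, head MLP; numpy with manual
   backprop), pretrained as an autoencoder, then fine-tuned to minimize the
   squared latent distance to a frozen center (the mean training
   representation). Deep scores are exactly invariant to molecule order.
5. **`pistack.interpretability`** — Shapley attribution of deep scores (exact
   coalition enumeration ≤ 12 features, seeded permutation sampling above),
   global importances, and correlation mapping of opaque descriptors to
   interpretable ones (|r| > 0.75).
6. **`pistack.ratio_model`** — 1:1 vs other stoichiometry classification:
   SMOTE-style minority oversampling (training split only) + gradient-boosted
   trees on latent representations.
7. **`pistack.selection`** — inlier thresholding (score > 0.7), top-quartile
   extraction, co-former popularity counts, Pareto front over (model score,
   reference similarity), nearest known pairs by orientation-minimal
   Euclidean distance, and a 2D-projection distance-preservation QC metric
   (UMAP-backed).
8. **`pistack.synthetic_fixtures`** — seeded generators planting the
   structure the workflow assumes (correlated descriptor blocks, constant
   columns, cross-co-former complementarity at a configurable strength,
   outlier pairs without it, a dominant 1:1 ratio class), so everything is
   testable offline.

## CLI

All stages are exposed under one entry point:

```sh
pistack make-fixture --spec fixture.yaml --seed 0 --out fixture/
pistack build-dataset --labelled pairs.csv --candidates mols.smi --out dataset/
pistack featurize --descriptors desc.csv --pairs-a a.csv --pairs-b b.csv --out feats/
pistack train --features pair_vectors.csv --models all --contamination 0.05 \
    --cv 5 --tune-budget 50 --seed 0 --out models/
pistack deep-train --features pair_vectors.csv --seed 0 --out deep/
pistack select --scores models/scores.csv --threshold 0.7 --out report/
pistack ratio --latents latents.csv --seed 0 --out ratio/
```

Inputs are plain text: `.smi` files (SMILES + optional id per line), CSVs of
multi-component SMILES / descriptors / pair vectors, YAML configs. Outputs are
CSV score tables plus JSON run manifests (specs, seeds, thresholds).

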