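# modfuse

Multimodal distance fusion and functional-landscape clustering for
gene-level data modalities.

## The problem

Large gene superfamilies — the motivating case is the human solute
carrier (SLC) transporters — accumulate heterogeneous evidence layers:
perturbation transcriptomes and metabolomes, protein interaction sets,
subcellular localization annotations, structural similarity, tissue
expression profiles, chemical substrate annotations, and disease
associations. No single layer suffices to place a gene functionally,
and the layers live on incompatible scales (Euclidean profile
distances, Jaccard set overlaps, ontology semantic distances, bounded
similarity matrices) with very different coverage.

`modfuse` implements the integration recipe that turns eight such
layers into one *functional landscape*:

1. **Modality distances.** Each layer gets a data-type-specific
   pairwise distance: Euclidean on standard-normalized profiles,
   Jaccard on interactor sets, `d = √((1 − r_s)/2)` on tissue
   expression ranks, `1 − similarity` for structure, term-cooccurrence
   Jaccard + best-match average (BMA) for localization,
   Tanimoto/element-embedding + BMA for substrates, and Leacock
   ontology distance + BMA for diseases.
2. **Harmonization.** Every distance distribution is mapped onto a
   common reference via ordered-quantile (rank-based inverse normal)
   normalization followed by the quantile function of a normal
   distribution with µ = 0.5 and σ = 0.194 truncated to [0, 1]
   (σ chosen so the untruncated normal covers 99% of its mass in the
   unit interval). Structural atoms at exactly 0 or 1 in the four
   set-derived metrics bypass the transform and re-enter unchanged.
3. **Fusion.** Similarities `1 − d` are averaged per gene pair with
   per-modality weights (3 for structure and the three perturbation /
   interaction readouts, 2 for substrates, 1 for the annotation-derived
   context layers), renormalizing over the modalities that cover the
   pair.
4. **Landscape.** The fused dissimilarity feeds a fuzzy k-nearest-
   neighbor graph (k = 15, per-point bandwidth calibration, fuzzy-union
   symmetrization). The graph is embedded in 2-D, clustered with the
   Leiden algorithm under modularity (resolution 1.0, 100 iterations),
   and converted into a shortest-path metric with edge length
   `1 − ln(adjacency)`.
5. **Evaluation.** Silhouette scores on graph distances, ANOSIM
   permutation tests of annotation coherence, adjusted mutual
   information, one-sided Fisher enrichment with Benjamini–Hochberg
   correction, micro-averaged F1 for multi-label annotation agreement,
   and leave-one-modality-out cross-validation.

A first-class synthetic-data generator plants a K-cluster structure
consistently across all eight modalities (with configurable noise and
per-modality missingness), so the entire pipeline is testable without
any external downloads.

## Worked example

```python
import numpy as np
from modfuse import (GeneratorConfig, generate_world, modality_distance_matrices,
                     harmonize_modality, fuse, DEFAULT_WEIGHTS,
                     FunctionalLandscape, adjusted_mutual_information, anosim)

world = generate_world(GeneratorConfig(n_entities=120, n_clusters=4,
                                       noise_level=0.1, seed=42))
dms = modality_distance_matrices(world)
harmonized = {m: harmonize_modality(dm) for m, dm in dms.items()}
fused = fuse(list(harmonized.values()), DEFAULT_WEIGHTS, list(harmonized))
model = FunctionalLandscape(random_state=42).fit(fused)

print(f"clusters found: {model.labels_.max() + 1}")
print(f"modularity:     {model.modularity_:.3f}")
ami = adjusted_mutual_information(world.planted_labels, model.labels_)
print(f"AMI vs planted: {ami:.3f}")
res = anosim(np.nan_to_num(model.graph_distances_.values, nan=50.0),
             world.planted_labels, permutations=999, seed=42)
print(f"ANOSIM R = {res.r:.3f}, p = {res.p_value:.4f}")
```

prints

```
clusters found: 4
modularity:     0.750
AMI vs planted: 1.000
ANOSIM R = 1.000, p = 0.0010
```

The four planted communities are recovered exactly (AMI 1.0); the
ANOSIM statistic R = 1 says every between-cluster graph distance ranks
above every within-cluster one, with the add-one permutation p-value at
its floor of 1/(999+1).

`FunctionalLandscape`, `QuantileHarmonizer`, `WeightedSimilarityFusion`
and `WardTree` are scikit-learn-style estimators (`fit`,
`get_params`/`set_params`, trailing-underscore fitted attributes), so
they compose with sklearn model-selection tooling; the module-level
functions are thin wrappers over them.

A CLI mirrors the stages:

```bash
modfuse simulate --seed 7 --out world/
modfuse run --world world/ --seed 7 --out artifacts/
modfuse tree --dist artifacts/graph_distances.tsv --out tree.nwk
```

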