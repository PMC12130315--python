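# Methods

## Overview

`modfuse` fuses eight heterogeneous per-gene evidence layers into a
single similarity per gene pair, builds a fuzzy neighborhood graph on
it ("the functional landscape"), and evaluates the resulting clusters
statistically. The pipeline is deterministic given its seeds and is
exercised end to end on synthetic cohorts with planted cluster
structure.

## Modality distances

Let `i, j` index genes ("entities"). Per modality a pairwise
dissimilarity `d_m(i, j)` is computed on the modality's native type:

| modality            | input                       | distance                                        | bounded |
|---------------------|-----------------------------|-------------------------------------------------|---------|
| transcriptome       | log-FC profile              | Euclidean on per-entity z-scored profiles       | no      |
| metabolome          | log-FC profile              | Euclidean on per-entity z-scored profiles       | no      |
| interactome         | interactor set              | Jaccard distance                                 | yes     |
| localization        | location-term set           | term-cooccurrence Jaccard, aggregated by BMA     | yes     |
| structure           | similarity matrix in [0,1]  | `1 − s`                                          | yes     |
| tissue expression   | expression profile          | `√((1 − r_s)/2)`, Spearman with average ranks    | yes     |
| substrate           | substrate set + catalog     | Tanimoto / scaled element embedding, BMA         | yes     |
| disease             | ontology-term set           | Leacock semantic distance, BMA                   | yes     |

**Best-match average (BMA).** For item sets A, B with item distances
`d`, `BMA = ½ (mean_{a∈A} min_{b∈B} d(a,b) + mean_{b∈B} min_{a∈A}
d(a,b))`. BMA lies between the min and max of its inputs, is symmetric,
and is 0 for identical sets with zero self-distances.

**Leacock distance.** On the is-a taxonomy, similarity
`s = −log(len / 2D)` with `len` the node count of the shortest path
through a common ancestor (1 for identical terms) and `D` the maximum
root-to-leaf depth in node count; the reported distance is
`1 − s/s_max` with `s_max = −log(1/2D)`, so it lives in [0, 1], is
symmetric, vanishes on the diagonal, and is 1 for terms without a
common ancestor. The classical measure comes in several library
variants; this node-count variant with a global depth normalizer was
chosen because the downstream harmonization needs a bounded distance,
and no bit-level agreement with any particular library is claimed.
Only is-a edges define depth and paths; the extended relation
whitelist (conjugate base/acid, tautomer, has-role) applies solely to
substrate class matching, where chemistry-equivalent terms should
count as matches.

**Substrate chemistry.** Molecular substrates carry binary
fingerprints; their distance is `1 − Tanimoto` over set bits (the
Tanimoto coefficient is a similarity, so the complement is taken to
obtain a distance). Elemental substrates carry numeric element
embeddings; features are z-scored over the catalog and Euclidean
distances divided by the catalog-wide maximum so the range is [0, 1].
A molecular–elemental pair is assigned distance 1 exactly. All-zero
fingerprints are excluded with a warning.

Entities with no data in a modality are missing there (NaN rows in the
modality's matrix); pairs touching a missing entity stay missing.

## Harmonization

Raw modality distances differ in range and shape. Upper-triangle
non-missing entries (diagonal excluded — its structural zeros would
distort the rank transform) are mapped by:

1. **Ordered-quantile normalization**: `z_i = Φ⁻¹((r_i − 0.5)/n)` with
   average ranks for ties — a strictly monotone, distribution-free map
   to standard-normal scores.
2. **Truncated-normal quantile map**: `v = Q_trunc(Φ(z))` where
   `Q_trunc` is the quantile function of N(µ = 0.5, σ) truncated to
   [0, 1]. σ defaults to `0.5 / Φ⁻¹(0.995) ≈ 0.194`, i.e. the
   untruncated normal covers 99% of its mass inside the bounds.

For bounded metrics, entries *exactly* at 0 or 1 are set aside first
and reintroduced unchanged afterwards. Boundary detection is exact
equality, not an epsilon: atoms at the bounds arise structurally
(identical or disjoint sets, forced cross-universe substrate pairs),
whereas the two continuous bounded metrics (structure, tissue) hit the
bounds only on a measure-zero event, so in practice the rule touches
the four set-derived modalities. Fewer than three transformable values
is an error (degenerate modality).

`QuantileHarmonizer` exposes the same map as a scikit-learn
transformer: `fit` stores the sorted reference sample, `transform`
interpolates ranks for new values (clamped to the observed quantile
range), and `fit_transform` on the training data reproduces the exact
ordered-quantile result.

## Fusion

Harmonized dissimilarities are complemented (`sim = 1 − d`) and fused
per pair as a weighted average over the modalities where both entities
are covered, with the effective weight sum recorded:

```
fused(i, j) = Σ_m w_m (1 − d_m(i,j)) / Σ_m w_m   over covering m
```

Default weights: transcriptome 3, metabolome 3, interactome 3,
structure 3, substrate 2, localization 1, tissue 1, disease 1.
Renormalizing over covering modalities is the only reading under which
partially covered entities still receive a similarity for every pair;
a pair covered by no modality is an error, which the complete-coverage
structure modality makes unreachable. Fusion is invariant to uniform
weight rescaling. Pearson correlations between harmonized modality
dissimilarities (pairwise-complete upper-triangle entries) are
reported as a redundancy diagnostic. The per-modality weights are
plain configuration; no information-content estimation is performed to
derive them.

## Landscape

The fused similarity is complemented to a dissimilarity and used as a
precomputed metric for the standard fuzzy simplicial set construction
(k = 15 nearest neighbors, per-point bandwidth calibration, local
connectivity 1 so each point's nearest neighbor enters with membership
1, fuzzy-union symmetrization). On that weighted graph:

* **Embedding**: 2-D layout with 500 optimization epochs and minimum
  point distance 0.1. The initialization is a seeded random layout
  rather than the spectral default: the spectral fallback for graphs
  with several connected components draws unseeded randomness, which
  would break the rerun-identical-artifacts guarantee. The embedding is
  display-only; clustering and distances operate on the graph itself.
* **Graph distances**: each edge gets length `1 − ln(a)` (natural
  log; `a = 1` gives length 1) and pairwise distances are shortest-path
  sums (Dijkstra). The metric blends local neighborhood structure with
  global connectivity, satisfies the triangle inequality exactly, and
  marks unreachable pairs. The log base is configurable; natural log is
  the default reading of "logarithmized".
* **Leiden clustering**: configuration-model quality at resolution 1.0
  (plain modularity), 100 iterations, seeded; the partition's
  modularity is reported.
* **Ward tree**: agglomerative clustering under Ward's criterion on a
  complete distance matrix (intended for the structure modality), with
  Newick branch lengths `√h_parent − √h_child` of merge heights — a
  concrete reading of square-root scaling that preserves the
  ultrametric ordering while compressing tall merges.

## Evaluation

* **Silhouette** `s(i) = (b − a)/max(a, b)` on graph distances
  (configurable to any precomputed matrix); singletons score 0.
  Disconnected graphs are handled by either excluding entities with
  non-finite distances (default) or capping unreachable pairs at the
  maximum finite distance plus one — the cap is exact for rank-based
  statistics ("farther than anything reachable") and a bounded proxy
  otherwise; the pipeline driver uses the cap.
* **ANOSIM**: `R = (mean rank between − mean rank within)/(M/2)` over
  the `M = n(n−1)/2` distance ranks with average ranks for ties;
  significance by label permutation with the add-one estimator
  `p = (1 + #{R_perm ≥ R_obs})/(1 + permutations)` (never exactly
  zero). Default 10,000 permutations.
* **AMI** under the permutation model with the arithmetic mean
  normalizer; two single-class labelings are defined as 1.0 and
  logged.
* **Enrichment**: per (cluster, label) a 2×2 in/out × has/lacks table,
  one-sided over-representation p from the exact hypergeometric upper
  tail; labels with fewer than two carriers are dropped before
  testing; Benjamini–Hochberg across all tests performed. Multi-label
  properties contribute one table per (entity, label) incidence.
  The significance cutoff for "enriched property counts" in
  cross-validation is BH-adjusted p < 0.05.
* **Micro-F1** over (entity, term) incidences: precision `TP/|A|`,
  recall `TP/|B|`, F1 their harmonic mean (0 without overlap).
* **Leave-one-modality-out**: the harmonize → fuse → graph → Leiden
  path reruns once per excluded modality plus a full-data baseline,
  reporting cluster count, AMI against planted labels and enriched
  property counts; a fusion failure (uncovered pair) marks that run
  failed without aborting the report.
* **Skewness** `g1 = m3/m2^{3/2}` with central sample moments, for
  quantifying asymmetry of per-group publication or annotation counts.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes,
nothing more: K latent unit-vector cluster centers (pairwise angular
separation ≥ 60° by rejection sampling, orthonormal fallback) drive
every modality. Profiles are fixed random projections of the centers
plus Gaussian noise; interactor sets come from disjoint cluster pools
with a 6-item always-present core and contamination probability equal
to the noise level; localization uses overlapping 3-compartment home
sets (stride 2, so neighboring clusters share one compartment and the
term-cooccurrence metric is not purely 0/1 at zero noise); substrate
and disease terms are leaves of balanced toy ontologies (default depth
3, branching 3) drawn from the cluster's branch with noise-probability
swaps; fingerprints are cluster-prototype bit vectors with per-bit flip
probability equal to the noise level; a configurable fraction of
clusters carries elemental substrates instead, exercising the
cross-universe distance; structural similarity is the monotone
transform `1 − d/d_max` of jittered latent distances.

Entities drop out of a modality independently with probability
`1 − coverage`; the structure modality is pinned at coverage 1.0 so
fusion never meets an uncovered pair. Default coverages mirror an
eight-modality study of 447 entities in which structure covers
everyone and the other layers cover 441, 378, 396, 418, 443, 329 and
226 entities (transcriptome, metabolome, interactome, localization,
tissue, substrate, disease respectively).

Defaults: 120 entities, 4 clusters, noise 0.1, latent dimension 8,
profile dimensions 60/30/50 (transcriptome/metabolome/tissue), 200
interactors, 10 compartments, 128 fingerprint bits. A
cross-modality-coupling knob exists but defaults to 0; no attempt is
made to match any particular empirical between-modality correlation,
and on these worlds all modalities share the same latent drivers, so
inter-modality correlations are far higher than in real data.

**What passing tests do and do not show.** The synthetic worlds make
the planted partition recoverable from every modality at low noise;
recovery there validates the plumbing and the statistics, not the
biological informativeness of any real data layer. Real modalities
are noisier, non-Gaussian, batch-confounded and mutually much less
redundant; absolute values of AMI, modularity or silhouette on
synthetic worlds do not transfer.

## Numerical choices and degenerate inputs

* Symmetry tolerance 1e-9 for input matrices; NaN marks missing pairs
  and must be symmetric.
* Constant (zero-variance) profiles are marked missing with a warning;
  constant rank profiles make a tissue pair missing; empty sets make
  an entity missing in a set modality.
* Ordered-quantile plotting position is `(r − 0.5)/n`; ties get
  average ranks.
* Distance floats are written with `%.17g` so artifacts round-trip
  bit-exactly; reruns with identical config and seeds produce
  byte-identical files, recorded as SHA-256 checksums in
  `provenance.json` (which deliberately contains no timestamps).
* Every stochastic stage (generator, graph construction, embedding,
  Leiden, permutation tests) takes an explicit integer seed; nothing
  falls back to wall-clock entropy.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to keep
a laptop run comfortable while leaving the statistics meaningful:
recovery on 120-entity / 4-cluster worlds over five seeds, ANOSIM
calibration with 1000 null simulations of 24 entities at 999
permutations, harmonization fidelity on 780 pairs, leave-one-out on a
96-entity world, and determinism on a 60-entity world with the full
500-epoch embedding.

## Known limitations

* The Leacock variant and the square-root branch scaling are concrete
  readings of under-specified conventions; alternatives would change
  numbers but not structure.
* Ties in Leiden (degenerate modularity optima) are resolved by the
  seed, not enumerated.
* The boundary-exclusion rule uses exact equality; values merely near
  0 or 1 pass through the rank transform.
* The evidence-merging layer ships with editable term maps and rules;
  the real source vocabularies (thousands of terms) are not
  reproduced.
* No OWL reasoning, cross-ontology identifier mapping, fingerprint
  generation from structures, or interactive visualization.
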