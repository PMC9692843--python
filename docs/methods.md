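# Methods

This note documents the models, parameters and design decisions behind
`testaclust`, and what its validation does and does not demonstrate.

## 1. Synthetic testa generator

**Model.** A patch is a Voronoi tessellation of 250 × 250 px whose ridges
play the role of anticlinal cell walls. Sites come from a jittered grid
(a cheap blue-noise sampler): `cell_count` requested sites are realized as
the nearest nx × ny grid, each site displaced uniformly by
±`mesh_jitter` × spacing. Sites are mirrored across the four borders so
every ridge adjacent to an original site has finite vertices.

Each ridge is drawn as a displaced polyline

```
p(t) = v0 + (tL + 0.6 ρ A sin(4πft)) t̂ + A sin(2πft) n̂ ,   t ∈ [0,1]
```

with a half-sine envelope pinning the endpoints. Amplitude `A` (px),
frequency `f` (cycles per wall) and lobe re-entrance `ρ` ∈ [0,1] encode the
anticlinal class; the tangential term makes lobes double back, producing
Ω-like necks. The per-class defaults are

| class | A | f | ρ |
|---|---|---|---|
| straight | 0 | 0 | 0 |
| S | 4 | 1.0 | 0 |
| U | 6.5 | 1.5 | 0 |
| U-to-Ω | 8.5 | 1.8 | 0.4 |
| Ω | 10.5 | 2.0 | 0.8 |
| irregular (×2) | 6 / 3 | 1.5 / 1.0 | 0 |

chosen so that mean wall tortuosity (arc length / chord) is strictly
monotone over straight < S < U < U-to-Ω < Ω; the two irregular classes
jitter amplitude and frequency per wall. Regular classes use a fixed
undulation phase — real undulation lobes run coherently along a wall, and
a random phase would only add within-class variance with no morphological
meaning. Amplitudes are clamped to 0.35 × ridge length so lobes of short
walls cannot collide with neighbours, and validated against half the cell
spacing.

Periclinal sculpture is rendered as bright disks placed by dart throwing
with a minimum separation (2r + 3 px; 2r + 1 for "dense" placement), so the
rendered blob count tracks `verruca_count` (±10 % contract for counts
≤ 100). "Marginal" placement samples along walls, offset just outside the
wall band. Per-class defaults: granule 90 × r2 dense; small verrucae
50 × r3 uniform; large verrucae 12 × r8 uniform; marginal verrucae
40 × r3 marginal; verrucate verrucae 70 × r5 dense.

**Gray levels.** Interiors sit at a per-class `interior_level`
(granule 0.88 … verrucate 0.66): heavier sculpture scatters more and images
darker under SEM, and brightness systematically varies across the
literature figures such a corpus is assembled from. Walls are drawn at
0.15, bumps add +0.14. The SEM finish is Gaussian blur (σ = 1 px) then
additive Gaussian noise (sd = 0.03), clipped to [0,1]. All interior levels
stay above the 0.6 threshold so testa cells remain the foreground
components downstream.

**Determinism.** All randomness flows from `TextureParams.seed` through a
fixed draw order (mesh → wall parameters → verruca placement → noise);
identical (class, params) gives bit-identical rasters. Dataset generation
derives per-image seeds from the master seed by stable CRC-32 hashing.

**What the generator does *not* emulate**: charging artifacts, depth
shading, perspective, contamination, magnification variation, cell files
with preferred orientation, and continuous morphological intergrades. The
planted classes used for validation (below) are deliberately
well-separated; passing them demonstrates the mechanics of the pipeline,
not its resolution on real SEM corpora.

## 2. Preprocessing

* Grayscale uses ITU-R BT.601 luminance weights (0.299, 0.587, 0.114) —
  a convention choice.
* Binarization is global with threshold 0.6 and the rule *pixel ≥
  threshold → foreground*. An optional local-mean (adaptive) switch exists
  for composite frames but is off by default.
* Components are labelled with 8-connectivity (corner-touching pixels
  merge); measurements (area, bbox, centroid, perimeter, eccentricity) come
  from `skimage.measure.regionprops`. Coordinates are row-major, origin
  top-left, 0-based; boxes half-open.
* Colorization assigns evenly spaced, seed-shuffled hues — exactly L
  distinct non-background colors for L components. The colors carry no
  information; the *colored* representation is therefore vectorized as a
  10-element region-statistics summary (component count; area, perimeter
  and eccentricity means/sds; foreground fraction; largest-component
  fraction; component density), not as raw RGB.
* Pixel representations (grayscale, threshold) are vectorized by
  downsampling to `downsample_side`² and flattening. The dataclass default
  is 64 (a faithful, nearly lossless grid). The planted study configuration
  uses 8: each feature then pools a ~31 px neighbourhood — about half a
  cell — so features measure local wall density and brightness rather than
  exact wall positions. Raw-pixel L2 at fine grids is dominated by
  misregistration of thin, high-contrast walls; pooling at the half-cell
  scale is the standard remedy and is an analysis choice, not a generator
  change.
* Augmentation draws rotation uniformly in ±5° and per-axis shifts
  uniformly in ±1 % of the side (≤ 2.5 px at 250); augmented copies are for
  enlarging training sets only — consensus always runs on original images.
* `shuffle_split` is a seeded permutation with train size ⌊n ×
  fraction⌋; the pipeline records the split but, by design, clusters the
  full original set so agreement is per-original-image.

## 3. k-selection

SSE curves use best-of-`restarts` (default 10) k-means++ fits; each k is
additionally warm-started from the previous k's best solution by splitting
the cluster with the largest within-cluster SSE (its farthest point becomes
an extra centroid). This makes the reported curve provably non-increasing
in k, which plain restarts cannot guarantee.

Elbow detection normalizes both axes to [0,1] and picks the interior k with
the maximum perpendicular distance to the chord joining the curve's
endpoints; ties (within 1e-12) break toward smaller k. Silhouette uses the
standard mean of (b − a)/max(a, b) with the singleton-0 convention
(delegated to scikit-learn; cross-checked against a direct implementation
in the tests); the argmax tie also breaks toward smaller k. Distances are
Euclidean throughout — no metric was imposed by the problem.

## 4. Clustering battery

* **M1 K-means**: Lloyd iterations from random distinct points, best of 10
  restarts; convergence on unchanged assignments or 300 iterations; empty
  clusters are re-seeded with the point farthest from its centroid.
* **M2 K-means++**: same Lloyd core with the D² initialization (first
  centroid uniform; subsequent centroids sampled ∝ squared distance to the
  nearest chosen centroid). M1 and M2 are kept distinct because the
  battery treats them as separate methods.
* **M3 Minibatch**: per-iteration random batch, per-centroid streaming
  update with learning rate 1/count, final nearest-centroid labelling with
  empty-cluster refill. The streaming pass cannot escape a bad start, so
  the whole pass is restarted (default 5) and the lowest-SSE labelling
  kept.
* **M4 Spectral**: RBF affinity (γ defaults to 1/(total feature variance ×
  dimension)), symmetric normalized Laplacian, the k smallest-eigenvalue
  eigenvectors, row normalization, then the package's k-means on the
  embedding. A precomputed affinity can be supplied (used by the
  block-diagonal oracle test).
* **M5 Birch**: scikit-learn's CF-tree (branching 50, radius threshold 0.5
  in standardized units) summarizes the data in one pass; leaf entries are
  merged to k clusters by SciPy centroid-linkage agglomeration, and points
  inherit their leaf entry's cluster.

Features are z-scored per dimension before spectral and Birch (affinity
and radius scales are otherwise meaningless); the k-means family sees raw
[0,1] features. The six proposed runs EG…SC use K-means++ as the workhorse
with the k chosen by their criterion on their representation; the M1–M5
comparison runs use one configurable representation (default grayscale)
and criterion (default elbow), and the report labels both.

## 5. Consensus

"Identical" and "related" are operationalized by Jaccard thresholds 0.9 and
0.5 — the analysis needs a scale-free criterion, and both values are
config-exposed. The report floor (default 500, matching corpus-scale
reporting; 5 in the 60-image study) is a *reporting* filter: higher tiers
are filters on the same relations, never a different algorithm. Separation
indices rank a cluster's reported overlaps by descending count, ties by
ascending partner index, for determinism.

Threads require ≥ 3 distinct runs; chains are maximal simple paths with
pairwise-distinct run codes, reported once in canonical endpoint order.
When several runs produce identical partitions the relation graph contains
cliques and the number of maximal chains grows factorially with the run
count — exhaustive enumeration is intended for the six proposed runs or a
human axis plus machine runs, and the CLI scopes it accordingly.

Agreement levels use *exact equality of cluster-mate sets*: for image i and
run r, mates_r(i) is the set of images sharing i's cluster (excluding i);
the level is the largest number of runs whose mates sets for i coincide,
which reduces to the largest multiplicity among the six sets. SI therefore
means "all six runs give exactly the same neighbourhood", and PD "no two
runs agree". Softer set-similarity variants were considered and rejected
as under-determined. A brute-force oracle over all run subsets verifies the
reduction in the tests.

The human-comparison path treats each annotation axis (anticlinal,
periclinal) as a reference partition and reuses the same contingency →
classification → thread machinery.

## 6. Pipeline and reproducibility

Stage seeds derive from the master seed by CRC-32 hashing of stage names —
no global random state, so stages are individually reproducible and
insertion of a new stage cannot shift another stage's stream. Reports
(CSV tables + JSON summary) contain no timestamps; two runs with one master
seed are byte-identical, and the JSON config echo reproduces the run when
fed back.

**Problem sizes.** The planted study uses 60 images (3 classes × 20), k
scanned 2–10, 10 restarts; the k-selection study uses 10 datasets of 200
points around 4 planted Gaussian blobs (centers 12 apart, sd 0.5); the
optimizer oracle uses 100 instances of n ≤ 8 points against exhaustive
enumeration over all 2-partitions. These sizes keep the full suite and the
acceptance script in the minutes range on one CPU while leaving each check
statistically meaningful.

## 7. Known limitations

* The planted three-class study is a positive control: its classes differ
  simultaneously in cell size, wall thickness, undulation and sculpture
  brightness. Perfect ARI/SI there says nothing about discriminating
  subtle intergrades on real corpora.
* The feature spaces (pooled pixels; region statistics) are deliberately
  simple; no claim is made that they are optimal descriptors of testa
  sculpture.
* Thread enumeration is exponential in adversarial relation graphs (see
  §5).
* The masking/cropping path handles one bright region per frame; multi-seed
  composite plates must be split upstream.
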