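# Methods

`bodyatlas` implements a two-stage self-organizing-map (SOM) analysis of
anthropometric body-scan tables: body measures are first aggregated into
*meta-measures* (clusters of correlated measures on a "feature map"),
participants are then stratified into *body types* (clusters on a "body
map" trained on the meta-measures), with consensus-based stability
statistics, classical body indices, bodygrams and map stainings on top.
This note records the model, its assumptions, the tunables that matter,
and the design choices made where the design was genuinely open.

## Preprocessing

The raw input is a participants × measures matrix (lengths/girths in cm,
angles in degrees, weight in kg) with per-participant gender, age and
body height. Three ordered filter stages remove missingness:

1. participants missing more than 50% of their measures,
2. measures missing in more than 5% of the *remaining* participants,
3. all remaining participants with at least one missing value.

The order is part of the contract — evaluating measure missingness after
the near-empty rows are gone prevents a handful of bad scans from
dragging many measures over the 5% line. The output is complete; no
imputation is ever performed.

Every measure is then divided by the participant's body height (cm/cm,
giving dimensionless shape measures). This encodes a proportionality
model: body shape is assumed to scale linearly with stature, so the
downstream body types describe shapes at a common height, not sizes.
Angle measures are divided too by default — a `exempt_kinds` switch
allows the physically cleaner exemption. Finally each measure column is
Z-normalized (sample SD, ddof = 1; the choice is numerically immaterial
at cohort scale but fixed for reproducibility), putting all measures on
a common SD scale, which the Euclidean-distance-based SOM requires.

Classical indices — BMI = w/h², WHR = waist/hip, WHtR = waist/h and
ABSI = waist/(BMI^(2/3)·h^(1/2)) — are computed from SI inputs and can be
appended to the measure table as ordinary columns (they then pass through
the same normalizations; `include_indices` controls this).

## SOM core

Maps are rectangular lattices of codebook vectors, trained in batch mode
by default: each epoch assigns every item to its best-matching unit
(BMU; Euclidean, ties to the lowest row-major unit index) and replaces
each codebook by the neighborhood-weighted mean of the items. The
Gaussian neighborhood kernel is separable over lattice rows and columns,
so one epoch costs one BLAS distance product plus two small tensor
contractions even on large maps. The radius decays linearly from
max(width, height)/2 to 1 over 100 epochs (all configurable); an online
(per-item) mode and a bubble (Chebyshev) kernel are available.

Initialization is deterministic: codebooks are seeded on the plane of
the first two principal axes (±2 SD), which pins map orientation and
removes run-to-run topology flips that would destabilize downstream
cluster detection; a seeded random fallback covers degenerate data. All
stochastic operations take an explicit integer seed; there is no global
RNG state.

The U-matrix (distance map) stores each unit's mean Euclidean codebook
distance to its lattice neighbors (von Neumann 4-neighborhood by
default, 8 configurable; border units average over existing neighbors).
Its ridges mark cluster borders. Per-epoch quantization error is logged;
at fixed radius the batch update minimizes the neighborhood-weighted
distortion, which quantization error tracks to within a fraction of a
percent (the test suite allows 1% wobble).

Map size is selected by growing the map until the downstream cluster
count stops increasing for two consecutive candidate sizes — the
smallest size that resolves the structure wins.

## Cluster detection on the U-matrix

A cluster is a map area surrounded by (locally) maximal U-matrix ridges.
Detection is watershed-by-steepest-descent:

1. every unit follows its lowest-valued neighbor downhill to a local
   minimum (plateaus resolved toward the lower row-major index, which
   guarantees termination and determinism);
2. adjacent basins are merged while their separating ridge is
   insufficiently prominent: prominence = saddle height − the higher of
   the two basin minima, and a ridge must reach θ × (U-matrix dynamic
   range) to survive. Merging proceeds lowest-prominence first;
3. items inherit the basin of their BMU; empty basins are background.

**θ default 0.30.** The ridge criterion is inherently scale-free but the
threshold is open; it is pinned by planted-block recovery on default
synthetic cohorts. Values in [0.2, 0.3] form a robust plateau (adjusted
Rand index 0.95–1.0 across seeds); below that, the dynamic range —
inflated by the very tall ridges that isolate unclustered noise
measures — makes ordinary within-cluster wrinkles look salient and
fragments real clusters.

**U-matrix smoothing.** Participant maps run at < 1 item per unit, so
the raw U-matrix carries substantial per-unit sampling noise. Body-type
detection therefore Gaussian-smooths the U-matrix (σ = 2 lattice units
by default) before the watershed; the feature map, whose items form
tight discrete clumps, is left unsmoothed (σ = 0).

## Meta-measures and body types

Feature clusters become meta-measures: per-participant arithmetic means
over the member measure columns (Z-units). Clusters with fewer than two
measures are dissolved and their measures excluded as singletons.
Columns are labelled "A", "B", … by the angle of the cluster's mean BMU
position around the map center, clockwise from 12 o'clock, so the axis
order of every bodygram mirrors the map layout. Each participant's
meta-measure vector is finally Z-normalized across meta-measures
(row-Z), removing additive offsets.

The body map trains on the row-Z meta table (130×130 units at full
cohort scale; desk-scale analyses use ~2 units per participant). Basins
of its smoothed U-matrix are body types; clusters smaller than
⌈1% × N⌉ participants are dissolved into an unassigned pool (an absolute
floor, e.g. 85, can be supplied for a specific cohort size). Types are
labelled by gender composition — F* when ≥ 80% female, M* when ≥ 80%
male, B* otherwise — and numbered by descending size within each letter.
The 80% quantification of "mainly one gender" and size-ordered numbering
are package choices; both are exposed and regression-pinned.

## Consensus and stability

Cluster robustness is judged by rerunning the *entire* training +
detection procedure on random sub-cohorts (without replacement,
Monti-style; a with-replacement flag exists) with per-iteration seeds
derived as seed + iteration. The consensus matrix holds, for each item
pair, co-clustering counts over the runs where both were sampled; the
consensus ratio is undefined (missing) for never-co-sampled pairs and
such pairs drop out of all averages. Unassigned items count as sampled
but co-clustered with nobody (their diagonal stays 1).

Intra-cluster consensus m(k) is the mean consensus over within-cluster
pairs of the full-cohort reference partition; ⟨m(k)⟩ is the *unweighted*
mean over clusters (the weighting is not dictated by the statistic;
unweighted is fixed here). Inter-cluster consensus feeds a
single-linkage dendrogram on dissimilarity 1 − inter(k, l) (scipy
agglomeration). Stability curves report mean ± SD of per-run cluster
counts, ⟨m(k)⟩, and the Pearson correlation between reference cluster
sizes and their m(k), per sub-cohort size.

## Atlas outputs

Bodygrams place the K meta-measures at angles 2πi/K clockwise from 12
o'clock with radius = Z-value; the Z = 0 polygon is the cohort
reference. Mean bodygrams average a stratum (the union of disjoint
strata equals their n-weighted mean, exactly). Map stainings aggregate a
per-participant characteristic per body-map unit (mean, mode, or modal
cohort tertile class; tertile boundaries at the empirical 1/3 and 2/3
quantiles with midpoint interpolation, boundary ties to the lower
class). All atlas products are plain tables first; matplotlib rendering
is an optional thin layer, so tests compare numbers, never pixels.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with planted ground truth for recovery tests:

* 13 correlated measure blocks (sizes 27…2, totalling 123) plus 17
  singleton noise measures = 140 raw measures. The 6 high-missingness
  columns are drawn from the singletons, so the three filters reproduce
  a 134 = 123 + 11 surviving split without damaging block structure.
* Participants draw gender (51.4% female), then a body-shape component
  conditional on gender (components 0–1 at 0.9 female affinity, 2–3 at
  0.1), then one latent factor per block from the component's vertex of
  a regular simplex (pairwise vertex distance = `component_separation`,
  default 5 latent-SD units) plus unit-variance noise. Each measure is
  √w·factor + √(1−w)·noise (w = within-block correlation, default 0.8),
  mapped to a measure-specific location/scale, and multiplied by the
  participant's relative body height so height normalization is
  non-trivial.
* Heights and weights are gender-specific normals (men 176 ± 7 cm,
  86 ± 14 kg; women 165 ± 7 cm, 71 ± 14 kg); age is uniform on 40–79;
  waist and hip are affine in designated girth factors so WHR/WHtR vary
  with component.
* Missingness is MCAR at three planted levels: background 0.001 per
  cell (calibrated so ~14% of participants remain incomplete after
  stages 1–2, matching a realistic complete-case loss), 10 near-empty
  participants (rate 0.6) and 6 bad measure columns (rate 0.10). The
  filters are count-based, so MCAR suffices to exercise them.

What the generator does **not** emulate: biomechanical coupling between
measures beyond shared block factors, non-Gaussian marginals, skewed or
age-dependent shape drift, and informative missingness. Passing recovery
tests therefore show that the pipeline finds block/mixture structure of
realistic strength under Gaussian noise — not that real scanner data
has that structure.

## Known limitations

* **Recovery ceiling of the body-type labeler.** Column-Z normalization
  divides each measure by its total SD *including* between-component
  variance, so the standardized separation between planted components
  saturates (≈ 3.3 SD at four balanced components) no matter how large
  `component_separation` is. On such moderately overlapping mixtures
  the watershed labeler misassigns boundary participants (the watershed
  line is displaced by unit-level sampling noise) and tops out at a mean
  recovery ARI ≈ 0.85–0.89 over seeds, while a centroid-based oracle
  (k-means at the true K) reaches ≈ 0.96 on the same meta table. The
  map-based procedure buys interpretability, type atlases and an
  explicit unassigned pool at a measurable cost in boundary accuracy;
  the acceptance suite records this ceiling honestly.
* Quantization error is only approximately monotone under batch updates
  (the exact Lyapunov function is the neighborhood-weighted distortion).
* The three-stage filter is order-dependent by design; permuting stages
  changes survivors (regression-tested on a hand-built fixture).
* Simulation sizes in tests and the acceptance script (n = 2,000,
  30×30/60×60 maps, 10–20 consensus iterations) are desk-scale choices;
  full-cohort analyses (~10⁴ participants, 50×50/130×130 maps, 100
  iterations) use the same code paths with larger settings.
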