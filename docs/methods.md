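# Methods

## Problem and measurement model

A breast imaged in the two standard screening projections (craniocaudal CC,
mediolateral-oblique MLO) is divided into four quadrants — upper-outer (UO),
upper-inner (UI), lower-outer (LO), lower-inner (LI) — and the amount of
dense (fibroglandular) tissue in each is quantified. Per quadrant the
quantities are breast area BA (cm²), dense area DA (cm²) and percent
density PD = 100·DA/BA. The cohort layer asks whether tumors
preferentially occur in the quadrant with the most density, using the
contralateral (tumor-free) breast as a surrogate for the diseased breast
before tumor onset, under an explicit bilateral-symmetry assumption.

## Segmentation

Fuzzy C-means on the 1-D gray-value distribution, objective
`J(U,V) = Σᵢⱼ uᵢⱼᵐ (xⱼ − vᵢ)²` with the standard membership/centroid
updates. Choices:

* fuzzifier `m = 2`, tolerance `1e-5` on the maximum centroid shift,
  `max_iter = 300` — the conventional FCM defaults;
* clusters: 4 for the air/tissue stage, 3 for the within-breast stage
  (fat = lowest centroid, dense = the two higher clusters). Both counts
  are config overrides (`clusters_outer`, `clusters_inner`) for the
  operator workflow in which an unsatisfactory segmentation is re-run with
  adjusted cluster numbers; no automatic adjustment is attempted;
* cluster identity is always by centroid order, never by index, so any
  relabelling of the solver output leaves the tissue masks unchanged;
* initialisation is deterministic: centroids evenly spaced across the
  value range. A quantile-based start was rejected because with heavily
  imbalanced classes (fat is ~90% of breast pixels) all initial centroids
  fall inside the dominant mode and the descent ends in a local optimum
  that splits fat instead of separating dense tissue. `seed` controls an
  optional initial-centroid jitter and the extra starts of the
  `n_restarts` mode (used on tiny, irregular value sets where a single
  descent can stop in a local optimum; image-sized histograms use one
  start). The implementation clusters unique values with multiplicity
  weights — exactly equivalent, and fast for integer-valued images;
* coincident centroids after an update are re-seeded at the midpoint of
  the widest empty gap of the data range (restarting the descent trace);
  a pixel exactly at a centroid receives membership 1 for that cluster;
* segmentation runs on raw intensities; `normalize_intensities` rescales
  to [0, 1] first (FCM on affinely rescaled values gives the same
  partition, so this is cosmetic);
* the breast foreground is the largest non-air connected component with
  holes filled. Degenerate guards: fewer distinct values than clusters, a
  foreground below 0.5% of the frame (a speck is never a breast), or an
  air/tissue centroid separation below 5% of the centroid span all raise
  a degenerate-input error. A breast whose pixels carry fewer than three
  distinct values yields the documented single-tissue fallback: a warning,
  an empty dense mask and a `degenerate` flag.

## Geometry

* Orientation convention: chest wall at the left image edge, superior at
  the top, for both lateralities (right-breast images pre-flipped). The
  CC lateral-half mapping (left breast: lateral above the nipple row) is a
  single config-overridable table.
* Chest-wall tracing (MLO): from the operator seed point P, follow the
  maximum Sobel-gradient column one row at a time within a ±5-column
  window, in both directions; a direction ends when the local gradient
  falls below 30% of the seed gradient. The seed gradient must exceed
  max(4× median image gradient, 0.1% of the maximum gradient) — this
  rejects a seed placed in homogeneous tissue — and fewer than 8 traced
  rows is an error naming the failing row (a real muscle edge spans many
  rows; a short trace means the ridge was lost rather than a wedge ended).
* The traced points are fitted with a cubic smoothing B-spline whose
  smoothing factor is relaxed until the worst residual is ≤ 3 px. The
  *edge line* is the tangent at the curve's arc-length midpoint (a chord
  or least-squares line are plausible alternatives; the midpoint tangent
  is the default because it is local to the straightest part of the
  interface). Outside the traced rows the cut extends linearly along the
  edge-line tangent — the local end tangents are noise-sensitive and can
  fold the cut back into the breast. Pixels on the chest side of the cut
  are removed from the MLO breast mask before tissue classification.
* Bisection: a line through the nipple perpendicular to the chest-wall
  edge (the image edge on CC, the traced edge line on MLO). Pixels are
  classified by their signed offset along the edge direction; the superior
  MLO half is the side containing the superior end of the traced boundary.
  Pixels exactly on the line go to the lateral (CC) / superior (MLO)
  partition, so the two partitions tile the breast mask exactly.
* The nipple is an input landmark throughout (it is operator-defined in
  this workflow); a convenience detector (contour point farthest from the
  chest edge) exists but is not used by any test of record.

## Quadrant combination

UO pairs CC-L with MLO-S, UI pairs CC-M with MLO-S, LO pairs CC-L with
MLO-I, LI pairs CC-M with MLO-I. The default rule is
`Q = (CC_half + MLO_half)/4`: the average of the two contributing halves,
halved again because the breast is counted once per view. Under this rule
`Σ_q BA_q` equals the mean of the two single-view breast areas exactly —
consistent with reference whole-breast values being the sum of the
quadrant means. A `half_sum` mode (`/2`) is kept for sensitivity analysis.
Areas are carried at full precision; display rounding (BA to whole cm², DA
to one decimal, percentages to one decimal, odds to two) happens only in
report formatting. A quadrant with BA = 0 has undefined PD and is excluded
from rank analyses with a logged reason.

## Synthetic data

The phantom generator emulates geometry, not texture. The breast profile
is a half-ellipse attached to the chest edge; MLO views add an oblique
pectoral wedge whose interface with the breast is a straight line (the
analytic slope lets tracing accuracy be asserted exactly). Dense tissue is
hard-edged, non-overlapping disks fully inside the breast, so ground-truth
DA is exact before noise; disks alternate between two intensity sub-levels
(`dense`, `dense + 25`) to emulate heterogeneous fibroglandular tissue —
this also gives the piecewise-constant phantom enough distinct gray levels
for the 4/3-cluster stages at zero noise (`dense_split = 0` collapses
them). Default levels (air 10, fat 100, dense 180, muscle 220 on an 8-bit
scale) and Gaussian noise SD 4 put the noise-to-contrast ratio at 0.05,
the regime in which dense-area recovery is asserted to ≤ 5%. Acquisition
gray-level statistics are otherwise free parameters. PD/BA truncation is
by whole-woman resampling, never clipping, to avoid boundary atoms in
recovery tests. What phantoms do **not** model: anatomical texture,
scattered fibroglandular patterns, compression deformation, skin folds —
so passing tests show the chain is correct on its stated geometry, not
that it is validated on clinical images.

The cohort generator draws, per woman, a tumor quadrant (multinomial), and
per-quadrant BA and PD for both breasts from a Gaussian copula with three
dependence parameters, each fixed once from the reference summary tables:

* bilateral correlation ρ = 0.90 (the reported left-right PD symmetry);
* intra-breast (across-quadrant) correlation: 0.89 for BA and 0.76 for
  PD, from the identity `Var(whole) = Σσ² + ρ·Σ_{i≠j}σᵢσⱼ` applied to the
  whole-breast BA SD (46 cm² against quadrant SDs 15/14/10/9) and the
  whole-breast DA SD (8.8 cm²); PD's own intra correlation is not
  identifiable from marginal summaries and re-uses the DA-level value;
* within-(quadrant, side) PD–BA correlation −0.40: percent density falls
  with breast size. This is the value for which the product DA = PD·BA/100
  reproduces the quadrant DA SDs from the BA and PD marginals, and it
  simultaneously recovers the quadrant DA means via
  `E[DA] = (μ_PD·μ_BA + ρ σ_PD σ_BA)/100`.

The joint draw uses the Kronecker square root `kron(√A, √B)` (so a
bilateral ρ of exactly 1 yields bitwise-equal sides) with the PD z-scores
formed as `r·z_BA + √(1−r²)·e`, the residual field's correlation chosen so
PD keeps its own intra/bilateral structure exactly. Known limit: with the
intra-DA correlation pinned at 0.76 by the whole-breast SD, the simulated
probability that a UO-tumor woman's UO dense area ranks first is ~0.67;
reference data report a higher concentration (~0.81), i.e. the printed
marginals and that rank proportion are not jointly reachable in this model
family. Tests therefore assert the qualitative rank structure (modal rank
r for the r-th quadrant's group), and exact rank proportions are computed
from the printed tables.

## Statistics

* Odds of tumor location in a quadrant: `n/(N−n)`; 95% CI
  `exp(log odds ± 1.96·√(1/n + 1/(N−n)))` (Wald on the log-odds scale,
  which reproduces the reference intervals at display precision). Boundary
  counts fall back to a +0.5 continuity correction, flagged.
* Equality of the four location probabilities: chi-square score test
  against p = ¼ (df = 3); since each woman contributes exactly one tumor
  quadrant, the repeated-measures formulation reduces to this multinomial
  test. Pairwise comparisons condition on the two counts involved
  (binomial z on nᵢ vs nⱼ given nᵢ+nⱼ) with Bonferroni ×6; the
  within-woman paired t-tests are reported unadjusted.
* Ranking: dense descending ranks 1–4, ties broken by the fixed quadrant
  order UO, UI, LO, LI (deterministic; ties are logged implicitly through
  the rule). Cross-tabs count women by tumor group × rank of the tumor
  quadrant's DA or PD in the normal breast.
* Bilateral symmetry: pooled Pearson r over the three non-tumor quadrants
  per woman (diseased vs normal breast PD). The pooled pairs are clustered
  (three per woman) and share quadrant means, so parameter-recovery checks
  use a woman-level effective sample size in the Fisher-z interval, and
  permutation nulls use quadrant-centred values with the clustered
  variance `(1 + (m−1)ρ²)/n_pairs`.

## Problem sizes used by the test and acceptance runs

Unit and acceptance tests use 128–160 px phantoms (20 seeds for recovery
properties), one 512×512 end-to-end pair in the acceptance script, 110 ×
50 replicate cohorts for correlation recovery, and a 10 000-woman cohort
for multinomial recovery; these sizes give comfortable statistical margins
for every asserted tolerance.

## Known limitations

* The chain is validated on geometric phantoms only; no claim is made
  about clinical-image performance.
* The tracing step assumes a single dominant gradient ridge; crossing
  structures (which the phantoms do not generate) could divert it.
* The pairwise-proportion test and the score test are stand-ins for a full
  repeated-measures (GEE-type) formulation, adequate here because each
  woman contributes exactly one tumor location.
* Volumetric density (tomosynthesis/MRI) is out of scope; the measure is
  2-D projected area density.
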