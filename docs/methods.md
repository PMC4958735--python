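# Methods

## Scope and model

The package implements an automated Ki67 scoring protocol for
brightfield TMA-core images and the statistical framework used to
validate such a protocol against visual reference scores.  Because no
patient imagery ships with the package, a synthetic-core generator
provides the study material: it renders cores whose per-nucleus ground
truth is known exactly, so every downstream claim (pixel labelling,
nucleus detection, scoring, QC, agreement statistics) is checked against
an oracle rather than against opinion.

## Synthetic core generator

**Optics.** Stains mix additively in optical density (Beer–Lambert):
each pixel's OD is the sum of stain deposits, and RGB = 255·10^(−OD).
The haematoxylin, eosin and DAB OD vectors are the widely used
Ruifrok–Johnston values shipped with scikit-image; they are calibration
constants of the rendering, not measurements.  Negative nuclei deposit
0.85 OD of haematoxylin; positive nuclei 0.90 DAB + 0.10 haematoxylin
(DAB-positive nuclei retain some counterstain); stroma carries a 0.12 OD
eosin tint with 8 % multiplicative texture.  Per-nucleus intensity has
log-normal noise (σ = 0.12).

**Geometry.** Cores are circular, default diameter 600 µm (real cores
run 0.6–1.0 mm).  Nuclei are anti-aliased ellipses: equivalent diameter
N(8, 1.5²) µm clipped at 3 µm, axis ratio uniform on [1.0, 1.6], random
orientation.  Placement is rejection sampling with a hard cap of 500·n
attempts; nuclei may touch but not overlap more than 30 % of a disc's
area (approximated by the equal-disc lens formula on equivalent
circles), so the watershed splitting step is genuinely exercised.
Pixel calibration defaults to 0.5 µm/px (a 250 µm field is 500 px); it
is stored per image and never assumed downstream.

**Ground truth.** Each core carries a per-nucleus table (centre, class,
diameter) and a pixel label mask (positive / negative / lymphocyte),
which doubles as the oracle for pixel-level classifier tests.  The true
score is 100·pos/(pos+neg); lymphocytes never enter it; blank cores have
an undefined score.

**Artifacts** (all levels ≥ 0, zero = identity):
`background_dab` adds diffuse DAB OD over the tissue; `membrane_dab`
draws DAB rings around a fraction of negative nuclei (membranous
staining); `lymphocyte_count` adds small haematoxylin blobs (4 µm,
strictly below tumour-nucleus size) that are recorded in the truth as
lymphocytes; `fold_fraction` doubles the optical density over a circular
cap of the requested area fraction and darkens it — a minimal model of a
folded core that produces the suboptimal-QC phenotype without modelling
the physics.

**Controls.** A generated TMA appends three flagged control cores:
strongly positive (positive fraction 0.95), negative (0.0) and blank
(no tissue).

## Nucleus classifier

Colour is applied before object detection. Pixels are unmixed into
haematoxylin/eosin/DAB densities (standard OD deconvolution, matrix
configurable) and gated in HSI space per class.  The HSI convention —
the instrument-style one, since the term alone does not fix a formula —
is: hue = hexcone hue in degrees [0, 360) (the DAB range wraps through
0); saturation = 255·(1 − min/mean); intensity = mean channel on 0–255.
A pixel matching both colour classes is resolved by the larger
deconvolved DAB vs haematoxylin density.

Touching nuclei are split by a distance-transform watershed.  Seeds are
regional maxima of the distance map under a (2·d+1)-px maximum filter
with d = spot_width/2; the map is Gaussian-smoothed (σ = d/6) before
seeding so the gentle EDT ridge of an elongated nucleus does not shed
spurious maxima, and seed components whose centroids fall within d px
are merged.  The proprietary "spot" detector this stands in for is
unspecified; the watershed is the declared substitute and the spot
width keeps its role as the separation scale.

Each watershed segment is assigned the majority colour label of its
pixels (ties go to positive, the conservative choice for hot-spot
sensitivity) and kept only if **all** its shape features fall inside
that class's configured ranges:

* width = 2·√(area/π) (µm) — the size gate; its lower bound discards
  lymphocyte-sized blobs;
* compactness = perimeter²/(4π·area), floored at 1;
* roundness = 4·area/(π·major²), capped at 1;
* axis ratio = major/minor, from the eigenvalues of the pixel-coordinate
  covariance (axis length = 4·√eig).

The perimeter estimator is the two-direction Crofton formula
π/4 · (exposed 4-neighbour unit edges), chosen because it is unbiased
for discs and computable for all segments at once with bincount
accumulation (the vendor's exact feature formulas are proprietary;
these definitions are declared stand-ins and numeric equality with any
instrument is not claimed).  Single-pixel or zero-minor-axis segments
are flagged degenerate and dropped.

The bundled universal configuration (`data/universal.yaml`) was
calibrated once against the generator's reference rendering: DAB hue
330–75°, haematoxylin hue 195–292°, saturation/intensity gates that
exclude white background and pale stroma, width 5–16 µm, compactness
≤ 2.5, roundness ≥ 0.35, axis ratio ≤ 2.6, spot width 8 µm.  Per-TMA
tuning is just an alternate YAML with the same schema.

## Quality control

Post-analytical exclusion is literal about its boundaries: totals below
50 are excluded (49 out, 50 in), totals above 15,000 are excluded
(15,000 in, 15,001 out), and a score of exactly 100 % is an exact count
condition (no negative nuclei, at least one positive) — never a
floating-point comparison.  Cores with no detected tissue are excluded
as `no_tissue`.  Control cores are exempt from the 100 % rule (the
strongly positive control is *supposed* to be high) and are checked
separately: positive control ≥ 50 %, negative ≤ 5 %, blank < 50 nuclei.
These two thresholds are package defaults — no published values exist —
and are configurable and echoed into every run log.  Pathologist
annotations map to categories: more than 500 malignant nuclei and no
staining/folding/fixation issues → satisfactory (invasive or DCIS);
otherwise suboptimal; missing annotation → unknown.

## CAV protocol emulation

The grid cells are disjoint 250 µm squares tiling the plane, so no
nucleus can be counted twice (each nucleus belongs to exactly one cell
by floor division of its coordinates).  Field selection is a seeded
draw stratified over grid quadrants around the tissue centroid —
unevenly infiltrating tumour is still covered because every quadrant is
visited in turn.  Empty regions are skipped and replacements drawn
until six occupied fields are read or the grid is exhausted (fewer sets
a low-tissue flag).  The score is the pooled-count percentage over all
counted fields, matching the whole-core definition; a mean-of-field-
percentages mode exists behind a flag for sensitivity analysis only,
because the two readings of the protocol differ and pooled is the one
consistent with "percentage across the entire spectrum of the core".
As coverage approaches the whole grid the pooled score equals the true
score exactly.  One subtlety: on a *fixed* core the average CAV score
over field-selection seeds converges to that realization's field-subset
mean, which differs from the whole-core truth by an O(between-field
variance) offset; unbiasedness is therefore a property over fresh
spatially uniform cores, and that is how it is tested.  A truth-only
generator (`uniform_truth`) supports such protocol-level studies
without rendering.

## Agreement statistics

* **Quartile binning** per method over the analysis set: boundaries are
  the 25/50/75th percentiles (linear interpolation); Q1 < p25,
  p25 ≤ Q2 ≤ p50, p50 < Q3 ≤ p75, Q4 > p75, so a value exactly on a
  printed boundary goes to the bin whose interval notation contains it.
  A pooled-vs-per-stratum boundary toggle exists; pooled is the
  default.
* **Linearly weighted kappa**: w_ij = 1 − |i−j|/(K−1);
  κ = (Σw·p_ij − Σw·p_i·q_j)/(1 − Σw·p_i·q_j).  At K = 2 it equals
  unweighted Cohen kappa (verified against scikit-learn).  CIs are
  seeded percentile bootstraps (2,000 resamples); the kappa-comparison
  test between independent strata is a two-sided z-test on the
  bootstrap SEs — the test used for such comparisons is not
  standardized, so the method is recorded in every report and numeric
  equality with any published comparison p-value is not claimed.
* **AUC**: Mann–Whitney probability with half credit for ties
  (scikit-learn point estimate, verified against an O(n²) oracle);
  variance and the paired two-scorer test by DeLong (implemented here —
  no pre-installed package provides it).  Visual scores are
  dichotomized at the conventional 10 % cut-off, inclusive (≥ 10 % is
  positive).
* **Count bins**: 50–500, then 500-wide bins to 4,500, then >4,500
  pooled; totals under 50 are a contract violation (QC should have
  removed them).  The count-agreement trend is the Pearson correlation
  of bin mean count with the bin metric, two-sided t-test.
* **Extreme discrepancy**: rate of Q1↔Q4 flips.
* **Subject scores**: arithmetic mean over QC-passing cores; subjects
  with no passing core are dropped and counted.

## Study harnesses and sizes

`ki67tma.experiments` packages two end-to-end studies used by the test
suite and the reproduction script.

**Recovery study** (default 200 cores): clean cores, 500–5,000 nuclei,
true fractions uniform on 0–50 %.  These cores use a 1.0 mm diameter —
the top of the standard core-size range — because 5,000 nuclei of 8 µm
cannot be placed in a 0.6 mm core under the 30 % overlap cap, and
1 µm/px rendering, which keeps the full study tractable on a laptop
while leaving nuclei 8 px wide.  Typical results: mean absolute score
error around one percentage point, AUC ≈ 1 against the truth dichotomy,
automated-vs-CAV quartile kappa ≈ 0.9.

**Stratification study** (default 80 cores, 30 % artifacted): the
artifacted subset receives strong background DAB (0.25 OD), membranous
DAB on 40 % of negative nuclei, 150 lymphocytes and a 15 % fold — the
reported drivers of visual/automated discrepancy — and is annotated
suboptimal.  Artifacts both inflate the automated score and depress the
detected count, so the suboptimal stratum shows lower kappa and the
500-cell count bins show agreement rising with count, reproducing the
directional behaviour of real cores.  Smaller (600 µm) cores with
100–2,500 nuclei keep replicates cheap enough to run twenty of them in
a test session.

**What the generator does not model** — and therefore what passing
tests do not establish about clinical material: benign ductal
epithelium (no benign-vs-malignant discrimination is attempted beyond
size/shape gates), stromal cell populations, chromatin texture,
out-of-focus regions, scanner colour variation between instruments, and
DCIS architecture.  The synthetic studies validate the machinery —
colour/shape classification, splitting, QC logic, statistics — not
clinical accuracy on patient tissue.

## Numerical choices and edge cases

* Determinism: every stochastic step takes an explicit seed;
  per-core seeds are derived from the study seed via `SeedSequence`,
  so one integer reproduces an entire TMA bit-for-bit.
* Undefined scores (blank cores) are `None` in memory and empty fields
  in CSV — never 0.
* Degenerate statistics fail loudly: single-class labels refuse an AUC,
  all-equal score vectors warn and collapse to one quartile bin,
  kappa comparison refuses strata under 10 pairs, trend correlation
  refuses fewer than 3 bins and flags a constant metric.
* The pixel-both-classes tie-break (deconvolved density argmax) and the
  segment class tie-break (ties → positive) are fixed and documented
  rather than configurable, to keep scores comparable across runs.

## Known limitations

Shape-feature values are estimator-specific (Crofton perimeter,
moment-based axes); configs tuned for another feature implementation
need re-tuning.  The watershed stands in for an unspecified proprietary
detector.  Overlap control during placement uses equivalent circles,
so highly elongated nuclei can overlap slightly more than the nominal
cap.  CAV emulation counts ground-truth nuclei perfectly within a
field; it models the protocol's sampling, not human counting error.
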