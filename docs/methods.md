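# Methods

## The density-histogram model of structural lung disease

A healthy, inspiratory adult lung is mostly air-filled parenchyma, so its
CT density histogram shows a sharp peak near −850 HU with a long right
tail contributed by pulmonary vessels (soft tissue, ≈ +30 HU, partial
volume spreading them over a wide range). Structural disease of the
bronchiectasis spectrum — bronchial wall thickening, mucus plugging,
consolidation, atelectasis — replaces aerated parenchyma with mid-density
material, adding mass between roughly −400 and +50 HU. This has two
measurable consequences:

1. the histogram **scatters** (SD rises) and **flattens** (kurtosis
   falls), and its asymmetry changes (skewness falls as the right tail
   gains mass relative to the peak);
2. the fraction of lung at or above any threshold in the mid-density
   range rises.

The CT-density score operationalizes (2): `score(t)` is the percentage of
lung voxels with HU ≥ t (inclusive, so a voxel exactly at threshold
counts). Scores are always computed from raw voxel values, never from
binned counts, so no bin-edge artifact can move mass across the threshold.

## Thresholds: fixed vs histogram-adapted

Lung attenuation also moves with nuisance factors, chiefly inspiration
level: a lower inspiration shifts the histogram toward higher HU and
spreads it. We model this as an affine map of lung densities about their
mean, `v → MLD + a·(v − MLD) + Δ`. A fixed threshold then counts nuisance
mass as disease. An adapted threshold `base + offset + k·SD` (base = MLD
or Mode) moves with the histogram. Exactness under the affine map:

* `MLD + k·SD` transforms identically with the data, so its score is
  **exactly** invariant (bit-identical in the tests);
* `Mode + k·SD` is invariant up to the 1-HU binning of the mode (observed
  deviations ≤ 0.01 percentage points on phantoms);
* `base + offset` forms are invariant under pure shifts only — an HU
  offset does not scale with the histogram, which is a genuine limitation
  of offset-adapted thresholds, not an implementation artifact.

The default suite evaluates fixed {−300, −400, −500, −600} HU and adapted
{MLD+2SD, MLD+1SD, Mode+500, Mode+400, Mode+300, Mode+3SD, Mode+2SD,
Mode+1SD}. MLD + 1·SD is flagged as the reference threshold (best
spirometry correlate among the suite).

## Histogram characteristics

MLD is the arithmetic mean of masked HU; SD is the **population**
(divide-by-n) standard deviation — with 10⁵–10⁷ lung voxels the n vs n−1
distinction is negligible and the population convention matches the
closed-form moment identities used as test oracles. Skewness and kurtosis
are the third and fourth standardized central moments; the kurtosis
convention is configurable (`excess` by default, i.e. Gaussian = 0;
`non_excess` Gaussian = 3) because published values of "kurtosis" from
commercial densitometry software rarely state theirs. The mode is the
center of the highest-count bin of a 1-HU histogram whose edges are
aligned to integer multiples of the bin width (half-open `[lo, hi)`
bins); ties break toward the lowest HU so the statistic is deterministic.
A constant region has SD = 0 and skewness/kurtosis are reported as
undefined (`None` with a `moments_defined` flag), never as a silent 0.

## Segmentation and regional split

Lung extraction is a deterministic threshold-and-morphology chain: air
below −320 HU → discard components touching the in-plane volume border
(outside air) → keep up to the two largest components ≥ 200 mL → optional
coarse trachea removal (narrow cranial air column near the midline,
region-grown caudally while its cross-section stays < 400 mm²) →
slice-wise 2-D hole filling (recovers vessels/lesions enclosed by lung) →
3-D morphological closing (2 mm). A single fused component is split at the
midsagittal plane of the body bounding box. On phantoms this recovers the
true lung mask with Dice ≥ 0.95 and volume within 10 %.

The upper/lower split defaults to an axial-fraction rule: per lung, whole
axial slices are assigned cranially until 50 % of that lung's voxels lie
above the cut, choosing the boundary slice that best balances the target
(imbalance < one slice). When a lobe label map exists, the anatomical
grouping is used instead: upper lungs = right upper lobe + upper part of
the left upper lobe; lower lungs = middle lobe, lingula and both lower
lobes. For regional scores the threshold is resolved **once from
whole-lung features**, so upper-vs-lower contrasts reflect regional
disease rather than regional histogram shifts, and the whole-lung score
is exactly the voxel-count-weighted mean of the regional scores.

## Cohort statistics

* **Spearman** via midrank Pearson correlation; p from the t
  approximation (adequate at cohort sizes of tens), with an exact
  permutation option for n ≤ 10 used to validate the approximation.
  Correlation magnitudes are banded |R| < 0.40 absent-to-weak, 0.40–0.59
  moderate, 0.60–0.79 good, ≥ 0.80 strong.
* **Wilcoxon signed-rank** (two-sided, zero differences discarded): exact
  p for n ≤ 25 without ties; exhaustive 2ⁿ sign enumeration with midranks
  for tied samples up to n = 15; normal approximation with tie correction
  otherwise.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  rater — from the ANOVA mean squares; undefined (flagged) only when both
  subject and residual variance vanish. This form fits the design of two
  fixed raters scoring the same scans; other forms can be obtained from
  the same mean squares.
* **Bland–Altman**: bias = mean(a−b), limits bias ± 1.96·SD with the
  sample (n−1) SD, per-pair plot data exported.
* **Visual subscore aggregation**: the nine-category rubric lives in
  configuration (categories and admissible ranges), not code; the default
  total is the plain sum (severity-increasing, 0 = normal scan). The
  classic offset-minus-sum presentation is an affine relabeling and
  changes no rank-based statistic.

## The phantom generator

The generator emulates the *statistical* structure the method relies on,
not anatomy: a +40 HU body ellipsoid in −1000 HU air; two lung ellipsoids
with parenchymal voxels ~ N(−850, 60) HU; vessel-like random tubes
(radius 1–3 voxels, length 20–60 mm) at N(+30, 25) HU filling 3 % of the
lung — the spread keeps the histogram mode at the parenchymal peak, as
partial volume does in real lungs; and lesion blobs (spheres, radius 2–5
voxels) at N(−150, 100) HU **replacing** parenchymal voxels so lung
volume is conserved and the recorded lesion fraction *f* is an exact
voxel count. Each blob is assigned to the caudal or cranial lung half
with probability `lesion_lower_bias` and clipped to its side, so the bias
parameter is the expected caudal share of lesion volume. Inspiration
level is applied as the affine transform above. All randomness flows from
one seed; outputs are bit-reproducible.

Default grid: 96³ voxels at 2.5 mm (≈ 2.7 L lungs, ≈ 10⁵ lung voxels).
The test suite mostly uses 64³/48³ grids, which keep every histogram
statistic stable to well below the tolerances asserted. Cohorts pair each
phantom with surrogate spirometry `FEV1, FVC = 100 − 300·f + N(0, 5)`
clamped to (0, 130] %predicted, encoding the assumption that structural
burden degrades lung function linearly up to noise.

**What the phantoms do not model** — and hence what passing tests do not
show about patient data: anatomical airway/fissure geometry, scanner
reconstruction kernels and beam hardening, breathing motion, emphysematous
low-density disease, and between-patient variation in body habitus or
acquisition protocol. On phantoms the score–spirometry Spearman
correlation is ≈ −0.9 because the only nuisance is the injected Gaussian
noise; patient cohorts carry far more unexplained variance, so
correlations of −0.6 to −0.7 are the realistic regime the interpretation
bands are designed for.

## Numerical choices and edge cases

* Volumes are float arrays in HU; DICOM stored values are rescaled with
  per-slice slope/intercept, slices sorted by position along the slice
  normal; mixed series and missing rescale tags are hard errors. Values
  below −1024 HU are logged but retained (no clipping by default).
* Masks must match their volume's grid within 10⁻³ mm spacing tolerance.
* Score comparison is `>=` (inclusive) by definition.
* Degenerate inputs raise typed errors (no body, no lung component ≥ the
  minimum volume, empty region, constant vector, all-zero differences)
  rather than returning sentinel numbers; the CLI maps error categories
  to exit codes (2 I/O, 3 validation, 4 segmentation).
* Scores are reported to 2 decimals in CSV output; tests compare at full
  precision.

## Known limitations

Pulmonary vessels are counted in the high-attenuating volume, so the
score floor is the vessel fraction rather than zero; vessel exclusion
would require vessel segmentation, which is out of scope. The axial
50 %-fraction regional split is a surrogate for lobar anatomy when no
lobe map is available. Trachea removal is a coarse heuristic tuned for
a visible cranial airway column and is a no-op on phantoms, which have
no airways.
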