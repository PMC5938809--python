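# Methods

## Tissue model and thresholding

A masked ROI on a T2-weighted axial slice is modelled as a two-component
intensity mixture: a dark muscle population and a bright fat population,
each approximately Gaussian. The ROI histogram (64 equal-width bins over
the masked min–max range by default; right-most bin closed, others
half-open) is fitted by nonlinear least squares with the model

    counts(x) ≈ Δ · [ w_m φ(x; μ_m, σ_m) + w_f φ(x; μ_f, σ_f) ]

where Δ is the bin width, φ the Gaussian density, and the weights w are
pixel masses. Fitting the *binned* histogram rather than running EM on raw
pixels keeps the estimator tied to the object the threshold is defined on
and damps single-pixel tails. The optimizer (bounded Levenberg–Marquardt /
trust-region via `scipy.optimize.curve_fit`) is started from moments of
the histogram split at its Otsu threshold; if that fails, a second start
uses the 25th/75th weighted-percentile split. Components are sorted so fat
is always the higher-mean component.

The fat/muscle threshold is the intensity where the two weighted component
densities are equal, strictly between the means. Equating log-densities
gives a quadratic with closed-form roots (linear when the sds are equal);
if no root lies between the means — possible under extreme weight
imbalance — the midpoint of the means is used and flagged. Pixels strictly
above the threshold are fat; pixels at or below are muscle (ties to
muscle, since only values *above* the intersection count as fat).

Degenerate inputs: a constant-intensity ROI raises a histogram error. A
fit whose means sit closer than 0.5 × the wider sd carries an overlap
warning — the two-component model is not resolving two tissues. If, in
addition, the bright component holds under 1 % of the pixel mass, the ROI
is read as fat-free (FSF 0, flagged). A truly single-tissue ROI whose
symmetric mass splits between two overlapping components keeps its overlap
warning rather than silently yielding a confident split; callers should
treat flagged fits as unreliable. These cases sit outside the validated
regime (see below), which requires visibly bimodal histograms.

Thresholds are computed per ROI (per muscle/side/rater/method), because
each traced region has its own intensity makeup; an optional mode pools
one subject's masks into a single histogram.

## Composition measures

With n_fat and n_muscle the classified counts and A_px the physical pixel
area (row_mm × col_mm): tCSA = (n_fat + n_muscle)·A_px,
FSF = n_fat/(n_fat + n_muscle), fCSA = tCSA·FSF, mCSA = tCSA − fCSA,
computed in exactly that order so mCSA + fCSA = tCSA holds to the last
bit. Each pixel is wholly fat or wholly muscle — the hard threshold admits
no partial volume. Both the pixel count and the mm² value of tCSA are
reported, so the area scale is never ambiguous.

## Agreement statistics

**Area fraction overlap.** Pixels foreground in *all* raters' masks over
pixels foreground in *any* mask. The denominator is implemented as the
union: a multiplicity-weighted sum would not pair coherently with an
all-raters numerator and would leave the statistic's range
scale-dependent, whereas the union keeps it in [0, 1]. An empty union
returns 0 with a flag.

**ICC(A,k).** From the two-way crossed ANOVA mean squares (subjects ×
raters, no replicates): ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n).
This is the absolute-agreement, average-of-k-raters coefficient; its point
estimate is identical under two-way random and two-way mixed models, so
one estimator serves the "2-way mixed, absolute agreement, mean of k"
specification. The 95 % CI is the McGraw & Wong (1996) construction: an F
interval for the single-rater coefficient with Satterthwaite degrees of
freedom, stepped up to k raters through the Spearman–Brown relation. A
grid with zero subject variance is flagged degenerate and reported as
computed (the estimate may be ≤ 0). Interpretation uses the Cicchetti
bands with 0.75 itself classed as excellent (the published band edges
"0.60–0.74 good" and "> 0.75 excellent" leave the boundary to the
implementer; closing the excellent band at 0.75 keeps the bands
exhaustive).

**Between-rater CV.** Sample (n−1) standard deviation across raters over
their mean; undefined (flagged, NaN) for non-positive means.

## Study-level analysis

Method 1 vs method 2 is tested per measure × muscle × side with two-sided
paired t-tests on per-subject values, raters averaged first (a per-rater
sensitivity mode exists); the same contrast runs on the overlap fractions.
A pair set with zero difference variance is flagged degenerate (t = 0,
p = 1 when all differences are zero). CV-vs-measure trends are ordinary
least squares of CV on the rater-mean measure value per
measure × muscle × side × method cell (≥ 3 defined points; constant
predictors flagged). No multiple-testing correction is applied; p-values
are reported raw, cell by cell. Descriptives are mean ± sd.

## The synthetic phantom

Each phantom emulates one muscle compartment on a 256 × 256 grid at 1 mm
isotropic spacing (both configurable):

* **Compartment** — an ellipse (axes ≈ 0.2 × grid) with smooth angular
  wobble; a single connected blob of ~8–14 k pixels.
* **Fatty infiltration** — exactly `round(true_fsf · area)` compartment
  pixels, chosen as the top-k values of a Gaussian random field smoothed
  at a 3-px correlation length. Thresholding a correlated field yields
  clustered patches like real infiltration (not i.i.d. salt-and-pepper),
  while the top-k rule hits the target fraction to rounding precision.
* **Epimuscular tent** — `round(tent_area_fraction · area)` pixels hugging
  the compartment's inferior/posterior boundary arc, all fat, disjoint
  from the compartment. Method-2 truth is the compartment; method-1 truth
  is compartment ∪ tent, so true FSF under method 1 always ≥ method 2,
  with equality iff the tent is empty.
* **Intensities** — muscle ~ N(100, 20), fat ~ N(300, 30) in arbitrary
  units, clipped at 0 (a negligible truncation at these parameters: the
  muscle mode sits 5 sd above zero). The surround outside compartment and
  tent is drawn from the muscle distribution, so ROIs that spill over a
  perturbed boundary still see a two-tissue histogram — the phantom does
  not model other organs, bone, or air.

**Grade presets** span the clinical none/moderate/severe spectrum:
grade 0 → FSF 0.05, tent 0; grade 1 → FSF 0.30, tent 0.10; grade 2 →
FSF 0.60, tent 0.25. These are package conventions — the visual grading
scale they emulate assigns no numeric fat fraction — chosen to bracket the
fat fractions typical of surgical low-back-pain cohorts.

**Simulated raters** perturb each truth boundary with a smooth random
field: the signed distance to the boundary is compared against a Gaussian
field with 8-px correlation length scaled to `boundary_sd_px` (default
2 px). This mimics a tracer's smooth over/under-shoot along arcs rather
than pixel jitter. Zero noise reproduces the truth masks exactly; a
perturbation that empties a mask is retried from a fresh sub-seed (10
attempts). Each rater's method-1 mask is that rater's perturbed
compartment united with an independently perturbed tent, so the two
methods share the rater's epimysial trace, as they would in practice.

**Score tables** for ICC validation are drawn from the two-way crossed
model score(i,j) = μ + s_i + r_j + e_ij with independent normal
components; the implied ICC(A,k) = σ_s² / (σ_s² + (σ_r² + σ_e²)/k) is
attached as metadata. Defaults (n = 37 subjects, k = 3 raters, σ_s = 1,
σ_r = 0.2, σ_e = 0.5) match a single-center reliability study's shape with
moderate rater offsets.

**What the phantom does not emulate** — and hence what passing tests do
not show about patient data: MRI bias fields and coil shading, partial
volume at tissue borders, Rician noise, anatomically realistic muscle
shapes, inter-subject anatomy correlation between sides, and human raters'
systematic (non-random) disagreements about fascial boundaries. Phantom
between-rater CVs are accordingly smaller than those of human raters on
real images; the pipeline's *directional* results (tent inclusion raising
tCSA and FSF; excellent ICC under small boundary noise) are the
transferable findings.

## Default cohort

The pipeline's default cohort (20 subjects, grades cycled 0/1/2, both
muscles, both sides, 3 raters, 2-px noise) gives the erector spinae its
preset tent and the multifidus none (`tent_scale = {multifidus: 0,
erector_spinae: 1}`). This reflects the anatomy in which the method
contrast concentrates in the erector spinae, and produces the expected
pattern: significant method-1 > method-2 differences in erector spinae
tCSA and FSF, and no FSF difference in the tent-free multifidus.

## Numerical choices and problem sizes

* Histogram: 64 bins; fit bounds keep sds in [bin width/10, 2 × range]
  and means within one range-width of the data.
* Closed-form intersection validated against a 10⁻⁴-step brute-force
  density scan (agreement to 10⁻³).
* ICC estimator validated against an explicit-loop ANOVA oracle (10⁻¹⁰)
  and, in the test extra, cross-checked against `pingouin`'s ICC(A,k).
* Validation sizes — 100 seeds per fat-fraction level for recovery, 200
  simulated tables for estimator recovery, 1000 for interval coverage,
  20-subject cohorts for the end-to-end directions — are chosen so each
  check's Monte-Carlo error is well below the tolerance it enforces while
  the whole suite stays desk-scale.

## Known limitations

* The two-component model cannot represent a third tissue (e.g. bone
  marrow inside an ROI) and will fold it into the nearest component.
* FSF recovery is validated for well-separated tissues (≥ 4 sd between
  modes) and fat fractions in [0.05, 0.7]; very low-fat ROIs route
  through the flagged no-fat/overlap path rather than a calibrated
  estimate.
* Masks must share the image grid exactly; no resampling is offered.
* The ICC assumes a complete subjects × raters grid; missing cells are an
  error, not an estimation problem.
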