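# paraspinal

Quantification of lumbar paraspinal muscle composition from axial MRI, and
the inter-rater reliability of the region-of-interest (ROI) definitions
used to measure it.

## The problem

Fatty infiltration of the multifidus and erector spinae muscles, measured
on axial T2-weighted MRI at the mid-lumbar level, is a widely used marker
of muscle quality in low-back-pain research. Two ROI conventions coexist:

* **Method 1** bounds the ROI posteriorly at the lumbosacral fascia, so it
  *includes* the epimuscular fat "tent" that can accumulate between the
  fascia and the muscle;
* **Method 2** bounds the ROI at the visible epimysial muscle border, so
  it *excludes* that tent.

The choice systematically shifts every downstream measure, and multiple
human raters tracing the same muscle never agree exactly. This package
implements the full measurement and reliability pipeline — and, because
patient images cannot be redistributed, a synthetic phantom generator that
produces images with *known* composition so every stage can be validated
against ground truth.

## The measurements

Pixels inside an ROI are classified as fat or muscle by fitting a two-term
Gaussian model to the ROI intensity histogram and thresholding at the
intersection of the two fitted densities (fat is the brighter component on
T2). From the fat/muscle counts and the pixel area:

* tCSA = (n_fat + n_muscle) · pixel_area — total cross-sectional area
* FSF = n_fat / (n_fat + n_muscle) — fat signal fraction
* mCSA = tCSA − tCSA · FSF, fCSA = tCSA · FSF

Agreement between raters is summarized by:

* **area fraction overlap** — pixels common to *all* raters' masks divided
  by the union of their masks;
* **ICC(A,k)** — intraclass correlation for absolute agreement of the mean
  of k raters, from two-way ANOVA mean squares, with the F-based 95 % CI
  and Cicchetti interpretation bands (< 0.40 poor, 0.40–0.59 fair,
  0.60–0.74 good, ≥ 0.75 excellent);
* **between-rater CV** — sd across raters over their mean, per measurement.

Study-level comparisons pair method 1 against method 2 with two-sided
paired t-tests (rater means per subject) and regress the between-rater CV
on each measure by ordinary least squares.

## Worked example

```python
import paraspinal as pp

# a moderate-infiltration phantom: true in-compartment FSF 0.30,
# epimuscular tent = 10 % of the compartment area
spec = pp.preset_for_grade(1, seed=7)
image, truth = pp.generate_phantom(spec)
masks = pp.simulate_rater_masks(
    truth, pp.RaterSimParams(n_raters=3, boundary_sd_px=2.0, seed=11),
    subject_id="s001")

m = next(m for m in masks if m.method == 2 and m.rater_id == "r1")
pair, labels = pp.segment_roi(image, m)
comp = pp.compute_composition(labels, image.pixel_spacing, roi_labels=m.labels)
```

Formatting those results prints:

```
muscle mode  : mean   100.1  sd  20.3
fat mode     : mean   300.7  sd  30.4
threshold    :   184.3
tCSA         : 11910.0 mm^2 (11910 px)
FSF          :   0.300   (true method-2 FSF 0.300)
mCSA / fCSA  :  8337.0 / 3573.0 mm^2
3-rater area fraction overlap (method 2): 0.922
```

The fitted modes recover the generating tissue distributions
(muscle ≈ N(100, 20), fat ≈ N(300, 30)); the threshold 184.3 sits at their
density intersection, and the estimated FSF of rater 1's perturbed ROI
matches the generative truth to three decimals. The overlap of 0.922 is
the fraction of the three raters' union covered by all three masks under
2-px boundary noise.

The same stages are available from the shell:

```sh
paraspinal simulate-cohort --n-subjects 5 --grade 1 --seed 0 --out cohort/
paraspinal quantify --image cohort/s000.nii \
    --mask cohort/s000_erector_spinae_left_r1_2.nii --out measures.csv
paraspinal agree --scores scores.csv
paraspinal report --config config.json --out report/
```

`report` reads a JSON configuration whose keys mirror
`paraspinal.CohortConfig`: `n_subjects`, `grades`, `muscles`, `sides`,
`tent_scale`, `n_raters`, `boundary_sd_px`, `grid_shape`,
`pixel_spacing`, `n_bins`, `seed`.

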