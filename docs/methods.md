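# Methods

`cervimage` quantifies the structure of stratified squamous epithelium
(the ectocervical/vaginal barrier tissue) in multi-channel
immunofluorescence sections, together with the microbiome- and
statistics-side analyses that typically accompany such measurements in
mucosal-immunology studies. This note records the model behind each
stage, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Thickness from operator-drawn boundaries

The analysis is anchored on three manually drawn polylines per image:
the basal membrane, the apical end of the E-cadherin-expressing layer,
and the last (most superficial) epithelial cell layer, plus a closed ROI
polygon outlining the epithelium. Automatic boundary detection is
deliberately out of scope: in real sections the basal membrane is drawn
by an operator, and the package treats those annotations as input.

Coordinates are 0-based `(x, y) = (column, row)` with the origin at the
top-left; pixel centers sit at integer coordinates. Polylines are
rasterized with per-segment Bresenham traversal, giving an 8-connected
pixel path; a pixel whose center lies on the line has depth 0
(half-pixel center convention). Depth maps are exact Euclidean distance
transforms (scipy's EDT) to the rasterized line, scaled by the physical
pixel size, and are defined only on epithelium pixels. The ROI mask
contains every pixel whose center falls inside the polygon.

Per-point thicknesses are nearest-neighbour distances between rasterized
boundary pixels: apical→basal (total), apical→E-cadherin boundary
(E-cadherin-negative, i.e. superficial layer), E-cadherin
boundary→basal (E-cadherin-positive layer). Each list is summarized per
image by the **median** (mean available via configuration): the median
is robust to digitization spikes at polyline ends, and nothing in the
measurement model prefers the mean. Because the three boundaries are
measured independently, `total` is not forced to equal `pos + neg`; on
near-parallel boundaries the additivity gap stays within ~2 pixel
widths, and this is asserted as a property rather than imposed.

Per-participant values pool multiple images/ROIs by an **area-weighted
mean** of image-level values, so a large section outweighs a sliver.

Degenerate cases: an E-cadherin boundary coincident with the apical line
yields a zero-thickness superficial layer (allowed, not an error); a
polyline with fewer than two vertices, an out-of-bounds vertex (reported
with its index), or a zero-area ROI polygon are errors.

## Depth segments and marker quantification

The epithelium is segmented by depth from the apical border:
the most apical 10 µm are excluded (surface autofluorescence), the rest
is cut into 50 µm half-open segments `[10,50), [50,100), …, [250,300)`,
and everything deeper than 300 µm forms one terminal segment
`[300, ∞)`. All three numbers are configurable (`bin_width_um`,
`apical_exclusion_um`, `cap_um`, with the cap a multiple of the width);
the defaults are the scheme the package is built around. Bin labels:
`-1` outside the epithelium, `0` the excluded margin, `1..K` the regular
segments, `K+1` terminal.

Marker positivity is **pixel-based**, not object-based — appropriate for
immune cells with irregular morphology, where segmentation into cells is
unreliable. The threshold is image-dependent, computed from
epithelium-restricted intensities only; the default method is **Otsu**
(the classic image-dependent threshold), with `percentile` and `fixed`
alternatives. The chosen threshold is always recorded in the output for
provenance. A constant channel makes Otsu undefined: the mask is then
all-negative and a warning is logged. Double positives are the pixelwise
conjunction of two thresholded masks; no colocalization statistics
beyond conjunction are attempted.

Fractions are `100 × positive px / epithelium px` with two denominators
reported: per segment (that segment's epithelium area; segments with
zero area are *missing*, not zero) and overall. The overall fraction
uses the **full ROI** as denominator ("total tissue area"), which makes
it independent of the binning scheme; the margin-excluded overall value
is reported alongside (`included_pct`) because the per-segment panels
cover only that region. Whether per-segment denominators should instead
be the total epithelium area is genuinely ambiguous in this kind of
analysis; per-segment area is used because segments differ in area by
construction — this choice is flagged here rather than silently assumed.

Markers stained in separate acquisitions (e.g. CD4 restained alongside
a second marker on a different day) are treated as separate channels and
never merged.

## Cervicotype classification

Genus-level relative abundances — with *Lactobacillus* split into
*L. iners* and non-*iners* — are classified into four community classes:
CT1 (*Lactobacillus* non-*iners* dominant), CT2 (*L. iners* dominant),
CT3 (*Gardnerella* dominant), CT4 (high diversity / anything else). A
sample is "dominant" when the argmax taxon is one of the three named
ones **and** its relative abundance reaches the dominance threshold,
default **0.5**. The 0.5 default expresses the dominant-vs-diverse
dichotomy; it is a package default, not a claim about any particular
published threshold, and is configurable. Ties at the maximum are broken
by the fixed priority (non-*iners*, *iners*, *Gardnerella*) and logged.
Compositions are renormalized internally, so the rule is
scale-invariant. Upstream 16S processing (ASV inference, taxonomy
assignment) is out of scope; the module starts from a table.

Group frequency tables report integer-rounded percentages with group
sizes as denominators; raw counts are available separately so the
rounding is auditable.

## Statistics

* **Quartiles**: linear interpolation between order statistics
  (`numpy.percentile`, method `"linear"`). Different packages
  (e.g. GraphPad) use different quartile conventions; the rule used here
  is fixed and stated.
* **Mann–Whitney U**: two-sided; exact permutation null for pooled
  n ≤ 12 without ties, otherwise the tie-corrected normal approximation
  *without* continuity correction — so two identical groups give exactly
  p = 1. The method used is recorded per result.
* **Normality-gated comparison**: Shapiro–Wilk per group at α = 0.05
  (the gate test is configurable in principle; Shapiro–Wilk is the
  default choice), pooled-variance t-test when both groups pass,
  Mann–Whitney otherwise; the routing decision is recorded.
* **Fisher's exact test**: two-sided by summing hypergeometric
  probabilities ≤ the observed table's; the odds ratio reported is the
  sample (cross-product) estimate, NaN when undefined; a zero margin
  gives p = 1 with a missing odds ratio.
* **Detection limits**: censored values are excluded from level
  comparisons and counted instead — above/below-limit flags per group go
  into a 2×2 Fisher test.
* **Cytokine concentrations** are log10-transformed before testing;
  note rank tests are invariant to this (asserted in the tests).
* **Age checks** are OLS slope with the two-sided p for slope = 0.
* **Luteal phase**: plasma progesterone strictly greater than
  1.2 ng/mL.
* **No multiple-testing correction** is applied anywhere in this
  battery; results are reported per comparison, and any correction is
  the caller's responsibility.

Tests are refused (with a message) below 3 observations per group;
descriptive summaries only need 1.

## The phantom generator

`generate_phantom` builds a multi-channel image whose ground truth is
known exactly, emulating: a curved epithelial band (apical surface a
sinusoid; basal membrane and E-cadherin boundary **normal-offset**
curves of it, so the true normal thickness is exactly the nominal value
even for curved geometry); an E-cadherin channel bright below the
boundary; marker channels with star-convex blobs (radius 3–8 px,
irregularity 0.3) Poisson-placed per depth segment to hit target
per-segment area fractions; double positives planted by duplicating
first-marker blobs into later channels with a configurable probability
(default 0.35); Gaussian background noise (SD 4 on background 10,
clipped at 0) and a +30% autofluorescence strip over the apical 10 µm —
present precisely so that the apical exclusion rule has something to
exclude.

Defaults describe the tissue scale the pipeline is meant for: ~1.5 mm²
of epithelium (2500×220 px at 2 µm/px), 300 µm total thickness, 45 µm
E-cadherin-negative layer, overall marker area fractions of ~1–3%.

Truth fractions are defined by **recounting the planted masks**, not by
the target densities: blob placement is Poisson, so realized area
differs from the target by sampling noise, but the truth tables are
exact for the phantom actually generated. Pipeline-vs-truth comparisons
therefore measure segmentation and binning fidelity, which is the
property under test.

What the phantoms do **not** emulate: point-spread blur, chromatic
aberration, uneven illumination, slide-scanner tile seams, nuclei
texture in DAPI, intensity gradients within cells, or annotation error
in the boundary lines. Passing the recovery battery shows the
measurement chain is correct on well-posed input; it does not show
robustness to stain quality or operator variability on real slides.

Generators are pure functions of spec + seed (bit-exact), with separate
spawned substreams for geometry, cells and noise, in that order, so
partial regeneration is stable.

`generate_abundance_tables` draws each intended dominant abundance
uniformly in (threshold + 0.02, 0.97) with the remaining mass
Dirichlet-spread (concentration 0.8) over seven other genera typical of
cervicovaginal communities; CT4 samples are flat-Dirichlet draws
rejected until the maximum falls below the threshold.
`generate_grouped_measurements` draws normal (or log10-normal) values at
a configurable location/scale (defaults: location 12, scale 8 —
regulatory-T-cell-percentage scale) with an optional location shift for
group A and detection-limit flags.

## Problem sizes used in the verification battery

The test suite and `scripts/acceptance.py` use: 50 random ≤64×64
instances for the distance-transform/brute-force comparison; a thickness
battery of 100–400 µm at 500×280 px, parallel and sinusoidal, a few
seeds each; 3–5 standard ~1.5 mm² phantoms for fraction recovery; 1,000
null replicates at n = 20/20 for the type-I-error check; and 1,000
constructed compositions for classifier recovery. These sizes make every
property estimate stable to well inside the asserted tolerances while
keeping a full run to a few minutes on one CPU.

## Known limitations

* Thickness is nearest-distance between rasterized polylines; for
  strongly non-parallel boundaries "thickness" is direction-dependent
  and the nearest-distance convention is one defensible choice.
* Otsu assumes a bimodal intensity distribution within the ROI; a
  marker with near-zero positive area degrades to thresholding noise —
  the percentile/fixed methods exist for that regime.
* Integer-rounded percentage tables can sum to 99–101.
* The exact Mann–Whitney path handles no ties; tied small samples fall
  back to the asymptotic tie-corrected form.
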