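# cervimage

Quantitative image analysis of stratified squamous epithelium — the
ectocervical/vaginal mucosal barrier — for studies that relate tissue
structure and HIV-target-cell distribution to clinical groups.

Given multi-channel immunofluorescence sections (DAPI, E-cadherin, and
immune-cell markers such as CD4, CCR5 or Langerin) with operator-drawn
boundary annotations, the package computes:

* **Epithelial layer thickness** — per-point nearest distances between
  the rasterized basal membrane, E-cadherin boundary and apical surface
  polylines, via an exact Euclidean distance transform; summarized per
  image (median) and pooled per participant (area-weighted mean). The
  E-cadherin⁺ (basal/intermediate) and E-cadherin⁻ (superficial) layers
  are measured separately.
* **Depth-binned marker quantification** — the epithelium is cut into
  50 µm segments of depth from the apical border (the most apical 10 µm
  excluded for surface autofluorescence; everything beyond 300 µm pooled
  into one terminal segment), and each marker's positively stained area
  fraction (% of epithelial tissue area, pixel-based with an
  image-dependent Otsu threshold) is reported per segment and overall,
  including double-positive conjunctions (e.g. CD4⁺CCR5⁺).
* **Cervicotype classification** — genus-level vaginal microbiome
  compositions (with *Lactobacillus* split into *iners* / non-*iners*)
  assigned to CT1 (*L.* non-*iners* dominant), CT2 (*L. iners*
  dominant), CT3 (*Gardnerella* dominant) or CT4 (high diversity), by an
  argmax-plus-dominance-threshold rule (default 0.5), with per-group
  frequency tables.
* **Two-group statistics** — median/IQR summaries, exact/asymptotic
  Mann–Whitney U, Shapiro–Wilk-gated pooled t-tests, Fisher's exact
  tests (including above-detection-limit counts), categorical
  percentage tables, OLS age checks and the luteal-phase progesterone
  rule (> 1.2 ng/mL).
* **Synthetic phantoms** — a first-class generator of tissue images
  with exact ground truth (curved epithelial band, E-cadherin
  sublayers, depth-dependent star-convex "cells", planted double
  positives, noise and an apical autofluorescence strip), so the whole
  measurement chain is verifiable without any real slides.

See `docs/methods.md` for the measurement model, defaults and
limitations.

## Worked example

Generate one standard phantom (~1.5 mm² of epithelium, 300 µm nominal
thickness, 45 µm E-cadherin-negative layer, planted CD4/CCR5 density
profiles) and run the measurement chain on it:

```python
import numpy as np
from cervimage import (PhantomSpec, generate_phantom, measure_thickness,
                       threshold_marker, double_positive, assign_depth_bins,
                       profile_segments)

spec = PhantomSpec(seed=1)
channels, boundaries, truth = generate_phantom(spec)

res = measure_thickness(boundaries, truth.mask)
print(f"total = {res.total_um:.1f} um, E-cad+ = {res.ecad_pos_um:.1f} um, "
      f"E-cad- = {res.ecad_neg_um:.1f} um")

cd4 = threshold_marker(channels["CD4"], truth.mask)      # Otsu, epithelium-only
ccr5 = threshold_marker(channels["CCR5"], truth.mask)
labels = assign_depth_bins(truth.depth, truth.scheme)
prof = profile_segments([cd4, ccr5, double_positive(cd4, ccr5)],
                        labels, truth.mask, truth.scheme)
print(f"CD4 overall = {prof.overall_pct['CD4']:.2f}%")
print("CD4 per segment:", np.round(prof.per_bin_pct["CD4"], 2))
```

prints

```
total = 299.3 um, E-cad+ = 254.1 um, E-cad- = 44.2 um
CD4 overall = 3.14%
CD4 per segment: [0.87 4.1  5.08 3.58 3.22 2.36 1.04]
```

The recovered total thickness is within 0.3% of the 300 µm ground truth
and the layer split within one pixel (2 µm). The seven per-segment
values are the CD4⁺ area percentages in the depth segments
[10,50), [50,100), …, [250,300), [300,∞) µm from the apical surface;
they equal the generator's planted truth (`truth.true_bin_fractions`)
to the printed precision, because the bright cells separate cleanly
from background at the Otsu threshold (28.9 here, logged per image).

## Command line

Each subcommand is a thin wrapper over the library; runs are described
by a YAML config pointing at a manifest CSV (one row per image:
`sample_id,image_id,group,boundary_path` plus one column per channel
image path). Boundary annotations are plain-text coordinate files, and
the physical pixel size always comes from the config.

```bash
cervimage simulate --seed 1 --out phantom/          # phantom dataset + truth
cervimage measure-thickness --config run.yaml       # per-image/sample CSVs + tests
cervimage profile-markers --config run.yaml         # long-format segment CSV
cervimage cervicotype --abundances ab.csv --groups groups.csv
cervimage compare-groups --table measurements.csv
```

A malformed boundary file fails only its image: the run continues,
errors are collected to `errors.csv`, and the exit status reflects the
partial failure.

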