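# sngfr — single-nephron GFR from intravital multiphoton imaging

`sngfr` estimates the **single-nephron glomerular filtration rate (snGFR)** —
the volume of primary filtrate one nephron produces per unit time, in
nl/min — from intravital two-photon microscopy of the mouse kidney. After a
bolus of a freely filtered, non-resorbable fluorescent dye (e.g. Lucifer
Yellow), the dye front advances along the proximal tubule (PT) at a speed set
by the filtration flow. The package turns that advance into a flow estimate,
for kidney physiologists analysing time series + z-stack acquisitions.

## Method

The continuous ("extended") workflow combines three ingredients:

1. **Kymograph.** A user-drawn polyline ROI traces the PT from the glomerular
   end. Intensity is sampled along the ROI in every frame, giving
   *I(s, t)* on a regular arclength grid *s*.
2. **3D tubule model.** The dye-channel z-stack is median-filtered, the
   vessel and nuclear channels are subtracted to remove spectral
   bleedthrough, and the PT is segmented by a seeded 3D watershed. Each mask
   voxel is assigned the arclength of its projection onto the ROI, yielding
   the cumulative-volume map *V(s)* (µm³).
3. **Front regression.** At every position the turning point of *I(t)* (the
   discrete maximum slope) marks the front's passage; the median of the
   per-position turning intensities is the global threshold *I\**. In each
   frame the front position is where the initial above-threshold run ends
   (sub-sample interpolated), converted to volume through *V(s)*. Ordinary
   least squares of front volume against frame index gives a slope *b* in
   µm³/frame, and

   snGFR = *b* · fps · 60 / 10⁶  [nl/min].

The legacy **two-point** method is included as a baseline: transit time of
the dye front between the ROI's endpoints, divided into a cylinder volume
π(d̄/2)²·L with d̄ the mean of five manually measured diameters. The
`repeatability` module provides the comparison statistics (per-dataset
mean/SD/CV, mean CV, two-sample Kolmogorov–Smirnov test) and ships a
reference repeatability table (15 glomeruli × 2 workflows × 5 repeats,
summarised).

A synthetic **phantom** renders everything the real acquisition provides —
2D+t dye series, co-registered 3-channel z-stack, tracing ROI — from a tube
model with known flow, noise and bleedthrough, so the whole pipeline is
testable without any microscope data.

## Worked example

```bash
python examples/phantom_extended_workflow.py
```

```
ground-truth flow     : 1.700 nl/min
estimated snGFR       : 1.632 nl/min
regression R²         : 0.9998
tubule length (ROI)   : 41.7 µm
segmented PT volume   : 7257 µm³
front threshold       : 104.9 (intensity units)
frames in regression  : 23
```

A phantom filling at 1.7 nl/min (with 5% noise) is analysed end to end; the
estimate lands within a few percent of the truth, with the regression fit
quality (R²), the tubule geometry and the threshold reported alongside —
the same numbers the file-driven pipeline writes to its result CSV.
`examples/compare_workflows.py` contrasts the replicate spread of both
estimators under annotation jitter, and
`examples/repeatability_statistics.py` aggregates the bundled reference
table:

```
previous : snGFR 1.72 ± 0.91 nl/min, mean CV 38.75% (15 glomeruli)
extended : snGFR 1.70 ± 0.78 nl/min, mean CV 10.35% (15 glomeruli)
```

## Command line

For file-driven runs (TIFF series, TIFF z-stacks, JSON or ImageJ `.roi`
polyline, YAML config with mandatory pixel size / voxel depth / frame rate):

```bash
sngfr phantom  --out phantom_dir/           # render synthetic data
sngfr extended --config config.yaml         # continuous workflow
sngfr legacy   --config config.yaml --diameters 15,15,14,16,15
sngfr stats    --replicates replicates.csv  # repeatability summary
```

Every `extended` run persists its intermediates (kymograph CSV,
volume-profile CSV, selected-mask TIFF, JSON run log, optional diagnostic
plots) so each analysis step can be verified after the fact.

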