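# Methods

## The estimation problem

A freely filtered, non-resorbable dye injected intravenously appears in the
glomerular capillaries and is filtered into the proximal tubule (PT). Because
the dye is not reabsorbed, the advance of its front along the PT is a pure
plug-flow signature of the filtration rate: if the front sits at arclength
*s(t)* and the tubule holds cumulative volume *V(s)* up to position *s*, then
*V(s(t)) = Q·t* with *Q* the single-nephron GFR. The estimator therefore
needs (a) the front position over time and (b) the position→volume map, and
regresses the composed quantity *V(s(t))* on time.

## Continuous workflow

**Kymograph.** The ROI polyline (pixel coordinates, first vertex at the
glomerular end) is resampled on a regular arclength grid, by default one
pixel (0.8513 µm) apart — finer spacing would pretend resolution the optics
do not provide. Intensities are bilinearly interpolated; a line width > 1
averages over perpendicular offsets, mirroring a wide line ROI.

**Volume model.** Preprocessing is a 3D median filter (default radius 1,
i.e. 3×3×3 — large enough to suppress shot noise, small enough to keep the
~9-pixel lumen radius intact) followed by voxel-wise subtraction of the
vessel and nuclear channels (default scale 1.0 each, clamped at zero,
matching unsigned-integer channel arithmetic). Filtering precedes
subtraction because the median is nonlinear. Binarization is Otsu by default
(a fixed threshold is available); since the package's foreground rule is
*x ≥ threshold* while Otsu's optimum splits *x ≤ t* / *x > t*, the reported
threshold is the smallest data value above Otsu's, making the rule exactly
variance-optimal. The watershed floods the negated Euclidean distance
transform from distance-transform maxima at least 5 voxels apart; seedless
small components are labelled separately so labels + background always
partition the volume. A long tubule typically splits into several basins, so
selection takes the **union** of all labels whose x-y projection intersects
the ROI dilated by 3 px. Each selected voxel is then assigned the arclength
of the orthogonal projection of its (x, y) center onto the ROI (z is ignored:
the time series is one plane, and the x-y projection is the only
correspondence that uses the ROI as drawn; ties resolve to the smaller
arclength). Voxels projecting beyond the ROI ends are excluded. Counting
voxels by assigned arclength gives *V(s)* as a non-decreasing step map,
evaluated by linear interpolation.

**Threshold and front.** Intensity-over-time curves are smoothed by a
centered 3-frame moving average (truncated at the series edges). The turning
point at a position is the frame pair with the maximal forward difference;
when smoothing spreads a sharp step into a run of numerically tied maximal
steps, the middle of the run is taken — this centers the estimate on the
inflection and makes it invariant under intensity rescaling (ulp-level
tie-breaking would otherwise be arbitrary). The turning intensity is the
mean of the two flanking samples; the global threshold is the median over
positions whose temporal rise is at least half the largest rise anywhere
(positions outside the tubule carry no transit and would drag the median
down). Per frame, the front is the end of the initial contiguous
above-threshold run scanned from the glomerular end — robust to dye
re-entering the field downstream — refined by linear interpolation between
the bracketing samples. Frames whose front volume lies outside 5%–95% of the
total are excluded: pre-arrival and saturation plateaus are uninformative
and would bias the least-squares fit. The fit is OLS of volume on frame
index (≥ 3 points required); R² is the squared Pearson correlation, and the
slope converts exactly as nl/min = (µm³/frame) · fps · 60 / 10⁶.

**Sign conventions and failure modes.** A time-reversed series produces
either "insufficient front transit" or a negative slope — never a silently
positive flow. Missing acquisition metadata is an error, never defaulted:
wrong units corrupt the estimate by orders of magnitude.

## Two-point workflow

The baseline estimator measures intensity-over-time at the ROI's first and
last vertices only. Arrival at each point uses the same maximal-forward-
difference detector as the continuous threshold (including the
middle-of-tied-run rule), so the comparison between workflows isolates their
structural difference — two points + cylinder volume versus continuous
tracking + 3D volume — rather than differing arrival detectors, whose exact
historical form is not documented. The tubule volume between the points is a
cylinder on the mean of five manual diameters; snGFR is volume over transit
time.

## The phantom

The phantom renders the study conditions: a tube of 15 µm luminal diameter
(mouse PT scale) with straight, arc or sine centerline and optionally
linearly tapering radius, filled by an advancing arclength cutoff *s(t)*
solving *V(s(t)) = Q·t* — exactly the plug-flow model the estimator assumes,
rendered with a ~1-pixel soft edge whose tip sits at *s(t)* (so the
pre-injection frame is genuinely blank). Default flow is 1.7 nl/min, the
physiological scale for healthy mice in this preparation. The z-stack
carries a parallel "vessel" tube and scattered "nuclei" blobs; the dye
channel receives 0.2× vessel + 0.1× nuclei bleedthrough; Gaussian noise (σ
as a fraction of the plateau intensity) is added per channel and clipped at
zero. All randomness derives from the spec's seed; identical specs render
identical data. The traced ROI is inset 3 px from the tube ends, as a user
traces a segment of a tubule that continues beyond the measured stretch.

**Field-of-view scaling.** Pixel size (0.8513 µm), voxel depth (1 µm) and
the tube diameter match the real acquisition, but the rendered field
(64×64×20 voxels, 30 frames by default) is much smaller than a real 512×512
field. At 1.7 nl/min the front would cross such a small field in about one
frame at the real 6 fps, so the default frame rate follows a transit-fit
rule: the front exits the tube one frame before the series ends. The snGFR
estimate is invariant to this choice because the frame→minute conversion is
exactly linear in the frame rate; the rule simply keeps the transit
temporally resolved at desk-scale problem sizes. Simulations in the tests
and the acceptance script use this 64×64×20 / 30-frame geometry (single
runs take ~0.2 s; the 20-seed studies a few seconds).

**What the phantom does not emulate.** No hemodynamics or pulsatility, no
tubular reabsorption, no photobleaching, no motion/breathing artifacts, no
depth-dependent attenuation, and the tubule is a smooth tube rather than a
convoluted brush-border lumen. Passing tests therefore demonstrate that the
estimator recovers flow under its own model assumptions with realistic
noise, sampling and annotation error — not that it is robust to every
artifact of in-vivo imaging.

## Repeatability statistics

Per dataset: mean, sample SD (n−1) and relative SD (CV, %) of the replicate
snGFRs. Across datasets: the unweighted mean of per-dataset CVs, and the
mean ± sample SD of per-dataset means; both conventions reproduce the
bundled reference table's published aggregates exactly, which fixes the
otherwise ambiguous aggregation rule. (One published rounding quirk: the 15
previous-workflow means in the reference table average to 1.716, printed
upstream as 1.71.) The two-sample Kolmogorov–Smirnov test uses the exact
small-sample p-value when n·m ≤ 10⁴ and the asymptotic one otherwise.

The annotation-jitter harness is the computational analogue of repeated
manual analysis: one rendered phantom, re-annotated per replicate with
Gaussian ROI-vertex jitter (σ = 1 px) and multiplicative diameter jitter
(σ = 5%, a realistic manual-calliper error). Diameters enter the two-point
estimate squared, so its CV is dominated by this term; the continuous
estimator uses no manual diameters and integrates the whole transit, which
is the mechanism behind its smaller replicate spread.

## Numerical choices and edge cases

- Coordinates are 0-based pixel centers, (x, y) with x = column; stacks are
  (z, y, x). ROI readers never rescale by pixel size.
- Sub-sample front localization interpolates the intensity linearly between
  the bracketing samples; a hard step between samples therefore localizes
  mid-way at the half-step threshold.
- The cumulative-volume map is a step function; its staircase offset (about
  half a voxel per cross-section) shifts the regression intercept only,
  never the slope.
- Degenerate inputs raise early with stage names: constant volumes under
  Otsu, empty foregrounds, ROIs that miss every segmented object, flat
  intensity curves, non-positive transit times, fewer than three usable
  frames.
- Smoothing windows must be odd so the moving average stays centered and
  phase-free.

## Known limitations

- The user-drawn ROI is authoritative: the package does not re-estimate the
  tubule centerline from the segmentation, so a grossly misplaced ROI
  degrades both workflows.
- The x-y projection of voxels onto the ROI assumes the tubule does not fold
  over itself in projection within the segmented region.
- One global threshold is used for all positions; strong depth- or
  position-dependent brightness gradients would argue for a per-position
  threshold, which the estimator does not implement.
- Proprietary microscope containers are out of scope; export to TIFF first.
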