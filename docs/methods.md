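# Methods

## The measurement and its failure modes

A proximity ligation assay (PLA) event is read out as a bright, compact
fluorescent punctum produced by rolling-circle amplification.  Acquired by
imaging flow cytometry, each cellular event is a small multichannel pixel
grid: a brightfield image, the PLA channel, and surface/intracellular marker
stains that define populations.  The reported quantity is deliberately the
*percentage of PLA-positive cells* in a population, not punctum counts or
intensities: amplification efficiency varies between samples, so a cell is
either above the background gate or it is not.

Three signal morphologies have to be separated in the PLA channel:

| morphology | origin | how it is removed |
|---|---|---|
| compact puncta inside the nucleus | true signal (for nuclear targets) | retained |
| puncta on the plasma membrane | nonspecific probe binding | interior (adaptive-erode) gate, MCP cutoff |
| diffuse elevation over the whole cell | autofluorescence | staining-area gate |

plus one artifact that is not a morphology: bleed-through between channels
that linear compensation cannot remove, excluded by the bright-detail
similarity (BDS) gate.

## Feature operators

All operators act on one channel grid and a boolean pixel mask.

- **Morphology mask** — Otsu threshold on the designated channel (default:
  the brightfield proxy), largest 4-connected component, interior holes
  filled; everything within the outermost contour.  A constant grid has no
  contour and yields an empty mask with a warning.
- **Adaptive-erode mask** — repeated 4-connected binary erosion of the base
  mask; the last iterate whose area is still ≥ *percent*/100 of the base
  area (default percent 78).  Interpreting the percent as retained area
  makes the definition shape-aware, monotone in the percent, and exactly
  reproducible; percent 100 is the base mask, percent 0 the last non-empty
  core.
- **Bright-detail image** — white top-hat with a disk footprint of radius 3
  px (boundary handling: symmetric reflection).  Only features whose
  support fits under the disk survive, which is precisely the punctum scale.
- **BDI** — sum of the bright-detail image over the mask.  Invariant to
  adding a constant to the image, linear under intensity scaling.
- **Max Pixel** — maximum over the mask of (pixel − background), floored at
  0.  The background estimate is the mode of the out-of-mask pixels (exact
  for integer-quantised data, and for simulated data where zero-clipped
  noise makes 0 the modal value); when no value repeats, the mean of the
  lowest decile is used instead.
- **MCP** — the mask is partitioned into 8 concentric rings by the Euclidean
  distance transform, normalised so 0 is the innermost point and 1 the
  perimeter; the reported value is the midpoint of the ring with the highest
  mean intensity (ties resolve inward).  Invariant to intensity scaling and
  to 90° rotations.
- **Staining area** — number of mask pixels whose background-subtracted
  intensity reaches 25% of the cell's Max Pixel.  A fraction-of-peak support
  measure: puncta give tens of pixels, diffuse elevation gives most of the
  cell.  The fraction is configurable (`FeatureConfig.area_fraction`).
- **BDS** — Pearson correlation of two channels' bright-detail images over
  the mask, clipped to ±0.999 and Fisher-z transformed
  (z = ½·ln((1+r)/(1−r)), so the 1.5 cutoff corresponds to r ≈ 0.905 and the
  clipped maximum is ≈ 3.8).  Zero-variance input yields 0 with a flag;
  masks under 3 pixels yield a missing value.

Missing features are NaN, never silently zero.  `extract_features` batches
the top-hat filtering over a whole sample (verified bit-identical to the
per-cell path).

## The gate cascade

1. **Population** — per-pixel mean marker intensities within the morphology
   mask.  Default policy: fixed cutoffs (50 intensity units) on a CD80-like
   target marker and a CD45-like control marker; control-marker-high cells
   are the negative-control population, target-high/low split the target
   population, cells dim in everything (or high in both) are unassigned and
   excluded from denominators.  An Otsu policy is available for samples
   where both modes are present.
2. **PLA gate** — 2-D axis-aligned threshold: BDI *and* Max Pixel of the PLA
   channel must exceed the 99.5th percentile (NumPy linear interpolation
   rule; configurable) of a probes-only control — the same assay run without
   the primary antibody, which carries only nonspecific background.
3. **Localization** — the 2-D gate is evaluated again on the adaptive-erode
   (78%) mask, with cutoffs *recalibrated on the probes-only control's
   erode-mask features* at the same percentile.  Recalibration is necessary
   because summed features scale with mask area: reusing the morphology-mask
   cutoffs on the smaller interior mask double-counts the area-dependent
   noise floor and costs sensitivity on dim positives.  (Callers that want
   the single-threshold behaviour simply pass no interior thresholds to
   `apply_gates`.)  For nuclear targets, MCP ≤ 0.6 is additionally required;
   membranal signal sits in the outermost ring (MCP → 0.94 at 8 rings) and a
   0.6*R nucleus keeps true signal at MCP ≤ 0.56, so the cutoff bisects the
   gap.
4. **Area** — PLA staining area within [2 px, 40% of the morphology-mask
   area].  Diffuse autofluorescence covers ~80–90% of the mask and fails the
   upper bound; puncta pass easily.  Both ends configurable; the gate is a
   range because neither direction is free of pathologies.
5. **BDS** — exclude cells with BDS > 1.5 against the spectrally adjacent
   channel (default: the channel next to the PLA channel in acquisition
   order), catching bleed-through artifacts.  Missing BDS passes with a
   flag by default (`bds_missing_strict` inverts this).

The final call is a pure conjunction, so the positive set is invariant to
filter order; the configured cascade order only attributes first-failure
reasons in the audit trail.  The reduced macrophage-style analysis
(`GatingConfig.bmdm()`) runs only the population and raw PLA gates.

Compensation precedes masking and feature extraction (fixed pipeline order);
unmixing is pixelwise (`observed = true @ S`, solved per pixel, negatives
floored at zero) because all downstream features are pixel-level.  The
spillover matrix is estimated as the per-cell median of ratio-of-sums
within a mask segmented on the source channel, which is robust to
zero-signal and doublet-like outlier cells; zero-signal cells below an
intensity floor are excluded.

## Statistics

Percent positive is computed per biological replicate; replicates are
averaged unweighted within experiment × group (cell counts are reported but
never used as weights, since replicates are the unit of biological
variation); groups are compared by a two-sided classical (equal-variance)
Student t-test across experiment-level means, with Welch behind a flag.
Two-sided testing is assumed.  Group means ± s.e.m. over experiment-level
values are reported alongside.  At least two independent experiments per
group are required; degenerate zero-variance comparisons are flagged.

## The simulator

One centred cell per image on a 49×49 grid (odd side, cell radius 21 px,
nucleus radius 0.6·R): a brightfield disk, uniform marker stains with
log-normal per-cell intensity (median 150 vs 12/8 intensity units for the
separating marker — a ~7σ separation in log space), and a PLA channel built
per planted class:

- **nuclear positive** — a zero-truncated Poisson (mean 5) number of
  Gaussian puncta (σ = 0.75 px, peak 400, log-normal jitter cv 0.25) placed
  uniformly in the nucleus;
- **membranal false positive** — Poisson (mean 8) puncta of peak 150 placed
  on a 2 px band straddling the cell boundary;
- **diffuse autofluorescent** — a 60-unit elevation over the cell with 35%
  Gaussian texture;
- **negative** — nothing.

Every sample additionally carries probes-only background by default
(Poisson mean 1.5 membrane puncta of peak 40, plus an 8-unit diffuse floor):
nonspecific probe stickiness affects all samples of an experiment, and the
percentile gate is only calibrated if the control's background transfers to
the sample.  Spillover is applied as linear mixing of the noise-free stack,
then Gaussian read noise (sd 2) is added and pixels floored at zero, so
compensation is exactly recoverable in the noise-free limit (the pre-mixing
stack can be retained as an oracle via `keep_premix`).  Two artifact modes
exist on top of the classes: `bleed` copies half of the PLA stack into the
adjacent channel *after* mixing (uncompensatable, for the BDS gate), and
`costain` plants an independent punctum set in the adjacent channel.

Geometry and intensity defaults were chosen once, by design, so the planted
classes reproduce the qualitative morphologies the cascade discriminates:
the 78% erosion boundary of a radius-21 disk clears the membrane band by
more than two punctum sigmas, so membranal signal is excluded from the
interior mask by construction, and a single 400-peak punctum clears the
99.5th-percentile control cutoff, so sensitivity is not count-limited.
Scenario scale mirrors the acquisition regime of roughly a thousand target
cells per sample; the validation runs use 1000-cell samples with 400-cell
probes-only controls (10 runs in the acceptance script, 100 seeds in the
long recovery test).

What the simulator does **not** emulate — and what passing tests therefore
do not establish about instrument data: optics (no point-spread function,
no camera gain curve or saturation), cell-shape variability (circular cells,
centred, no doublets or debris), chromatic autofluorescence spectra
(autofluorescence is a single-channel texture), focus variation, and any
punctum count/brightness calibration to a real assay (no in-paper
calibration exists; the defaults live in `SceneParams`, not in code paths).
Results on real data depend on those factors; the synthetic results validate
the *operators and the cascade logic*, not instrument performance.

## Numerical choices and edge cases

- Coordinates are row-major, 0-based; masks are plain boolean pixel sets.
- Percentile cutoffs carry a machine-epsilon guard so exact zeros never
  pass a strict `>` gate (an all-zero control yields cutoff ≈ 0⁺).
- Empty masks warn and yield 0 (BDI, Max Pixel, area) or NaN (MCP, BDS);
  `n = 0` samples and empty populations are flagged, not errors.
- Otsu thresholding of a constant grid is undefined: empty mask + warning.
- The spillover matrix must have unit diagonal, off-diagonals in [0, 1) and
  a condition number below 10⁶ (configurable); estimation and unmixing both
  validate.
- Randomness flows through a single `numpy.random.Generator` per sample;
  identical seeds give byte-identical images.

## Known limitations

- The adaptive-erode percent is interpreted as retained-area fraction; the
  instrument software's definition is not published, so numerical equality
  with it is not claimed (likewise for its BDS log base and Max Pixel
  background rule; cutoffs such as BDS 1.5 and MCP 0.6 are config-exposed
  for recalibration).
- 2-D gates are axis-aligned conjunctions; polygon gates are out of scope.
- The nested design is analysed by averaging, not by a mixed-effects model;
  a single planned comparison is assumed (no multiplicity correction).
- Population gating with the Otsu policy requires both modes present in the
  sample; use fixed cutoffs otherwise.
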