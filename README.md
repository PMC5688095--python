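# plic

Quantitative analysis for **proximity ligation imaging cytometry (PLIC)**:
proximity ligation assay (PLA) signal read out by imaging flow cytometry and
gated into a single number per sample — the percentage of PLA-positive cells
in a marker-defined population.

PLA turns a protein–protein interaction or a post-translational modification
into a bright, compact fluorescent punctum (a rolling-circle amplification
product) in the cell where it occurred.  Imaging flow cytometry records a
small multichannel image per cellular event, which makes it possible to ask
not just *how bright* the PLA channel is but *where* the signal sits in the
cell — and that is what separates true nuclear-speckle signal from the two
dominant false-positive modes: nonspecific probe binding (membranal puncta)
and cellular autofluorescence (diffuse signal).  This matters most for rare
populations (the motivating case is CD80-high medullary thymic epithelial
cells, <0.1% of the thymus), where a bulk assay has nothing to average over.

This package implements the computational core of that analysis for per-cell
image stacks, plus a synthetic-data simulator with ground truth so every
stage can be validated without instrument data:

- **`plic.simulate`** — single-cell image generator: planted nuclear-speckle
  positives, membranal false positives, diffuse autofluorescent cells,
  probes-only background samples, single-stain compensation controls,
  channel spillover; every draw recorded in a truth table.
- **`plic.imageops`** — the feature vocabulary: morphology mask (outermost
  contour, hole-filled), adaptive-erode mask (shape-aware erosion to a
  retained-area percent, default 78), bright-detail image (white top-hat,
  spot radius ≤ 3 px), **BDI** (bright detail intensity), **Max Pixel**
  (background-subtracted maximum), **MCP** (max contour position,
  0 = centre … 1 = perimeter), staining area, and **BDS** (bright detail
  similarity, the Fisher-z–transformed Pearson correlation of two channels'
  bright detail).
- **`plic.compensation`** — spillover matrix estimation from single-stain
  controls (median of ratio-of-sums per cell) and pixelwise linear unmixing.
- **`plic.gating`** — the gate cascade: population assignment from marker
  intensities; a 2-D (BDI, Max Pixel) PLA gate set at the 99.5th percentile
  of a probes-only control; a localization filter re-applying the gate on
  the adaptive-erode (interior) mask plus an MCP ≤ 0.6 nuclear cutoff; a
  staining-area filter against diffuse signal; and a BDS > 1.5 exclusion for
  channel bleed-through that compensation cannot remove.
- **`plic.quantify`** — percent positive per biological replicate,
  unweighted replicate averaging per experiment × group, and a two-sided
  Student t-test on experiment-level means (mean ± s.e.m. reported).

The compensation, feature-extraction and gating stages are also exposed as
scikit-learn-style estimators (`SpilloverCompensator`, `FeatureExtractor`,
`PLAGater`) with `fit`/`transform`/`predict` and fitted attributes, so they
compose with sklearn tooling.

## Worked example

```python
from plic import (GatingConfig, SceneParams, generate_probes_only,
                  generate_sample, knockout_scenario_mix,
                  nuclear_scenario_mix, run_pipeline)

params = SceneParams()
probes, _ = generate_probes_only(400, params, seed=3)
wt, truth = generate_sample(500, nuclear_scenario_mix(0.25), params, seed=1)
ko, _ = generate_sample(500, knockout_scenario_mix(), params, seed=2)

result = run_pipeline({"wildtype": wt, "knockout": ko}, probes, GatingConfig())
print(result.summary.to_string(index=False))
```

prints

```
  sample population   n  n_pos  pct_pla_pos
wildtype  TARGET_HI 500    121         24.2
knockout  TARGET_HI 500      0          0.0
```

The wild-type sample planted a nuclear-positive fraction of 24.2% (122/500
drawn at f = 0.25) and the pipeline calls 24.2% PLA-positive.  The
knockout-like sample contains only membranal and diffuse (false-positive)
signal; its *raw* PLA gate — before the localization/area/BDS filters — is
40.8% positive, and the filters reduce it to 0.0%.  The thresholds actually
used are logged and returned (`result.thresholds`, here BDI > 4702 and
Max Pixel > 85.4 from the probes-only control's 99.5th percentiles), and
`result.calls` carries the per-cell audit trail with every gate outcome and
failure reason.

A command-line interface mirrors the library:

```bash
plic simulate --scenario scenario.yaml --out data/ --seed 1
plic features --in data/ --out features.csv
plic gate --features features.csv --controls probes.csv --out gated/
plic quantify --design design.csv --out quant/ --compare wt ko
```

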