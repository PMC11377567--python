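# lysoquant

Quantification toolkit for the cellular response to lysosomal membrane
damage. When lysosomes are permeabilized (e.g. by the lysosomotropic
dipeptide LLOMe, or by intracellular pathogens such as *Salmonella*), cells
respond by membrane repair, lysophagy, and exocytosis of the damaged
organelles. Measuring that response from microscopy, flow cytometry and AFM
data requires a stack of small, well-defined quantification procedures.
`lysoquant` implements them as a tested, reusable Python library with a thin
CLI, aimed at cell biologists and image analysts who want scriptable,
provenance-tracked versions of readouts usually assembled ad hoc from
ImageJ plugins and instrument software:

- **Puncta quantification** — detection of fluorescent puncta (e.g.
  galectin-3 dots marking damaged lysosomes, Arp2 foci) inside a traced cell
  outline: per-cell thresholding (Otsu by default), 8-connected labelling,
  distance-transform watershed splitting of touching clusters, and washout
  timecourse normalization to the mean of a reference timepoint.
- **Colocalization** — Pearson's r and Manders' thresholded coefficients
  M1/M2 over a cell mask, plus an object-based triple-overlap fraction
  (share of reference vesicles carrying puncta of two partner markers).
- **Lysosome radial positioning** — per lysosome, the normalized distance
  from the nuclear membrane to the plasma membrane along the ray from the
  nucleus centroid through the lysosome (f = 0 at the nuclear membrane,
  f = 1 at the plasma membrane), binned into fraction-vs-distance profiles.
- **Actin network branching** — ridge-filter + skeletonize + graph pipeline
  yielding total branches, triple/quadruple junction counts, branch
  lengths, skeleton density, and doubled-angle orientation/alignment.
- **Laurdan generalized polarization** — pixel-wise
  GP = (I₄₀₀₋₄₆₀ − G·I₄₇₀₋₅₃₀) / (I₄₀₀₋₄₆₀ + G·I₄₇₀₋₅₃₀), with the
  calibration factor G derived from a DMSO reference of known GP (0.0357),
  and membrane-ROI mean GP.
- **AFM cell mechanics** — contact-point detection and Hertz-model fitting
  of approach force-distance curves (pyramidal tip F = 0.7453·E/(1−ν²)·tanα·δ²
  or spherical tip F = (4/3)·E/(1−ν²)·√R·δ^{3/2}), reporting Young's modulus
  E and the indentation depth at a stated force (500 pN).
- **Assay calculators** — autophagic flux (LC3B-II/LC3B-I ratio-of-ratios
  with/without bafilomycin), CFU concentrations and supernatant/intracellular
  secretion ratios from serial dilutions, ratiometric dual-dextran lysosomal
  pH, PI-gated surface-marker (LAMP1) summarization, DQ-BSA slope.
- **Synthetic data** — seed-deterministic generators with exact ground truth
  for every input class (puncta scenes with controllable counts, radial
  bias, colocalization and triple-overlap fractions; filament networks with
  known junction counts; Laurdan channel pairs with a known GP field;
  Hertz force curves with known E and contact point), so the whole pipeline
  is testable without microscope or AFM access.

Coordinates are 0-based `(row, col)` arrays; geometry files use
`(x, y) = (col, row)` with the origin at the top-left pixel centre. All
geometry outputs are in pixels unless a pixel size is supplied.

## Worked example

Simulate a damage scene, detect the puncta and position the lysosomes:

```python
import numpy as np
from lysoquant import simulate, puncta, positioning

spec = simulate.SceneSpec(n_puncta={"gal3": 25}, noise_sd=2.0,
                          min_separation=12, beta=0.6, seed=7)
stack, geometry, truth = simulate.simulate_scene(spec)

detected = puncta.detect_puncta(stack[0], geometry)
print(puncta.summarize_puncta(detected))

fractions = [positioning.radial_fraction(geometry, c) for c in detected.centroids]
profile = positioning.bin_profile(fractions, n_bins=5)
print(np.round(profile.fractions, 2))
```

Output:

```
{'count': 25, 'total_intensity': 50264.971598742406, 'mean_area': 25.04}
[0.16 0.   0.24 0.4  0.2 ]
```

All 25 simulated puncta are recovered; their summed background-subtracted
intensity is within ~0.5 % of the generated total of 50 000. The radial
profile leans towards the outer bins because the scene was generated with
a peripheral bias (`beta=0.6`), the redistribution pattern seen after
lysosomal damage.

The same operations are available from the shell:

```bash
lysoquant simulate --kind scene --seed 7 --out scene/
lysoquant puncta --image scene/scene.tif --geometry scene/geometry.csv --out puncta.csv
lysoquant assay flux --values 4,2,1,1     # {"autophagic_flux": 2.0}
```

Every result CSV ships with a `.meta.yaml` sidecar recording the
parameters, seed and software version that produced it.

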