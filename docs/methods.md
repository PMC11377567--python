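# Methods

This note documents the models, algorithms and parameter choices behind
each `lysoquant` module, what the synthetic-data generators emulate, and
the limits of what the test suite demonstrates.

## Conventions and geometry

Arrays are indexed 0-based as `(row, col)`; geometry files and all polygon
vertex lists use `(x, y) = (col, row)` with the origin at the centre of the
top-left pixel. Point-in-polygon tests follow the even-odd rule with
boundary points counting as inside (a deterministic tie-break). Pixel masks
are rasterized by pixel-centre containment. No channel registration is
performed; planes of a stack are assumed aligned. Because acquisitions
rarely state calibrated pixel sizes, all geometric outputs are reported in
pixels unless `pixel_size` is supplied.

## Puncta detection (`puncta`)

Pixels inside the cell polygon are thresholded. The default threshold is
Otsu's method computed within the cell, computed on a lightly smoothed copy
of the image (Gaussian `smooth_sigma` = 1 px). The smoothing acts as a
matched filter: with realistic shot noise, the raw in-cell histogram is
nearly unimodal and Otsu lands inside the noise, flooding the mask; 1 px of
smoothing restores a clean bimodal separation without merging puncta more
than ~2 px apart. A fixed threshold can be supplied instead. Intensities
are always measured on the raw image.

Components are labelled with 8-connectivity. Watershed splitting of
touching clusters uses the negated Euclidean distance transform, seeded at
its regional maxima with **prominence ≥ 1 px** (h-maxima). Plain local
maxima with a minimum 2 px separation were tried first and rejected: the
distance transform of a single round punctum with a noise-roughened
boundary routinely carries twin sub-pixel maxima more than 2 px apart,
which over-splits a substantial fraction of single puncta; a 1 px
prominence requirement suppresses exactly those twins while still
separating two spots joined by a neck (the valley between genuine puncta
is at least 1 px deep at any realistic spot radius).

Components below `min_area` (default 4 px — the upstream protocol states no
size gates, so this is a package default recorded in provenance) are
dropped. The background is the median of in-cell pixels below threshold;
integrated intensity sums background-subtracted pixels over the component
**expanded by 3 px** (`measure_dilation_px`, expansion never crossing into a
neighbouring component). Without the expansion, the threshold clips the
PSF tails and 20–40 % of a spot's integrated intensity is lost; with it,
recovery on noise-free renders is within ~1 %, the residual being genuine
tail mass beyond 3 px and at the cell boundary.

Washout timecourses are normalized by the mean of the reference timepoint
(the end of the damage pulse), which therefore maps to exactly 1.0.

## Colocalization (`coloc`)

Pearson's r is the sample correlation of paired in-mask pixels. Manders'
thresholded coefficients restrict each channel to its above-threshold
pixels: M1 is the fraction of A's integrated intensity on pixels where B
exceeds its threshold, and symmetrically M2. `coloc_pair` applies per-cell
background subtraction (median of sub-threshold pixels) and per-channel
Otsu thresholds within the mask; Costes auto-thresholding and randomization
tests are out of scope. Both r and M1/M2 are reported side by side, since
both are standard readouts for the same panels.

The object-based `triple_overlap` matches reference puncta to each partner
set greedily (nearest pair first, one-to-one, within `match_radius`) and
reports the fraction of reference puncta matched in both partner sets.
One-to-one matching prevents a single bright partner punctum from
"explaining" several reference vesicles.

## Radial positioning (`positioning`)

For one lysosome, a ray is cast from the nucleus centroid through the
lysosome centroid. P_n is the ray's exit through the nuclear boundary and
P_c the nearest crossing of the cell boundary beyond P_n; the radial
fraction is |lysosome − P_n| / |P_c − P_n|, clamped to [0, 1]. For concave
cell outlines crossed several times, the nearest crossing past P_n is used
— the only convention that keeps f ≤ 1 for quasi-convex cells. Tiny
negative or >1 values from boundary round-off are clamped with a warning.
Profiles use equal-width bins on [0, 1] (default 10; the bin count is a
config parameter recorded in provenance), final bin right-closed.

## Actin branching (`actin`)

The upstream line-extraction plugin used for published actin skeletons is
a black box; this module substitutes a standard pipeline — optional
Gaussian pre-smoothing (off by default, matching the original `preGauss`
setting), a tubeness/ridge filter (Sato, sigma 1.5 px ≈ half the filament
width), Otsu threshold, morphological thinning — feeding a fully specified
graph stage that honours the two interpretable plugin settings: terminal
spurs shorter than 5 px are shaved and components shorter than 5 px
deleted. The plugin settings `giwslter` and `mdnmsLen` have no documented
meaning and are left unmapped.

Graph construction: skeleton pixels with ≥ 3 neighbours are junction
pixels; 8-connected junction clusters lying within 2 px of each other merge
into a single node (thinning splits a "+" crossing into two nearby degree-3
pixels; clustering restores one degree-4 node, the dominant failure mode of
naive degree counting). Paths between node pixels become edges with
geodesic lengths (diagonal steps √2). After spur pruning, degree-2
junction remnants are contracted so their two incident edges merge.
Nodes of degree ≥ 5 are counted in `n_multiple` but reported separately
from triples and quadruples.

Orientation per edge is the angle of its endpoint-to-endpoint chord in
[0°, 180°); the alignment index is the resultant length of unweighted
doubled-angle unit vectors (1 = all parallel; 0 for perpendicular-balanced
sets). Skeleton density is skeleton pixels per cell-area pixel; mean
in-cell intensity can be reported alongside since published "actin
density" may refer to either.

## Laurdan GP (`gp`)

GP = (I_blue − G·I_red) / (I_blue + G·I_red), with G solved from a DMSO
reference of known GP (0.0357): G = (I_blue/I_red)·(1 − GP_ref)/(1 + GP_ref).
Per-channel backgrounds are subtracted (clipping at 0) before the map;
when no off-cell region is supplied the 1st-percentile intensity per
channel is used. Pixels whose summed intensity falls below
`intensity_floor` (default 2× the summed background) are undefined,
suppressing GP blow-up near a vanishing denominator. Per-cell GP is the
arithmetic mean of defined GP pixels in the membrane ROI (the pixel-mean,
not the GP of mean intensities). Z-stacks may be plane-summed per channel
first (`--zsum`), matching equatorial-section summation.

## AFM mechanics (`afm`)

Units: nm, pN, Pa (1 Pa = 10⁻⁶ pN/nm²), spring constant in N/m
(1 N/m = 1000 pN/nm). The distance axis is the nominal tip-sample
separation (piezo axis); indentation is δ = (z₀ − z) − F/k, the piezo
travel past contact corrected for cantilever deflection. Defaults mirror
the original acquisition: four-sided pyramidal silicon-nitride tip
(Bilodeau prefactor 0.7453, half-angle 35°), ν = 0.5 (incompressible
cell), k = 0.02 N/m, fit window from contact to 500 pN; a spherical model
(R = 15 nm tip radius) is available, since instrument software does not
state which geometry it assumed.

Contact-point detection estimates the baseline from the first 30 % of
approach samples as median + 3·(1.4826·MAD) — robust statistics, so
post-contact samples leaking into the window cannot inflate the level —
and takes the last sample before the force permanently exceeds it. On
soft samples this is systematically late: with a quadratic pyramid
contact at E ≈ 5 kPa, the force only clears a few-pN baseline tens of nm
past contact, a physical limitation of any threshold detector.
`fit_hertz` therefore refines z₀ jointly with E: for fixed z₀ the modulus
has a closed-form least-squares solution, and z₀ is chosen by a coarse
scan over an asymmetric window (10 sample spacings below to 40 above the
threshold estimate, matching the direction of the bias) followed by
bounded scalar polishing. At zero noise this recovers (E, z₀) to machine
precision; at 5 pN noise on 500 pN curves the median relative error of E
is ~0.6 %. `indentation_at_force` inverts the fitted model in closed form.

## Assay calculators (`assays`)

Autophagic flux = (LC3B-II/LC3B-I with bafilomycin) / (same ratio
untreated). CFU/mL averages count × dilution / volume over countable
plates (3–300 colonies, standard microbiological practice; not stated
upstream). The secretion ratio is total supernatant CFU over total
intracellular CFU (concentration × compartment volume). The lysosomal pH
readout is the per-punctum ratio of background-subtracted summed FITC to
far-red intensities over ROIs detected in the pH-insensitive far-red
channel; non-positive denominators yield flagged missing values.
PI-gated summarization excludes PI-positive events and requires ≥ 5000
events by default. DQ-BSA degradative activity reduces to an OLS slope
over a time window. Normalization bases for released-enzyme
quantification are caller-supplied columns, not computed.

## Synthetic data (`simulate`)

The generators define the conditions under which the pipeline is validated;
all are bit-deterministic given (spec, seed).

**Scenes.** Cells are concentric circle polygons (cell radius 100 px,
nucleus 30 px in a 256² frame by default — typical of a HEK cell at
~10 px/µm). Puncta live in the cytoplasmic annulus; their radial fraction
f is drawn with density ∝ ((1−β) + β·f)·r(f), the bias weight applied to
the annulus area element, so β = 0 is exactly uniform over cytoplasmic
area and increasing β enriches the periphery. Spots are isotropic
Gaussians (σ = 1.5 px) of controllable integrated intensity (default
2000 a.u.) on a background of 10 a.u.; noise is additive Gaussian clipped
at zero (Poisson statistics are not simulated). A colocalization fraction
ρ between channels places exactly round(ρ·n) partner puncta at source
centroids; a triple-overlap fraction reserves one shared reference subset
for both partner channels, so the triple-positive fraction is the
requested value by construction. `min_separation` enforces non-touching
placement (with a capacity error when the demand cannot be packed);
statistics-only scenes may overlap freely.

**Networks.** Junction motifs (3 or 4 arms, ~120°/90° spacing with jitter)
and free filaments are placed on a jittered grid with enough margin never
to merge, drawn as 3 px-wide lines, lightly blurred, and noised; the truth
graph carries exactly the requested degree-3/degree-4 node counts. Real
cortical actin is denser and more entangled than these scenes, so the
90 %-recovery result validates the graph stage, not segmentation of
crowded cytoskeletons.

**Laurdan.** Per pixel with total T and true gp: I_blue = T(1+gp)/2,
I_red = T(1−gp)/(2G) — the exact inverse of the GP equation, so the map
must recover the field identically at zero noise for any G.

**Force curves.** Force is zero before contact; past contact it solves the
implicit balance F = C·((z₀−z) − F/k)^m per sample (Brent root-finding),
so generator and fitter share the same deflection-corrected model and
zero-noise recovery is exact by construction. Default noise 0–5 pN spans
quiet instrument baselines.

What passing tests do **not** show: performance on real images with uneven
illumination, autofluorescence, out-of-focus light, anisotropic PSFs or
Poisson noise; segmentation of overlapping organelles in 3D (analyses are
2D per-section); AFM tilt or viscoelastic effects. The generators emulate
the statistical structure of the readouts, not microscope optics.

## Problem sizes and runtime

The test suite runs in well under a minute: 100 random 16×16 image pairs
against the brute-force colocalization oracle; scenes of 200 puncta per
channel for Manders-vs-ρ and triple overlap; 10⁴ radial samples against
numerically integrated bin expectations; 50 seeded networks (3 triple + 2
quadruple junctions) at 5 % noise; 500 noisy force curves against the
(E, z₀) grid-search oracle; 100 seeded scenes for exact count recovery.
`scripts/acceptance.py` re-runs the same computations at the same or
slightly reduced sizes (100 noisy curves) and finishes in ~10 s.
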