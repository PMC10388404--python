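# Methods

## Scope and data model

The package operates on two raster containers — `Grid` (numeric, NaN as
nodata, pixel size in metres) and `ClassMap` (integer codes tied to a
legend, −1 as nodata) — plus tabular tree inventories and shoreline
points. Rasters use a top-left origin with 0-based row/column indexing.
On disk, rasters travel as ESRI ASCII grid (single band, plain text) or
TIFF with pixel size, origin and nodata stored as JSON in the
ImageDescription tag; vectors as GeoJSON; tables as CSV.

## SAR calibration and preprocessing

Digital numbers calibrate to gamma-naught backscatter as
γ⁰ = 10·log₁₀(DN²) + CF. The calibration factor for L-band PALSAR-type
data has magnitude 83 dB; the sign convention applied here is −83 dB,
because a positive offset would put backscatter of natural surfaces in a
physically implausible range (DN near 1000 maps to −23 dB under the
negative convention). `cf` is configurable for other sensors. DN = 0 has
no defined backscatter and becomes nodata; negative DN is treated as a
data error rather than silently clipped.

Speckle filtering is a focal median (default 3×3): the filter family is a
free choice here, and the median was picked for robustness to impulse
noise, idempotence on flat fields, and exact testability. It is
nodata-aware: nodata pixels stay nodata and valid pixels use only valid
neighbours. Cloud masking is deliberately generic — a binary-mask
operation — rather than a per-sensor QA-bitfield decoder.

## Classification and accuracy

The classifier is a random forest with 100 trees and 5 candidate
predictors per split (the protocol defaults; both configurable), trained
on stratified sample pixels and applied per pixel to a user-composed
feature stack — the pipeline's default stack is
[γ⁰ (speckle-filtered), NDVI, red, NIR]. The learner itself is
scikit-learn's `RandomForestClassifier`; this module's contribution is
the protocol contract: deterministic training under a seed, nodata
propagation, layer-order checking, and vote ties resolved to the lowest
class code.

Accuracy assessment recomputes all marginals from the confusion-matrix
cells (published marginals are never trusted; one published column total
is internally inconsistent with its cells and recomputation is the only
defensible rule). Total disagreement D = N − trace splits into quantity
disagreement Q = ½·Σ_g |row_g − col_g| and allocation disagreement
A = D − Q, and QADI = √((A/N)² + (Q/N)²). The source formula is printed
ambiguously ("AN2+QN2"); the root-sum-of-squares reading is adopted as
the only variant consistent with a [0, 1] index, and satisfies
max(A,Q)/N ≤ QADI ≤ (A+Q)/N, QADI = 0 ⇔ diagonal matrix. The published
QADI values for the two epochs (0.00794, 0.00529) are not reproducible
from the published matrices under this or any standard variant (the
matrices give ≈0.0060 for the second epoch); the package reports the
formula value. Confidence bins: [0, 0.07) very high, [0.07, 0.12) high,
[0.12, 0.20) moderate, [0.20, 0.30) low, [0.30, 1] very low confidence.

## Change accounting

Areas are pixel counts × pixel_size²/10⁴ ha per class; percent change is
signed, 100·(a₂ − a₁)/a₁, undefined (NaN) for a class absent at the first
epoch. The transition table cross-tabulates per-pixel class pairs in
hectares; pixels nodata in either epoch are excluded, so the marginals
reproduce the per-epoch area tables exactly over jointly valid pixels.

## Canopy height and biomass

Inside the mangrove mask a DEM value H (which for radar DEMs over closed
canopies lies between ground and canopy top, near Lorey's height) scales
linearly to two stand-height measures: maximum canopy height
H_max = 1.697·H and basal-area-weighted height H_ba = 1.08·H. Biomass
density follows B = 3.25·H_ba^1.53 Mg/ha. H_ba is computed from the
original DEM, not from H_max: the two readings give materially different
biomass, the source of the 1.08 factor defines it against the raw DEM
value, and no joint choice reproduces both a 6.3–12.7 m height envelope
and a 105 Mg/ha biomass ceiling (the ceiling corresponds to
H_ba ≈ 9.70 m, above 1.08× the DEM range); the literal definition is
therefore followed. Heights below a configurable floor (default 0) are
clamped to 0 before exponentiation.

## Field allometry

Per-tree aboveground biomass in kg from DBH D (cm), height H (m) and
wood density ρ (g/cm³):

* Komiyama (pantropic): 0.251·ρ·D^2.46 — height-free;
* Chave (universal): 0.0509·ρ·D²·H;
* Njana (East-African regional): 0.353·ρ^1.13·D^2.08·H^0.29.

On a small fringing-stand stem (D = 4.48, H = 6.10, ρ = 0.87) the models
order Chave < Komiyama < Njana (≈5.42, 8.74, 11.53 kg). Wood density is
resolved per species from a compiled low/middle/high table or by a global
default of 0.87 g/cm³ (the compiled middle-column mean is 0.8725; 0.87 is
kept as the conventional rounded default). Plot totals sum tree values;
with 5 m × 5 m plots, kg converts to Mg/ha by ×0.4. Trees below 2 m
height are excluded by default, matching the usual field protocol;
inventory totals are reported both as raw kg and as Mg/ha, since
published plot summaries of this kind sometimes label per-tree kg values
as densities.

## Coastal exposure

Each shoreline point (spaced every 250 m by arc length, floor(L/s)+1
points including the start) carries six hazard variables. Numeric
variables rank 1–5 by quantile binning at the 20/40/60/80th percentiles
of the point set, with a direction flag (`lower_is_riskier` reverses the
bins); a constant variable carries no signal and maps to the neutral
rank 3. Categorical geomorphology arrives as a 1–5 lookup supplied by the
user (or the scene generator). The exposure index is the geometric mean
of the six ranks, bounded in [1, 5], symmetric and strictly increasing in
each rank. Habitat scenarios recompute EI with the habitat rank set to 1
(protective, present) versus 5 (absent) — both configurable — holding all
other ranks fixed; removing protection can therefore never lower any
point's EI. Risk classes use equal-width EI breaks on [1, 5]
(1.8/2.6/3.4/4.2), a simple transparent choice since no published
cut-points exist for this index.

## Synthetic scene

The generator emulates a small estuarine wetland so every stage runs
without external data. Epoch-1 classes come from thresholding a
Gaussian-smoothed noise field (smoothing σ default 3 px) at the
cumulative class fractions — classes form coherent patches, and empirical
fractions are exact to ±1 pixel by construction. Defaults: 100×100 cells
at 25 m; fractions 0.278/0.253/0.058/0.411 for
water/mangrove/bare/other-vegetation (the proportions of a ~6400-ha
coastal study area); a transition matrix with strong persistence and
mangrove retention 0.83, so the simulated decade loses roughly 17% of
mangrove cover. Epoch-2 classes are drawn per pixel from the transition
row of the pixel's epoch-1 class (transitions are conditionally
independent given epoch 1 — real change is spatially clustered; tests of
transition structure are tests of the accounting, not of change-detection
skill). Band signatures are per-class Gaussians over [SAR DN, red, NIR]
with means separated by ≥3 standard deviations, so a competent classifier
should approach perfect validation accuracy — the classifier tests
exercise the protocol plumbing, not discrimination of ambiguous spectra.
The DEM is uniform on 3.71–7.48 m inside the epoch-1 mangrove mask (zero
outside), the range whose 1.697-scaled envelope spans 6.3–12.7 m.
Sampling produces 2131 stratified points split 80/20, with the train
count fixed at floor(n·f) and largest-remainder allocation across
classes. The tree inventory places four 5 m × 5 m plots 25 m apart on a
100-m transect with Poisson tree counts declining away from the
shoreline (a plot may be empty), DBH in 0.67–6.48 cm and heights in
2.0–6.34 m correlated with DBH. The shoreline is a sinusoid along the
scene's seaward edge; wind/wave forcing is Weibull-distributed, surge and
relief uniform, geomorphology a categorical 1–5 draw, and the habitat
variable is the local mangrove cover fraction.

What the synthetic scene does not emulate: radiometric SAR physics
(speckle statistics, incidence-angle effects), cloud-contamination
patterns, spatially autocorrelated transitions, species-level canopy
structure, and met-ocean derivation of the wind/wave/surge variables.
Passing tests demonstrate that the operations are correct on data with
known structure, not that the pipeline would reach the same accuracy on
real imagery.

## Numerical and testing choices

Default problem sizes (100×100 to 150×150 grids, 2131 samples, ≤300
shoreline points) keep the full pipeline under a few seconds while
leaving enough pixels for 3σ statistical checks; statistical tests on
simulated frequencies use chi-square goodness-of-fit at a conservative
threshold rather than per-cell bounds, to control the familywise error of
many correlated comparisons. Percentages are reported to one decimal and
QADI to five, matching conventional presentation. All stochastic
components take explicit integer seeds and are bit-reproducible; the
pipeline manifest records the seed and per-stage summaries.
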