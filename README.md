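# mangresil

Assessment toolkit for mangrove ecosystems in the context of coastal
resilience: it quantifies how much mangrove cover a coastal wetland has
lost, how much aboveground biomass the remaining stand holds, and how much
shelter the stand provides against coastal hazards. It is written for
coastal-management and remote-sensing researchers who want each step of
that assessment as a tested, scriptable operation rather than a chain of
GIS clicks.

The pipeline covers five stages:

1. **Preprocessing** — SAR digital numbers to calibrated backscatter
   (γ⁰ = 10·log₁₀ DN² + CF, CF defaulting to −83 dB), NDVI compositing,
   focal-median speckle filtering, and generic binary masking.
2. **Classification & accuracy** — a random-forest classifier (100 trees,
   5 candidate predictors per split) maps four cover classes (water,
   mangrove, bare/built-up, other vegetation); accuracy is assessed with a
   confusion matrix: overall, user's and producer's accuracy, and the
   quantity-allocation disagreement index

   QADI = √((A/N)² + (Q/N)²),

   where Q = ½·Σ|row − column totals| is the quantity disagreement,
   A = (N − trace) − Q the allocation disagreement, read against a
   five-band confidence scale (QADI < 0.07 ⇒ very high confidence).
3. **Change accounting** — per-class areas in hectares, signed percent
   change between two epochs, and the full class-transition table.
4. **Canopy height & biomass** — inside the mangrove extent a DEM value
   H is scaled to maximum canopy height (1.697·H) and basal-area-weighted
   height (1.08·H), and biomass density follows B = 3.25·H_ba^1.53 Mg/ha.
   Field inventories are handled with three per-tree allometries
   (AGB in kg, D in cm, H in m, ρ in g/cm³):
   Komiyama 0.251·ρ·D^2.46, Chave 0.0509·ρ·D²·H and
   Njana 0.353·ρ^1.13·D^2.08·H^0.29, with a compiled wood-density table
   (global default ρ = 0.87).
5. **Coastal exposure** — at shoreline points every 250 m, six hazard
   variables (geomorphology, relief, habitats, wind, wave, surge) are
   ranked 1–5 and combined as the geometric mean
   EI = (R₁·…·R₆)^{1/6}; recomputing EI with the habitat rank set to
   "protective" versus "absent" quantifies the mangrove's defensive value.

A synthetic-scene generator replaces the satellite, DEM and field data, so
the entire pipeline runs and is tested without any downloads.

## Worked example

```python
from mangresil import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig().with_seed(1), out_dir="out")
print(manifest["change"]["percent_change"])
print(manifest["canopy"]["height_max_m"]["min"], manifest["canopy"]["height_max_m"]["max"])
print(manifest["vulnerability"]["mean_ei_with"], manifest["vulnerability"]["mean_ei_without"])
```

prints (seed 1, default 100×100 scene at 25-m pixels):

```
{'water': 9.9, 'mangrove': -14.3, 'bare_builtup': 69.3, 'other_vegetation': -7.7}
6.3 12.69
2.3224 3.0368
```

Reading: over the simulated decade the scene loses ~14% of its mangrove
area while bare/built-up land expands; maximum canopy height inside the
mangrove mask spans 6.3–12.7 m (the DEM range times the 1.697 factor); and
removing the mangrove habitat raises the mean shoreline exposure index
from 2.32 to 3.04 — shoreline points migrate from the low/moderate into
the moderate/high risk classes. The classifier reproduces the (well
separated) synthetic classes at ≥95% validation accuracy with QADI in the
very-high-confidence band.

The same stages are available from the shell:

```bash
mangresil simulate --seed 1 --out scene/
mangresil run-all --seed 1 --out run/
mangresil allometry --inventory scene/inventory.csv --model all --out agb.csv
```

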