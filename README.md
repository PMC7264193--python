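# sizeclines

Spatiotemporal body-size cline analysis for multi-source small-mammal
trait records.

## The problem

Has the North American deer mouse (*Peromyscus maniculatus*) been
getting smaller as climates warm and landscapes urbanize? Answering
that requires stitching together trait measurements from digitized
museum specimens, historical census programs, and modern live-capture
surveys — data streams with different measurement protocols and
biases — then pairing each record with the climate of its collection
year and the human population density of its collection decade, and
fitting models that separate spatial ecogeography (Bergmann's rule:
larger bodies in colder places) from genuine change over time.

`sizeclines` is a tested, reusable implementation of that workflow for
anyone analysing occurrence-linked morphometric data:

- **harmonize** — Darwin-Core-flavoured record cleaning with a per-step
  audit trail: HB length = total − tail derivation, 9 g adult mass
  floor, date/sex/life-stage filters, single-pass 3-SD outlier rule,
  equinox/solstice season bins, ten-year decade bins anchored at 1895.
- **covariates** — year-indexed MAT/MAP and decade-indexed log human
  population density extracted at record coordinates, with block-mean
  raster aggregation and standardization metadata.
- **zonation** — ecoregion labelling (with 42°N splits) and a
  stochastic optimizer that packs non-overlapping 200 × 200 km
  equal-area cells, each holding ≥ 75 records spread over ≥ 4 decades
  with ≥ 10 records each, to serve as spatiotemporal replicates.
- **models** — linear-mixed-model suites fit by maximum likelihood:
  spatial candidates (fixed effects ⊆ {MAT, MAP, sex, season, density};
  crossed ecoregion and source random intercepts) and temporal
  candidates (+ decade; correlated random intercept/decade-slope per
  zone), ranked by AICc with Akaike weights, Nakagawa marginal and
  conditional R², and random-effect diagnostics including the zone
  slope–intercept correlation.
- **synth** — a generator for the full study system (climate surfaces,
  density layers, ecoregions, contaminated multi-source records) with
  known generative truth, so the entire chain is testable end to end.

The statistic at the heart of the temporal analysis is the correlation
r between zone random intercepts a_z and zone decade slopes b_z in

    y_i = x_i'β + a_z(i) + b_z(i)·decade_i + ε_i,   (a_z, b_z) ~ N₂(0, Σ):

r < 0 means populations of large-bodied mice are shrinking over the
decades while small-bodied populations grow.

## Worked example

```python
from sizeclines import workflow, models

bundle = workflow.simulate_bundle({"n_records": 8000, "seed": 7})
prep = workflow.prepare_dataset(bundle, "body_mass", "temporal",
                                zone_source="lattice")
fit = models.fit_lmm(prep.data,
                     models.ModelSpec("body_mass", models.TEMPORAL_GLOBAL,
                                      "temporal"))
diag = models.random_effect_diagnostics(fit)
r2m, r2c = models.nakagawa_r2(fit, prep.data)
```

prints, via the obvious f-strings:

```
n = 5558, k = 13, AICc = 23175.5
beta(MAT) = -0.396 +- 0.068
beta(decade) = -0.247 +- 0.041
marginal R2 = 0.183, conditional R2 = 0.334
slope-intercept corr: model = -0.67, BLUP = -0.89
```

Reading it: of 8,000 simulated raw records, 5,558 survive cleaning and
temporal filtering. Mass declines with temperature (Bergmann-consistent,
−0.40 g per standardized °C unit) and declines across decades
(−0.25 g per standardized decade bin) after adjusting for climate,
sex, and season. Fixed effects explain 18% of variance; adding the
zone structure brings it to 33%. Both estimates of the zone
slope–intercept correlation are strongly negative: heavy populations
trend lighter and light populations heavier — exactly the structure
the generator planted (true correlation −0.9).

The same pipeline runs from a shell:

```
sizeclines simulate --seed 7 --n 8000 --out out/
sizeclines run-all  --seed 7 --out out/
sizeclines recover  --seed 7 --out out/
```

`run-all` harmonizes all 12 dataset variants (2 traits × with/without
juveniles × spatial/temporal/NEON handling), fits the candidate suites
for the primary variants, and writes selection tables, coefficient
tables, zone scatter data, and a manifest with config, child seeds and
artifact digests.

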