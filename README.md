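# isowue

Community-level analysis of leaf **intrinsic water-use efficiency (iWUE)**
along aridity gradients, derived from bulk-leaf stable isotopes.

In arid and semi-arid grasslands, the balance a leaf strikes between carbon
gain and water loss — iWUE = A/gs, the ratio of photosynthetic rate to
stomatal conductance — is a central axis of plant strategy. Bulk-leaf
carbon isotope ratios record this balance in time-integrated form:
photosynthetic discrimination

Δ¹³C = (δ¹³C_a − δ¹³C_L) / (1 + δ¹³C_L/1000)

is linearly related to the ratio of intercellular to ambient CO₂,
Ci/Ca = (Δ¹³C − a)/(b − a) with a = 4.4‰ (stomatal diffusion) and
b = 27‰ (Rubisco fixation), so that

iWUE = Ca/1.6 · [1 − (Δ¹³C − a)/(b − a)]   (μmol mol⁻¹).

Oxygen isotope enrichment of leaf tissue above source water,
Δ¹⁸O = (δ¹⁸O_L − δ¹⁸O_S)/(1 + δ¹⁸O_S/1000), serves as the companion proxy
for stomatal conductance. The package is written for ecophysiologists
working with species-by-site leaf survey tables: it takes delimited-text
tables of raw isotope and leaf-trait measurements plus per-site
environmental covariates, and runs the full community analysis chain:

- **isotopes** — Δ¹³C, Ci/Ca, iWUE, Δ¹⁸O, and the C3/C4 split at −20‰.
- **community** — per-site frequency-distribution characteristics (mean,
  variance, SD, CV, range, skewness, kurtosis), Shapiro–Wilk normality,
  one-way ANOVA with Duncan's multiple range test, within- vs among-site
  variance split.
- **varcomp** — species / site / species×site decomposition of explained
  sums of squares on unbalanced two-factor survey designs.
- **gradient** — regressions of distribution characteristics on the
  aridity index (1 − MAP/PET), Pearson correlation tables against soil
  moisture, vapour pressure deficit and soil C:N, slope-homogeneity tests,
  and variation partitioning between water and nutrient predictor sets.
- **traits** — PCA of {iWUE, Δ¹⁸O, SLA, N_area} and of the three traits
  without iWUE, with regressions of iWUE on axis scores.
- **phylo** — Blomberg's K with a tip-shuffling permutation test.
- **simulate** — a two-transect synthetic-data generator with known ground
  truth (latent iWUE targets, variance fractions, trait correlations,
  Yule phylogenies), so every estimator above can be tested against truth.

## Worked example

```bash
isowue simulate --seed 4 --out demo
isowue derive --leaf demo/leaf_samples.csv --sites demo/sites.csv --out demo/derived.csv
isowue partition --derived demo/derived.csv --out demo/ss.csv
isowue phylosignal --tree demo/phylogeny.nwk --traits demo/derived.csv --nperm 999 --seed 1
```

which prints:

```
wrote 383 leaf samples to demo
wrote 383 derived records to demo/derived.csv
species 71.0% | site 6.9% | interaction 22.1% of explained SS
K = 0.0500, p = 0.6580 (96 tips)
```

The partition line says that, of the explained variation in iWUE across
this simulated transect, most is attributable to species
identity, with site and the species-by-site interaction sharing the rest —
the typical structure for these surveys, where most iWUE variability sits
within rather than among sites. The phylogenetic-signal line reports a
Blomberg's K near zero with a non-significant permutation p-value: species
mean iWUE is not clustered on the (simulated) phylogeny, as expected since
the generator assigns species effects independently of the tree.

The same chain is available end to end from a YAML config
(`isowue run-all --config config.yaml --seed 1 --out report`), which
writes per-transect tables for every stage plus a `manifest.json` with
filter bookkeeping; identical config and seed give byte-identical bundles.

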