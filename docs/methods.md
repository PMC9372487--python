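# Methods

## Isotope model

iWUE is derived through the simple form of the carbon-isotope
discrimination model: Δ¹³C = (δ¹³C_a − δ¹³C_L)/(1 + δ¹³C_L/1000),
Ci/Ca = (Δ¹³C − a)/(b − a), iWUE = Ca/1.6·(1 − Ci/Ca). The constants are
a = 4.4‰ (fractionation during stomatal diffusion), b = 27‰ (Rubisco
fixation), and 1.6 the water/CO₂ stomatal diffusivity ratio. Mesophyll
conductance and photorespiration terms are deliberately excluded: with
them, Δ¹³C is no longer an affine function of Ci/Ca and bulk-leaf surveys
rarely have the gas-exchange data to constrain the extra parameters. The
consequences are the usual ones: absolute iWUE values carry a
species-dependent bias of a few μmol mol⁻¹, while comparative statements
(site contrasts, gradients, correlations) are essentially unaffected.

Atmospheric inputs are per-site columns with defaults Ca = 400 μmol mol⁻¹
and δ¹³C_air = −8.5‰ — plausible recent growing-season values; every
analytic identity in the package is independent of these defaults. Source
water δ¹⁸O is taken from the site table as a precipitation proxy for soil
water. Records are classified C3 when δ¹³C_L < −20‰ strictly; the
boundary value itself goes to C4 so the rule is total. Discrimination
outside [a, b] yields Ci/Ca outside [0, 1]; such records are computed,
flagged, and retained — a pipeline switch excludes them from downstream
statistics, but silent dropping is never done.

## Synthetic study design

The generator emulates a two-transect grassland survey: ten sites per
transect spanning aridity (= 1 − MAP/PET) 0.51–0.63 on the short transect
and 0.42–0.83 on the long one, species richness declining toward the dry
end, one pooled record per species per site by default (replicates are a
free parameter), and roughly 7–10% of species C4 with δ¹³C drawn from
Uniform(−16, −11)‰.

A record's latent iWUE is additive Gaussian:
`mu(site) + e_species + e_species×site + e_residual(site)`, with
mu(site) linear in aridity (intercept 30 μmol mol⁻¹, slope
90 μmol mol⁻¹ per aridity unit) plus site-level noise. The variance
budget works backwards from two observable targets: the per-site
community CV (linear in aridity: 40% − 25·aridity, so communities
converge as sites dry) fixes each site's within-site variance
s_i² = (CV_i·mu_i/100)²; the configured fractions f_species = 0.50,
f_site = 0.25, f_interaction = 0.15 are shares of the total variance
scale T = mean(s_i²)/(1 − f_site). Species and interaction effects get
variances f·T; the per-site residual absorbs s_i² minus those, which is
how the CV gradient is realised; site noise is f_site·T minus the
variance already contributed by the aridity trend (floored at zero). The
defaults put 75% of variance within sites, matching the structure such
surveys report (>60% within-site).

Leaf traits are coupled to iWUE through a one-factor Gaussian copula on
the standardized iWUE deviation z: each trait is ρ·z + √(1−ρ²)·ε mapped
to its natural scale (Δ¹⁸O: 30 ± 4‰; N_area: 2.0 ± 0.45 g m⁻²; SLA:
16 ± 3.2 mm² mg⁻¹), with default correlations +0.55 (Δ¹⁸O), +0.45
(N_area), −0.55 (SLA). The one-factor construction guarantees a
positive-definite joint correlation matrix for any |ρ| < 1; the implied
4×4 matrix is still checked by Cholesky before sampling. Leaf δ¹³C is
back-calculated by exact algebraic inversion of the discrimination chain
(so deriving traits from generated tables reproduces the latent iWUE to
1e−9 relative), and δ¹⁸O_L by inverting the enrichment formula against
the site's source water.

Species occupy contiguous blocks of 3–6 sites (seeded-random placement),
which makes the design unbalanced like real transects; `None` switches to
full occupancy for calibration tests that need balance. Site covariates
are linear in aridity with small Gaussian noise; VPD is derived from a
temperature and relative-humidity trend through the Magnus form
es(T) = 0.6108·exp(17.27·T/(T + 237.3)) kPa, with supersaturation clipped
at zero.

Phylogenies are pure-birth (Yule, rate 1) trees from dendropy. The
simulator stops at the n-th speciation, leaving zero-length terminal
branches; one further Exp(n) waiting time is added to every tip edge —
the correct completion of the Yule process — so trees stay ultrametric
with positive terminal branches. Tip labels are assigned to species in
seeded-random order: species ids are ordered by site block, and
traversal-order labelling would alias spatial structure into spurious
phylogenetic signal. Species effects are drawn independently of the tree,
so generated datasets carry no signal by construction; Brownian and
tip-shuffled trait simulators provide known-signal and signal-free
fixtures for the K statistic.

What the generator does *not* emulate: spatial autocorrelation of site
covariates beyond the aridity trend, non-Gaussian trait distributions,
intraspecific trait-environment interactions, water-source partitioning
among coexisting species, and measurement error on isotopes. Passing
recovery tests therefore show the estimators are correct and calibrated
under the stated generative model, not that real surveys satisfy that
model.

## Statistical conventions

- Distribution characteristics: sample (n−1) variance; bias-corrected
  skewness G1 and excess kurtosis G2 (the conventions of mainstream
  commercial statistics software); CV in percent. n = 1 yields the mean
  only, with the rest flagged missing.
- Shapiro–Wilk delegates to scipy (3 ≤ n ≤ 5000, non-constant input).
- Duncan's multiple range test: least significant range
  R_p = q(1−(1−α)^(p−1); p, df)·√(MS_within/n_h) with the
  studentized-range quantile evaluated numerically (no tables), n_h the
  harmonic mean of the span's group sizes, α = 0.05; spans inside a
  homogeneous span are never subdivided. In the two-group case this
  reduces exactly to the pooled t-test at α.
- Variance components: partial (Type II) sums of squares by nested
  least-squares RSS comparisons on explicit dummy designs, interaction
  entered last; sequential (Type I) behind a flag. RSS differences remain
  well-defined on rank-deficient missing-cell designs, where the classical
  closed forms do not. Percentages are shares of explained SS, so the
  three terms sum to 100 whenever the interaction is estimable (it is
  dropped, with a marker, when observed cells add no df over the additive
  model). With one observation per fully crossed cell the saturated model
  is interpolating and the interaction absorbs the whole remainder — the
  convention in which published species/site/interaction percentages sum
  to ≈100.
- Variation partitioning: nested-regression R² differences; both raw
  (fractions sum to one identically) and adjusted (default report,
  standard when predictor sets differ in size; negative fractions are
  reported unclipped) flavours.
- PCA: eigendecomposition of the correlation matrix by default (traits
  have incommensurable units); covariance behind a flag. Loading signs
  are fixed by making each column's largest-magnitude element positive.
  Missing rows are dropped listwise.
- Blomberg's K: with C the shared-path-length matrix,
  K = (MSE₀/MSE)_observed / [(tr C − n/(1ᵀC⁻¹1))/(n−1)], where the
  phylogenetic mean â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1). Solved via Cholesky
  factorization; zero-length terminal branches are raised to 1e−8 of tree
  height to keep C invertible; polytomies are accepted as-is. The
  permutation test shuffles trait values across tips (default 999
  permutations), measures significance on the phylogenetically corrected
  MSE (one-sided toward low MSE), and uses the add-one convention so
  p ≥ 1/(n_perm + 1) and p is never zero. Species missing from the tree
  are dropped with a warning.

## Calibration and recovery checks

The acceptance suite verifies, by simulation at fixed seeds: mean K over
200 Brownian replicates on 128-tip Yule trees within [0.9, 1.1];
Kolmogorov distance of tip-shuffled permutation p-values from uniform
below 0.1 (200 replicates, 199 permutations each); null one-way ANOVA F
with mean within 0.1 of one (1000 replicates of 5 groups × 50); recovery
of the configured within-site variance share within 3 points and of the
explained-SS shares 0.60/0.25/0.15 within 5 points. Because the
between-site sum of squares carries only k − 1 degrees of freedom, a
single dataset's share estimate fluctuates by several points at realistic
site counts; recovery is therefore assessed on the mean over seeded
replicate datasets (30 datasets of 40 sites for the within-site share;
15 balanced 30-species × 10-site × 5-replicate datasets for the SS
shares), i.e. as a property of the estimator's expectation.

Coverage of the site-mean-vs-aridity regression CI (95% nominal, ≥90/100
replicates required) is evaluated under full species occupancy. Under
block occupancy neighbouring sites share species, their community means
are positively correlated through shared species effects, and the naive
OLS interval covers the true slope in only ~80% of replicates — a known
hazard of regressing community means on gradients when composition turns
over gradually; analyses of real transect data should bear it in mind.

## Problem sizes and determinism

Default analysis runs use the two-transect study (≈400–560 records per
transect, 10 sites, ≈100–140 species); calibration simulations use the
replicate counts above. All randomness flows from explicit integer seeds
through `numpy.random.default_rng` (and a seeded `random.Random` inside
dendropy's tree simulator); the pipeline writes only deterministic text
outputs, so identical config and seed give byte-identical report bundles.
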