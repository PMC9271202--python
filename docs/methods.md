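# Methods

This note records the models implemented in `lulcrisk`, their
assumptions, the defaults and why, the numerical choices, and what the
synthetic generators do and do not emulate.

## 1. Transition-rate accounting

**Class schema.** Base map classes are {forest, pasture, cropland,
other}. The analysis schema refines forest into five states: primary
forest — never clear-cut within the observed record — in three
degradation states (UF undisturbed, LF selectively logged, LBF logged
and burned), and secondary forest (regrowth on previously cleared land)
in two age classes (SFy young, SFo old). Pasture maps to PA, cropland to
MA (mechanized agriculture); "other" is tabulated but excluded from the
18-transition report.

**Change detection.** A pixel that is forest from the first year of the
series is primary forest until its first non-forest year. Regrowth that
predates the record is indistinguishable from primary forest and is
deliberately counted as primary — the record must therefore start well
before the analysis window for old secondary forest to be detectable at
all (with a 20-y threshold and a record starting in 1985, SFo can first
appear in 2006). Forest re-appearing after a non-forest year is
secondary with age 1; the age increments per consecutive forest year and
resets to 1 on each re-entry. A pixel that was cleared can never be
primary again.

**Age classes.** Young means age ≤ 20 y and old means age > 20 y by
default. The threshold and the boundary operator are configurable
(`AgePolicy`), because ≤/</≥ conventions differ between descriptions of
this kind of analysis; the procedural (≤ 20 young) convention is the
default.

**Degradation overlay.** Logging and fire event grids drive a per-pixel
state machine on primary forest: UF →(logging)→ LF →(fire)→ LBF, both
states absorbing while the pixel remains primary; clearing resets the
history. Fire on never-logged primary forest routes to LBF by default;
a distinct burned class is available (`fire_on_unlogged="distinct"`)
because the source data for such analyses do not always distinguish the
two. Events falling on non-primary pixels are ignored with a warning.

**Rates.** For every consecutive year pair in the window, the transition
area i→j is (pixel count moving i→j) × pixel area; the mean annual rate
and its SD are taken across year pairs. The SD is the sample SD (n−1) —
an explicit assumption, since "±" is rarely defined in summary tables.
Self-transitions are excluded from the report but available. Area is
conserved exactly: per year pair the outflows of a class plus its
self-transition sum to the class's area.

**Destination allocation.** When the degradation-mapped deforestation
rate of a primary-forest state does not record the destination, it is
split by a fixed ratio, default 0.985 to pasture and 0.015 to
agriculture (the observed all-primary-forest destination split); the two
outputs sum to the input exactly. Bidirectional pairs (PA–MA, PA–SFy,
MA–SFy) are reported combined as the sum of the two directional means;
the combined SD is the quadrature sum, which treats the directions as
uncorrelated — a simplification recorded here.

**Windows.** Different map sources cover different periods (degradation
maps vs land-use maps); `tabulate_rates` takes an explicit window and
can be called per transition group with different windows.

## 2. Synthetic landscape generator

Pixels evolve as independent Markov chains under a 4×4 row-stochastic
annual matrix over the base classes; degradation events are sampled on
primary-forest pixels each year (logging with probability 0.012/y given
undisturbed; fire with 0.02/y given logged; fire given undisturbed
defaults to 0; a newly logged pixel can burn the same year). Defaults:
120×120 grid (200×200 in the recovery checks), 1 km² pixels, years
1985–2019, initial mix 60% forest / 25% pasture / 10% cropland / 5%
other, annual matrix

|        | forest | pasture | cropland | other |
|--------|-------:|--------:|---------:|------:|
| forest | 0.979  | 0.018   | 0.001    | 0.002 |
| pasture| 0.060  | 0.905   | 0.020    | 0.015 |
| cropland| 0.010 | 0.030   | 0.950    | 0.010 |
| other  | 0.005  | 0.010   | 0.005    | 0.980 |

chosen once to give a slowly deforesting forest pool, fast
pasture/secondary-forest turnover and a small cropland share — the
qualitative rate ordering seen in Amazonian map products (pasture ↔
young secondary forest largest, conversions to cropland rare).

The simulator returns the base-class grids, the event grids and the
realized (counted) transition table in the analysis schema, which is the
exact ground truth: the accounting chain reproduces it bit-for-bit
(tested). Independently, `expected_transition_stats` computes the exact
expectation *and standard deviation* of every mean annual rate from an
extended-state Markov chain (degradation states × secondary ages ×
non-forest classes), including the across-year covariance of a pixel's
repeated transitions. Rate-recovery tests therefore use closed-form
3-SE bands, not resimulated tolerances.

**What the generator does not emulate:** spatial autocorrelation of
land-cover change (pixels are independent; the accounting never uses
adjacency), sub-annual timing, cloud/gap artifacts, and edge-effect or
isolation degradation classes. Passing tests show the accounting is
correct for independent-pixel dynamics; rate *uncertainty* on real,
spatially clustered landscapes will be larger than the binomial bands.

## 3. Ecological site generator

Sites nest in catchments (18 per region by default) in two regions
("STM", "PGM"), with the 310-site class allocation UF 21 / LF 68 /
LBF 65 / SFy 33 / SFo 25 / PA 72 / MA 26 dealt round-robin into
catchments after shuffling. Responses are Gaussian:

`y = class mean + Σ slope·z(covariate) + b_catchment + b_region + ε`,

with covariates uniform on clay 5–80%, elevation 20–200 m, slope 0–25°,
standardized internally so the class means stay marginal means; slopes
are expressed in response units per covariate SD. Default class means
for the 18 variables qualitatively mirror the field system (forest-rich
taxa and above-ground carbon collapse under PA/MA; soil pH and nutrient
cations rise under agriculture; aluminum falls; soil carbon and sodium
flat). Default variance components are derived from each variable's
class-mean spread: residual SD = 0.25 × spread, catchment SD = 0.4 ×
residual SD, region SD = 0.25 × residual SD (flat variables use 15% of
the mean) — single choices, not fitted to anything. Orchid-bee richness
is generated in one region only (NaN elsewhere), emulating a taxon
sampled in a single region. Gaussian noise is the default and only
implemented family; the truth object is parameterized so heavier-tailed
alternatives can be added.

The occurrence generator draws a binary site × species matrix from two
species pools (forest / open-habitat) with occupancy 0.4 for forest
species at forest sites, 0.05 across habitats, 0.3 for open species at
open sites.

## 4. Field metrics

Total richness is a row sum of the binary matrix. Forest-species
richness counts only species recorded at least once at any primary
forest (UF/LF/LBF) site; it is undefined (an error) without primary
sites. Carbon pools are fraction × Σ component biomasses with 0.5 for
live and dead pools; the litter fraction has no default and must be
given. Soil carbon stock per layer is content × bulk density ×
thickness × 100 (Mg C ha⁻¹ from g cm⁻³ and cm), summed over layers.
The equivalent-soil-mass correction (optional, off by default) trims the
deepest layer so all profiles are compared over the same soil mass; the
reference is the lightest profile by default, the heaviest selectable —
which reference a given study used is usually unstated, so neither is
asserted.

## 5. Mixed models and single-step inference

Per response: center and scale (mean 0, sample SD 1, ddof = 1,
complete-case per variable), REML fit of class (7-level, treatment-coded
against UF) + clay + elevation + slope, with random intercepts for
catchment nested in region (statsmodels MixedLM: region as the grouping
factor, catchment as a variance component). Variables observed in a
single region drop the region term automatically. A region variance
estimated from 2 levels is weakly identified — it is kept for fidelity
to the standard design, with `region_as_fixed=True` available.
Optimization tries lbfgs, then derivative-free Powell and Nelder–Mead;
a candidate is accepted only if the optimizer reports convergence *and*
the REML log-likelihood is finite (lbfgs can park on a degenerate
boundary). Non-convergence is flagged on the result, never silent.

Contrasts are destination-minus-origin differences of class means (so a
harmful deforestation gives a negative standardized effect size);
bidirectional pairs are estimated once, oriented second-minus-first
(PA–MA means MA − PA). With estimates c'β and covariance C V C', the
single-step adjusted p-value of contrast j is P(max_k |Z_k| ≥ |z_j|)
under Z ~ N(0, R), R the correlation of the contrast statistics, and the
simultaneous (1−α) CI is estimate ± q·SE with q the equicoordinate
(1−α) quantile of max|Z|. Both are evaluated by quasi-Monte-Carlo:
scrambled Sobol points with a fixed seed (default 2¹³ points × 8
scrambles), integration error estimated from the scrambles, sample size
escalated ×4 until the error meets the tolerance (default 2.5e-4, hard
failure above 1e-3). Adjusted p-values are constrained to the
theoretical envelope [p_unadjusted, min(1, k·p_unadjusted)], which the
exact single-step quantities satisfy; the clipping only removes QMC
noise at the boundaries. One contrast short-circuits to the exact
normal answer.

The reference distribution is standard normal (large-sample mixed-model
practice, and what `multcomp::glht` uses on mixed models); a
t-with-stated-df option exists (`df=`), implemented as a chi-square
scale mixture of the same Sobol draws. Against R's `multcomp` on
identical (β, V, C) inputs, adjusted p-values agree to ~1e-3 and
simultaneous CI bounds to ~4e-3 — both methods' own integration error.

**Calibration.** Under a null simulation (7 classes × 20 sites, all
class means equal, catchment/region/residual variances 2/1/4), the
simultaneous 95% CIs cover all 15 zero differences in ≈94% of
replicates. The ≈1-point shortfall is the usual plug-in effect: the
fixed-effect covariance treats REML variance components as known, and
the z reference ignores finite-sample df. It shrinks with more
catchments and sites; a df-adjusted reference would close most of it
and is left as an extension.

**Significance and direction.** A transition affects a variable when the
adjusted p < α (default 0.05); the sign of the estimate gives the
direction. Effect sizes enter the risk stage as absolute values.

## 6. Risk linkage

Per component (biodiversity: 7 variables; carbon: 4; soil: 7) and
transition, the impact is the median |ES| across the component's
variables (midpoint convention for even counts). Transitions are ranked
by impact (stable sort; ties keep label order). The impact vector is
correlated with the mean annual rates of the same 15 transitions
(bidirectional pairs use combined rates): by default the impact vector
is Shapiro–Wilk-tested at α = 0.05 and Pearson (on log10 rates) is used
when normality is not rejected, Spearman otherwise; the method can be
forced per component. Whether log or raw rates enter a Pearson test is
ambiguous in practice; log10 is the default with a raw option (Spearman
is transform-invariant). Transitions with zero rate are dropped from a
log-scale Pearson correlation with a warning (they remain in the
quadrant classification).

Quadrants: cutoffs are the medians of the rate vector and of the impact
vector; strictly greater than the cutoff is "high", equal is "low"
(tie rule configurable). Median cutoffs make the classification
invariant to monotone transforms of either axis; with an odd number of
transitions the median transition itself is classed "low" on that axis
— a documented consequence of the strict rule.

## 7. Determinism and problem sizes

One global seed expands into independent substreams (landcover, eco,
occurrence, analysis) via `SeedSequence.spawn`, so stages can be
regenerated independently; all outputs are bit-reproducible under a
fixed config. The recovery and calibration checks use 200×200 (tests)
or 150×150 (acceptance script) landscapes over 1985–2019 with the
2006–2019 window, 1,000 (tests) or 300 (script) null replicates for
familywise coverage, and 500/200 replicates for effect-size recovery —
sizes chosen to keep closed-form tolerances tight while the whole suite
runs in minutes on one CPU.

## 8. Known limitations

- No spatial process: rates' sampling bands are exact only for
  independent pixels.
- Gaussian responses only; count-like variables with many zeros (e.g.
  tree richness in cropland) are modeled on the scaled Gaussian scale,
  as in standard LMM practice for this design; quantile-regression
  sensitivity checks are out of scope.
- The 2-level region random intercept is weakly identified; its variance
  estimate is reported but should not be interpreted.
- Simultaneous CIs under-cover by ≈1 point at the default null-design
  size (plug-in + z reference; see §5).
- Equivalent-soil-mass correction implements the fixed-reference-mass
  rule only; cubic-spline mass interpolation variants are not included.
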