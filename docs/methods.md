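# Methods

This note documents the statistical models, the synthetic-data generator's
study conditions, the numerical choices inside the REML engine, and what the
package's benchmarks do and do not demonstrate.

## The two-stage analysis

**Stage 1.** Each trial is analysed on its own plot data. Randomized
complete block trials use `yield = genotype (fixed) + replicate (random) +
error`; alpha-lattice trials add a random incomplete block nested in
replicate. Genotype BLUEs and their standard errors come from the
fixed-effect solution; stage-2 weights are 1/SE². Cullis broad-sense
heritability is computed from a companion fit with genotype random:
H² = 1 − v̄_ΔBLUP / (2σ²_g), where v̄_ΔBLUP is the mean prediction-error
variance of pairwise BLUP differences. On trials with more than 2000
genotype pairs, v̄ is estimated from a fixed-seed subsample of 2000 pairs
(sampling error on the mean is far below the reporting precision of H²).
For the generator's balanced complete-block layouts the genotype means are
exactly the stage-1 BLUEs; `stage1.cell_means` exposes that fast path and is
used inside large replicate studies where thousands of per-trial REML fits
would add nothing.

**Stage 2.** All genomic-prediction models act on the genotype-by-trial
BLUEs with residual covariance σ²_e · diag(1/wᵢ). The residual scale σ²_e is
a free parameter initialised at 1, i.e. the stage-1 error variances are used
as starting values rather than frozen; a strict known-weights mode
(`fix_residual_scale=True`) freezes the scale instead. With one trial per
environment the i.i.d. genotype-by-environment term operates at the record
level and is confounded with the weighted residual; the likelihood then has
a flat ridge along which only the sum is identified. Fits handle this
gracefully (the scale simply decays to its floor) but it is the main reason
stage-2 fits use a practical likelihood tolerance (below).

## Covariance structures

* `KnownMatrix` — σ² K for a known PSD matrix, here the VanRaden genomic
  relationship matrix K = ZZᵀ / (2Σpⱼ(1−pⱼ)) built from column-centred
  dosages. Non-PSD inputs are bent by flooring eigenvalues at
  1e-6 × mean diagonal.
* `FAKronecker` — factor-analytic environment covariance crossed with K:
  cov(ge_{ij}, ge_{i'j'}) = Σ_E[j,j'] · K[i,i'], Σ_E = ΛΛᵀ (+ diag ψ when
  `specific=True`). Reduced rank (ψ = 0) is the default; identifiability is
  imposed by zeroing loadings above the diagonal. Starting loadings come
  from the leading eigenvectors of a crude genotype-matched environment
  covariance of residualised responses. An FA(q) term requires at least
  2q+1 environments.
* `KroneckerRegression` — the reaction-norm structure: each genotype
  carries d = 1 + n_EC random coefficients with covariance Ω ⊗ K. All
  scale lives in Ω (Σ_g is K itself), which makes the parameterisation
  identifiable without a redundant genetic variance. Ω is parameterised by
  its free symmetric entries — the covariance is then *linear* in the
  parameters, which gives average-information updates near-quadratic
  convergence; indefinite proposals are rejected by the line search, and Ω
  is PSD-bent at readout should the optimum sit on the boundary. EC columns
  are centred and unit-scaled with constants estimated from the training
  rows only, stored in the fit, and reused for any prediction (no leakage
  into cross-validation).

## The REML engine

Dense average-information (AI) REML, intended for up to a few thousand
records. Per iteration: one Cholesky of V, the explicit projection matrix
P, per-parameter scores −½(tr(P·∂V) − yᵀP·∂V·Py) and the AI matrix
½HᵀPH. Non-negative variance parameters are updated on the log scale
(multiplicative steps cannot overshoot zero); loadings and Ω entries stay
linear. Steps are safeguarded by Levenberg-style adaptive damping, a
halving line search, and a steepest-ascent fallback, so the accepted
likelihood sequence is non-decreasing by construction. Aliased fixed-effect
columns are dropped in declaration order. Variance floors sit at
1e-10 × the phenotypic variance.

Convergence defaults to a relative likelihood change < 1e-8 together with a
relative parameter change < 1e-6 (parameter changes are measured against
1% of the largest parameter so that near-zero entries do not block
termination), capped at 200 iterations. Because of the GEI/residual ridge
described above, the benchmark workflows and cross-validation fits use a
documented practical tolerance of 1e-6 on the likelihood; at that point the
predictions have long stabilised while the flat-direction parameters are
still drifting by fractions of a percent.

Cross-validation refits are warm-started from the full-data parameter
estimates of the same model class — a pure speed device; the training data
of each fold still determine the optimum.

## The synthetic generator's study conditions

The generator is the study's definition, not a tuning knob. Defaults:

* **Program**: 300 genotypes over 5 years × 2 locations × 2 sowing windows
  (20 environments), 40% annual genotype turnover, one trial per
  environment, RCBD with 2 replicates; ~2300 genotype-trial cells, each
  genotype tested in ~8 environments.
* **Markers**: 1000 biallelic loci; 40 founders drawn binomial(2, p) with
  p ~ U(0.1, 0.5), progeny from random founder pairs, then inbred to 2%
  residual heterozygosity. Family structure is what makes prediction of
  untested genotypes (CV1) a well-posed problem; fully independent
  genotypes would have near-zero genomic relationships and nothing to
  borrow. With `n_founders >= n_genotypes` the generator reduces to
  independent binomial dosages.
* **Weather**: one calendar series per (year, location); daily mean
  temperature = seasonal harmonic (southern-hemisphere winter minimum)
  + year and location offsets + AR(1) noise (φ = 0.65, σ = 2 °C); diurnal
  range 10 ± 1.5 °C; wet-day probability 0.35 with gamma rain; radiation,
  humidity, cloud cover, wind and evapotranspiration derived with
  physically plausible couplings (ET rises with radiation and
  temperature). Environments sharing a season share weather.
* **Phenology**: heading ≈ 115/105/95 days after sowing for early/optimal/
  late windows, plus genotype (σ² = 25 d², MVN with K), year, location,
  G×Y, G×L and residual terms, rounded to whole days; ~30% of trials have
  20–90% of heading dates masked.
* **Yield truth** (kg/ha): μ = 5000; intercept variance σ²_g0 = 160 000;
  three active ECs (VTmax, RPP, VPP) each with slope variance
  0.30 × σ²_g0, so EC-driven GEI totals 0.9 × the intercept variance —
  chosen to mirror the GEI-to-genotype variance ratio typical of
  multi-environment wheat yield data, where interaction variance exceeds
  genotypic main variance about two-fold. Intercepts and slopes are drawn
  jointly MVN(0, Ω ⊗ K) with diagonal Ω by default. Year/location/sowing/
  trial/replicate/plot variances: 500 000 / 40 000 / 30 000 / 15 000 /
  8 000 / 80 000 (per-trial H² ≈ 0.8–0.95). A small i.i.d. GEI term
  (15 000) represents interaction unrelated to the ECs. The
  `misspecified` switch adds rank-2 environment-loading GEI
  (variance 100 000) that no EC can explain — the regime in which a
  factor-analytic model should overtake the reaction norm for known
  genotypes in known environments.

What the generator does *not* emulate: spatial field trends, non-linear
(threshold) yield responses, weather-driven environment means beyond the
fixed EC effects, stage-wise selection (a single turnover rate stands in
for PYT/AYT/EYT promotion), and per-genotype harvest dates (harvest is a
trial constant). Passing benchmarks therefore demonstrate correctness of
the machinery and qualitative model behaviour under a linear reaction-norm
world, not performance on any real dataset.

## Benchmark designs and problem sizes

* **Slope recovery** runs at the full default scale (300 × 20 × 1000,
  ~2300 cells) through the complete pipeline: stage-1 REML, heading-date
  prediction for the masked cells, EC construction, and the reaction-norm
  fit with the three true ECs.
* **VIP recovery** uses 100 replicates of a wide program (10 years × 4
  locations × 3 sowing windows = 120 environments, ~2000 cells) with a
  response carrying 0.5 SD effects on seven active covariates spanning
  distinct meteorological axes (VTmax, RPP, VPP, GSR, RWS, VTA, RFD) plus
  unit noise. Two design facts drive this layout. First, covariate
  selection from yields is an environment-level problem: with only 20
  environments (10 independent weather seasons) chance environment-level
  correlations of order 0.3–0.5 swamp any importance measure, so the study
  uses the many-environment regime where the question is well posed.
  Second, recovery of near-collinear duplicates (the three vegetative
  temperature means correlate > 0.95) is ill-posed for any selector; a
  recovery study needs identifiable actives, hence the seven distinct
  axes. VIP is a *marginal* importance measure: inactive covariates that
  aggregate correlations with several actives can still outrank a weakly
  correlated active, which is why the acceptance bar is five of seven
  rather than all seven.
* **Cross-validation benchmark** runs on a reduced program (120 genotypes,
  10 environments, 400 loci, turnover 0.25 so that each genotype is tested
  in ~8 environments — the same per-genotype environment count as the full
  design; halving it would handicap the reaction norm, whose slopes are
  estimated from within-genotype environmental contrasts). Five-fold CV1
  and CV2 use 5 iterations; CV0 is leave-one-environment-out. The truth
  model (FA2 GEI + genotype-by-trial) is fitted once on the full data and
  shared by all schemes; predictions for masked cells are scored by
  within-trial Pearson correlation (within-environment, after centring,
  for the factor-analytic model — its predictions carry environment-level
  interaction structure that would otherwise inflate pooled correlations).
  Non-converging fold fits are recorded as missing, never zero-scored.
  Median abilities at this scale carry appreciable Monte Carlo variability
  across generator seeds (the realized spread of the active ECs across ten
  environments differs seed to seed, and with it the GEI share the reaction
  norm can exploit); the benchmark therefore runs under a fixed seed and
  its orderings are read as qualitative, not as universal margins.
* **Heading prediction** masks heading dates at the default regime (30% of
  trials, 20–90% of genotypes) on a 160-genotype, 8-environment program
  and correlates the model's filled values with the generator's truth.
* **Variance decomposition** regenerates a program with zero fixed EC
  effects (isolating the random decomposition) and refits the plot-level
  model with all eleven i.i.d. terms. Year and location effects have only
  a handful of realized draws, so the estimable target is the *realized*
  variance of those draws, not the configured one; similarly the
  genotype-main versus interaction split is weakly identified under
  turnover and relatedness, and only their sum is compared tightly.

## Numerical and design choices

* Anthesis is proxied by heading (offset constant `ANTHESIS_OFFSET = 0`,
  user-changeable); the critical window is the 31-day span heading−20 …
  heading+10 inclusive, and the three phases tile [0, harvest] exactly.
* Frost days count tmin ≤ 0 °C (meteorological frost); threshold covariates
  use strict inequalities as named (T>25, T<15, T<4); evapotranspiration
  and precipitation are summed (fluxes), everything else averaged. The
  photothermal quotient averages daily radiation/temperature ratios and
  excludes days with tmean ≤ 0 to avoid division blow-ups.
* PLS uses scikit-learn's NIPALS with internal centring/scaling; the
  component count is chosen by 10-fold cross-validated RMSEP capped at 10
  unless given. VIP follows the standard projection-importance formula and
  satisfies mean(VIP²) = 1 by construction. Responses are centred per
  environment by default (`center_by_env`), which targets GEI-relevant
  signal; the VIP benchmark documents when the uncentred, many-environment
  regime is the right tool. Ties at the selection cut are broken by
  lexicographic column name and logged.
* Two-stage weights: strictly positive and finite by construction
  (boundary-zero standard errors are replaced by the trial median in the
  fast path).
* The sowing windows are month-day constants (May 15 / June 15, both
  inclusive of the optimal window); dates are handled internally as
  inclusive day offsets from sowing.
* Marker QC order: filter (MAF < 0.05, heterozygosity > 0.10,
  missingness > 0.80) first, then per-locus mean-dosage imputation —
  deterministic and sufficient for relationship-matrix construction on
  synthetic data.

## Known limitations

* The dense engine scales as n³ per iteration; a few thousand records is
  the practical ceiling.
* The FA likelihood can split total genetic variance between the genotype
  main term and an all-positive Σ_E almost arbitrarily (only the sum is
  well identified); interaction BLUPs are unaffected.
* CV0 predictions for the reaction norm use the held-out environment's own
  weather- and phenology-derived ECs; environment intercept and i.i.d. GEI
  are unknowable for a new environment and enter as zero, which leaves
  within-environment rankings intact but means absolute levels are not
  predicted.
* Forward stepwise EC selection is exposed as a generic driver over a
  caller-supplied cross-validated scoring function; combinations that fail
  to converge are recorded and skipped, and ties are logged.
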