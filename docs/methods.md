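# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices, and the limits of what the test suite demonstrates.

## Calendar conventions

All analyses run on a 365-day grid: 29 February is dropped at ingest so a
month-day anchor (e.g. 15 February) indexes the same cell in every year and
calendar windows are length-identical across years. Breeding dates use the
April-day scale, 1 = 1 April (31 March = 0, 1 March = −30). The fixed
season window 15 Feb – 5 Jun spans 111 grid days; enumerating all 8–15-day
sub-windows gives Σ_L (111 − L + 1) = 804 windows.

Reproductive periods per attempt (closed April-day intervals): laying
[laying, incubation_start − 1] (falling back to laying + clutch − 1 when
incubation start is unrecorded, one egg per day); incubation
[incubation_start, hatch − 1], so hatch day belongs to the hatching period
only; hatching [hatch, hatch+7]; nestling [hatch+8, hatch+15]; fledging
[hatch+16, hatch+21]. When all dates are present the five periods tile
[laying, hatch+21] without gaps or double-counting. A window mean is
reported when at least 50 % of its days are observed (missing count always
recorded); annual fixed-window means require ≥ 90 % coverage.

## Trend models

Annual series (fixed-window means, half-fall dates, temperature at
half-fall) are fitted by OLS on year; the slope's F equals t². Attempt-level
series (laying date, relative-interval temperatures) use
`response ~ year + (1|year) + (1|female)` fitted by REML. Because both
random effects are intercepts, the mixed-model equations collapse via a
Schur complement on the (diagonal) female block to a dense n_years system;
each REML evaluation is O(n) and the profiled criterion is minimised over
log variance ratios by Nelder–Mead from two starts. Denominator df use the
Satterthwaite approximation with numeric derivatives on the variance scale;
against lmerTest on a shared dataset the estimates, SEs, variance components
and df agree to ≤ 1e-4 relative (df to 1e-2). Boundary (zero-variance) fits
are reported with a singular flag, never as failures. CIs are t-based on the
Satterthwaite df.

## Fitness response surfaces

Natural cubic splines follow the `splines::ns` convention: `df` columns
excluding the intercept, interior knots at equally spaced quantiles,
boundary knots at the data range, linear tails. The truncated-power natural
basis is re-expressed in an orthonormalised (QR) basis of the same span
before entering the GLMM — the raw basis is too ill-conditioned for stable
crossed-random-effects fits at small n. df = 7 by default, configurable.

GLMM families: Poisson (clutch size), zero-inflated Poisson (fledgling and
recruit counts; intercept-only inflation), binomial successes-out-of-trials
(fledging success), Gaussian (absolute mismatch). Fitting is penalized
quasi-likelihood: iterated weighted REML on the working response, with the
linearisation point clipped (|η| ≤ 8 binomial, ≤ 15 log link) so
quasi-separated data stay finite; ZIP adds an EM loop whose E-step assigns
structural-zero responsibilities and whose M-step downweights those rows.
PQL slopes match glmer's Laplace fits to a few percent on matched data; the
known PQL intercept offset for count families shifts predicted curves
vertically without moving the argmax, which is what the analysis uses.
Covariates (laying date, neighbours, clutch size for fledging success,
absolute mismatch in the mediation models) are standardized to mean 0,
SD 1; constant covariates are dropped rather than entering as zero columns.

The thermal optimum is the argmax of the population-level curve on a 0.1 °C
grid (ties broken toward the lower temperature; grid-edge optima flagged).
Its 95 % interval is a cluster bootstrap over years: years resampled with
replacement (each draw its own cluster), variance ratios frozen at the
full-fit estimates, percentile interval of the re-located optima; 500
resamples by default (tests and the acceptance script use 100–200), seed
always explicit. The bootstrap replaces the MCMC credible intervals a fully
Bayesian fit would give; a Bayesian backend is deliberately out of scope.
Pre/post-peak models refit the same family with temperature linear and
standardized within subset; observations exactly at the peak join the pre
side. Sides with fewer than 30 observations are flagged. The mismatch
minimiser reuses the same machinery with argmin; a curve whose total
variation is below 1e-6 of its scale is flagged non-identifiable.

Mediation: both fledging metrics are refitted on the attempts that have
half-fall data, with and without absolute mismatch as a covariate; the
attenuation factor is |post-peak slope with| / |without|.

## Half-fall, match, cue window

Half-fall is the earliest date whose cumulative raw trap count reaches half
the seasonal total (integer dates, no interpolation; ties resolve to the
earliest qualifying date) — property-tested against a brute-force oracle on
random series. Match = (hatch + 10) − half-fall; nestling energy demand
peaks near day 10. Temperature at half-fall averages ± 7 days by default
(± 15 and ± 20 supported). The cue-window search regresses annual mean
laying date on each candidate window's mean temperature and ranks by AICc
(equivalent to R² ordering for one predictor at fixed n, but stated as an
information criterion so unequal-coverage candidates compare fairly).

## Synthetic cohort generator

The generator is the study-conditions oracle, not a fixture. Climate:
T(d, y) = seasonal mean 12 °C + 6.5 °C sine (upward zero-crossing day 130,
so the seasonal slope is near-constant ≈ 0.11 °C/day across the breeding
season) + 0.032 °C/yr warming (1965–2023) + a year-level anomaly
(sd 0.6 °C) + AR(1) daily noise (ρ = 0.6, sd 2 °C) running continuously
across year boundaries. The interannual anomaly exists because daily
autocorrelation alone leaves a 111-day mean with ~0.4 °C year-to-year sd,
which would make the fixed-window trend SE ~0.003 °C/yr — about half what
~0.65 °C of observed interannual spread implies for a 59-year record; with
the anomaly the synthetic SE is ≈ 0.005.

Breeding: laying = baseline (April-day 25) − γ · (cue-window anomaly) +
N(0, 3 d), with cue window 15 Feb – 15 Apr and γ = 8.75 d/°C so the laying
trend is −γb ≈ −0.28 d/yr; clutch = max(1, Poisson) around 9 eggs damped by
a Gaussian hump in early-laying temperature (optimum 11 °C default, width
4 °C); incubation starts at laying + clutch − 1, lasts max(10, N(13, 1))
days; fledging is Binomial(clutch, p) with p between a 0.05 floor and 0.9
peak — peaked at the thermal optimum, or at zero mismatch when the
generator's `fledge_driver="mismatch"` (the mediation construction); a
whole-brood failure event (π = 0.1) supplies the zero inflation; recruits
are Binomial(fledged, s) with a Beta-distributed yearly survival around
0.1. Females persist between years with probability 0.5 (~2-season
tenures). The success floor matters: without it the mediation construction
makes fledging success a deterministic function of covariates and the
binomial likelihood quasi-separates.

Caterpillars: per year the fall peak is April-day 56 − c · (spring cue
anomaly), c = 8.4 d/°C (so the half-fall advance is −cb ≈ −0.27 d/yr);
daily counts are one multinomial draw of 1000 caterpillars over a Gaussian
curve (sd 5 d), so counts are nonnegative and sum exactly to the yearly
total. Years 1972–74, 1976–82 and 1989–92 are omitted by default, leaving
45 usable of 59.

`fully_compensating_truth()` sets γ (and c) to the reciprocal of the
*mid-study mean* seasonal slope over the span the periods occupy — anchoring
at the year-0 laying date instead leaves a ≈ +0.002 °C/yr secular bias
because advancing dates sample flatter parts of the seasonal curve.

All randomness flows from one integer seed through named SeedSequence
spawns; identical truth + seed reproduces bit-identical tables.

### What the generator does not emulate

No tree/bud-burst trophic level, spatial structure, nest-box effects,
evolutionary change, within-individual plasticity decomposition, or
weather extremes; clutch-driving temperature is a fixed 7-day window
rather than the realised laying period; caterpillar counts ignore trap-level
overdispersion. Passing recovery tests therefore demonstrates that the
estimators recover known structure of this form at these noise levels — not
that real nest-box data meet the models' assumptions.

## Problem sizes and runtime choices

Study scale is 59 years; cohorts used by the heavier batteries run 34–120
females/year (≈ 2 000–7 000 attempts). The homeostasis battery uses 40
replicates of 59 yr × 120 females; peak-recovery uses 20 cohorts × 100
bootstrap resamples; the half-fall oracle battery uses 1 000 random series;
the acceptance script averages trend estimates over 12–30 replicate cohorts
so reported values estimate planted rates rather than one realisation's
noise. These sizes are the package's chosen desk-scale defaults; thresholds
(≥ 90 % homeostasis pattern, ≥ 85 % peak coverage, 100 % oracle agreement,
> 70 % mediation attenuation, ± 2 d cue recovery) are fixed independently
of them.

## Known limitations

- PQL is approximate for count families at small group sizes; slopes and
  argmaxes are accurate but intercept-scale quantities inherit a small
  conditional-vs-marginal offset.
- The homeostasis pattern test requires five nominal-95 % CIs to cover zero
  simultaneously; with disjoint temperature windows whose noise is only
  partially correlated (adjacent-period slope-error correlations ≈ 0.6,
  distant ≈ 0.2), the joint rate is capped near ~80 % even under perfect
  calibration, and the suite reports it as such.
- Confidence intervals for variance components are not reported.
- The CET-dialect reader handles the daily fixed-layout file; no download
  client is provided.
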