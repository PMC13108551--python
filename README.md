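# thermotrack

Analysis tools for **phenological thermal-niche tracking**: does a
population's shift in reproductive timing keep the temperatures it actually
experiences during breeding stable, even as the calendar-date climate warms?

The package was built around long-term individual-based breeding studies of
cavity-nesting songbirds (great-tit-style nest-box data: laying date, clutch
size, hatch date, fledglings, recruits) paired with a daily temperature
record and a caterpillar water-trap series, but every component works on any
data in the same shape.

## The analysis chain

1. **Fixed vs relative interval trends.** The yearly mean temperature of a
   fixed calendar window (default 15 February – 5 June, 111 days) is
   regressed on year (OLS), giving the local warming rate *b*. The same
   temperature record is then re-averaged over five windows anchored to each
   nest's own timing — laying, incubation, hatching (hatch + 0–7 d),
   nestling (+8–15 d), fledging (+16–21 d) — and each attempt-level series
   is fitted with a linear mixed model
   `temp ~ year + (1 | year) + (1 | female)` (REML, Satterthwaite df). Flat
   relative trends alongside a positive fixed trend are the signature of
   thermal homeostasis through plasticity. All 804 calendar sub-windows of
   8–15 days give a slope distribution that controls for interval length.
2. **Temperature–fitness surfaces.** Each reproductive-success measure is
   modelled against period temperature through a natural cubic spline
   (df = 7) in a GLMM with year and female random intercepts and
   standardized laying-date/neighbour (plus clutch) covariates — Poisson for
   clutch size, zero-inflated Poisson for fledgling and recruit counts,
   binomial (fledglings out of clutch) for fledging success. The thermal
   optimum is the curve argmax on a 0.1 °C grid with a cluster-bootstrap
   (over years) 95 % interval, followed by linear pre-/post-peak GLMMs.
3. **Trophic mismatch.** The caterpillar **half-fall date** (earliest day
   the cumulative trap count reaches 50 % of the seasonal total) tracks the
   food peak; `match = (hatch + 10) − half-fall`. The package fits half-fall
   trends, temperature-at-half-fall trends (± 7/15/20-day windows),
   Gaussian spline models of absolute mismatch vs period temperature, and a
   paired with/without-mismatch comparison that measures how much the
   post-peak fitness slope attenuates when mismatch is controlled.
4. **Cue-window search.** An AICc-ranked sliding-window regression finds
   the calendar window whose mean temperature best predicts annual mean
   laying date.
5. **Synthetic cohort generator.** `thermotrack.simulate` produces climate
   (seasonal cycle + linear warming + interannual anomaly + AR(1) daily
   noise), a plastic breeding cohort, and caterpillar falls, with every
   parameter recorded in a `GeneratorTruth` — the ground-truth oracle for
   the parameter-recovery tests. Defaults echo a six-decade temperate
   woodland study: warming 0.032 °C yr⁻¹ (1965–2023), laying advance
   ≈ −0.28 d yr⁻¹, fitness optima near 11 °C, half-fall advance
   ≈ −0.27 d yr⁻¹, and the 14 missing caterpillar years that leave 45
   usable ones.

## Worked example

```bash
thermotrack simulate --out cohort --seed 4        # synthetic study, known truth
cat > cfg.yaml <<EOF
output_dir: run
seed: 4
n_boot: 5
inputs:
  temperature: cohort/temperature.csv
  breeding: cohort/breeding.csv
  caterpillar: cohort/caterpillar.csv
EOF
thermotrack run --config cfg.yaml
thermotrack report run
```

`run/run_summary.json` from this exact invocation contains (abridged):

```
fixed_slope            0.0277 ± 0.0050 °C/yr   total_warming 1.61 °C
laying_slope          -0.259  ± 0.049  d/yr
n_windows              804    window_slope_mean 0.0272 ± 0.0067 °C/yr
relative_ci95          laying      [-0.0143, 0.0205]
                       incubation  [-0.0115, 0.0178]
                       hatching    [-0.0170, 0.0120]
                       nestling    [-0.0143, 0.0167]
                       fledging    [-0.0226, 0.0125]
clutch_size            peak 11.8 °C [10.75, 11.87]; prepeak +0.165, postpeak -0.092
half_fall_slope       -0.236 ± 0.054  d/yr  (45 usable years)
temp_at_half_fall      +0.0025 °C/yr
cue_window             15 Feb – 15 Apr
```

Reading it: the calendar window warmed significantly (0.028 °C/yr) while
all five individually-anchored interval trends have 95 % CIs covering zero —
the cohort's plastic laying advance (−0.26 d/yr) produced thermal
homeostasis. Clutch size peaks at 11.8 °C (the generator's planted optimum)
with rising/falling link-scale slopes on either side; the caterpillar food
peak advanced in step (−0.24 d/yr) with no trend in the temperature around
it, and the laying cue window is recovered at 15 February — all matching
the truth recorded in `cohort/truth.json`.

`run/` also contains per-stage CSVs (`trend_summary.csv`,
`window_slopes.csv`, `interval_temps.csv`, `fitness_fits.csv`,
`predicted_curves.csv`, `half_fall.csv`, `mismatch.csv`,
`cue_window_support.csv`) and `report.md` with figures.

Real data drop in the same way: a tidy `date,tmean_c` CSV **or** the Met
Office CET daily fixed-layout dialect for temperature
(`read_daily_temperature(path, dialect="cet_daily")`), plus the breeding and
caterpillar CSV schemas shown in `thermotrack/io.py`.

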