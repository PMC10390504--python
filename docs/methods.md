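# Methods

This note records the modelling choices, defaults and numerical
conventions behind `leafphen`, and what the synthetic experiments do and
do not demonstrate.

## Driver windows and photoperiod

All models consume a 365-day window of daily mean temperature and
photoperiod.  Emergence windows are anchored at 1 September of the
preceding calendar year so that autumn dormancy induction and winter
chilling lie inside the window — 1 September precedes every plausible
dormancy-induction date at mid latitudes; senescence windows are the
calendar year.  Years are standardized to 365 days by dropping
31 December of leap years (the Daymet convention, so Daymet files ingest
losslessly); window positions are treated as days of a fixed non-leap
calendar.

Photoperiod uses a standard declination/hour-angle formulation:
declination `δ = −23.44°·cos(2π(doy+10)/365)`, hour angle
`cos H₀ = −tan(lat)·tan(δ)` clamped to [−1, 1] so polar day and night
saturate at 24 h and 0 h.  The formula is smooth and symmetric
(day lengths at ±lat sum to 24 h); any standard alternative would shift
photoperiod-sensitive fits only marginally, but fitted photoperiod
thresholds are formula-relative and should not be transplanted between
implementations.

## Model conventions

- **Inclusive start:** the start day itself accumulates; a threshold is
  met on the first day the running sum is ≥ the threshold.  With unit
  rates and threshold 10 from day 1, the date is day 10.
- **Integer parameters** (start days, the DM exponents x and y) are
  searched continuously and rounded at evaluation.
- **NOT_REACHED** (threshold never attained) is an explicit sentinel,
  never an arbitrary date.  During calibration such predictions map to a
  fixed far day (the window's last reportable day + 100) so the objective
  stays finite and the search is pushed away from degenerate regions.
- **Autumn gates:** the WM trigger scan and the JM daylength gate start
  at the summer solstice (day 172).  Photoperiod below the gate threshold
  also occurs in January; without the solstice anchor both models would
  fire in winter of the same calendar year, which is not the process
  being modelled.
- **Photoperiod normalization** in PTT/PTTs/M1 is L/24 (configurable via
  one module constant); the M1 literature also uses L/10, which rescales
  the fitted F* but not the dynamics.
- **AT chill days** are counted with strict `T < T_c`; boundary equality
  is excluded.
- **DP forcing** begins at dormancy induction (the induction day itself
  accrues chilling and forcing).
- **SQ forcing** begins on the day the chilling requirement completes,
  and that day also accrues forcing.
- The preceding-spring threshold adjustment of DMs/DPDIs is linear and
  multiplicative, `threshold·(1 + α·(SOS − SOS_ref))` floored at 1e-6,
  isolated in one function (`adjust_threshold_by_sos`) for replacement;
  SOS and SOS_ref come from a fitted PTTs model run on the focal
  emergence window and on a window tiled from the site climatology
  (all available years before the focal year, capped at 30; falling back
  to all years when none precede).

## Greenness extraction

The pipeline is percentile filter → LOESS outlier replacement →
dormant-season mode fill → 50%-amplitude dating.

- The 3-day moving 50th-percentile filter is computed over date windows
  (gaps respected), removing single-day spikes in both directions.
- Outlier replacement fits a locally linear LOESS with a span covering
  about 15 days of data.  A 30-day linear span mis-tracks the logistic
  shoulders of a seasonal curve by several residual standard deviations,
  which would flag clean data; 15 days tracks the shoulders while still
  averaging ~15 points.  Residuals beyond +4 sd / below −2 sd are
  replaced by the fitted value (the asymmetry preferentially removes
  anomalous greenness drops).  The residual scale is a Gaussian-consistent
  MAD over not-yet-imputed points, so screened outliers do not inflate or
  (once replaced) deflate their own threshold.  Passes repeat until the
  series stops changing (4–6 passes typically, capped at 20), making the
  filter a projection — applying it to its own output is a no-op.  A
  residual scale under 0.2% of the seasonal range is treated as pure
  lack-of-fit and the series is returned unchanged.
- The dormant-season mode is the local maximum of a Gaussian KDE of the
  year's values at the lowest greenness; if the density has no local
  maximum the median is used with a warning.  Default dormant windows
  are days 1–75 and 320–365.
- Amplitude is seasonal maximum minus the dormant mode (one shared annual
  amplitude; the dormant mode is far more noise-robust than the annual
  minimum).  SOS is the first upward crossing of baseline + amplitude/2
  (linear interpolation between bracketing days, rounded half-up to a
  whole day, since phenology observations are integer days); EOS is the
  last day above that level.  Amplitudes at or below a configurable floor
  raise an explicit "insufficient amplitude" error, mirroring the
  screening of low-signal evergreen curves.

## Calibration

`scipy.optimize.dual_annealing` with local search disabled is the
generalized (Tsallis) simulated annealing; the iteration budget is a cap
on objective evaluations (default 50,000) and the starting temperature is
10,000.  Model prediction is vectorized across site-years (one matrix
cumulative-sum pass per evaluation), which is what makes tens of
thousands of evaluations per model affordable; an independent naive
daily-loop implementation of each model is kept in the test suite and
must agree exactly with the vectorized path on random windows.
Cross-validation refits are capped at 4,000 evaluations and seeded from
the global fit's parameters to offset the reduced budget.  k is
`max(2, min(10, ⌊n/5⌋))` — every fold has at least five samples; the cap
of 10 bounds compute.  Warm/cold site-year subsets use
linear-interpolation percentiles with inclusive cuts (≥ 75th / ≤ 25th).

## Synthetic study conditions

The generators define fixed study conditions (module `leafphen.study`):
eight sites spanning latitudes 44–47° N with annual mean temperatures
10 → 4 °C (a coastal temperate-boreal transect), seasonal amplitude 14 °C
peaking at day 200, AR(1) daily noise with ρ = 0.7 and marginal sd 3 °C,
ten focal years per site (n = 80 site-years), and integer-rounded
observation noise of sd 3 days.  Greenness curves are double logistics
(baseline 0.33, amplitude 0.10, midpoints day 140/280, noise sd 0.003,
2% outliers displaced by ±5–10 noise sd).  Ground-truth model parameters
were chosen once so that every model resolves a date for every site-year
at physically sensible times (emergence mid-May, senescence early
October) with a clear temperature signal (inter-site/inter-annual spread
of roughly 5–13 days).  Scenario ensembles draw a warming trend per
member (0.04 °C/yr for the high scenario, ~3.6 °C by 2100) with
independent AR(1) noise.

What the generator emulates: a spatial temperature gradient, serially
correlated weather, camera noise and outliers, day-integer observations,
model-structural signal.  What it does not: camera white-balance drift,
snow contamination, missing image days, species mixtures within a ROI,
spatially correlated weather between sites, non-temperature senescence
drivers (moisture, frost frequency, wind).  Passing tests therefore
demonstrate the correctness and statistical behaviour of the machinery —
filter fidelity, optimizer recovery at a known noise floor, sign-correct
climate response — not predictive skill on real canopies.

## Problem sizes and runtime choices

The recovery experiments use the full n = 80 design with a
50,000-evaluation global fit and 4,000-evaluation cross-validation refits
per model; with vectorized prediction each model completes in seconds to
~2 minutes (the spring-adjusted senescence variants are slowest; their
fixed-parameter PTTs emergence dates are cached per window batch).  The
acceptance script limits recovery to four representative models (TT,
PTTs, DM, DPDI) and one 20-member projection ensemble to keep a single
run within a few minutes; the test suite covers all fourteen.

## Known limitations

- Appendix-level source equations for the published model variants were
  not available; rate functions follow the verbal definitions and the
  cited model lineage (thermal-time family, alternating/sequential
  chilling, Dormphot, Delpierre/Jeong/White), each isolated in one small
  method so a variant form is a one-line swap.
- Default parameter bounds are plausibility brackets, not literature
  ranges; override them via the YAML mechanism for real applications.
- The annealer's visiting/acceptance hyper-parameters beyond the
  iteration cap and starting temperature are library defaults.
- Senescence windows are a single calendar year, so a senescence date in
  the following winter (beyond 31 December) cannot be represented.
- The climatology reference for DMs/DPDIs uses available prior years
  (≤ 30); with short synthetic records this is a few years, noisier than
  a true 30-year normal.
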