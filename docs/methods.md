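# Methods

## Model and estimation

greycast implements the non-homogeneous discrete grey model NDGM(1,1), a
two-term recursion on the accumulated series designed for very short annual
series (n around 10–20) where ARIMA-class models have too little data. With
`x1` the running total of annual counts,

    x̂1(L+1) = β1·x̂1(L) + β2·L + β3,   x̂1(1) = x1(1) + β4.

β1 is a dimensionless multiplier (β1 > 1: accelerating growth; β1 < 1:
saturating), β2 a linear drift per year index and β3 an intercept, both in
cumulative-count units; β4 shifts the initial condition to absorb
first-observation noise.

**Linear coefficients.** The n−1 one-step equations give the design matrix
with rows `(x1(L), L, 1)` and response `x1(L+1)`. We solve the least-squares
problem by SVD on a column-equilibrated copy of the design (the accumulated
counts dwarf the index and intercept columns by up to seven orders of
magnitude) rather than forming `(BᵀB)⁻¹BᵀY` explicitly; on well-conditioned
systems the two agree to 1e-10 and a unit test asserts this on all six study
series. A rank-deficient design (for example a constant annual series, whose
running total is exactly linear, making the first column a multiple of the
second) raises a singular-system error from the estimator; the top-level
`fit` recovers the special case where the one-step equations are still
exactly satisfiable by taking the minimum-norm solution, which reproduces
the data exactly — so a constant series is fitted as a constant.

**Initial-condition shift.** Since `x̂1(k) = z(k) + β4·β1^(k−1)`, where `z`
is the recursion seeded at the observed `x1(1)`, the SSE over k = 2…n is a
quadratic in β4 and its unique minimiser is the scalar projection
`β4 = Σ d_k w_k / Σ w_k²` with `d_k = x1(k) − z(k)` and `w_k = β1^(k−1)`.
This is algebraically the same closed form as the geometric-sum expression
usually quoted for the NDGM, but it needs no `1/(1−β1)` factors, so β1 = 1
is not a special case and no degenerate branch exists. A test cross-checks
the closed form against Brent minimisation of the SSE on random instances.
The k = 1 residual is identically zero by construction and carries no
information about β4.

**Restoration and forecasting.** Annual values are first differences of the
fitted accumulated trajectory, with the first restored value equal to
`x̂1(1)` itself (the standard inverse-AGO convention). Forecasts continue
the recursion from the last *fitted* accumulated value with the correct
year index, then difference; the default horizon is 8 years, matching an
eight-year projection window (2020–2027 for data ending 2019).

**Scoring.** MAPE over all n points by default; a `skip_first` mode
excludes the anchored first observation. Both modes are reported in pipeline
summaries because published grey-model work mixes the two conventions.

## Growth metrics

RGR(t) = ln(C_t/C_{t−1}) on the cumulative series, with unit annual steps
(the 1/(t₂−t₁) factor is 1). Running totals of positive annual counts are
strictly increasing, so RGR > 0 and Dt = ln(2/RGR) is always defined on
real data; Dt is negative for RGR > 2, and the library raises a domain
error for RGR ≤ 0 rather than dropping points silently.

Window means default to the second observed year through the third-to-last
(2006–2017 for a 2005–2019 series) and, on the forecast side, to the second
forecast year through the last (2021–2027 at horizon 8): the first forecast
RGR mixes observed and projected totals, and the late observed years are
where the study data's published layout restarts its cumulative column, so
both defaults keep the means on a clean single-regime stretch. Both windows
are explicit configuration parameters.

Growth metrics for the forecast period continue the observed cumulative
total — one running sum across the boundary. Restarting the total at the
forecast boundary (as the published tables do at 2018 and 2020, apparently a
software artifact) changes RGR's meaning mid-series; a display-only
`reset_years` option reproduces that layout in an extra column without
affecting any computed metric.

Synthetic indices blend the observed- and forecast-window means with weight
θ (default 0.5, equal weights). Rankings sort descending for RGR and
ascending for Dt with alphabetical tie-break. Year by year, Dt is a strictly
decreasing transform of RGR, so per-year orderings mirror each other
exactly; the *mean* of Dt over a window is not a monotone function of the
mean of RGR, and on the study data one adjacent pair (Pakistan and Kenya,
mean RGRs 0.0008 apart) swaps between the two orderings.

## Synthetic data

The generator inverts the model: run the recursion from `x0 + shift`,
restore annual counts by differencing, optionally multiply each annual
count by `exp(ε)`, ε ~ N(0, σ²), from a privately seeded stream.
Multiplicative log-normal noise keeps counts positive and mimics
proportional registration error in cause-of-death statistics; the generator
refuses coefficient combinations whose noise-free differences are not
strictly positive, naming the first offending year.

Defaults emulate the study setting: fifteen annual values from 2005, scale
of tens of thousands of deaths per year, mild super-exponential growth
(β1 = 1.05, β2 = 300, β3 = 1500, x0 = 30000 — coefficients of the same
relative magnitude as the fitted study countries), noise off. What the
generator does *not* emulate: age structure, competing causes of death,
reporting-system changes, or any cross-country correlation. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation chain on the model's own manifold, not robustness to real
epidemiological data quality.

A note on identifiability: a noise-free draw satisfies the recursion from
its own first observation, so refitting returns β4 ≈ 0 while the *sum*
`x1(1) + β4` reproduces the generator's seed `x0 + shift` — the
decomposition of the first value into x0 and shift is not observable, only
the seeded initial condition is. Recovery tests assert β1–β3 directly and
β4 through the initial condition. The shift estimator itself is additionally
tested on off-manifold series (first value deliberately displaced from the
trajectory), where it recovers the planted displacement exactly.

## Bundled study data and reproduction scope

The package bundles the six countries' annual CVD deaths 2005–2019,
transcribed from the published per-country tables' original-data columns
(thousands separators stripped; all derived columns excluded). Reproduction
status, all verified by the test suite:

- **Model values**: our fitted per-year values match the published NDGM
  columns to well under 0.1% median relative deviation (most cells digit
  for digit), and the published 2020–2027 forecasts to within rounding for
  five countries; the USA forecast drifts at long horizon because its
  fitted β1 ≈ 1.49 is explosive and amplifies rounding in the published
  cells, one of which is unreadable anyway.
- **Published MAPE cells do not verify**: the study prints two mutually
  inconsistent MAPE sets (e.g. 1.56 vs 2.95 for Pakistan), and neither is
  derivable from its own printed model columns, which give 0.17%. We report
  the computed value.
- **Growth cells**: the per-year Dt columns are consistent with the RGR
  formula applied to the original data and we match them; a sizeable subset
  of the printed per-year *RGR* cells (India and China 2006, USA 2007–2008,
  Kenya 2008/2016/2017, among others) contradict both the formula and the
  adjacent Dt cell, so the published per-country mean RGRs — and the
  cross-country ranking assembled from them — inherit the errors. Our
  recomputed means agree with the published ones for Pakistan (0.223) and
  Sweden (0.208) and with the published mean *Dt* for all of Pakistan
  (2.397), Kenya (2.400), and the published value multiset generally, but
  the recomputed original-data RGR ranking is
  India > China > Kenya > Pakistan > USA > Sweden, not the published
  ordering. The ranking operation reproduces the published sequence when
  fed the published means; the pipeline reports the recomputed one.
- **Forecast-period means**: published values are based on the restarted
  cumulative layout and are not reproducible under continuous accumulation;
  they are used only as inputs when reproducing the synthetic-index blends
  (e.g. Sweden 0.5·0.208 + 0.5·0.254 = 0.231).

## Numerical choices and limitations

- Display rounding is half away from zero at 3 decimals, matching the
  published tables; every CSV emits full-precision values alongside the
  display column. All comparisons in code use full precision.
- The pipeline is deterministic end to end; only the synthetic-data
  generator consumes randomness, always from an explicit seed.
- Problem sizes everywhere are tiny (n ≤ ~20 per series, six series), so
  the full test suite and the reproduction script run in seconds.
- The doubling-time statistic is the transform ln(2/RGR) of cumulative
  growth; it is not a demographic claim that deaths will literally double
  in that many years, and the package does not interpret it further.
- NDGM forecasts extrapolate a fixed recursion; with β1 well above 1
  (USA here) long-horizon projections grow explosively and should be read
  as trend continuation, not as calibrated predictions.
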