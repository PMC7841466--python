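# Methods

## Model and assumptions

The package implements a deliberately minimal kinetic model for the window
between cancer diagnosis and treatment, typically a few months and hence a few
doubling times:

1. **Exponential primary growth.** The primary tumor cell count is
   `P(t) = P0 · e^{g t}` with `t` the delay in months since diagnosis. No
   saturation (Gompertz, power-law) is modeled; over a few doubling times the
   exponential regime dominates and keeps the parameter count minimal.
2. **Cell-count-proportional metastasis hazard.** New metastases form as a
   nonhomogeneous Poisson process with hazard `M(t)` obeying
   `dM/dt = k·P(t)`, so `M(t) = M0 + (k P0/g)(e^{g t} − 1)` and the
   probability of at least one new metastasis by `t` is
   `PM(t) = 1 − exp(−Λ(t))` with `Λ(t) = M0 t + k P0 t² φ(g t)`,
   `φ(x) = (e^x − 1 − x)/x²`. `M0 = 0` throughout: patients are assumed
   metastasis-free at diagnosis. Surface-area-proportional emission and
   metastasis-to-metastasis seeding are out of scope.
3. **Poisson TCP.** If treatment leaves each of the `P(t)` cells surviving
   independently with probability `S`, local control requires zero survivors:
   `TCP(t) = exp(−S P0 e^{g t})`.
4. **Normally distributed growth rates.** Across patients
   `g ~ Normal(G, σ)`, untruncated: negative rates model spontaneous
   regression and are intentionally retained, which is why the lung risk
   bands touch zero at short delays.

"TCP loss" is `100·(tcp0 − E_g[TCP(t)])` in percentage points against the
no-delay baseline `tcp0 = exp(−S·P0)` (exactly 0.9 for the bundled sets, by
construction of `S`); "new-metastasis risk" is `100·E_g[PM(t)]`.

## Calibration

The chain runs at full precision with no intermediate rounding:

| step | formula | bundled values |
|---|---|---|
| `P0` | sphere volume × 10⁸ cells/cm³ | 6.54e6 (lung, 0.5 cm), 1.41e9 (head & neck, 3.0 cm), 6.54e9 (colorectal, 5.0 cm) |
| `S` | `−ln(tcp0)/P0`, `tcp0 = 0.9` | 1.61e−8, 7.45e−11, 1.61e−11 |
| `G` | `ln 2/(doubling days / 30)` | 0.0598, 0.210, 0.099 /mo |
| `σ` | geometric mean of one-sided spread estimates | 0.0361, 0.0282, 0.032 /mo |
| `k` | closed form from one upstaging observation | ≈1.37e−10, 1.53e−12, 1.92e−12 |

**Months.** All rates are per 30-day month; this convention is what makes the
doubling-time conversions land on the values above.

**σ from doubling-time spreads.** A *shorter* doubling time is a *faster*
rate, so the lower day-bound maps to the upper growth-rate bound. Each
one-sided offset of a converted bound from `G` is divided by `z` (2 when the
spread is a full range read as `G ± 2σ`; 0.674 when it is an interquartile
range, each quartile sitting 0.674σ from the mean) and the two one-sided
estimates are combined by their geometric mean. The two-sided `1.349σ` IQR
construction is deliberately not used; the one-sided-then-geometric-mean
recipe is the one that reproduces the bundled σ values.

**k modes.** The default `point` mode solves `PM(t_obs) = p_obs` at the single
rate `g = G`:

    k = −ln(1 − p_obs) / (P0 · t_obs² · φ(G·t_obs)).

The alternative `distributional` mode root-solves so the growth-rate-averaged
`E_g[PM(t_obs)]` matches the observation; since `PM` is convex in `g` here,
Jensen's inequality makes the distributional `k` smaller (about −0.7% for
head and neck and −1.8% for lung relative to point mode). Both modes sit
within a few percent of the three published rounded constants; `point` is the
default for determinism and simplicity.

**Precision modes.** `derived` is the full-precision chain throughout.
`printed` (the default used for the risk table) keeps the full-precision
chain for `P0, S, G, σ` but substitutes the published rounded `k`; this
combination reproduces every published table cell to within 0.01 pp, which
indicates the original table was computed from unrounded intermediates with
the rounded `k`.

## Numerical choices

- **Stability near `g = 0`.** All closed forms are expressed through
  `ψ(x) = (e^x − 1)/x` and `φ(x) = (e^x − 1 − x)/x²`, computed via `expm1`
  with a quartic series branch below `|g t| < 1e−4` (series truncation error
  < 1e−16 relative there). The mixture integrates across `g = 0`, so the
  forms must be continuous there; tests check ±1e−12 against the limit.
- **Quadrature.** Expectations over `g` use 128-node Gauss–Hermite (tests
  verify 64 vs 128 nodes agree to 1e−8 relative). `σ = 0` short-circuits to
  the point evaluation.
- **Percentiles.** TCP, PM and P are monotone in `g` at fixed `t`, so the
  q-quantile is a single evaluation at `g = G + z_q σ` (orientation flipped
  for the decreasing TCP); `z = ±1.959964` for the 95% band. The published
  intervals are reproduced exactly under this percentile reading, which is
  therefore adopted over a delta-method normal CI.
- **Display conventions.** Percentage-point quantities round to 2 decimals;
  negative TCP-loss lower bounds (regressing-tumor mass) floor at 0.00 in the
  table and curves. Full precision is always available from the library and
  the `--full-precision` CLI flag.
- **Degenerate inputs.** `t < 0`, non-positive geometry, observation
  probabilities outside [0, 1), inverted doubling-time bounds and duplicate
  cancer labels are rejected with `ValueError`.

## Monte-Carlo cohort oracle

`simulate_cohort` draws per-patient growth rates from `Normal(G, σ)`, then
local control as Bernoulli with the Poisson-zero probability (optionally by
sampling the surviving-cell Poisson count and requiring zero — identical in
distribution) and metastasis occurrence as Bernoulli with `PM(g, t)`.
`simulate_event_times` generates full event-time sequences by thinning
against the majorant `M(t_max)`, valid for every `g` since `M' = kP(t) > 0`.
A root `SeedSequence` spawns one substream per random quantity, making
results bitwise reproducible per seed. The simulator shares only the
closed-form probability evaluations with the analytic route, so agreement
within Monte-Carlo error (checked at n = 10⁶ per cohort in the tests, and
n = 10⁵ in the acceptance script) validates the quadrature and percentile
machinery.

What the simulator emulates is exactly the model's own stochastic semantics —
it is a consistency oracle, not a source of real-world realism: passing tests
show the analytic and stochastic routes agree, not that the exponential /
proportional-hazard assumptions hold in patients.

## Known limitations

- Exponential growth and cell-count-proportional hazard are short-horizon
  approximations; beyond ~1 year, saturating growth and surface-area emission
  models would be needed.
- `k` rests on a single (probability, time) calibration point per cancer with
  substantial clinical uncertainty; the published rounded constants differ
  from the exact closed-form recalculation by 1–2% (direction inconsistent),
  so `k` should be read to no better than a few percent.
- The normal growth-rate mixture is a convenience; its untruncated left tail
  slightly inflates the favorable bounds for slow tumors.
- No survival/mortality extrapolation, stage migration beyond the single
  calibration point, or uncertainty in `P0` and `S` is modeled.
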