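# delayrisk

Quantitative estimates of what a delay in cancer treatment costs a patient:
how much **local tumor control probability (TCP)** is lost, and how much the
risk of a **new distant metastasis** rises, as a function of the delay in
months. The package is aimed at radiation oncologists, modelers and
health-policy analysts who need order-of-magnitude, parameter-transparent risk
numbers for triaging treatment postponements (e.g. during pandemic surges),
not patient-level predictions.

## Model

The primary tumor grows exponentially from its size at diagnosis, and new
metastases arise as a nonhomogeneous Poisson process whose hazard is
proportional to the instantaneous primary cell count:

    P(t)  = P0 · e^{g t}
    M(t)  = M0 + (k P0 / g)(e^{g t} − 1)            (dM/dt = k P(t))
    PM(t) = 1 − exp(−∫₀ᵗ M(u) du)
    TCP(t) = exp(−S · P0 · e^{g t})                  (Poisson TCP)

with `P0` the initial cell count, `S` the surviving fraction after treatment,
`k` the metastasis proportionality constant and `M0 = 0` (no metastases at
diagnosis). Patient heterogeneity enters through `g ~ Normal(G, σ)`, which
admits dormant (`g = 0`) and regressing (`g < 0`) tumors; population means are
Gauss–Hermite quadrature over this mixture and 95% intervals are percentile
evaluations at `g = G ± 1.96 σ`.

The five parameters are calibrated from literature summaries: `P0` from the
diagnosed diameter (sphere at 10⁸ cells/cm³), `S` from a 90% baseline TCP,
`G` and `σ` from the median and spread of volume doubling times (30-day
months), and `k` from one observed upstaging fraction at a stated delay.
Three calibrated cancers are bundled: `head_and_neck` (3.0 cm, doubling time
99 d), `colorectal` (5.0 cm, 211 d) and `lung` (0.5 cm NSCLC, 348 d). A
seedable Monte-Carlo cohort simulator independently cross-checks every
analytic expectation.

## Worked example

```sh
$ delayrisk table
cancer,delay_months,tcp_loss_mean,tcp_loss_lo,tcp_loss_hi,met_risk_mean,met_risk_lo,met_risk_hi
head_and_neck,2.0,4.84,3.37,6.4,0.49,0.47,0.51
head_and_neck,6.0,21.26,13.4,30.42,5.96,5.23,6.8
colorectal,2.0,2.06,0.7,3.54,2.69,2.58,2.81
colorectal,6.0,7.57,2.24,14.22,24.68,21.89,27.81
lung,2.0,1.22,0.0,2.79,0.19,0.18,0.2
lung,6.0,4.26,0.0,10.6,1.86,1.6,2.16
```

Each row gives, for one cancer and delay, the expected TCP loss in percentage
points against the 90% no-delay baseline with its 2.5th–97.5th percentile
band, and the probability (pp) of at least one new metastasis during the
delay. Reading the first row: a 2-month delay for a 3-cm head-and-neck tumor
costs on average 4.84 pp of local control (between 3.37 and 6.40 pp for 95%
of patients) and carries a 0.49 pp risk of a new distant metastasis. The
`0.0` lower bounds for lung reflect the mass of slow or regressing tumors for
which a short delay costs essentially nothing.

The calibration behind those rows is inspectable:

```sh
$ delayrisk calibrate --cancer head_and_neck
[
  {
    "cancer": "head_and_neck",
    "p0_cells": 1413716694.1154068,
    "surviving_fraction": 7.452731943846263e-11,
    "g_mean_per_month": 0.2100446001696804,
    "g_sd_per_month": 0.028240414780949425,
    "k_per_month_per_cell": 1.5261673797286467e-12,
    ...
  }
]
```

i.e. P0 ≈ 1.41×10⁹ cells, S ≈ 7.45×10⁻¹¹, G ≈ 0.210/mo, σ ≈ 0.0282/mo,
k ≈ 1.53×10⁻¹². Other subcommands: `curves` (dense mean/band series up to 12
months, per cancer) and `simulate` (Monte-Carlo cohorts vs the analytic
expectations, with z-scores; nonzero exit if any |z| ≥ 3). Custom tumors go
through a flat YAML parameter file (`--params`, schema in
`delayrisk.write_parameter_config`).

The same API is available in Python:

```python
import delayrisk as dr
p = dr.published_parameters("head_and_neck")
dr.expect_over_growth(p, 2.0, dr.tumor_control_probability)  # 0.8516...
dr.tcp_loss(p, 6.0)   # RiskEstimate(mean=21.26..., lo=13.39..., hi=30.42..., ...)
```

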