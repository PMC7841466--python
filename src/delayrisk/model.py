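"""Quantitative risk model for delays in cancer treatment.

The model asks: if treatment of a diagnosed solid tumor is postponed by ``t``
months, how much local tumor control probability (TCP) is lost, and how likely
is the patient to develop a new distant metastasis during the delay?

Model
-----
The primary tumor grows exponentially from its size at diagnosis,

    P(t) = P0 * exp(g * t),

and new metastases arise as a nonhomogeneous Poisson process whose hazard is
proportional to the instantaneous primary cell count,

    M(t) = M0 + (k * P0 / g) * (exp(g*t) - 1),        dM/dt = k * P(t),

so the probability of at least one new metastasis by time t is

    PM(t) = 1 - exp(-Integral_0^t M(u) du).

Local control of a tumor treated at time t follows the Poisson TCP model: if a
fraction S of the P(t) cells present at treatment survives, control requires
zero survivors,

    TCP(t) = exp(-S * P0 * exp(g*t)).

Patient heterogeneity enters through the growth rate: g is drawn from a normal
distribution with mean G and standard deviation sigma, which admits dormant
(g = 0) and spontaneously regressing (g < 0) tumors.  Population means are
computed by Gauss-Hermite quadrature over this mixture, and 95% intervals by
evaluating the (g-monotone) quantities at g = G +/- 1.96 sigma.

The five adjustable parameters (P0, S, G, sigma, k) are calibrated from
literature-style summaries: P0 from the diagnosed tumor diameter assuming
spherical geometry at 1e8 cells/cm^3; S from a 90% baseline TCP for treatment
without delay; G and sigma from the median and spread of published volume
doubling times (30-day months); and k from one observed upstaging fraction at
a stated delay.  Three calibrated cancer examples are bundled: head and neck
(fast-growing), colorectal (intermediate) and non-small-cell lung (slow).

A seedable Monte-Carlo patient-cohort simulator provides an independent
stochastic cross-check of the analytic expectations.

Sections below follow the order the method runs: numerical primitives, domain
types, single-growth-rate closed forms, parameter calibration, bundled
parameter sets and config I/O, population (mixture) estimates, Monte-Carlo
cohort, and report assembly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "DAYS_PER_MONTH",
    "CELL_DENSITY_PER_CM3",
    "GH_NODES",
    "Z_95",
    "SpreadKind",
    "TumorGeometry",
    "DoublingTimeSummary",
    "MetastasisObservation",
    "BaselineControl",
    "TumorParameters",
    "RiskEstimate",
    "CohortResult",
    "primary_cell_count",
    "metastasis_hazard",
    "cumulative_hazard",
    "metastasis_probability",
    "tumor_control_probability",
    "cells_from_diameter",
    "surviving_fraction_from_baseline",
    "growth_rate_from_doubling_time",
    "growth_sd_from_spread",
    "calibrate_metastasis_rate",
    "build_parameter_set",
    "LITERATURE_INPUTS",
    "PRINTED_PARAMETERS",
    "CANCER_LABELS",
    "published_parameters",
    "read_parameter_config",
    "write_parameter_config",
    "growth_rate_density",
    "expect_over_growth",
    "quantile_over_growth",
    "tcp_loss",
    "metastasis_risk",
    "delay_risk_table",
    "format_risk_table",
    "delay_curves",
    "simulate_cohort",
    "simulate_event_times",
    "compare_cohort_to_analytic",
]

logger = logging.getLogger("delayrisk")

# ---------------------------------------------------------------------------
# Constants and numerical primitives
# ---------------------------------------------------------------------------

#: Calendar convention for converting doubling times in days to monthly rates.
#: 30-day months reproduce the published growth rates, e.g. ln2/(99/30) = 0.210.
DAYS_PER_MONTH = 30.0

#: Tumor cell density assumed for all cancers (cells per cm^3).
CELL_DENSITY_PER_CM3 = 1.0e8

#: Default Gauss-Hermite node count for expectations over the growth-rate mixture.
GH_NODES = 128

#: Standard-normal 97.5th-percentile quantile used for the 95% intervals.
Z_95 = float(norm.ppf(0.975))

# Below this |g*t| the closed forms switch to series to avoid cancellation;
# truncation error of the quartic series is < 1e-16 relative at the cutoff.
_SERIES_CUTOFF = 1e-4


def _as_float_or_array(x: np.ndarray, scalar: bool) -> float | np.ndarray:
    return float(x) if scalar else x


def _psi(x):
    """(e^x - 1)/x, the relative-growth factor of the hazard; psi(0) = 1."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_CUTOFF
    xs = x[small]
    out[small] = 1.0 + xs / 2.0 + xs * xs / 6.0 + xs**3 / 24.0
    xl = x[~small]
    out[~small] = np.expm1(xl) / xl
    return _as_float_or_array(out[0] if scalar else out, scalar)


def _phi(x):
    """(e^x - 1 - x)/x^2, the cumulative-hazard shape factor; phi(0) = 1/2."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_CUTOFF
    xs = x[small]
    out[small] = 0.5 + xs / 6.0 + xs * xs / 24.0 + xs**3 / 120.0
    xl = x[~small]
    out[~small] = (np.expm1(xl) - xl) / (xl * xl)
    return _as_float_or_array(out[0] if scalar else out, scalar)


def _check_time(t: float) -> None:
    if not np.all(np.asarray(t) >= 0):
        raise ValueError(f"delay time must be nonnegative, got {t!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class SpreadKind(str, Enum):
    """Interpretation of the (lower, upper) doubling-time spread."""

    FULL_RANGE = "full_range"
    INTERQUARTILE = "interquartile"


# One-sided z multiplier mapping a spread bound's offset from the median to a
# standard deviation: full range read as mean +/- 2 sigma, quartiles as 0.674 sigma.
_SPREAD_Z = {SpreadKind.FULL_RANGE: 2.0, SpreadKind.INTERQUARTILE: 0.674}


@dataclass(frozen=True)
class TumorGeometry:
    """Spherical primary tumor at diagnosis.

    Parameters
    ----------
    diameter_cm : float
        Initial tumor diameter in cm; must be positive.
    cell_density_per_cm3 : float
        Clonogen density, cells per cm^3 (default 1e8 for all cancers).
    """

    diameter_cm: float
    cell_density_per_cm3: float = CELL_DENSITY_PER_CM3

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError(f"diameter_cm must be > 0, got {self.diameter_cm}")
        if self.cell_density_per_cm3 <= 0:
            raise ValueError(
                f"cell_density_per_cm3 must be > 0, got {self.cell_density_per_cm3}"
            )


@dataclass(frozen=True)
class DoublingTimeSummary:
    """Median and spread of published volume doubling times, in days."""

    median_days: float
    lower_days: float
    upper_days: float
    spread_kind: SpreadKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "spread_kind", SpreadKind(self.spread_kind))
        if not (0 < self.lower_days <= self.median_days <= self.upper_days):
            raise ValueError(
                "doubling-time summary requires 0 < lower <= median <= upper, got "
                f"({self.lower_days}, {self.median_days}, {self.upper_days})"
            )


@dataclass(frozen=True)
class MetastasisObservation:
    """Observed fraction of patients upstaged with new metastases at a delay."""

    probability: float
    at_months: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability < 1.0):
            raise ValueError(f"probability must be in [0, 1), got {self.probability}")
        if self.at_months <= 0:
            raise ValueError(f"at_months must be > 0, got {self.at_months}")


@dataclass(frozen=True)
class BaselineControl:
    """Local tumor control probability for treatment without delay."""

    tcp0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tcp0 < 1.0):
            raise ValueError(f"tcp0 must be in (0, 1), got {self.tcp0}")


@dataclass(frozen=True)
class TumorParameters:
    """The five adjustable model parameters (plus M0) for one cancer type.

    Attributes
    ----------
    p0 : float
        Initial number of primary tumor cells at diagnosis (> 0).
    s : float
        Surviving fraction of tumor cells after treatment, in (0, 1).
    g_mean : float
        Mean growth rate G, per month.
    g_sd : float
        Growth-rate standard deviation sigma, per month (>= 0).
    k : float
        Metastasis-formation proportionality constant, per month per cell (>= 0).
    m0 : float
        Initial metastasis hazard at t = 0, per month (default 0).
    label : str
        Cancer-type identifier.
    """

    p0: float
    s: float
    g_mean: float
    g_sd: float
    k: float
    m0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError(f"p0 must be > 0, got {self.p0}")
        if not (0.0 < self.s < 1.0):
            raise ValueError(f"s must be in (0, 1), got {self.s}")
        if self.g_sd < 0:
            raise ValueError(f"g_sd must be >= 0, got {self.g_sd}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be >= 0, got {self.m0}")

    @property
    def baseline_tcp(self) -> float:
        """TCP for treatment without delay, exp(-S*P0); g-independent."""
        return math.exp(-self.s * self.p0)

    def fingerprint(self) -> str:
        """Short stable hash of the parameter values, for provenance logs."""
        payload = repr((self.p0, self.s, self.g_mean, self.g_sd, self.k, self.m0))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RiskEstimate:
    """A mean with 2.5th/97.5th percentile bounds for one delay time.

    For ``tcp`` the bounds are ordinary percentiles of TCP; for ``tcp_loss``
    and ``metastasis_prob``, ``lo`` is the favorable bound (smaller loss/risk).
    Values are percentages / percentage points for the loss and risk
    quantities, probabilities for ``tcp``.
    """

    mean: float
    lo: float
    hi: float
    quantity: str
    t: float


@dataclass(frozen=True)
class CohortResult:
    """Summary of a simulated patient cohort at one delay time."""

    n: int
    t: float
    control_fraction: float
    metastasis_fraction: float
    control_se: float
    metastasis_se: float
    seed: int
    parameter_fingerprint: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


# ---------------------------------------------------------------------------
# Single-growth-rate closed forms
# ---------------------------------------------------------------------------


def primary_cell_count(params: TumorParameters, g, t: float):
    """Primary tumor cell count P(t) = P0 * exp(g*t).

    ``g`` may be a scalar or array of growth rates (per month; negative values
    model spontaneous regression); ``t`` is the delay in months.
    """
    _check_time(t)
    return params.p0 * np.exp(np.multiply(g, t))


def metastasis_hazard(params: TumorParameters, g, t: float):
    """Metastasis hazard M(t) = M0 + (k*P0/g)(e^{g t} - 1), per month.

    Evaluated as M0 + k*P0*t*psi(g*t) with psi(x) = (e^x - 1)/x, which is the
    analytic limit M0 + k*P0*t at g = 0 and stable for |g*t| near 0.
    """
    _check_time(t)
    return params.m0 + params.k * params.p0 * t * _psi(np.multiply(g, t))


def cumulative_hazard(params: TumorParameters, g, t: float):
    """Integral of the metastasis hazard over [0, t] (dimensionless).

    Closed form M0*t + k*P0*t^2*phi(g*t) with phi(x) = (e^x - 1 - x)/x^2;
    equals M0*t + k*P0*t^2/2 in the g -> 0 limit.
    """
    _check_time(t)
    return params.m0 * t + params.k * params.p0 * t * t * _phi(np.multiply(g, t))


def metastasis_probability(params: TumorParameters, g, t: float):
    """Probability of at least one new metastasis by time t: 1 - exp(-Lambda)."""
    lam = cumulative_hazard(params, g, t)
    return np.clip(-np.expm1(-lam), 0.0, 1.0)


def tumor_control_probability(params: TumorParameters, g, t: float):
    """Poisson TCP for treatment at delay t: exp(-S * P0 * e^{g t})."""
    _check_time(t)
    return np.exp(-params.s * primary_cell_count(params, g, t))


# ---------------------------------------------------------------------------
# Parameter calibration
# ---------------------------------------------------------------------------


def cells_from_diameter(geom: TumorGeometry) -> float:
    """Initial cell count from spherical volume times cell density."""
    radius = geom.diameter_cm / 2.0
    return geom.cell_density_per_cm3 * (4.0 / 3.0) * math.pi * radius**3


def surviving_fraction_from_baseline(baseline: BaselineControl | float, p0: float) -> float:
    """Surviving fraction S solving TCP(0) = tcp0, i.e. S = -ln(tcp0)/P0."""
    tcp0 = baseline.tcp0 if isinstance(baseline, BaselineControl) else BaselineControl(baseline).tcp0
    if p0 <= 0:
        raise ValueError(f"p0 must be > 0, got {p0}")
    return -math.log(tcp0) / p0


def growth_rate_from_doubling_time(days: float) -> float:
    """Exponential growth rate per month from a doubling time in days."""
    if days <= 0:
        raise ValueError(f"doubling time must be > 0 days, got {days}")
    return math.log(2.0) / (days / DAYS_PER_MONTH)


def growth_sd_from_spread(summary: DoublingTimeSummary) -> float:
    """Growth-rate SD sigma from the doubling-time spread.

    The lower doubling-time bound maps to the *upper* growth-rate bound and
    vice versa.  Each one-sided offset from the median growth rate is divided
    by the z appropriate to the spread's interpretation (2 for a full range
    read as G +/- 2 sigma, 0.674 for quartiles), and the two one-sided
    estimates are combined by their geometric mean.
    """
    g_median = growth_rate_from_doubling_time(summary.median_days)
    g_upper = growth_rate_from_doubling_time(summary.lower_days)
    g_lower = growth_rate_from_doubling_time(summary.upper_days)
    if not (g_lower <= g_median <= g_upper):
        raise ValueError("doubling-time bounds invert after conversion to growth rates")
    z = _SPREAD_Z[summary.spread_kind]
    sd_up = (g_upper - g_median) / z
    sd_low = (g_median - g_lower) / z
    return math.sqrt(sd_up * sd_low)


def calibrate_metastasis_rate(
    obs: MetastasisObservation,
    p0: float,
    g_mean: float,
    mode: str = "point",
    g_sd: float = 0.0,
) -> float:
    """Metastasis rate constant k matching one observed upstaging fraction.

    mode="point" (default) solves PM(t_obs) = p at the single growth rate
    g = G in closed form:

        k = -ln(1 - p) / (P0 * t^2 * phi(G * t)),

    equivalently -ln(1-p) * G^2 / (P0 * (e^{G t} - 1 - G t)).  mode
    "distributional" instead root-solves so that the growth-rate-averaged
    metastasis probability over Normal(G, sigma) equals the observation
    (requires g_sd).  Both land within a few percent of each other for the
    bundled cancers.
    """
    if p0 <= 0:
        raise ValueError(f"p0 must be > 0, got {p0}")
    t = obs.at_months
    target = -math.log1p(-obs.probability)
    denom = p0 * t * t * _phi(g_mean * t)
    if denom <= 0:
        raise ValueError("degenerate calibration denominator")
    k_point = target / denom
    if mode == "point":
        return k_point
    if mode != "distributional":
        raise ValueError(f"unknown calibration mode {mode!r}")
    if g_sd < 0:
        raise ValueError(f"g_sd must be >= 0, got {g_sd}")
    if g_sd == 0 or k_point == 0.0:
        return k_point

    def mismatch(k: float) -> float:
        trial = TumorParameters(p0=p0, s=0.5, g_mean=g_mean, g_sd=g_sd, k=k)
        mean_pm = expect_over_growth(trial, t, metastasis_probability)
        return mean_pm - obs.probability

    # Averaged PM is monotone in k, so the point solution brackets the root
    # within a modest factor.
    return brentq(mismatch, k_point / 10.0, k_point * 10.0,
                  xtol=k_point * 1e-14, rtol=1e-13)


def build_parameter_set(
    geometry: TumorGeometry,
    baseline: BaselineControl | float,
    doubling_summary: DoublingTimeSummary,
    metastasis_obs: MetastasisObservation,
    label: str = "",
    k_mode: str = "point",
) -> TumorParameters:
    """Run the full calibration chain at full precision.

    P0 from geometry, S from the baseline TCP, (G, sigma) from doubling times,
    then k from the upstaging observation; M0 = 0 (no metastases at diagnosis).
    """
    p0 = cells_from_diameter(geometry)
    s = surviving_fraction_from_baseline(baseline, p0)
    g_mean = growth_rate_from_doubling_time(doubling_summary.median_days)
    g_sd = growth_sd_from_spread(doubling_summary)
    k = calibrate_metastasis_rate(metastasis_obs, p0, g_mean, mode=k_mode, g_sd=g_sd)
    params = TumorParameters(p0=p0, s=s, g_mean=g_mean, g_sd=g_sd, k=k, m0=0.0, label=label)
    logger.info(
        "calibrated %s: p0=%.4g s=%.4g G=%.4g sigma=%.4g k=%.4g (mode=%s, fingerprint=%s)",
        label or "<unnamed>", p0, s, g_mean, g_sd, k, k_mode, params.fingerprint(),
    )
    return params


# ---------------------------------------------------------------------------
# Bundled parameter sets and config I/O
# ---------------------------------------------------------------------------

#: Literature inputs for the three bundled cancer examples.  Head and neck:
#: 3.0 cm stage II tumor, median (range) doubling time 99 (61-112) days, 60%
#: upstaged with new metastases at a 14.9-month median delay.  Colorectal:
#: 5.0 cm, 211 (112-404) days, 17% at 5 months.  Lung (NSCLC, stage I):
#: 0.5 cm, median (IQR) 348 (222-492) days, 8% at 12 months.
LITERATURE_INPUTS: Mapping[str, Mapping[str, object]] = {
    "head_and_neck": dict(
        geometry=TumorGeometry(3.0),
        baseline=BaselineControl(0.9),
        doubling=DoublingTimeSummary(99.0, 61.0, 112.0, SpreadKind.FULL_RANGE),
        metastasis=MetastasisObservation(0.60, 14.9),
    ),
    "colorectal": dict(
        geometry=TumorGeometry(5.0),
        baseline=BaselineControl(0.9),
        doubling=DoublingTimeSummary(211.0, 112.0, 404.0, SpreadKind.FULL_RANGE),
        metastasis=MetastasisObservation(0.17, 5.0),
    ),
    "lung": dict(
        geometry=TumorGeometry(0.5),
        baseline=BaselineControl(0.9),
        doubling=DoublingTimeSummary(348.0, 222.0, 492.0, SpreadKind.INTERQUARTILE),
        metastasis=MetastasisObservation(0.08, 12.0),
    ),
}

#: Published rounded parameter values (3 significant figures).
PRINTED_PARAMETERS: Mapping[str, Mapping[str, float]] = {
    "head_and_neck": dict(p0=1.41e9, s=7.45e-11, g_mean=0.210, g_sd=0.0282, k=1.51e-12),
    "colorectal": dict(p0=6.54e9, s=1.61e-11, g_mean=0.099, g_sd=0.032, k=1.95e-12),
    "lung": dict(p0=6.54e6, s=1.61e-8, g_mean=0.0598, g_sd=0.0361, k=1.40e-10),
}

CANCER_LABELS = tuple(LITERATURE_INPUTS)


def published_parameters(label: str, precision: str = "printed") -> TumorParameters:
    """Bundled calibrated parameter set for one cancer type.

    precision="printed" (default) runs the full-precision calibration chain
    for P0, S, G and sigma but uses the published rounded k — the combination
    that best reproduces the published risk table.  precision="derived" is the
    full-precision chain throughout, with point-mode k.
    """
    if label not in LITERATURE_INPUTS:
        raise KeyError(f"unknown cancer label {label!r}; known: {CANCER_LABELS}")
    inputs = LITERATURE_INPUTS[label]
    params = build_parameter_set(
        inputs["geometry"], inputs["baseline"], inputs["doubling"],
        inputs["metastasis"], label=label,
    )
    if precision == "derived":
        return params
    if precision != "printed":
        raise ValueError(f"unknown precision mode {precision!r}")
    return TumorParameters(
        p0=params.p0, s=params.s, g_mean=params.g_mean, g_sd=params.g_sd,
        k=PRINTED_PARAMETERS[label]["k"], m0=0.0, label=label,
    )


_CONFIG_KEYS = (
    "cancer_label", "diameter_cm", "cell_density_per_cm3", "baseline_tcp",
    "doubling_median_days", "doubling_lower_days", "doubling_upper_days",
    "spread_kind", "metastasis_prob", "metastasis_at_months",
)


def read_parameter_config(path: str | Path) -> dict:
    """Read and validate a flat YAML/JSON parameter-set file.

    Returns a dict with keys ``label``, ``geometry``, ``baseline``,
    ``doubling`` and ``metastasis`` ready for :func:`build_parameter_set`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    missing = [key for key in _CONFIG_KEYS if key not in raw]
    if missing:
        raise ValueError(f"config {path} is missing keys: {missing}")
    return dict(
        label=str(raw["cancer_label"]),
        geometry=TumorGeometry(float(raw["diameter_cm"]), float(raw["cell_density_per_cm3"])),
        baseline=BaselineControl(float(raw["baseline_tcp"])),
        doubling=DoublingTimeSummary(
            float(raw["doubling_median_days"]),
            float(raw["doubling_lower_days"]),
            float(raw["doubling_upper_days"]),
            SpreadKind(raw["spread_kind"]),
        ),
        metastasis=MetastasisObservation(
            float(raw["metastasis_prob"]), float(raw["metastasis_at_months"])
        ),
    )


def write_parameter_config(
    path: str | Path,
    label: str,
    geometry: TumorGeometry,
    baseline: BaselineControl,
    doubling: DoublingTimeSummary,
    metastasis: MetastasisObservation,
    derived: TumorParameters | None = None,
    k_mode: str = "point",
) -> None:
    """Write the flat config schema, optionally with derived parameters."""
    doc: dict = {
        "cancer_label": label,
        "diameter_cm": geometry.diameter_cm,
        "cell_density_per_cm3": geometry.cell_density_per_cm3,
        "baseline_tcp": baseline.tcp0,
        "doubling_median_days": doubling.median_days,
        "doubling_lower_days": doubling.lower_days,
        "doubling_upper_days": doubling.upper_days,
        "spread_kind": doubling.spread_kind.value,
        "metastasis_prob": metastasis.probability,
        "metastasis_at_months": metastasis.at_months,
    }
    if derived is not None:
        doc["derived"] = {
            "p0": derived.p0, "s": derived.s, "g_mean": derived.g_mean,
            "g_sd": derived.g_sd, "k": derived.k, "m0": derived.m0,
            "calibration_mode": k_mode,
            "days_per_month": DAYS_PER_MONTH,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Population estimates over the growth-rate mixture
# ---------------------------------------------------------------------------


def growth_rate_density(params: TumorParameters, g) -> float | np.ndarray:
    """Normal density of the growth rate, mean G, SD sigma."""
    if params.g_sd <= 0:
        raise ValueError("growth_rate_density requires g_sd > 0; sigma = 0 is the "
                         "degenerate case handled by the expectation/quantile ops")
    return norm.pdf(g, loc=params.g_mean, scale=params.g_sd)


@lru_cache(maxsize=8)
def _gh_rule(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return hermgauss(nodes)


ModelFunction = Callable[[TumorParameters, np.ndarray, float], np.ndarray]


def expect_over_growth(
    params: TumorParameters, t: float, f: ModelFunction, nodes: int = GH_NODES
) -> float:
    """Expectation of f(g, t) over g ~ Normal(G, sigma) by Gauss-Hermite.

    For sigma = 0 returns the point evaluation f(G, t).  ``f`` must accept a
    vector of growth rates.
    """
    _check_time(t)
    if params.g_sd == 0.0:
        return float(f(params, params.g_mean, t))
    x, w = _gh_rule(nodes)
    g = params.g_mean + math.sqrt(2.0) * params.g_sd * x
    vals = np.asarray(f(params, g, t), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite integrand in growth-rate expectation")
    return float(w @ vals / math.sqrt(math.pi))


def quantile_over_growth(
    params: TumorParameters, t: float, f: ModelFunction, q: float
) -> float:
    """q-quantile of f(g, t) under g ~ Normal(G, sigma), for f monotone in g.

    Monotonicity lets the quantile be read off a single evaluation at
    g = G + z*sigma: an increasing f uses z = Phi^{-1}(q), a decreasing f the
    mirrored quantile (e.g. the 2.5th TCP percentile sits at the 97.5th growth
    quantile).  Non-monotone f (probed on G +/- 2 sigma) is rejected.
    """
    _check_time(t)
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if params.g_sd == 0.0:
        return float(f(params, params.g_mean, t))
    probe_g = params.g_mean + params.g_sd * np.linspace(-2.0, 2.0, 5)
    probe = np.asarray(f(params, probe_g, t), dtype=float)
    diffs = np.diff(probe)
    if np.all(diffs >= 0):
        z = norm.ppf(q)
    elif np.all(diffs <= 0):
        z = norm.ppf(1.0 - q)
    else:
        raise ValueError("quantile_over_growth requires f monotone in g")
    return float(f(params, params.g_mean + z * params.g_sd, t))


def tcp_loss(params: TumorParameters, t: float) -> RiskEstimate:
    """Local-control loss at delay t, in percentage points.

    Mean loss is 100*(tcp0 - E[TCP(t)]) against the no-delay baseline
    tcp0 = exp(-S*P0); the bounds come from the 2.5th/97.5th TCP percentiles
    (lo is the favorable, smaller loss).  The lower bound can be negative when
    the mixture puts mass on regressing tumors; display layers floor it at 0.
    """
    tcp0 = params.baseline_tcp
    mean_tcp = expect_over_growth(params, t, tumor_control_probability)
    tcp_hi = quantile_over_growth(params, t, tumor_control_probability, 0.975)
    tcp_lo = quantile_over_growth(params, t, tumor_control_probability, 0.025)
    return RiskEstimate(
        mean=100.0 * (tcp0 - mean_tcp),
        lo=100.0 * (tcp0 - tcp_hi),
        hi=100.0 * (tcp0 - tcp_lo),
        quantity="tcp_loss",
        t=t,
    )


def metastasis_risk(params: TumorParameters, t: float) -> RiskEstimate:
    """New-metastasis probability at delay t, in percentage points."""
    mean_pm = expect_over_growth(params, t, metastasis_probability)
    if t == 0.0:
        pm_lo = pm_hi = float(metastasis_probability(params, params.g_mean, 0.0))
    else:
        pm_lo = quantile_over_growth(params, t, metastasis_probability, 0.025)
        pm_hi = quantile_over_growth(params, t, metastasis_probability, 0.975)
    return RiskEstimate(
        mean=100.0 * mean_pm, lo=100.0 * pm_lo, hi=100.0 * pm_hi,
        quantity="metastasis_prob", t=t,
    )


_TABLE_COLUMNS = [
    "cancer", "delay_months",
    "tcp_loss_mean", "tcp_loss_lo", "tcp_loss_hi",
    "met_risk_mean", "met_risk_lo", "met_risk_hi",
]


def delay_risk_table(
    param_sets: Sequence[TumorParameters], delays: Iterable[float]
) -> pd.DataFrame:
    """Risk table with one row per (cancer, delay), full precision.

    TCP-loss lower bounds are floored at 0 (a delay cannot improve control;
    negative raw bounds only reflect regressing-tumor mass), matching the
    published table's 0.00 entries.
    """
    labels = [p.label for p in param_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate cancer labels in parameter sets: {labels}")
    delays = list(delays)
    if not param_sets or not delays:
        raise ValueError("param_sets and delays must be nonempty")
    rows = []
    for params in param_sets:
        for t in delays:
            loss = tcp_loss(params, t)
            met = metastasis_risk(params, t)
            rows.append({
                "cancer": params.label,
                "delay_months": t,
                "tcp_loss_mean": max(loss.mean, 0.0),
                "tcp_loss_lo": max(loss.lo, 0.0),
                "tcp_loss_hi": max(loss.hi, 0.0),
                "met_risk_mean": met.mean,
                "met_risk_lo": met.lo,
                "met_risk_hi": met.hi,
            })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def format_risk_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display-rounded copy of a risk table (2 decimals, pp)."""
    out = table.copy()
    for col in _TABLE_COLUMNS[2:]:
        out[col] = out[col].round(2)
    return out


def delay_curves(params: TumorParameters, t_grid: Sequence[float]) -> pd.DataFrame:
    """Mean and 95%-band curves of TCP loss and metastasis risk on a time grid."""
    t_grid = np.asarray(list(t_grid), dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be nonempty")
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be nonnegative")
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted ascending")
    table = delay_risk_table([params], t_grid)
    return table.rename(columns={"delay_months": "t"}).drop(columns=["cancer"]).assign(
        cancer=params.label
    )[["cancer", "t"] + _TABLE_COLUMNS[2:]]


# ---------------------------------------------------------------------------
# Monte-Carlo cohort simulator (independent stochastic oracle)
# ---------------------------------------------------------------------------


def simulate_cohort(
    params: TumorParameters,
    t: float,
    n: int,
    seed: int,
    control_mode: str = "bernoulli",
) -> CohortResult:
    """Simulate n patients with heterogeneous growth rates at delay t.

    Each patient draws g ~ Normal(G, sigma); local control is a Bernoulli
    event with the Poisson-zero probability exp(-S*P0*e^{g t})
    (control_mode="poisson" instead samples the surviving-cell count and
    declares control iff zero — identical in distribution), and a new
    metastasis occurs with probability 1 - exp(-Lambda(g, t)).  A root
    SeedSequence spawns one independent substream per random quantity, so
    results are bitwise reproducible for a given seed.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    _check_time(t)
    ss_growth, ss_control, ss_met = np.random.SeedSequence(seed).spawn(3)
    g = np.random.default_rng(ss_growth).normal(params.g_mean, params.g_sd, size=n)
    p_control = np.asarray(tumor_control_probability(params, g, t), dtype=float)
    rng_control = np.random.default_rng(ss_control)
    if control_mode == "bernoulli":
        controlled = rng_control.random(n) < p_control
    elif control_mode == "poisson":
        survivors = rng_control.poisson(params.s * np.asarray(primary_cell_count(params, g, t)))
        controlled = survivors == 0
    else:
        raise ValueError(f"unknown control_mode {control_mode!r}")
    p_met = np.asarray(metastasis_probability(params, g, t), dtype=float)
    metastasized = np.random.default_rng(ss_met).random(n) < p_met
    control_frac = float(controlled.mean())
    met_frac = float(metastasized.mean())
    return CohortResult(
        n=n,
        t=t,
        control_fraction=control_frac,
        metastasis_fraction=met_frac,
        control_se=math.sqrt(control_frac * (1.0 - control_frac) / n),
        metastasis_se=math.sqrt(met_frac * (1.0 - met_frac) / n),
        seed=seed,
        parameter_fingerprint=params.fingerprint(),
    )


def simulate_event_times(
    params: TumorParameters, g: float, t_max: float, seed: int
) -> list[float]:
    """Metastasis event times on [0, t_max] for one tumor with growth rate g.

    Nonhomogeneous Poisson process with rate M(u), simulated by thinning a
    homogeneous process at the majorant M(t_max) — valid for every g because
    dM/dt = k*P(u)*e^{g u} > 0, so M is nondecreasing even for regressing
    tumors.
    """
    _check_time(t_max)
    rate_max = float(metastasis_hazard(params, g, t_max))
    if rate_max == 0.0 or t_max == 0.0:
        return []
    rng = np.random.default_rng(seed)
    n_proposed = rng.poisson(rate_max * t_max)
    if n_proposed == 0:
        return []
    times = np.sort(rng.uniform(0.0, t_max, size=n_proposed))
    rates = params.m0 + params.k * params.p0 * times * _psi(g * times)
    keep = rng.random(n_proposed) * rate_max < rates
    return [float(u) for u in times[keep]]


def compare_cohort_to_analytic(
    params: TumorParameters, t: float, n: int, seed: int
) -> dict:
    """Side-by-side analytic vs Monte-Carlo estimates with z-scores."""
    cohort = simulate_cohort(params, t, n, seed)
    mean_tcp = expect_over_growth(params, t, tumor_control_probability)
    mean_pm = expect_over_growth(params, t, metastasis_probability)
    z_control = (
        (cohort.control_fraction - mean_tcp) / cohort.control_se
        if cohort.control_se > 0 else 0.0
    )
    z_met = (
        (cohort.metastasis_fraction - mean_pm) / cohort.metastasis_se
        if cohort.metastasis_se > 0 else 0.0
    )
    return {
        "cancer": params.label,
        "t": t,
        "n": n,
        "seed": seed,
        "analytic_tcp": mean_tcp,
        "cohort_control_fraction": cohort.control_fraction,
        "z_control": z_control,
        "analytic_pm": mean_pm,
        "cohort_metastasis_fraction": cohort.metastasis_fraction,
        "z_metastasis": z_met,
        "parameter_fingerprint": cohort.parameter_fingerprint,
    }
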