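"""Synthetic CVC-registry generation.

Emulates the statistical structure of a multicenter hematology CRBSI
registry's control arm so the downstream randomization / truncation /
inference pipeline can be exercised without any real patient data:

* dwell times: a day-floored log-normal fitted by least squares to the target
  quartiles (median 14 d, IQR 7-23 d by default);
* infection events: either a log-normal onset-time model (default) in which a
  calibrated "susceptible" fraction of catheters carries a latent infection
  time and an event is recorded iff that time falls within the dwell period,
  or a Weibull hazard with shape > 1 (rising hazard) and a scale calibrated
  by bisection — in both cases calibrated so the definite-CRBSI incidence
  density of untruncated cohorts matches a target (4.15/1000 CVC days by
  default);
* covariates, pathogens and day-7/14/21 platelet counts drawn independently
  from configurable marginals.

The log-normal onset model is the default because its onset-time quartiles
can be matched to observed CRBSI onset quartiles (median 13 d, IQR 10-20.5 d):
infection hazard in this population peaks during the post-chemotherapy
neutropenic window one to three weeks after insertion and declines afterwards,
which no monotone Weibull hazard reproduces jointly with a right-skewed dwell
distribution.  See docs/methods.md for the full calibration account.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .registry import (
    Cohort,
    CVCRecord,
    DISEASES,
    PATHOGENS,
    PLATELET_DAYS,
)

__all__ = [
    "DwellParams",
    "OnsetParams",
    "GeneratorConfig",
    "GeneratorError",
    "fit_lognormal_quartiles",
    "fit_dwell_distribution",
    "fit_onset_distribution",
    "calibrate_event_probability",
    "calibrate_susceptible_fraction",
    "generate_cohort",
    "realized_marginals",
]

#: z-score of the 75th percentile of the standard normal.
_Z75 = float(stats.norm.ppf(0.75))

#: Fixed stream for Monte-Carlo calibration, separate from cohort seeds so
#: that calibrated parameters are a function of the configuration only.
_CALIBRATION_SEED = 20_220_817

_SIGMA_FLOOR = 1e-9


class GeneratorError(ValueError):
    """Raised for invalid generator configuration or failed calibration."""


@dataclass(frozen=True)
class DwellParams:
    """Log-normal dwell-time parameters (before day-rounding).

    ``degenerate`` flags a zero-spread fit (all three quartiles equal), in
    which case ``sigma`` sits at its lower bound.
    """

    mu: float
    sigma: float
    degenerate: bool = False

    def quantile(self, p: float) -> float:
        return float(np.exp(self.mu + self.sigma * stats.norm.ppf(p)))

    def survival(self, t):
        """P(continuous dwell > t)."""
        t = np.asarray(t, dtype=float)
        return stats.norm.sf((np.log(t) - self.mu) / self.sigma)


@dataclass(frozen=True)
class OnsetParams:
    """Log-normal latent infection-time parameters."""

    mu: float
    sigma: float


def fit_lognormal_quartiles(q1: float, median: float, q3: float) -> tuple[float, float]:
    """Least-squares log-normal fit to (q1, median, q3).

    Minimizes the sum of squared log-quantile errors at the 25th/50th/75th
    percentiles.  The minimizer is closed-form: ``mu`` is the mean of the
    three log quartiles (the sigma terms cancel) and ``sigma`` equals the
    log-IQR divided by twice the 75th-percentile z-score.  Note a log-normal
    is log-symmetric (q3/median = median/q1), so asymmetric targets are met
    in the least-squares sense only.
    """
    if not (0 < q1 <= median <= q3):
        raise GeneratorError(
            f"quartiles must satisfy 0 < q1 <= median <= q3, got ({q1}, {median}, {q3})"
        )
    l1, lm, l3 = math.log(q1), math.log(median), math.log(q3)
    mu = (l1 + lm + l3) / 3.0
    sigma = (l3 - l1) / (2.0 * _Z75)
    return mu, max(sigma, _SIGMA_FLOOR)


def fit_dwell_distribution(median_days: float, q1_days: float, q3_days: float) -> DwellParams:
    """Fit the log-normal dwell distribution to observed dwell quartiles."""
    mu, sigma = fit_lognormal_quartiles(q1_days, median_days, q3_days)
    return DwellParams(mu=mu, sigma=sigma, degenerate=sigma <= _SIGMA_FLOOR)


@lru_cache(maxsize=64)
def _fit_onset_cached(dwell_mu: float, dwell_sigma: float,
                      q1: float, median: float, q3: float) -> OnsetParams:
    dwell = DwellParams(dwell_mu, dwell_sigma)
    grid = np.arange(0.05, 240.0, 0.05)
    at_risk = dwell.survival(grid)

    def tilted_quartiles(mu: float, sigma: float) -> np.ndarray:
        w = stats.lognorm.pdf(grid, sigma, scale=np.exp(mu)) * at_risk
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        return np.interp([0.25, 0.5, 0.75], cdf, grid)

    target = np.log([q1, median, q3])

    def loss(params: np.ndarray) -> float:
        mu, sigma = params
        if sigma < 0.05 or sigma > 3.0:
            return 1e9
        q = tilted_quartiles(mu, sigma)
        return float(np.sum((np.log(q) - target) ** 2))

    start = np.array(fit_lognormal_quartiles(q1, median, q3))
    res = optimize.minimize(loss, start, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-12})
    return OnsetParams(mu=float(res.x[0]), sigma=float(res.x[1]))


def fit_onset_distribution(dwell_params: DwellParams,
                           median_days: float, q1_days: float, q3_days: float) -> OnsetParams:
    """Fit latent infection-time parameters to *observed* onset quartiles.

    Observed onsets are infection times conditioned on falling within the
    dwell period, i.e. the latent density tilted by the dwell survival
    function.  The fit inverts that tilt: it finds log-normal parameters whose
    tilted quartiles match the targets in least squares (the event probability
    itself cancels from the conditional density, so the fit is independent of
    the later incidence calibration).
    """
    if not (0 < q1_days <= median_days <= q3_days):
        raise GeneratorError("onset quartiles must satisfy 0 < q1 <= median <= q3")
    return _fit_onset_cached(dwell_params.mu, dwell_params.sigma,
                             float(q1_days), float(median_days), float(q3_days))


# ---------------------------------------------------------------------------
# Event-probability calibration


def _draw_dwell_days(rng: np.random.Generator, n: int, dwell: DwellParams) -> np.ndarray:
    """Day-floored log-normal dwell times, minimum 1 whole day."""
    x = np.exp(dwell.mu + dwell.sigma * rng.standard_normal(n))
    return np.maximum(np.floor(x), 1.0).astype(np.int64)


def _weibull_times(u: np.ndarray, shape: float, scale: float) -> np.ndarray:
    return scale * (-np.log(u)) ** (1.0 / shape)


def calibrate_event_probability(dwell_params: DwellParams, hazard_shape: float,
                                target_incidence_per_1000: float,
                                n_mc: int = 200_000, seed: int = _CALIBRATION_SEED,
                                probable_fraction: float = 0.0) -> float:
    """Weibull scale such that untruncated cohorts hit the incidence target.

    Monte-Carlo bisection with common random numbers: a fixed sample of dwell
    times and event-time uniforms makes the simulated definite-CRBSI
    incidence a deterministic, monotone decreasing function of the scale, so
    bisection converges to well under the 2% relative tolerance the
    calibration promises.  ``probable_fraction`` thins events to the definite
    class in expectation.
    """
    if target_incidence_per_1000 <= 0:
        raise GeneratorError("target incidence must be > 0 (a zero target is unattainable)")
    if n_mc < 10_000:
        raise GeneratorError("n_mc must be >= 10^4 for a stable calibration")
    if not 0 <= probable_fraction < 1:
        raise GeneratorError("probable_fraction must be in [0, 1)")
    target_all = target_incidence_per_1000 / (1.0 - probable_fraction)

    rng = np.random.default_rng(seed)
    dwell_days = _draw_dwell_days(rng, n_mc, dwell_params)
    u = rng.uniform(size=n_mc)
    total_days = float(dwell_days.sum())

    def incidence(scale: float) -> float:
        onset = np.ceil(_weibull_times(u, hazard_shape, scale))
        return float((onset <= dwell_days).sum()) / total_days * 1000.0

    lo, hi = 1e-2, 1e7  # incidence decreasing in scale
    if not (incidence(hi) <= target_all <= incidence(lo)):
        raise GeneratorError(
            f"target incidence {target_all:.3f}/1000 not bracketed by the "
            f"search interval [{lo}, {hi}] for the event-time scale"
        )
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if incidence(mid) > target_all:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    return math.sqrt(lo * hi)


def calibrate_susceptible_fraction(dwell_params: DwellParams, onset_params: OnsetParams,
                                   target_incidence_per_1000: float,
                                   n_mc: int = 200_000, seed: int = _CALIBRATION_SEED,
                                   probable_fraction: float = 0.0) -> float:
    """Susceptible fraction for the log-normal onset model.

    The incidence is linear in the susceptible fraction, so a single
    Monte-Carlo evaluation at fraction 1 suffices.
    """
    if target_incidence_per_1000 <= 0:
        raise GeneratorError("target incidence must be > 0 (a zero target is unattainable)")
    if n_mc < 10_000:
        raise GeneratorError("n_mc must be >= 10^4 for a stable calibration")
    target_all = target_incidence_per_1000 / (1.0 - probable_fraction)

    rng = np.random.default_rng(seed)
    dwell_days = _draw_dwell_days(rng, n_mc, dwell_params)
    t = np.exp(onset_params.mu + onset_params.sigma * rng.standard_normal(n_mc))
    inc_at_one = float((np.ceil(t) <= dwell_days).sum()) / float(dwell_days.sum()) * 1000.0
    frac = target_all / inc_at_one
    if frac > 1.0:
        raise GeneratorError(
            f"incidence target {target_all:.3f}/1000 exceeds the model maximum "
            f"{inc_at_one:.3f}/1000 (susceptible fraction would be > 1)"
        )
    return frac


# ---------------------------------------------------------------------------
# Configuration


def _prob_vector(values) -> tuple[float, ...]:
    return tuple(float(v) for v in values)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults are the control-arm calibration targets of the study conditions
    this package models: 2984 catheter episodes over six centers, dwell
    median 14 d (IQR 7-23), definite-CRBSI incidence 4.15/1000 CVC days,
    probable fraction 37/87, onset median 13 d (IQR 10-20.5), and the
    covariate / pathogen / platelet marginals of a hematology population
    (AML-dominated disease mix, ~93% jugular insertion, ~18% neutropenic at
    insertion).
    """

    n_records: int = 2984
    n_centers: int = 6
    center_weights: tuple[float, ...] = (0.32, 0.20, 0.16, 0.12, 0.12, 0.08)

    dwell_median_days: float = 14.0
    dwell_q1_days: float = 7.0
    dwell_q3_days: float = 23.0

    #: "onset_lognormal" (default) or "weibull".
    event_model: str = "onset_lognormal"
    hazard_shape: float = 1.5  # Weibull model only; > 1 means rising hazard
    onset_median_days: float = 13.0
    onset_q1_days: float = 10.0
    onset_q3_days: float = 20.5

    target_incidence_per_1000: float = 4.15
    probable_fraction: float = 37.0 / 87.0
    pathogen_probs: tuple[float, ...] = (63 / 87, 8 / 87, 2 / 87, 9 / 87, 1 / 87, 4 / 87)

    male_prob: float = 1754 / 2984
    disease_probs: tuple[float, ...] = (
        1217 / 2984,  # AML
        250 / 2984,   # ALL
        612 / 2984,   # NHL
        634 / 2984,   # MM
        91 / 2984,    # HL
        180 / 2984,   # other
    )
    jugular_prob: float = 2781 / 2984
    coated_prob: float = 294 / 2984
    chg_prob: float = 936 / 2984
    neutropenic_prob: float = 524 / 2984
    age_quartiles: tuple[float, float, float] = (49.0, 59.0, 66.0)
    age_bounds: tuple[int, int] = (16, 95)

    platelet_quartiles_d7: tuple[float, float, float] = (25_000.0, 72_000.0, 123_000.0)
    platelet_quartiles_d14: tuple[float, float, float] = (12_000.0, 20_000.0, 33_000.0)
    platelet_quartiles_d21: tuple[float, float, float] = (16_000.0, 30_000.0, 89_000.0)

    n_mc_calibration: int = 200_000
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_records < 1:
            raise GeneratorError("n_records must be >= 1")
        if self.n_centers < 1 or len(self.center_weights) != self.n_centers:
            raise GeneratorError("center_weights length must equal n_centers")
        for name, vec in (("center_weights", self.center_weights),
                          ("pathogen_probs", self.pathogen_probs),
                          ("disease_probs", self.disease_probs)):
            if any(p < 0 for p in vec) or abs(sum(vec) - 1.0) > 1e-9:
                raise GeneratorError(f"{name} must be non-negative and sum to 1 within 1e-9")
        if len(self.pathogen_probs) != len(PATHOGENS):
            raise GeneratorError(f"pathogen_probs must have {len(PATHOGENS)} entries")
        if len(self.disease_probs) != len(DISEASES):
            raise GeneratorError(f"disease_probs must have {len(DISEASES)} entries")
        for name in ("male_prob", "jugular_prob", "coated_prob", "chg_prob",
                     "neutropenic_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise GeneratorError(f"{name} must be in [0, 1]")
        if not 0 <= self.probable_fraction < 1:
            raise GeneratorError("probable_fraction must be in [0, 1)")
        if self.target_incidence_per_1000 <= 0:
            raise GeneratorError("target_incidence_per_1000 must be > 0")
        if self.event_model not in ("onset_lognormal", "weibull"):
            raise GeneratorError("event_model must be 'onset_lognormal' or 'weibull'")
        if self.event_model == "weibull" and self.hazard_shape <= 0:
            raise GeneratorError("hazard_shape must be > 0")
        for name in ("age_quartiles", "platelet_quartiles_d7",
                     "platelet_quartiles_d14", "platelet_quartiles_d21"):
            q1, med, q3 = getattr(self, name)
            if not (0 < q1 <= med <= q3):
                raise GeneratorError(f"{name} must satisfy 0 < q1 <= median <= q3")
        if not (0 < self.dwell_q1_days <= self.dwell_median_days <= self.dwell_q3_days):
            raise GeneratorError("dwell quartiles must satisfy 0 < q1 <= median <= q3")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise GeneratorError(f"unknown generator config keys: {sorted(unknown)}")
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))

    # -- derived parameters -------------------------------------------------

    def dwell_params(self) -> DwellParams:
        return fit_dwell_distribution(self.dwell_median_days,
                                      self.dwell_q1_days, self.dwell_q3_days)


@lru_cache(maxsize=64)
def _event_params_cached(key: tuple) -> dict:
    (model, dmu, dsig, shape, om, oq1, oq3, target, pf, n_mc) = key
    dwell = DwellParams(dmu, dsig)
    if model == "weibull":
        scale = calibrate_event_probability(dwell, shape, target, n_mc=n_mc,
                                            probable_fraction=pf)
        return {"model": model, "shape": shape, "scale": scale}
    onset = fit_onset_distribution(dwell, om, oq1, oq3)
    frac = calibrate_susceptible_fraction(dwell, onset, target, n_mc=n_mc,
                                          probable_fraction=pf)
    return {"model": model, "onset": onset, "susceptible_fraction": frac}


def _event_params(config: GeneratorConfig) -> dict:
    dwell = config.dwell_params()
    key = (config.event_model, dwell.mu, dwell.sigma, config.hazard_shape,
           config.onset_median_days, config.onset_q1_days, config.onset_q3_days,
           config.target_incidence_per_1000, config.probable_fraction,
           config.n_mc_calibration)
    return _event_params_cached(key)


# ---------------------------------------------------------------------------
# Cohort generation


def _quartile_normal(rng, n, quartiles):
    q1, med, q3 = quartiles
    mu = (q1 + med + q3) / 3.0
    sd = max((q3 - q1) / (2.0 * _Z75), 1e-9)
    return mu + sd * rng.standard_normal(n)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a synthetic cohort; identical config (incl. seed) => identical cohort.

    Draw order is fixed (centers, dwell, events, labels, pathogens,
    covariates, ages, platelets), so outputs are byte-stable across runs.
    """
    config.validate()
    ev = _event_params(config)
    dwell_p = config.dwell_params()
    n = config.n_records
    rng = np.random.default_rng(config.seed)

    centers = rng.choice(config.n_centers, size=n, p=np.asarray(config.center_weights))
    dwell_days = _draw_dwell_days(rng, n, dwell_p)

    if ev["model"] == "weibull":
        t = _weibull_times(rng.uniform(size=n), ev["shape"], ev["scale"])
        onset = np.ceil(t).astype(np.int64)
        has_event = onset <= dwell_days
    else:
        susceptible = rng.uniform(size=n) < ev["susceptible_fraction"]
        op: OnsetParams = ev["onset"]
        t = np.exp(op.mu + op.sigma * rng.standard_normal(n))
        onset = np.ceil(t).astype(np.int64)
        has_event = susceptible & (onset <= dwell_days)

    probable = rng.uniform(size=n) < config.probable_fraction
    pathogen_idx = rng.choice(len(PATHOGENS), size=n, p=np.asarray(config.pathogen_probs))

    male = rng.uniform(size=n) < config.male_prob
    disease_idx = rng.choice(len(DISEASES), size=n, p=np.asarray(config.disease_probs))
    jugular = rng.uniform(size=n) < config.jugular_prob
    coated = rng.uniform(size=n) < config.coated_prob
    chg = rng.uniform(size=n) < config.chg_prob
    neutro = rng.uniform(size=n) < config.neutropenic_prob
    lo, hi = config.age_bounds
    ages = np.clip(np.rint(_quartile_normal(rng, n, config.age_quartiles)), lo, hi).astype(int)

    platelets: dict[int, np.ndarray] = {}
    for day in PLATELET_DAYS:
        q = getattr(config, f"platelet_quartiles_d{day}")
        mu, sigma = fit_lognormal_quartiles(*q)
        raw = np.exp(mu + sigma * rng.standard_normal(n))
        platelets[day] = np.maximum(np.rint(raw / 1000.0) * 1000.0, 1000.0).astype(np.int64)

    width = max(6, len(str(n)))
    records: list[CVCRecord] = []
    for i in range(n):
        event = bool(has_event[i])
        cls = "none"
        if event:
            cls = "probable" if probable[i] else "definite"
        dw = int(dwell_days[i])
        records.append(CVCRecord(
            record_id=f"R{i + 1:0{width}d}",
            center_id=f"C{int(centers[i]) + 1}",
            age_years=int(ages[i]),
            sex="male" if male[i] else "female",
            disease=DISEASES[int(disease_idx[i])],
            insertion_site="jugular" if jugular[i] else "subclavian",
            antimicrobial_coated=bool(coated[i]),
            chg_dressing=bool(chg[i]),
            neutropenic_at_insertion=bool(neutro[i]),
            dwell_days=dw,
            crbsi_class=cls,
            crbsi_onset_day=int(min(max(onset[i], 1), dw)) if event else None,
            pathogen=PATHOGENS[int(pathogen_idx[i])] if event else None,
            platelets_d7=int(platelets[7][i]) if dw >= 7 else None,
            platelets_d14=int(platelets[14][i]) if dw >= 14 else None,
            platelets_d21=int(platelets[21][i]) if dw >= 21 else None,
        ))
    return Cohort(records=records)


def realized_marginals(cohort: Cohort) -> dict:
    """Audit summary of a generated (or real) cohort's key marginals."""
    dwell = np.array([r.dwell_days for r in cohort])
    events = [r for r in cohort if r.crbsi_class != "none"]
    definite = [r for r in cohort if r.crbsi_class == "definite"]
    total_days = int(dwell.sum())
    out = {
        "n_records": len(cohort),
        "cvc_days": total_days,
        "dwell_median": float(np.median(dwell)),
        "dwell_q1": float(np.percentile(dwell, 25)),
        "dwell_q3": float(np.percentile(dwell, 75)),
        "crbsi_fraction": len(events) / len(cohort) if len(cohort) else 0.0,
        "definite_incidence_per_1000": 1000.0 * len(definite) / total_days if total_days else 0.0,
        "dp_incidence_per_1000": 1000.0 * len(events) / total_days if total_days else 0.0,
    }
    if events:
        onsets = np.array([r.crbsi_onset_day for r in events])
        out["onset_median"] = float(np.median(onsets))
        out["onset_q1"] = float(np.percentile(onsets, 25))
        out["onset_q3"] = float(np.percentile(onsets, 75))
        counts = {p: 0 for p in PATHOGENS}
        for r in events:
            counts[r.pathogen] += 1
        out["pathogen_counts"] = counts
    return out
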