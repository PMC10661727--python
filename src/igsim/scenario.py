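"""Treatment scenarios: regimens, population-level simulation, calibration.

Two subcutaneous regimens are compared after a switch from stable IVIG:
conventional SCIG at 0.15 g/kg weekly and hyaluronidase-facilitated SCIG
(fSCIG) at 0.6 g/kg every 4 weeks — the same monthly dose.  Dosing is based
on total body weight while IgG disposition scales with lean body mass; the
mismatch between the two body-size measures is what drives the BMI and age
effects on exposure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .exposure import ExposureMetrics, compute_metrics, ss_window
from .pkmodel import ConcProfile, PopulationParameters, individualize, simulate_profile
from .vpop import PopulationSpec, Subject, sample_population

__all__ = [
    "Regimen",
    "ScenarioResult",
    "CalibrationAnchors",
    "CalibrationError",
    "weight_based_dose",
    "subject_etas",
    "run_scenario",
    "calibrate_defaults",
    "DEFAULT_GRID_STEP",
    "DEFAULT_C0",
]

DEFAULT_GRID_STEP = 0.25   # days; resolves peak/trough to ~2% for IgG kinetics
DEFAULT_C0 = 7.0           # g/L, trough on stable IVIG at the switch


@dataclass(frozen=True)
class Regimen:
    """A subcutaneous dosing schedule (weight-normalized)."""

    formulation: str        # "scig" | "fscig"
    dose_per_kg: float      # g/kg per administration
    interval: float         # days
    horizon: float = 140.0  # days simulated (20 weeks)
    first_dose_time: float = 0.0

    def __post_init__(self) -> None:
        if self.formulation not in ("scig", "fscig"):
            raise ValueError(f"unknown formulation: {self.formulation!r}")
        if self.dose_per_kg <= 0 or self.interval <= 0:
            raise ValueError("dose_per_kg and interval must be positive")
        if self.horizon < 2 * self.interval:
            raise ValueError("horizon must cover at least two dosing intervals")

    @classmethod
    def scig(cls, **kw) -> "Regimen":
        """Conventional SCIG, 0.15 g/kg weekly for 20 weeks."""
        return cls(formulation="scig", dose_per_kg=0.15, interval=7.0, **kw)

    @classmethod
    def fscig(cls, **kw) -> "Regimen":
        """Facilitated SCIG, 0.6 g/kg every 4 weeks for 20 weeks."""
        return cls(formulation="fscig", dose_per_kg=0.6, interval=28.0, **kw)

    def to_dict(self) -> dict:
        return {
            "formulation": self.formulation, "dose_per_kg": self.dose_per_kg,
            "interval": self.interval, "horizon": self.horizon,
            "first_dose_time": self.first_dose_time,
        }


@dataclass(frozen=True)
class ScenarioResult:
    """Per-subject profiles and exposure metrics plus provenance."""

    subjects: list
    profiles: list
    metrics: list
    provenance: dict

    def __post_init__(self) -> None:
        if not (len(self.subjects) == len(self.profiles) == len(self.metrics)):
            raise ValueError("one profile and one metrics record per subject required")


def weight_based_dose(subject: Subject, dose_per_kg: float) -> float:
    """Administered dose in grams: dose_per_kg * total body weight."""
    if subject.weight <= 0:
        raise ValueError("subject weight must be positive")
    return dose_per_kg * subject.weight


def subject_etas(seed: int, index: int) -> np.ndarray:
    """Standard-normal random effects for one subject.

    Each subject consumes its own substream keyed by (seed, index), so
    enlarging the population never reshuffles the draws of earlier subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))
    return rng.standard_normal(4)


_MAX_ETA_REDRAWS = 1000


def _draw_eligible_individual(pop_params, subj, seed, index, formulation, c0):
    """Individualize with an eligibility screen on endogenous production.

    The simulated cohort consists of patients maintained at the c0 trough by
    prior IVIG, i.e. patients whose own IgG production cannot reach c0.  A
    random-effect draw implying an endogenous steady state at or above c0
    describes a patient outside that cohort, so the subject's etas are
    redrawn from its substream (truncated joint distribution).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))
    for _ in range(_MAX_ETA_REDRAWS):
        ind = individualize(pop_params, subj, rng.standard_normal(4),
                            formulation=formulation)
        if ind.ksyn / ind.cl < c0:
            return ind
    raise RuntimeError(
        f"subject {subj.subject_id}: no eligible random-effect draw in "
        f"{_MAX_ETA_REDRAWS} attempts"
    )


def _config_hash(pop_params: PopulationParameters, regimen: Regimen) -> str:
    payload = json.dumps(
        {"model": pop_params.to_dict(), "regimen": regimen.to_dict()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_scenario(population: list[Subject], regimen: Regimen,
                 pop_params: PopulationParameters, seed: int,
                 c0: float = DEFAULT_C0,
                 grid_step: float = DEFAULT_GRID_STEP) -> ScenarioResult:
    """Simulate every subject under one regimen and derive exposure metrics.

    Random effects come from per-subject substreams of ``seed``; the run is
    fully deterministic given (population, regimen, pop_params, seed).
    """
    if not population:
        raise ValueError("population is empty")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    window = ss_window(regimen)
    n_steps = int(round(regimen.horizon / grid_step))
    tgrid = np.linspace(0.0, regimen.horizon, n_steps + 1)
    profiles: list[ConcProfile] = []
    metrics: list[ExposureMetrics] = []
    for i, subj in enumerate(population):
        ind = _draw_eligible_individual(pop_params, subj, seed, i,
                                        regimen.formulation, c0)
        dose = weight_based_dose(subj, regimen.dose_per_kg)
        try:
            prof = simulate_profile(ind, regimen, dose, c0, tgrid)
        except ValueError as exc:
            raise ValueError(f"subject {subj.subject_id}: {exc}") from exc
        profiles.append(prof)
        metrics.append(compute_metrics(prof, window))
    return ScenarioResult(
        subjects=list(population),
        profiles=profiles,
        metrics=metrics,
        provenance={
            "seed": seed,
            "c0_gL": c0,
            "config_hash": _config_hash(pop_params, regimen),
            "regimen": regimen.to_dict(),
        },
    )


# --------------------------------------------------------------------------
# Calibration of the packaged parameter set


@dataclass(frozen=True)
class CalibrationAnchors:
    """Target stratum means the packaged defaults are pinned to.

    The three anchors are the healthy-BMI adult mean trough under each
    regimen and the (2-<6 years)/adult trough ratio under weekly SCIG.
    """

    scig_healthy_cmin: float = 12.1     # g/L
    fscig_healthy_cmin: float = 10.7    # g/L
    scig_youngest_ratio: float = 0.78   # dimensionless


class CalibrationError(RuntimeError):
    pass


_CAL_SEED = 20120     # internal seed for the calibration cohorts
_CAL_N = 400          # subjects per calibration cohort
_CAL_RTOL = 0.005     # each anchor matched to 0.5%


def _cal_populations(n: int = _CAL_N, seed: int = _CAL_SEED):
    """Fixed calibration cohorts: healthy-BMI adults, 2-<6y children, adults."""
    bmi_pop = sample_population(PopulationSpec("bmi", n_per_group=n, seed=seed))
    age_pop = sample_population(PopulationSpec("age", n_per_group=n, seed=seed + 1))
    healthy = [s for s in bmi_pop if s.bmi_group == "healthy"]
    youngest = [s for s in age_pop if s.age_group == "2-<6 years"]
    adults = [s for s in age_pop if s.age_group == ">=18 years"]
    return healthy, youngest, adults


def _mean_cmin(pop_params, population, regimen, seed):
    """Mean steady-state trough of a cohort."""
    res = run_scenario(population, regimen, pop_params, seed=seed)
    return float(np.mean([m.cmin_ss for m in res.metrics]))


def calibrate_defaults(pop_params: PopulationParameters,
                       anchors: CalibrationAnchors = CalibrationAnchors(),
                       n: int = _CAL_N, seed: int = _CAL_SEED,
                       max_passes: int = 6) -> PopulationParameters:
    """Pin the packaged parameter set to the three anchor values.

    Nested one-dimensional solves on fixed calibration cohorts (random
    effects included, with a fixed internal seed so every solver evaluation
    sees the same virtual patients):

    1. scale ``cl_ref`` jointly with ``ksyn_ref`` (holding the endogenous
       steady state fixed) to match the healthy-BMI SCIG mean trough;
    2. adjust ``f_fscig`` (falling back to ``ka_fscig`` in [0.05, 0.5]/day if
       bioavailability alone cannot reach it) to match the healthy-BMI fSCIG
       mean trough;
    3. adjust ``theta_cl`` to match the (2-<6 y)/adult SCIG trough ratio.

    The solves interact weakly, so they are iterated until every anchor is
    met to 0.5%.
    """
    healthy, youngest, adults = _cal_populations(n=n, seed=seed)
    scig, fscig = Regimen.scig(), Regimen.fscig()
    p = pop_params

    def resid_scig(p):
        return _mean_cmin(p, healthy, scig, seed) / anchors.scig_healthy_cmin - 1

    def resid_fscig(p):
        return _mean_cmin(p, healthy, fscig, seed) / anchors.fscig_healthy_cmin - 1

    def resid_ratio(p):
        ratio = (_mean_cmin(p, youngest, scig, seed + 2)
                 / _mean_cmin(p, adults, scig, seed + 3))
        return ratio / anchors.scig_youngest_ratio - 1

    for _ in range(max_passes):
        if (abs(resid_scig(p)) < _CAL_RTOL and abs(resid_fscig(p)) < _CAL_RTOL
                and abs(resid_ratio(p)) < _CAL_RTOL):
            return p

        # (1) clearance scale; trough is monotone decreasing in CL
        def f1(s):
            return resid_scig(replace(p, cl_ref=p.cl_ref * s, ksyn_ref=p.ksyn_ref * s))
        try:
            s = brentq(f1, 0.2, 5.0, xtol=1e-4, maxiter=100)
        except ValueError as exc:
            raise CalibrationError(f"clearance-scale solve failed: {exc}") from exc
        p = replace(p, cl_ref=p.cl_ref * s, ksyn_ref=p.ksyn_ref * s)

        # (2) fSCIG bioavailability; trough increases with f
        def f2(f):
            return resid_fscig(replace(p, f_fscig=f))
        lo, hi = 0.30, 1.0
        if f2(lo) > 0 or f2(hi) < 0:
            # fall back on the absorption rate: slower ka deepens the Q4W trough
            def f2k(ka):
                return resid_fscig(replace(p, ka_fscig=ka))
            try:
                ka = brentq(f2k, 0.05, 0.5, xtol=1e-5, maxiter=100)
            except ValueError as exc:
                raise CalibrationError(
                    f"fSCIG solve failed: bioavailability bracket exhausted and "
                    f"ka bracket failed: {exc}"
                ) from exc
            p = replace(p, ka_fscig=ka)
        else:
            f = brentq(f2, lo, hi, xtol=1e-5, maxiter=100)
            p = replace(p, f_fscig=f)

        # (3) allometric clearance exponent; pediatric/adult ratio rises with theta
        def f3(theta):
            return resid_ratio(replace(p, theta_cl=theta))
        try:
            theta = brentq(f3, 0.3, 1.6, xtol=1e-5, maxiter=100)
        except ValueError as exc:
            raise CalibrationError(f"allometric-exponent solve failed: {exc}") from exc
        p = replace(p, theta_cl=theta)

    resids = {"scig": resid_scig(p), "fscig": resid_fscig(p), "ratio": resid_ratio(p)}
    if all(abs(r) < _CAL_RTOL for r in resids.values()):
        return p
    raise CalibrationError(f"anchors not met after {max_passes} passes: {resids}")
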