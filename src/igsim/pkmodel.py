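"""Structural and variability model for serum total IgG.

The model is a linear two-compartment disposition system with first-order
subcutaneous absorption, formulation-specific bioavailability, and a
zero-order endogenous IgG synthesis entering the central compartment.
Body-size dependence enters through lean body mass (fat-free mass) as an
allometric scalar on clearance-like and volume-like parameters; per-subject
variability is multiplicative log-normal.

Because the system is linear and time-invariant, a multiple-dose profile is
the superposition of single-dose unit responses (tri-exponential closed
form) plus the decay of the IgG excess present at the switch from prior
IVIG therapy, plus the constant endogenous steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "PopulationParameters",
    "IndividualParameters",
    "ConcProfile",
    "individualize",
    "endogenous_css",
    "disposition_eigenvalues",
    "sc_unit_response",
    "initial_excess_response",
    "simulate_profile",
]

_EIG_DEGENERACY_RTOL = 1e-9
_EIG_PERTURB_RTOL = 1e-8


@dataclass(frozen=True)
class PopulationParameters:
    """Reference-scale model parameters with variability magnitudes.

    Rates are per day, volumes in litres, synthesis in g/day; the allometric
    reference size ``lbm_ref`` is in kg of fat-free mass.  ``omega_*`` are the
    standard deviations of the log-normal inter-individual random effects.
    """

    cl_ref: float = 0.10      # clearance at lbm_ref, L/day
    vc_ref: float = 3.0       # central volume, L
    q_ref: float = 0.3        # inter-compartmental clearance, L/day
    vp_ref: float = 3.0       # peripheral volume, L
    ka_scig: float = 0.25     # first-order absorption, conventional SCIG, 1/day
    ka_fscig: float = 0.20    # absorption, hyaluronidase-facilitated SCIG, 1/day
    f_scig: float = 0.70      # bioavailability fractions
    f_fscig: float = 0.73
    ksyn_ref: float = 0.20    # endogenous IgG synthesis at lbm_ref, g/day
    lbm_ref: float = 56.0
    theta_cl: float = 0.88    # allometric exponent, clearances
    theta_v: float = 1.0      # allometric exponent, volumes
    omega_cl: float = 0.25
    omega_vc: float = 0.25
    omega_ka: float = 0.30
    omega_ksyn: float = 0.30

    def __post_init__(self) -> None:
        for name in ("cl_ref", "vc_ref", "q_ref", "vp_ref", "ka_scig",
                     "ka_fscig", "ksyn_ref", "lbm_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("f_scig", "f_fscig"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("omega_cl", "omega_vc", "omega_ka", "omega_ksyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class IndividualParameters:
    """Subject-scale realization of the model parameters."""

    cl: float
    vc: float
    q: float
    vp: float
    ka: float
    f: float
    ksyn: float

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q", "vp", "ka", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ksyn < 0:
            raise ValueError("ksyn must be non-negative")


@dataclass(frozen=True)
class ConcProfile:
    """Serum total IgG over a time grid, split into endogenous and exogenous
    components (exogenous = absorbed doses plus the pre-switch IVIG excess)."""

    times: np.ndarray          # days, strictly increasing
    conc_endogenous: np.ndarray
    conc_exogenous: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        if np.any(self.conc_endogenous < 0) or np.any(self.conc_exogenous < -1e-12):
            raise ValueError("concentrations must be non-negative")

    @property
    def conc_total(self) -> np.ndarray:
        return self.conc_endogenous + self.conc_exogenous


def individualize(pop: PopulationParameters, subject, etas,
                  formulation: str = "scig") -> IndividualParameters:
    """Realize per-subject parameters from the population model.

    Clearance-like parameters (CL, Q, and the synthesis rate) scale with
    (LBM / LBM_ref) ** theta_cl, volumes with ** theta_v; random effects are
    exp(omega * eta) with ``etas`` standard-normal draws (eta order: CL, Vc,
    ka, ksyn).  Q and Vp carry no random effect of their own.
    """
    if subject.lbm <= 0:
        raise ValueError("subject.lbm must be positive")
    if formulation not in ("scig", "fscig"):
        raise ValueError(f"unknown formulation: {formulation!r}")
    etas = np.asarray(etas, dtype=float)
    if etas.shape != (4,):
        raise ValueError("etas must be a length-4 vector (CL, Vc, ka, ksyn)")
    r_cl = (subject.lbm / pop.lbm_ref) ** pop.theta_cl
    r_v = (subject.lbm / pop.lbm_ref) ** pop.theta_v
    ka_form = pop.ka_scig if formulation == "scig" else pop.ka_fscig
    f_form = pop.f_scig if formulation == "scig" else pop.f_fscig
    return IndividualParameters(
        cl=pop.cl_ref * r_cl * np.exp(pop.omega_cl * etas[0]),
        vc=pop.vc_ref * r_v * np.exp(pop.omega_vc * etas[1]),
        q=pop.q_ref * r_cl,
        vp=pop.vp_ref * r_v,
        ka=ka_form * np.exp(pop.omega_ka * etas[2]),
        f=f_form,
        ksyn=pop.ksyn_ref * r_cl * np.exp(pop.omega_ksyn * etas[3]),
    )


def endogenous_css(ind: IndividualParameters) -> float:
    """Steady-state concentration from endogenous synthesis alone, ksyn/CL."""
    return ind.ksyn / ind.cl


def disposition_eigenvalues(ind: IndividualParameters) -> tuple[float, float]:
    """The two disposition rate constants (lambda1 >= lambda2 > 0)."""
    k10 = ind.cl / ind.vc
    k12 = ind.q / ind.vc
    k21 = ind.q / ind.vp
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(max(s * s - 4.0 * p, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return lam1, lam2


def _safe_ka(ka: float, lam1: float, lam2: float) -> float:
    # perturb ka away from a removable singularity of the tri-exponential
    for lam in (lam1, lam2):
        if abs(ka - lam) / lam < _EIG_DEGENERACY_RTOL:
            ka = ka * (1.0 + _EIG_PERTURB_RTOL)
    return ka


def sc_unit_response(ind: IndividualParameters, t) -> np.ndarray:
    """Central concentration after a unit (1 g) subcutaneous dose at t = 0.

    Tri-exponential closed form

        C(t) = f*ka/Vc * [ A1 e^(-lam1 t) + A2 e^(-lam2 t) + A3 e^(-ka t) ]

    with A_i built from k21 and the disposition eigenvalues.  Zero at t = 0,
    non-negative, and integrates to f/CL over [0, inf).  Scalar or array t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam1, lam2 = disposition_eigenvalues(ind)
    ka = _safe_ka(ind.ka, lam1, lam2)
    k21 = ind.q / ind.vp
    a1 = (k21 - lam1) / ((ka - lam1) * (lam2 - lam1))
    a2 = (k21 - lam2) / ((ka - lam2) * (lam1 - lam2))
    a3 = (k21 - ka) / ((lam1 - ka) * (lam2 - ka))
    c = (ind.f * ka / ind.vc) * (
        a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t) + a3 * np.exp(-ka * t)
    )
    return np.maximum(c, 0.0)


def initial_excess_response(ind: IndividualParameters, c0_excess: float, t) -> np.ndarray:
    """Decay of the switch-time IgG excess above the endogenous steady state.

    The excess starts distributed at equal concentration in the central and
    peripheral compartments (pseudo-equilibrium after prolonged IVIG therapy)
    and then evolves under two-compartment disposition.  Equals ``c0_excess``
    at t = 0 and is monotone non-increasing.
    """
    if c0_excess < 0:
        raise ValueError("c0_excess must be non-negative")
    t = np.asarray(t, dtype=float)
    if c0_excess == 0.0:
        return np.zeros_like(t)
    lam1, lam2 = disposition_eigenvalues(ind)
    k10 = ind.cl / ind.vc
    k12 = ind.q / ind.vc
    k21 = ind.q / ind.vp
    # amounts: central x = c0*Vc, peripheral y = c0*Vp; solve the 2x2 linear ODE
    x, y = c0_excess * ind.vc, c0_excess * ind.vp
    if lam1 - lam2 < _EIG_DEGENERACY_RTOL * lam1:
        # degenerate (identical eigenvalues) — mono-exponential fallback
        return c0_excess * np.exp(-lam1 * t)
    beta = ((lam1 - k10 - k12) * x + k21 * y) / (lam1 - lam2)
    alpha = x - beta
    return (alpha * np.exp(-lam1 * t) + beta * np.exp(-lam2 * t)) / ind.vc


def simulate_profile(ind: IndividualParameters, regimen, dose_g: float,
                     c0: float, tgrid) -> ConcProfile:
    """Total IgG profile over ``tgrid`` under repeated SC dosing.

    Exogenous concentration is the superposition of ``dose_g`` times the unit
    response over all doses given at ``regimen.first_dose_time + k*interval``
    within the horizon, plus the decaying pre-switch excess ``c0 - css``;
    the endogenous component is the constant ``css = ksyn/CL``.
    """
    tgrid = np.asarray(tgrid, dtype=float)
    if np.any(tgrid < 0) or np.any(tgrid > regimen.horizon):
        raise ValueError("tgrid must lie within [0, horizon]")
    css = endogenous_css(ind)
    if c0 < css - 1e-12:
        raise ValueError(
            f"starting concentration {c0} g/L below endogenous steady state "
            f"{css:.3g} g/L"
        )
    dose_times = np.arange(regimen.first_dose_time, regimen.horizon, regimen.interval)
    exo = initial_excess_response(ind, max(c0 - css, 0.0), tgrid)
    if dose_g != 0.0:
        for td in dose_times:
            mask = tgrid >= td
            if not mask.any():
                continue
            exo[mask] += dose_g * sc_unit_response(ind, tgrid[mask] - td)
    return ConcProfile(
        times=tgrid,
        conc_endogenous=np.full_like(tgrid, css),
        conc_exogenous=exo,
    )
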