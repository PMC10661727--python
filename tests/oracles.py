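"""Independent numerical oracles used to cross-check the analytic solver.

The reference here is direct numerical integration of the full ODE system
(depot, central, peripheral, plus cumulative elimination for mass balance),
with doses applied as boluses of f*D into the depot — deliberately sharing
no code with the closed-form superposition path it checks.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_profile(ind, regimen, dose_g, c0, tgrid):
    """Total-IgG concentration by brute-force ODE integration.

    Returns (conc_total, states_final) where states_final is
    (depot, central, peripheral, cumulative_eliminated) amounts in grams.
    """
    ka, cl, vc, q, vp, f, ksyn = (ind.ka, ind.cl, ind.vc, ind.q, ind.vp,
                                  ind.f, ind.ksyn)
    k10, k12, k21 = cl / vc, q / vc, q / vp

    def rhs(t, y):
        depot, ac, ap, _ = y
        return [
            -ka * depot,
            ka * depot - (k10 + k12) * ac + k21 * ap + ksyn,
            k12 * ac - k21 * ap,
            k10 * ac,
        ]

    tgrid = np.asarray(tgrid, dtype=float)
    dose_times = list(np.arange(regimen.first_dose_time, regimen.horizon,
                                regimen.interval))
    # pseudo-equilibrated start: equal concentration in both compartments
    y = np.array([0.0, c0 * vc, c0 * vp, 0.0])
    conc = np.empty_like(tgrid)
    if tgrid[0] == 0.0:
        conc[0] = c0
    breakpoints = sorted({0.0, *dose_times, float(tgrid[-1])})
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t0 in dose_times:
            y[0] += f * dose_g
        inner = tgrid[(tgrid > t0) & (tgrid <= t1)]
        t_eval = np.unique(np.concatenate([inner, [t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, method="LSODA",
                        rtol=1e-11, atol=1e-13)
        y = sol.y[:, -1]
        for t, ac in zip(sol.t, sol.y[1]):
            idx = np.searchsorted(tgrid, t)
            if idx < len(tgrid) and abs(tgrid[idx] - t) < 1e-9:
                conc[idx] = ac / vc
    return conc, y


def bateman_conc(ind, dose_g, t):
    """One-compartment first-order-absorption concentration (single dose)."""
    ke = ind.cl / ind.vc
    return (ind.f * dose_g * ind.ka / (ind.vc * (ind.ka - ke))
            * (np.exp(-ke * t) - np.exp(-ind.ka * t)))


def bateman_ss_trough(ind, dose_g, tau):
    """Steady-state pre-dose trough of repeated one-compartment dosing."""
    ke = ind.cl / ind.vc
    acc = (np.exp(-ke * tau) / (1 - np.exp(-ke * tau))
           - np.exp(-ind.ka * tau) / (1 - np.exp(-ind.ka * tau)))
    return ind.f * dose_g * ind.ka / (ind.vc * (ind.ka - ke)) * acc
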