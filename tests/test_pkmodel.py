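import numpy as np
import pytest

from igsim import (
    IndividualParameters, PopulationParameters, Regimen, endogenous_css,
    individualize, initial_excess_response, sc_unit_response, simulate_profile,
)

from conftest import make_subject, random_individual
from oracles import bateman_conc, ode_profile


def one_compartment(ke=0.03, vc=3.0, ka=0.25, f=0.7, ksyn=1e-12):
    """Effectively one-compartment: vanishing inter-compartmental clearance."""
    return IndividualParameters(cl=ke * vc, vc=vc, q=1e-9, vp=1.0, ka=ka,
                                f=f, ksyn=ksyn)


class TestIndividualize:
    def test_identity_at_reference(self, pop_params):
        subj = make_subject(weight=70.9, height=1.755)  # lbm == 56.0 kg?
        # construct a subject whose fat-free mass equals lbm_ref exactly by
        # scaling weight at fixed height
        from igsim import compute_lbm
        from scipy.optimize import brentq
        h = 1.75
        w = brentq(lambda w: compute_lbm(w, w / h**2, "male") - pop_params.lbm_ref,
                   40, 120)
        subj = make_subject(weight=w, height=h)
        ind = individualize(pop_params, subj, np.zeros(4), "scig")
        assert ind.cl == pytest.approx(pop_params.cl_ref, rel=1e-9)
        assert ind.vc == pytest.approx(pop_params.vc_ref, rel=1e-9)
        assert ind.ka == pytest.approx(pop_params.ka_scig, rel=1e-9)
        assert ind.f == pop_params.f_scig
        assert ind.ksyn == pytest.approx(pop_params.ksyn_ref, rel=1e-9)

    def test_allometric_scaling(self, pop_params):
        # theta_cl = 1 doubles CL when LBM doubles
        p = PopulationParameters(theta_cl=1.0)
        s1 = make_subject(weight=60, height=1.7)
        ind1 = individualize(p, s1, np.zeros(4))
        ratio = 2 * s1.lbm / p.lbm_ref
        p2 = PopulationParameters(theta_cl=1.0, lbm_ref=p.lbm_ref)
        # same subject against half the reference size -> CL doubles
        p_half = PopulationParameters(theta_cl=1.0, lbm_ref=p.lbm_ref / 2)
        ind2 = individualize(p_half, s1, np.zeros(4))
        assert ind2.cl == pytest.approx(2 * ind1.cl, rel=1e-9)

    def test_power_law_child_ratio(self, pop_params):
        # lbm ratio 0.2632 with exponent 0.88 -> CL ratio 0.3088
        assert 0.2632 ** 0.88 == pytest.approx(0.3088, abs=2e-4)

    def test_formulation_selects_ka_and_f(self, pop_params, adult_subject):
        ind_s = individualize(pop_params, adult_subject, np.zeros(4), "scig")
        ind_f = individualize(pop_params, adult_subject, np.zeros(4), "fscig")
        assert (ind_s.ka, ind_s.f) == (pytest.approx(pop_params.ka_scig),
                                       pop_params.f_scig)
        assert (ind_f.ka, ind_f.f) == (pytest.approx(pop_params.ka_fscig),
                                       pop_params.f_fscig)


class TestEndogenousSteadyState:
    def test_ratio_and_homogeneity(self):
        ind = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        assert endogenous_css(ind) == pytest.approx(2.0)
        scaled = IndividualParameters(cl=0.3, vc=3, q=0.3, vp=3, ka=0.25,
                                      f=0.7, ksyn=0.6)
        assert endogenous_css(scaled) == pytest.approx(2.0)
        none = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                    ksyn=0.0)
        assert endogenous_css(none) == 0.0


class TestUnitResponse:
    def test_zero_at_dose_time_and_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            ind = random_individual(rng)
            t = np.linspace(0, 200, 2001)
            c = sc_unit_response(ind, t)
            assert c[0] == 0.0
            assert np.all(c >= 0)

    def test_dose_recovery_integral(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            ind = random_individual(rng)
            t = np.linspace(0, 2000, 400001)
            c = sc_unit_response(ind, t)
            assert np.trapezoid(c, t) == pytest.approx(ind.f / ind.cl, rel=1e-4)

    def test_one_compartment_limit_matches_bateman(self):
        ind = one_compartment()
        t = np.linspace(0, 120, 1201)
        assert sc_unit_response(ind, t) == pytest.approx(
            bateman_conc(ind, 1.0, t), rel=1e-6, abs=1e-12)

    def test_ka_eigenvalue_degeneracy_is_finite(self):
        ind = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        from igsim.pkmodel import disposition_eigenvalues
        lam1, _ = disposition_eigenvalues(ind)
        degenerate = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3,
                                          ka=lam1, f=0.7, ksyn=0.2)
        c = sc_unit_response(degenerate, np.linspace(0, 100, 101))
        assert np.all(np.isfinite(c))


class TestInitialExcess:
    def test_initial_condition_and_monotone_decay(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            ind = random_individual(rng)
            t = np.linspace(0, 300, 3001)
            c = initial_excess_response(ind, 5.0, t)
            assert c[0] == pytest.approx(5.0, rel=1e-12)
            assert np.all(np.diff(c) <= 1e-12)
            assert np.all(initial_excess_response(ind, 0.0, t) == 0.0)

    def test_one_compartment_closed_form(self):
        ind = one_compartment(ke=0.03)
        c = initial_excess_response(ind, 5.0, np.array([28.0]))
        assert c[0] == pytest.approx(5.0 * np.exp(-0.84), rel=1e-6)
        assert c[0] == pytest.approx(2.158, abs=2e-3)


class TestSimulateProfile:
    def test_no_dose_at_steady_state_is_flat(self):
        ind = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        reg = Regimen.scig()
        t = np.linspace(0, 140, 561)
        prof = simulate_profile(ind, reg, 0.0, endogenous_css(ind), t)
        assert prof.conc_total == pytest.approx(np.full_like(t, 2.0), rel=1e-12)

    def test_dose_linearity_of_exogenous_component(self):
        ind = IndividualParameters(cl=0.12, vc=3.2, q=0.3, vp=3, ka=0.22,
                                   f=0.7, ksyn=0.25)
        reg = Regimen.fscig()
        t = np.linspace(0, 140, 561)
        p1 = simulate_profile(ind, reg, 10.0, 7.0, t)
        p2 = simulate_profile(ind, reg, 20.0, 7.0, t)
        excess = initial_excess_response(ind, 7.0 - endogenous_css(ind), t)
        np.testing.assert_allclose(p2.conc_exogenous - excess,
                                   2 * (p1.conc_exogenous - excess),
                                   rtol=1e-9, atol=1e-9)

    def test_total_is_endogenous_plus_exogenous(self):
        ind = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        t = np.linspace(0, 140, 561)
        prof = simulate_profile(ind, Regimen.scig(), 9.0, 7.0, t)
        np.testing.assert_allclose(
            prof.conc_total, prof.conc_endogenous + prof.conc_exogenous,
            rtol=1e-12)

    def test_rejects_start_below_endogenous_steady_state(self):
        ind = IndividualParameters(cl=0.05, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.5)  # css = 10 g/L
        with pytest.raises(ValueError, match="endogenous"):
            simulate_profile(ind, Regimen.scig(), 9.0, 7.0,
                             np.linspace(0, 140, 561))

    def test_agrees_with_ode_oracle_on_default_set(self):
        ind = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        reg = Regimen.scig()
        t = np.linspace(0, 140, 281)
        prof = simulate_profile(ind, reg, 9.0, 7.0, t)
        ref, _ = ode_profile(ind, reg, 9.0, 7.0, t)
        np.testing.assert_allclose(prof.conc_total, ref, rtol=1e-6)

    def test_approach_to_periodicity(self):
        # past ~5 terminal half-lives the profile repeats each interval
        ind = IndividualParameters(cl=0.15, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        from igsim.pkmodel import disposition_eigenvalues
        _, lam2 = disposition_eigenvalues(ind)
        t_ss = 5 * np.log(2) / lam2
        reg = Regimen.scig(horizon=7.0 * np.ceil((t_ss + 28) / 7.0))
        t = np.arange(t_ss, t_ss + 14, 0.25)
        t0 = np.floor(t_ss / 7) * 7  # align to dose times
        ta = np.arange(t0, t0 + 7, 0.25)
        pa = simulate_profile(ind, reg, 9.0, 7.0, ta).conc_total
        pb = simulate_profile(ind, reg, 9.0, 7.0, ta + 7).conc_total
        assert np.max(np.abs(pb - pa) / pa) < 0.005

    def test_mass_balance_on_ode_oracle(self):
        ind = IndividualParameters(cl=0.1, vc=3, q=0.3, vp=3, ka=0.25, f=0.7,
                                   ksyn=0.2)
        reg = Regimen.fscig()
        t = np.linspace(0, 140, 141)
        c0 = 7.0
        _, (depot, ac, ap, elim) = ode_profile(ind, reg, 12.0, c0, t)
        n_doses = len(np.arange(0, reg.horizon, reg.interval))
        total_in = (c0 * (ind.vc + ind.vp) + ind.f * 12.0 * n_doses
                    + ind.ksyn * reg.horizon)
        assert depot + ac + ap + elim == pytest.approx(total_in, rel=1e-6)
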