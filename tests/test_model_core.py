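"""Structural model: forcing functions, closed-form PK, PD dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from ppipkpd import (
    ILAPRAZOLE_PD,
    ILAPRAZOLE_PK,
    DoseEvent,
    IndividualPK,
    Regimen,
    circadian_factor,
    daily_regimen,
    food_effect,
    h_from_ph,
    individual_parameters,
    individual_pd_parameters,
    observed_h,
    ph_from_h,
    pk_concentration,
    simulate_individual,
)
from ppipkpd.model_core import pd_rhs


class TestCircadianFactor:
    def test_zero_amplitude_is_flat(self):
        pd = ILAPRAZOLE_PD.replace(MA=0.0)
        assert circadian_factor(3.7, pd) == 1.0
        assert np.all(circadian_factor(np.linspace(0, 48, 33), pd) == 1.0)

    def test_peak_value_at_mtmax(self):
        # f(MTmax) = 1 + MA
        assert circadian_factor(22.38, ILAPRAZOLE_PD) == pytest.approx(29.48)

    def test_daytime_value_matches_direct_evaluation(self):
        expected = 1 + 28.48 / ((10.38 / 0.99) ** 4 + 1)
        assert circadian_factor(12.0, ILAPRAZOLE_PD) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.0024, abs=2e-4)

    @given(st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_surge_bounded_and_periodic(self, t):
        f = circadian_factor(t, ILAPRAZOLE_PD)
        assert 1.0 <= f <= 1.0 + ILAPRAZOLE_PD.MA
        assert f == pytest.approx(circadian_factor(t + 24.0, ILAPRAZOLE_PD), rel=1e-9)

    def test_maximal_at_peak_time(self):
        t = np.linspace(0, 24, 2401)
        f = circadian_factor(t, ILAPRAZOLE_PD)
        assert abs(t[np.argmax(f)] - ILAPRAZOLE_PD.MTmax) < 0.02


class TestFoodEffect:
    def test_fasting_before_lunch(self):
        assert food_effect(2.0, ILAPRAZOLE_PD) == 1.0

    def test_lunch_bolus_dilution(self):
        assert food_effect(4.0, ILAPRAZOLE_PD) == pytest.approx(1 / 41.04, rel=1e-12)

    def test_dinner_adds_to_decaying_lunch_effect(self):
        expected = 1.0 / (1 + 40.04 * math.exp(-0.64 * 6) + 97.7)
        assert food_effect(10.0, ILAPRAZOLE_PD) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.01005, abs=2e-5)

    def test_meals_recur_daily(self):
        t = np.array([2.0, 5.0, 11.0])
        assert food_effect(t + 24.0, ILAPRAZOLE_PD) == pytest.approx(
            food_effect(t, ILAPRAZOLE_PD)
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            food_effect(-0.5, ILAPRAZOLE_PD)

    @given(st.floats(0, 72))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, t):
        fe = food_effect(t, ILAPRAZOLE_PD)
        assert 0.0 < fe <= 1.0

    def test_monotone_recovery_between_meals(self):
        t = np.linspace(4.0, 9.99, 100)
        fe = food_effect(t, ILAPRAZOLE_PD)
        assert np.all(np.diff(fe) > 0)


class TestPhConversions:
    def test_reference_points(self):
        assert ph_from_h(1.0) == 0.0
        assert ph_from_h(0.033) == pytest.approx(1.4815, abs=1e-4)

    @given(st.floats(1e-6, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, h):
        assert h_from_ph(ph_from_h(h)) == pytest.approx(h, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ph_from_h(0.0)

    def test_observed_h_dilution(self):
        assert observed_h(0.033, 1.0) == 0.033
        assert observed_h(0.033, 0.5) == pytest.approx(0.0165)

    def test_lunch_dilution_raises_ph_by_1_6(self):
        fe = food_effect(4.0, ILAPRAZOLE_PD)
        rise = ph_from_h(observed_h(0.033, fe)) - ph_from_h(0.033)
        assert rise == pytest.approx(1.613, abs=2e-3)


class TestIndividualParameters:
    def test_reference_covariates_recover_typical_values(self):
        ind = individual_parameters(ILAPRAZOLE_PK, 70.0, 0)
        assert (ind.CLp, ind.CLt, ind.Vc, ind.Vt) == (2.57, 4.59, 8.80, 3.65)

    def test_allometric_weight_scaling_of_vc(self):
        ind = individual_parameters(ILAPRAZOLE_PK, 62.6, 0)
        assert ind.Vc == pytest.approx(8.80 * (62.6 / 70.0) ** 1.35, rel=1e-12)
        assert ind.Vc == pytest.approx(7.57, abs=0.01)

    def test_sex_effect_multiplies_clearance(self):
        ind = individual_parameters(ILAPRAZOLE_PK, 70.0, 1)
        assert ind.CLp == pytest.approx(2.57 * 1.30)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            individual_parameters(ILAPRAZOLE_PK, 0.0, 0)


class TestPKConcentration:
    def test_zero_before_and_at_dose_start(self, pk_typical):
        doses = [DoseEvent(0.0, 10.0, 0.5)]
        assert pk_concentration(0.0, doses, pk_typical) == 0.0
        assert pk_concentration(-1.0, doses, pk_typical) == 0.0

    def test_dose_linearity(self, pk_typical):
        t = np.linspace(0.1, 48, 40)
        doses1 = [DoseEvent(0.0, 10.0, 0.5), DoseEvent(24.0, 5.0, 0.5)]
        doses2 = [DoseEvent(0.0, 20.0, 0.5), DoseEvent(24.0, 10.0, 0.5)]
        np.testing.assert_allclose(
            pk_concentration(t, doses2, pk_typical),
            2.0 * pk_concentration(t, doses1, pk_typical), rtol=1e-12,
        )

    def test_auc_equals_dose_over_clearance(self, pk_typical):
        doses = [DoseEvent(0.0, 10.0, 0.5)]
        auc, _ = quad(lambda t: pk_concentration(float(t), doses, pk_typical),
                      0, 2000, limit=500)
        assert auc == pytest.approx(10.0 / 2.57 * 1000.0, rel=1e-6)  # ng*h/mL

    @given(
        cl=st.floats(0.5, 10), q=st.floats(0.5, 10),
        vc=st.floats(2, 30), vt=st.floats(1, 30),
        amount=st.floats(1, 40),
    )
    @settings(max_examples=15, deadline=None)
    def test_closed_form_matches_ode_integration(self, cl, q, vc, vt, amount):
        """Superposed bi-exponential infusion solution vs an independent stiff
        ODE integration of the mass-balance equations (rtol 1e-6)."""
        ind = IndividualPK(cl, q, vc, vt)
        doses = [DoseEvent(0.0, amount, 0.5), DoseEvent(24.0, amount / 2, 1.0)]

        def rhs(t, y):
            rin = sum(1000.0 * e.amount / e.duration
                      for e in doses if e.start_time < t <= e.start_time + e.duration)
            cp, ct = y
            return [(-cl * cp - q * (cp - ct) + rin) / vc, q * (cp - ct) / vt]

        grid = np.linspace(0.25, 36.0, 30)
        expected = np.empty_like(grid)
        state = [0.0, 0.0]
        breaks = [0.0, 0.5, 24.0, 25.0, 36.0]
        for a, b in zip(breaks[:-1], breaks[1:]):
            m = (grid > a) & (grid <= b)
            te = np.unique(np.concatenate([grid[m], [b]]))
            sol = solve_ivp(rhs, (a, b), state, method="LSODA",
                            rtol=1e-11, atol=1e-12, t_eval=te)
            state = sol.y[:, -1]
            expected[m] = sol.y[0][np.searchsorted(te, grid[m])]
        got = pk_concentration(grid, doses, ind)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)


class TestPDRightHandSide:
    def test_steady_state_without_drug(self, pd_typical):
        de, dh = pd_rhs(5.0, (1.0, ILAPRAZOLE_PD.HBASE), lambda t: 0.0,
                        individual_pd_parameters(ILAPRAZOLE_PD.replace(MA=0.0)))
        assert de == 0.0
        assert dh == pytest.approx(0.0, abs=1e-15)

    def test_inhibition_term_magnitude(self, pd_typical):
        # at Cp = 100 ng/mL the inactivation term is kd*E*Cp = 1824/h
        de, _ = pd_rhs(0.0, (1.0, 0.033), lambda t: 100.0, pd_typical)
        assert de == pytest.approx(ILAPRAZOLE_PD.kdeg * 0.0 - 1824.0, rel=1e-12)


class TestSimulateIndividual:
    def test_zero_dose_gives_baseline_profile(self, pk_typical, pd_typical):
        reg = Regimen("none", (DoseEvent(0.0, 0.0, 0.5),), 24.0)
        grid = np.arange(0.0, 24.25, 0.25)
        prof = simulate_individual(reg, pk_typical, pd_typical, grid)
        assert np.all(prof.cp == 0.0)
        np.testing.assert_allclose(prof.e_rel, 1.0, rtol=1e-12)
        # observed pH is the baseline circadian/meal profile
        expected = ph_from_h(observed_h(prof.h, food_effect(grid, ILAPRAZOLE_PD)))
        np.testing.assert_allclose(prof.ph, expected, rtol=1e-12)
        # meal discontinuities at 4 h and 10 h
        i4 = np.searchsorted(grid, 4.0)
        assert prof.ph[i4] - prof.ph[i4 - 1] > 1.0

    def test_drug_free_fixed_point_is_stable_over_72h(self, pk_typical):
        pd_ind = individual_pd_parameters(ILAPRAZOLE_PD.replace(MA=0.0))
        reg = Regimen("none", (DoseEvent(0.0, 0.0, 0.5),), 72.0)
        grid = np.arange(0.0, 72.5, 0.5)
        prof = simulate_individual(reg, pk_typical, pd_ind, grid)
        np.testing.assert_allclose(prof.e_rel, 1.0, atol=1e-10)
        np.testing.assert_allclose(prof.h, ILAPRAZOLE_PD.HBASE, rtol=1e-8)

    def test_ph_rise_lags_concentration_peak(self, pk_typical, pd_typical,
                                             regimen_20mg):
        grid = np.arange(0.0, 24.05, 0.05)
        prof = simulate_individual(regimen_20mg, pk_typical, pd_typical, grid,
                                   food=False)
        t_cmax = grid[np.argmax(prof.cp)]
        t_half_ph = grid[np.argmax(prof.ph > 0.5 * (prof.ph[0] + prof.ph.max()))]
        assert t_half_ph > t_cmax

    def test_fast_stepper_matches_stiff_bdf_oracle(self, pk_typical, regimen_20mg):
        grid = np.arange(0.0, 24.5, 0.5)
        for eta in ([0.0] * 3, [1.0, -0.5, 0.5]):
            pdi = individual_pd_parameters(ILAPRAZOLE_PD, eta)
            fast = simulate_individual(regimen_20mg, pk_typical, pdi, grid)
            ref = simulate_individual(regimen_20mg, pk_typical, pdi, grid,
                                      method="bdf", rtol=1e-10)
            np.testing.assert_allclose(fast.h, ref.h, rtol=1e-4)
            np.testing.assert_allclose(fast.e_rel, ref.e_rel, rtol=1e-4, atol=1e-12)

    def test_halving_kout_slows_ph_response(self, pk_typical, regimen_20mg):
        grid = np.arange(0.0, 6.05, 0.05)
        fast_k = simulate_individual(regimen_20mg, pk_typical,
                                     individual_pd_parameters(ILAPRAZOLE_PD), grid)
        slow_k = simulate_individual(
            regimen_20mg, pk_typical,
            individual_pd_parameters(ILAPRAZOLE_PD.replace(kout=2.8)), grid)
        t_fast = grid[np.argmax(fast_k.ph > 3.0)]
        t_slow = grid[np.argmax(slow_k.ph > 3.0)]
        assert t_slow > t_fast

    @given(amount=st.floats(0.0, 80.0), e1=st.floats(-2, 2), e2=st.floats(-2, 2))
    @settings(max_examples=15, deadline=None)
    def test_pump_activity_stays_in_unit_interval(self, pk_typical, amount, e1, e2):
        pdi = individual_pd_parameters(ILAPRAZOLE_PD, [e1, e2, 0.0])
        reg = Regimen("x", (DoseEvent(0.0, amount, 0.5),), 24.0)
        prof = simulate_individual(reg, pk_typical, pdi, np.arange(0.0, 24.5, 0.5))
        assert np.all(prof.e_rel > 0.0)
        assert np.all(prof.e_rel <= 1.0 + 1e-12)

    def test_mean_ph_monotone_in_dose(self, pk_typical, pd_typical):
        grid = np.arange(0.0, 24.25, 0.25)
        means = []
        for amt in (5.0, 10.0, 20.0, 40.0):
            reg = daily_regimen([amt], f"{amt}")
            prof = simulate_individual(reg, pk_typical, pd_typical, grid)
            means.append(np.trapezoid(prof.ph, grid) / 24.0)
        assert np.all(np.diff(means) > 0)

    def test_invalid_grid_rejected(self, pk_typical, pd_typical, regimen_20mg):
        with pytest.raises(ValueError):
            simulate_individual(regimen_20mg, pk_typical, pd_typical, [1.0, 0.5])
        with pytest.raises(ValueError):
            simulate_individual(regimen_20mg, pk_typical, pd_typical, [-1.0, 2.0])


class TestDoseEventAndRegimen:
    def test_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, -1.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            Regimen("r", (), 24.0)
        with pytest.raises(ValueError):
            Regimen("r", (DoseEvent(30.0, 10.0, 0.5),), 24.0)

    def test_events_sorted_by_start(self):
        reg = Regimen("r", (DoseEvent(24.0, 5.0), DoseEvent(0.0, 10.0)), 48.0)
        assert [e.start_time for e in reg.events] == [0.0, 24.0]
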