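"""Single-cycle kinetics simulation/fitting, 4PL and Cheng-Prusoff."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from knobminer import (InjectionProtocol, KineticsModel, cheng_prusoff,
                       fit_4pl, fit_sck, four_pl, make_sck_protocol,
                       simulate_sck)
from knobminer.binding import subtract_background


class TestProtocol:
    def test_default_series_reaches_1_37_nM(self):
        p = make_sck_protocol()
        assert len(p.concentrations) == 7
        assert p.concentrations[-1] == 1e-6
        assert p.concentrations[0] == pytest.approx(1.3717e-9, rel=1e-4)

    def test_single_injection(self):
        p = make_sck_protocol(n_injections=1)
        assert p.concentrations == (1e-6,)

    def test_consecutive_ratios_equal_dilution(self):
        c = make_sck_protocol(dilution=3).concentrations
        ratios = [b / a for a, b in zip(c, c[1:])]
        assert np.allclose(ratios, 3.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_sck_protocol(top_conc=-1)
        with pytest.raises(ValueError):
            make_sck_protocol(dilution=1.0)
        with pytest.raises(ValueError):
            InjectionProtocol(concentrations=(1e-6, 1e-7))  # descending


class TestSimulateSck:
    MODEL = KineticsModel(kon=1e5, koff=1e-3, rmax=100.0)

    def test_kd_derived_from_rates(self):
        assert self.MODEL.kd == pytest.approx(1e-8)

    def test_response_never_exceeds_rmax_noiseless(self):
        sg = simulate_sck(self.MODEL, make_sck_protocol())
        assert np.all(sg.response <= self.MODEL.rmax + 1e-9)
        assert np.all(np.diff(sg.time) > 0)

    def test_monotone_saturation_when_koff_vanishes(self):
        slow = KineticsModel(kon=1e5, koff=1e-12, rmax=50.0)
        protocol = InjectionProtocol(concentrations=(1e-6,),
                                     contact_time=60_000.0,
                                     final_dissociation_time=1.0)
        sg = simulate_sck(slow, protocol)
        contact = sg.response[sg.time < 60_000.0]
        assert np.all(np.diff(contact) >= -1e-12)
        assert contact[-1] == pytest.approx(50.0, rel=1e-3)

    def test_long_contact_plateau_is_langmuir_isotherm(self):
        c = 1e-8
        protocol = InjectionProtocol(concentrations=(c,),
                                     contact_time=500_000.0,
                                     final_dissociation_time=1.0,
                                     sampling_rate=0.01)
        sg = simulate_sck(self.MODEL, protocol)
        plateau = sg.response[np.searchsorted(sg.time, 499_000.0)]
        expected = self.MODEL.rmax * c / (c + self.MODEL.kd)
        assert plateau == pytest.approx(expected, rel=1e-6)

    def test_req_increasing_in_concentration(self):
        reqs = [self.MODEL.rmax * c / (c + self.MODEL.kd)
                for c in make_sck_protocol().concentrations]
        assert all(a < b for a, b in zip(reqs, reqs[1:]))

    def test_seed_determinism(self):
        a = simulate_sck(self.MODEL, make_sck_protocol(), noise_sd=1.0,
                         seed=3)
        b = simulate_sck(self.MODEL, make_sck_protocol(), noise_sd=1.0,
                         seed=3)
        assert np.array_equal(a.response, b.response)

    def test_closed_form_agrees_with_numeric_integrator(self):
        """Dual route: piecewise analytic solution vs an ODE solver for
        dR/dt = kon*C*(Rmax - R) - koff*R."""
        from knobminer.binding import _model_response
        protocol = make_sck_protocol(n_injections=3, contact_time=100.0,
                                     final_dissociation_time=300.0)
        segments = protocol.segments
        t0, r0 = 0.0, 0.0
        times, values = [], []
        for conc, duration in segments:
            def rhs(_t, r, c=conc):
                return self.MODEL.kon * c * (self.MODEL.rmax - r[0]) \
                    - self.MODEL.koff * r[0]
            grid = np.linspace(t0, t0 + duration, 50)
            sol = solve_ivp(rhs, (t0, t0 + duration), [r0], t_eval=grid,
                            rtol=1e-10, atol=1e-12)
            times.extend(sol.t)
            values.extend(sol.y[0])
            r0 = sol.y[0][-1]
            t0 += duration
        analytic = _model_response(np.array(times), self.MODEL, protocol)
        assert np.allclose(analytic, values, atol=1e-5)


class TestFitSck:
    def test_noiseless_recovery_within_0_1_percent(self):
        truth = KineticsModel(kon=1e5, koff=1e-3, rmax=100.0)
        fit = fit_sck(simulate_sck(truth, make_sck_protocol()))
        assert fit.success
        assert fit.model.kon == pytest.approx(truth.kon, rel=1e-3)
        assert fit.model.koff == pytest.approx(truth.koff, rel=1e-3)
        assert fit.model.rmax == pytest.approx(truth.rmax, rel=1e-3)
        assert fit.kd == pytest.approx(1e-8, rel=1e-3)
        assert not fit.koff_below_limit

    def test_off_grid_parameters_recovered(self):
        truth = KineticsModel(kon=3.3e4, koff=4.7e-4, rmax=85.0)
        fit = fit_sck(simulate_sck(truth, make_sck_protocol()))
        assert fit.model.kon == pytest.approx(truth.kon, rel=1e-3)
        assert fit.model.koff == pytest.approx(truth.koff, rel=1e-3)

    def test_koff_below_determination_limit_flagged(self):
        truth = KineticsModel(kon=1e5, koff=5e-6, rmax=100.0)
        fit = fit_sck(simulate_sck(truth, make_sck_protocol()))
        assert fit.koff_below_limit

    def test_kd_invariant_to_joint_signal_rescaling(self):
        truth = KineticsModel(kon=1e5, koff=1e-3, rmax=100.0)
        sg = simulate_sck(truth, make_sck_protocol())
        scaled = type(sg)(time=sg.time, response=sg.response * 3.0,
                          protocol=sg.protocol)
        fit = fit_sck(scaled)
        assert fit.kd == pytest.approx(truth.kd, rel=1e-3)
        assert fit.model.rmax == pytest.approx(300.0, rel=1e-3)

    def test_noisy_replicates_median_kd_error_below_10_percent(self):
        truth = KineticsModel(kon=1e5, koff=1e-3, rmax=100.0)
        protocol = make_sck_protocol()
        errors = []
        for i in range(20):
            sg = simulate_sck(truth, protocol, noise_sd=1.0, seed=100 + i)
            fit = fit_sck(sg)
            errors.append((fit.kd - truth.kd) / truth.kd)
        assert np.median(np.abs(errors)) < 0.10
        # unbiased: the signed median error is close to zero
        assert abs(np.median(errors)) < 0.05


class TestFit4pl:
    X = np.logspace(-10.5, -6.5, 9)

    def test_noiseless_recovery_within_0_1_percent(self):
        y = four_pl(self.X, 0.0, 100.0, 1e-8, 1.0)
        fit = fit_4pl(self.X, y)
        assert fit.bottom == pytest.approx(0.0, abs=1e-3)
        assert fit.top == pytest.approx(100.0, rel=1e-3)
        assert fit.midpoint == pytest.approx(1e-8, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)
        assert fit.hill_in_range

    def test_midpoint_property(self):
        for hill in (0.8, 1.0, -1.3):
            y_mid = four_pl(np.array([1e-8]), 10.0, 90.0, 1e-8, hill)[0]
            assert y_mid == pytest.approx(50.0)

    def test_inhibition_curve_negative_hill(self):
        y = four_pl(self.X, 5.0, 95.0, 3e-8, -1.2)
        fit = fit_4pl(self.X, y)
        assert fit.hill == pytest.approx(-1.2, rel=1e-3)
        assert fit.hill_in_range

    def test_hill_out_of_expected_range_flagged(self):
        y = four_pl(self.X, 0.0, 100.0, 1e-8, 3.0)
        fit = fit_4pl(self.X, y)
        assert not fit.hill_in_range

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_4pl(np.full(6, 1e-8), np.arange(6.0))
        with pytest.raises(ValueError):
            fit_4pl(self.X[:4], np.arange(4.0))

    def test_background_subtraction(self):
        y = np.array([10.0, 20.0, 30.0])
        assert np.allclose(subtract_background(y, np.array([9.0, 11.0])),
                           [0.0, 10.0, 20.0])


class TestChengPrusoff:
    def test_assay_at_kdapp_halves_ic50(self):
        assert cheng_prusoff(10e-9, 5e-9, 5e-9) == pytest.approx(5e-9)

    def test_no_competition_limit(self):
        assert cheng_prusoff(10e-9, 0.0, 5e-9) == pytest.approx(10e-9)

    def test_direct_evaluation(self):
        assert cheng_prusoff(12.0, 12.0, 4.0) == pytest.approx(3.0)

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            cheng_prusoff(1e-9, 1e-9, 0.0)

    @given(st.floats(min_value=1e-12, max_value=1e-3),
           st.floats(min_value=0.0, max_value=1e-3),
           st.floats(min_value=1e-12, max_value=1e-3))
    def test_ki_never_exceeds_ic50(self, ic50, r_conc, kd):
        ki = cheng_prusoff(ic50, r_conc, kd)
        assert 0 < ki <= ic50

    def test_continuity_as_r_vanishes(self):
        kis = [cheng_prusoff(1e-8, r, 1e-9)
               for r in (1e-9, 1e-12, 1e-15, 0.0)]
        assert kis[-1] == 1e-8
        assert np.all(np.diff(kis) > 0) and kis[-2] == pytest.approx(1e-8,
                                                                     rel=1e-5)
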