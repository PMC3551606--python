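import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldshift import synthetic_data
from foldshift.cd_thermo import (
    CELSIUS_OFFSET,
    R_KCAL,
    MeltCurve,
    TwoStateFit,
    delta_delta_G,
    fit_two_state,
    fraction_unfolded,
    gibbs_free_energy,
    mdeg_to_mre,
    two_state_model,
    two_state_signal,
)


def make_fit(dH=50.0, Tm=331.15, Yn=-10.0, Mn=0.0, Yd=-2.0, Md=0.0, **kw):
    return TwoStateFit(Yn=Yn, Mn=Mn, Yd=Yd, Md=Md, dH=dH, Tm=Tm, **kw)


class TestMreConversion:
    def test_zero_signal_is_zero(self):
        assert mdeg_to_mre(0.0, 30e-6, 79, 0.1) == 0.0

    def test_hand_computed_value(self):
        # 100 mdeg, 30 uM, 79 residues, 1 mm path: 100 / (10*0.1*3e-5*79)
        assert mdeg_to_mre(100.0, 30e-6, 79, 0.1) == pytest.approx(4.21941e4, rel=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(
        signal=st.floats(-1e3, 1e3),
        scale=st.floats(0.1, 10),
        conc=st.floats(1e-6, 1e-3),
        path=st.floats(0.01, 1.0),
        nres=st.integers(1, 500),
    )
    def test_homogeneity(self, signal, scale, conc, path, nres):
        base = mdeg_to_mre(signal, conc, nres, path)
        assert mdeg_to_mre(scale * signal, conc, nres, path) == pytest.approx(
            scale * base, rel=1e-12, abs=1e-9
        )
        assert mdeg_to_mre(signal, scale * conc, nres, path) == pytest.approx(
            base / scale, rel=1e-12, abs=1e-9
        )

    @pytest.mark.parametrize("bad", [dict(concentration=0), dict(n_residues=0), dict(path_length=-1)])
    def test_domain_errors(self, bad):
        kwargs = dict(concentration=30e-6, n_residues=79, path_length=0.1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            mdeg_to_mre(1.0, **kwargs)

    def test_array_signal(self):
        out = mdeg_to_mre(np.array([0.0, 100.0]), 30e-6, 79, 0.1)
        assert out.shape == (2,)


class TestTwoStateSignal:
    def test_midpoint_is_mean_of_baselines(self):
        fit = make_fit(Yn=-10, Mn=0.02, Yd=-2, Md=-0.01, Tm=331.15)
        native = fit.Yn + fit.Mn * fit.Tm
        denatured = fit.Yd + fit.Md * fit.Tm
        assert two_state_signal(fit, fit.Tm) == pytest.approx((native + denatured) / 2)

    def test_low_temperature_limit_is_native_baseline(self):
        fit = make_fit(dH=50.0, Tm=331.15, Mn=0.01)
        T = 250.0
        assert two_state_signal(fit, T) == pytest.approx(fit.Yn + fit.Mn * T, rel=1e-6)

    def test_closed_form_value(self):
        fit = make_fit(dH=50.0, Tm=331.15, Yn=-10.0, Yd=-2.0)
        T = 293.15
        dG = 50.0 * (1 - T / 331.15)
        K = np.exp(-dG / (R_KCAL * T))
        expected = (-10.0 + (-2.0) * K) / (1 + K)
        assert two_state_signal(fit, T) == pytest.approx(expected, rel=1e-12)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            two_state_signal(make_fit(), -1.0)


class TestFitTwoState:
    def test_noiseless_curve_recovers_truth(self, noiseless_melt):
        fit = fit_two_state(noiseless_melt)
        assert fit.converged
        assert fit.Tm == pytest.approx(58.0 + CELSIUS_OFFSET, rel=1e-3)
        assert fit.dH == pytest.approx(40.0, rel=1e-3)
        assert fit.cooperative == "cooperative"
        assert fit.dS == pytest.approx(fit.dH / fit.Tm, rel=1e-9)

    def test_straight_line_is_non_cooperative(self):
        temps = np.arange(4.0, 97.0, 2.0)
        curve = MeltCurve(temperature_c=temps, signal=-5.0 + 0.01 * temps)
        fit = fit_two_state(curve)
        assert fit.cooperative == "non-cooperative"

    def test_narrow_scan_rejected(self):
        temps = np.linspace(20, 40, 15)
        with pytest.raises(ValueError, match="span"):
            fit_two_state(MeltCurve(temperature_c=temps, signal=np.zeros(15)))

    def test_brute_force_grid_search_matches_fit_rmse(self):
        """A grid search over (dH, Tm), baselines solved linearly at each node,
        attains a residual RMSE within 5% of the nonlinear fit's."""
        curve = synthetic_data.gen_melt(dH=45.0, Tm_c=55.0, noise_frac=0.03, seed=7)
        assert len(curve.temperature_c) <= 47
        fit = fit_two_state(curve)
        T, y = curve.temperature_k, curve.signal
        best = np.inf
        for dh in np.arange(5.0, 100.1, 2.5):
            for tm in np.arange(T.min(), T.max() + 0.25, 0.5):
                dG = dh * (1 - T / tm)
                K = np.exp(np.clip(-dG / (R_KCAL * T), -500, 500))
                w = 1.0 / (1.0 + K)
                A = np.column_stack([w, w * T, 1 - w, (1 - w) * T])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                rmse = float(np.sqrt(np.mean((A @ coef - y) ** 2)))
                best = min(best, rmse)
        assert abs(best - fit.rmse) / fit.rmse < 0.05

    def test_parameter_recovery_under_noise(self):
        """Median |Tm error| < 0.5 degC and median relative dH error < 10%
        over 100 noisy simulations at sigma = 3% of transition amplitude."""
        tm_errs, dh_errs = [], []
        for seed in range(200, 300):
            curve = synthetic_data.gen_melt(dH=40.0, Tm_c=55.0, noise_frac=0.03, seed=seed)
            fit = fit_two_state(curve)
            tm_errs.append(abs(fit.tm_c - 55.0))
            dh_errs.append(abs(fit.dH - 40.0) / 40.0)
        assert np.median(tm_errs) < 0.5
        assert np.median(dh_errs) < 0.10

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            MeltCurve(temperature_c=np.arange(5), signal=np.arange(5))  # too few
        with pytest.raises(ValueError):
            MeltCurve(
                temperature_c=np.arange(4, 97, 2)[::-1], signal=np.zeros(47)[:46]
            )


class TestDerivedThermo:
    def test_dG_zero_at_Tm(self):
        fit = make_fit(dH=50.0, Tm=331.15)
        assert gibbs_free_energy(fit, fit.Tm) == 0.0

    def test_dG_hand_value(self):
        fit = make_fit(dH=50.0, Tm=331.15)
        assert gibbs_free_energy(fit, 293.15) == pytest.approx(
            50.0 * (1 - 293.15 / 331.15), rel=1e-12
        )
        assert gibbs_free_energy(fit, 293.15) == pytest.approx(5.7376, abs=5e-4)

    def test_dG_positive_below_Tm(self):
        assert gibbs_free_energy(make_fit(dH=30.0, Tm=320.0), 290.0) > 0

    def test_dG_rejects_nonpositive_T(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(make_fit(), 0.0)

    def test_fraction_half_at_Tm(self):
        fit = make_fit(dH=50.0, Tm=331.15)
        assert fraction_unfolded(fit, fit.Tm) == pytest.approx(0.5, abs=1e-12)

    def test_fraction_approaches_one_far_above_Tm(self):
        assert fraction_unfolded(make_fit(dH=50.0, Tm=300.0), 450.0) > 0.999

    def test_fraction_direct_evaluation(self):
        fit = make_fit(dH=50.0, Tm=331.15)
        T = 293.15
        dg = 50.0 * (1 - T / 331.15)
        K = np.exp(-dg / (R_KCAL * T))
        assert fraction_unfolded(fit, T) == pytest.approx(K / (1 + K), rel=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(
        dh=st.floats(5.0, 150.0),
        tm=st.floats(280.0, 370.0),
        offset=st.floats(-20.0, 19.0),
        dt=st.floats(0.1, 10.0),
    )
    def test_fraction_strictly_increasing_in_T(self, dh, tm, offset, dt):
        # strictly increasing around the transition; far from Tm the
        # fraction saturates to 0/1 within double precision
        fit = make_fit(dH=dh, Tm=tm)
        t1 = tm + offset
        assert fraction_unfolded(fit, t1 + dt) > fraction_unfolded(fit, t1)

    def test_ddG_zero_for_identical_fits(self):
        fit = make_fit(dH=40.0, Tm=330.0)
        assert delta_delta_G(fit, fit, 293.15) == 0.0

    def test_ddG_negative_for_destabilized_mutant(self):
        ref = make_fit(dH=40.0, Tm=331.15)
        mut = make_fit(dH=40.0, Tm=303.15)
        assert delta_delta_G(ref, mut, 293.15) < 0

    def test_ddG_matches_hand_difference(self):
        ref = make_fit(dH=40.0, Tm=331.15)
        mut = make_fit(dH=25.0, Tm=303.15)
        expected = 25.0 * (1 - 293.15 / 303.15) - 40.0 * (1 - 293.15 / 331.15)
        assert delta_delta_G(ref, mut, 293.15) == pytest.approx(expected, rel=1e-12)

    def test_ddG_requires_convergence_unless_forced(self):
        ref = make_fit(dH=40.0, Tm=331.15)
        mut = make_fit(dH=40.0, Tm=303.15, converged=False)
        with pytest.raises(ValueError):
            delta_delta_G(ref, mut, 293.15)
        assert delta_delta_G(ref, mut, 293.15, force=True) < 0
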