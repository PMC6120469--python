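import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanodomain import (
    CorrelationCurve,
    FcsFitResult,
    FcsModelParams,
    IntensityTrace,
    autocorrelate,
    crosscorrelate,
    eval_model,
    fit_tacc,
    rcca,
    slow_fast_regression,
)
from nanodomain.exceptions import DegenerateInputError, DegenerateRegressionError

TAUS = np.geomspace(1e-6, 1.0, 80)


def params_2ct(n=1.0, y=0.7, td1=5e-4, td2=9e-2, t=0.2, tt=5e-6):
    return FcsModelParams(
        n=n, y=y, tau_d1=td1, tau_d2=td2, t_trip=t, tau_t=tt,
        model_tag="2comp+triplet",
    )


class TestEvalModel:
    def test_one_component_half_decay(self):
        """At tau = tau_D the single-component G has decayed half way."""
        p = FcsModelParams(n=1.0, tau_d1=1e-3, model_tag="1comp")
        assert eval_model(p, 1e-3) == pytest.approx(1.5)

    def test_long_lag_limit_is_one(self):
        p = params_2ct()
        assert eval_model(p, 1e5) == pytest.approx(1.0, abs=1e-5)

    def test_full_model_frozen_value(self):
        """Independent arithmetic evaluation of the 2-component + triplet
        closed form at tau = tau_T (frozen oracle value)."""
        p = params_2ct()
        assert eval_model(p, 5e-6) == pytest.approx(2.084384, abs=5e-6)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            eval_model(params_2ct(), -1e-6)

    @pytest.mark.parametrize("tag", ["1comp", "1comp+triplet", "2comp", "2comp+triplet"])
    def test_zero_lag_amplitude_is_inverse_n(self, tag):
        """G(0) = 1 + 1/N for every model variant when T = 0."""
        for n in (0.5, 1.0, 4.0):
            p = FcsModelParams(
                n=n, y=0.6, tau_d1=5e-4, tau_d2=5e-2, t_trip=0.0,
                tau_t=5e-6, model_tag=tag,
            )
            assert eval_model(p, 0.0) == pytest.approx(1.0 + 1.0 / n)

    @given(
        n=st.floats(0.2, 50),
        y=st.floats(0.0, 1.0),
        t=st.floats(0.0, 0.4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decay(self, n, y, t):
        p = FcsModelParams(
            n=n, y=y, tau_d1=3e-4, tau_d2=3e-2, t_trip=t, tau_t=5e-6,
            model_tag="2comp+triplet",
        )
        g = eval_model(p, TAUS)
        assert np.all(np.diff(g) < 1e-12)

    def test_doubling_n_halves_amplitude(self):
        g1 = eval_model(params_2ct(n=1.0), TAUS) - 1.0
        g2 = eval_model(params_2ct(n=2.0), TAUS) - 1.0
        assert np.allclose(g1, 2 * g2)


class TestFitTacc:
    def test_exact_curve_recovered(self):
        truth = params_2ct(n=1.4, y=0.62, td1=4e-4, td2=6e-2, t=0.12, tt=4e-6)
        curve = CorrelationCurve(TAUS, eval_model(truth, TAUS))
        fit = fit_tacc(curve, "2comp+triplet")
        p = fit.params
        assert p.n == pytest.approx(truth.n, rel=1e-3)
        assert p.y == pytest.approx(truth.y, rel=1e-3)
        assert p.tau_d1 == pytest.approx(truth.tau_d1, rel=1e-3)
        assert p.tau_d2 == pytest.approx(truth.tau_d2, rel=1e-3)
        assert fit.n1 + fit.n2 == pytest.approx(p.n, rel=1e-9)

    def test_auto_prefers_single_component_when_true(self):
        truth = FcsModelParams(
            n=2.0, tau_d1=1e-3, t_trip=0.1, tau_t=5e-6, model_tag="1comp+triplet"
        )
        rng = np.random.default_rng(4)
        values = eval_model(truth, TAUS) + rng.normal(0, 2e-4, len(TAUS))
        fit = fit_tacc(CorrelationCurve(TAUS, values), "auto")
        assert fit.params.model_tag == "1comp+triplet"

    def test_auto_detects_two_components(self):
        truth = params_2ct(n=1.0, y=0.6)
        curve = CorrelationCurve(TAUS, eval_model(truth, TAUS))
        fit = fit_tacc(curve, "auto")
        assert fit.params.model_tag == "2comp+triplet"

    def test_triplet_warning_flag(self):
        truth = params_2ct(t=0.35)
        curve = CorrelationCurve(TAUS, eval_model(truth, TAUS))
        with pytest.warns(UserWarning, match="triplet"):
            fit = fit_tacc(curve, "2comp+triplet")
        assert fit.triplet_warning

    def test_parameter_recovery_under_noise(self):
        """Median recovery over 20 noisy synthetic curves: diffusion times
        within 15% and slow fraction within 0.05 for 100x-separated
        components."""
        truth = params_2ct(n=1.2, y=0.6, td1=5e-4, td2=5e-2, t=0.15, tt=5e-6)
        rng = np.random.default_rng(12)
        errs_td1, errs_td2, errs_frac = [], [], []
        for _ in range(20):
            noise = rng.normal(0, 0.004, len(TAUS)) * (1 + 2 * (TAUS < 1e-4))
            curve = CorrelationCurve(TAUS, eval_model(truth, TAUS) + noise)
            p = fit_tacc(curve, "2comp+triplet").params
            errs_td1.append(abs(p.tau_d1 - truth.tau_d1) / truth.tau_d1)
            errs_td2.append(abs(p.tau_d2 - truth.tau_d2) / truth.tau_d2)
            errs_frac.append(abs((1 - p.y) - (1 - truth.y)))
        assert np.median(errs_td1) <= 0.15
        assert np.median(errs_td2) <= 0.15
        assert np.median(errs_frac) <= 0.05


def _mock_fit(n1, n2):
    n = n1 + n2
    y = n1 / n
    params = FcsModelParams(
        n=n, y=y, tau_d1=5e-4, tau_d2=5e-2, model_tag="2comp"
    )
    return FcsFitResult(params=params, stderr={}, reduced_chi2=1.0)


class TestSlowFastRegression:
    def test_exact_line_slope(self):
        """Cells on an exact N2 = 0.42 N1 line give that slope, zero error."""
        n1 = np.array([0.5, 1.0, 2.0, 3.5, 5.0])
        fits = [_mock_fit(a, 0.42 * a) for a in n1]
        slope, stderr = slow_fast_regression(fits)
        assert slope == pytest.approx(0.42, rel=1e-9)
        assert stderr == pytest.approx(0.0, abs=1e-9)

    def test_axis_swap_inverts_slope(self):
        n1 = np.array([0.5, 1.0, 2.0, 3.5, 5.0])
        fits = [_mock_fit(a, 0.42 * a) for a in n1]
        swapped = [_mock_fit(0.42 * a, a) for a in n1]
        slope, _ = slow_fast_regression(fits)
        inv_slope, _ = slow_fast_regression(swapped)
        assert inv_slope == pytest.approx(1.0 / slope, rel=1e-9)

    def test_noisy_constant_ratio(self):
        """Per-cell fits at ratio 0.16 + noise regress to within 2 stderr."""
        rng = np.random.default_rng(8)
        n1 = rng.uniform(0.5, 6.0, 25)
        n2 = 0.16 * n1 + rng.normal(0, 0.05, 25)
        n2 = np.abs(n2)
        fits = [_mock_fit(a, b) for a, b in zip(n1, n2)]
        slope, stderr = slow_fast_regression(fits)
        assert abs(slope - 0.16) <= 2 * stderr

    def test_degenerate_abscissa(self):
        fits = [_mock_fit(1.0, v) for v in (0.3, 0.5, 0.7)]
        with pytest.raises(DegenerateRegressionError):
            slow_fast_regression(fits)

    def test_too_few_fits(self):
        with pytest.raises(DegenerateInputError):
            slow_fast_regression([_mock_fit(1, 1), _mock_fit(2, 1)])


def _correlated_channel_traces(rng, dual_fraction, n=2**16, bin_time=1e-5):
    """Two Poisson channels sharing a fraction of a slow stochastic signal.

    Emulates dual-color detection where ``dual_fraction`` of the fluctuating
    species carries both labels; the remainder fluctuates independently per
    channel.
    """

    def smooth(x, m=400):
        k = np.ones(m) / m
        return np.convolve(x, k, mode="same")

    shared = smooth(rng.normal(0, 1, n))
    only_g = smooth(rng.normal(0, 1, n))
    only_r = smooth(rng.normal(0, 1, n))
    scale = 60.0
    base = 4.0
    lam_g = np.clip(
        base + scale * (dual_fraction * shared + (1 - dual_fraction) * only_g), 0.05, None
    )
    lam_r = np.clip(
        base + scale * (dual_fraction * shared + (1 - dual_fraction) * only_r), 0.05, None
    )
    tg = IntensityTrace(rng.poisson(lam_g), bin_time, "green")
    tr = IntensityTrace(rng.poisson(lam_r), bin_time, "red")
    return tg, tr


class TestRcca:
    def test_self_cross_correlation_unity(self):
        rng = np.random.default_rng(21)
        tg, _ = _correlated_channel_traces(rng, 1.0)
        tacc = autocorrelate(tg)
        tccc = crosscorrelate(tg, tg)
        res = rcca(tacc, tacc, tccc)
        assert res.rcca == pytest.approx(1.0, abs=0.02)

    def test_independent_channels_below_nobinding_level(self):
        """Channels with no shared species stay below the no-binding cutoff
        RCCA ~ 0.10."""
        rng = np.random.default_rng(22)
        tg, tr = _correlated_channel_traces(rng, 0.0)
        res = rcca(autocorrelate(tg), autocorrelate(tr), crosscorrelate(tg, tr))
        assert res.rcca <= 0.10

    def test_monotone_in_dual_labeled_fraction(self):
        rng = np.random.default_rng(23)
        values = []
        for frac in (0.0, 0.25, 0.5, 1.0):
            tg, tr = _correlated_channel_traces(rng, frac)
            res = rcca(autocorrelate(tg), autocorrelate(tr), crosscorrelate(tg, tr))
            values.append(res.rcca)
        assert all(b > a for a, b in zip(values, values[1:]))
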