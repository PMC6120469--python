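import numpy as np
import pytest

from nanodomain import (
    CorrelationCurve,
    PalmSimConfig,
    PeakList,
    SaccFit,
    classify_random,
    detected_density,
    domain_params,
    ensemble_analysis,
    fit_complex,
    fit_exponential,
    group_peaks,
    pair_correlation,

)
from nanodomain.exceptions import InsufficientDataError, InvalidRoiError
from nanodomain.pcpalm import MoleculeList, _complex_model
from conftest import pairwise_g_oracle


def make_peaks(x, y, frame, roi=(3.0, 3.0), frame_time=0.1, sigma=16.0):
    n = len(x)
    return PeakList(
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        frame=np.asarray(frame, int),
        photons=np.full(n, 100.0),
        sigma=np.full(n, sigma),
        roi=roi,
        frame_time=frame_time,
    )


def csr_molecules(n, roi=(5.0, 5.0), seed=0):
    rng = np.random.default_rng(seed)
    w, h = roi[0] * 1000, roi[1] * 1000
    return MoleculeList(
        x=rng.uniform(0, w, n),
        y=rng.uniform(0, h, n),
        appearances=np.ones(n, int),
        first_frame=np.zeros(n, int),
        last_frame=np.zeros(n, int),
        roi=roi,
    )


class TestGroupPeaks:
    def test_nearby_consecutive_peaks_merge(self):
        peaks = make_peaks([1000, 1005], [1000, 1000], [0, 1])
        mols = group_peaks(peaks)
        assert len(mols) == 1
        assert mols.appearances[0] == 2

    def test_distant_peaks_stay_separate(self):
        peaks = make_peaks([500, 1500], [500, 500], [0, 1])
        assert len(group_peaks(peaks)) == 2

    def test_dark_time_rule_splits(self):
        """Coincident peaks separated by a 6 s dark gap (> 5 s maximum dark
        time) become two molecules."""
        peaks = make_peaks([1000, 1000], [1000, 1000], [0, 60], frame_time=0.1)
        assert len(group_peaks(peaks, max_dark_time=5.0)) == 2

    def test_centroid_is_precision_weighted(self):
        peaks = PeakList(
            x=np.array([1000.0, 1010.0]),
            y=np.array([1000.0, 1000.0]),
            frame=np.array([0, 1]),
            photons=np.array([400.0, 100.0]),
            sigma=np.array([8.0, 16.0]),  # weights 1/64 vs 1/256 -> 4:1
            roi=(3.0, 3.0),
        )
        mols = group_peaks(peaks)
        assert len(mols) == 1
        assert mols.x[0] == pytest.approx(1002.0)

    def test_empty_input(self):
        peaks = make_peaks([], [], [])
        assert len(group_peaks(peaks)) == 0


class TestDetectedDensity:
    def test_simple_count_over_area(self):
        mols = csr_molecules(100, roi=(np.sqrt(2.0), np.sqrt(2.0)))
        with pytest.warns(UserWarning):
            assert detected_density(mols) == pytest.approx(50.0)

    def test_empty_roi_zero(self):
        mols = csr_molecules(0, roi=(3.0, 3.0))
        assert detected_density(mols) == 0.0

    def test_zero_area_invalid(self):
        mols = csr_molecules(0, roi=(3.0, 3.0))
        object.__setattr__(mols, "roi", (0.0, 3.0))
        with pytest.raises(InvalidRoiError):
            detected_density(mols)


class TestPairCorrelation:
    def test_csr_baseline_flat(self):
        """Complete spatial randomness: mean g over 100-500 nm within 3%."""
        mols = csr_molecules(5000, roi=(5.0, 5.0), seed=1)
        g = pair_correlation(mols)
        sel = (g.lags >= 100) & (g.lags <= 500)
        assert 0.97 <= np.mean(g.values[sel]) <= 1.03

    def test_matches_pairwise_oracle(self):
        """Spectral estimator equals the O(N^2) pair-histogram oracle."""
        mols = csr_molecules(500, roi=(4.0, 4.0), seed=2)
        g = pair_correlation(mols, bin_nm=10.0, r_max_nm=500.0)
        _, g_direct = pairwise_g_oracle(
            mols.x, mols.y, 4000.0, 4000.0, 10.0, 500.0
        )
        ok = ~np.isnan(g_direct)
        assert np.all(np.abs(g.values[ok] - g_direct[ok]) <= 0.03 * np.maximum(g_direct[ok], 1.0))

    def test_gaussian_cluster_process_amplitude(self):
        """Thomas process short-range excess matches the closed form
        g(r) = 1 + exp(-r^2/4 sigma^2)/(4 pi sigma^2 kappa), averaged over
        realizations (kappa taken as the realized parent intensity)."""
        rng = np.random.default_rng(3)
        mu = 20.0
        sigma_nm = 30.0
        w = h = 5000.0
        curves = []
        kappas = []
        for _ in range(5):
            parents = rng.poisson(2.0 * 25.0)
            px = rng.uniform(0, w, parents)
            py = rng.uniform(0, h, parents)
            counts = rng.poisson(mu, parents)
            x = np.repeat(px, counts) + rng.normal(0, sigma_nm, counts.sum())
            y = np.repeat(py, counts) + rng.normal(0, sigma_nm, counts.sum())
            keep = (x >= 0) & (x <= w) & (y >= 0) & (y <= h)
            mols = MoleculeList(
                x=x[keep], y=y[keep],
                appearances=np.ones(keep.sum(), int),
                first_frame=np.zeros(keep.sum(), int),
                last_frame=np.zeros(keep.sum(), int),
                roi=(5.0, 5.0),
            )
            g = pair_correlation(mols, bin_nm=5.0, r_max_nm=500.0)
            curves.append(g.values)
            kappas.append(parents / (25.0 * 1e6))  # realized, per nm^2
        mean_g = np.mean(curves, axis=0)
        kappa_nm = np.mean(kappas)
        model = 1.0 + np.exp(-g.lags**2 / (4 * sigma_nm**2)) / (
            4 * np.pi * sigma_nm**2 * kappa_nm
        )
        sel = g.lags <= 50.0
        assert np.mean(mean_g[sel]) == pytest.approx(np.mean(model[sel]), rel=0.10)

    def test_too_few_molecules(self):
        with pytest.raises(InsufficientDataError):
            pair_correlation(csr_molecules(20))


RADII = np.arange(2.5, 500, 5.0)


class TestSaccFits:
    def test_exponential_exact_recovery(self):
        curve = CorrelationCurve(RADII, 5.0 * np.exp(-RADII / 90.0) + 1.0, kind="spatial")
        a, xi, r2 = fit_exponential(curve)
        assert a == pytest.approx(5.0, rel=1e-6)
        assert xi == pytest.approx(90.0, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_exponential_on_flat_curve(self):
        rng = np.random.default_rng(5)
        curve = CorrelationCurve(RADII, 1.0 + rng.normal(0, 0.005, len(RADII)), kind="spatial")
        a, _, _ = fit_exponential(curve)
        assert a <= 0.02

    def test_complex_beats_exponential_on_two_scale_curve(self):
        values = _complex_model(RADII, 8.0, 15.0, 0.0, 3.0, 110.0)
        curve = CorrelationCurve(RADII, values, kind="spatial")
        _, _, r2_exp = fit_exponential(curve)
        r2_complex = fit_complex(curve).r_squared
        assert r2_complex > r2_exp

    def test_complex_exact_recovery(self):
        values = _complex_model(RADII, 20.0, 12.0, 0.0, 4.5, 100.0)
        curve = CorrelationCurve(RADII, values, kind="spatial")
        fit = fit_complex(curve)
        assert fit.a1 == pytest.approx(20.0, rel=0.01)
        assert fit.b == pytest.approx(12.0, rel=0.01)
        assert fit.a2 == pytest.approx(4.5, rel=0.01)
        assert fit.xi_d == pytest.approx(100.0, rel=0.01)
        assert fit.peak_max == 0.0
        assert fit.r_squared >= 0.999
        assert fit.domain_is_exponential
        assert fit.domain_radius == pytest.approx(100.0, rel=0.01)

    def test_no_domain_term_when_absent(self):
        """Pure short-range (blinking-like) curve: the long-range amplitude
        stays negligible."""
        values = _complex_model(RADII, 12.0, 20.0, 0.0, 0.0, 100.0)
        curve = CorrelationCurve(RADII, values, kind="spatial")
        fit = fit_complex(curve)
        short_amp = fit.a1 if fit.b < 60 else fit.a2
        long_amp = fit.a2 if fit.b < 60 else fit.a1
        assert long_amp <= 0.05 * short_amp


class TestDomainParams:
    def test_a1_zero_reduces_to_2a2(self):
        fit = SaccFit(a1=0.0, b=15.0, a2=2.6, xi_d=105.0, peak_max=0.0, r_squared=0.99)
        stats = domain_params(fit, 51.0)
        assert stats.psi_domain == pytest.approx(2 * 2.6, rel=1e-9)
        assert stats.radius == 105.0

    def test_identity_psi_n_radius(self):
        """psi * pi * R^2 * rho == N for any fit (Eq. 7-8 consistency)."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            fit = SaccFit(
                a1=rng.uniform(0, 20), b=rng.uniform(5, 120),
                a2=rng.uniform(0.01, 8), xi_d=rng.uniform(20, 200),
                peak_max=rng.uniform(0, 15), r_squared=0.99,
            )
            rho = rng.uniform(20, 80)
            st = domain_params(fit, rho)
            lhs = st.psi_domain * np.pi * st.radius**2 * rho * 1e-6
            rhs = st.n_domain * 1e-0
            assert lhs == pytest.approx(rhs * 1e-0, rel=0.01)

    def test_linear_in_amplitudes(self):
        fit1 = SaccFit(a1=2.0, b=15.0, a2=1.5, xi_d=100.0, peak_max=0.0, r_squared=0.99)
        fit2 = SaccFit(a1=6.0, b=15.0, a2=4.5, xi_d=100.0, peak_max=0.0, r_squared=0.99)
        s1 = domain_params(fit1, 51.0)
        s2 = domain_params(fit2, 51.0)
        assert s2.n_domain == pytest.approx(3 * s1.n_domain, rel=1e-9)
        assert s2.psi_domain == pytest.approx(3 * s1.psi_domain, rel=1e-9)

    def test_printed_identity_check(self):
        """9.4 proteins in a 105 nm domain at 51 /um^2 average density give a
        5.3-fold local enhancement."""
        psi = 9.4 / (np.pi * 0.105**2 * 51.0)
        assert round(psi, 1) == 5.3


class TestClassifyRandom:
    def test_csr_is_random(self):
        mols = csr_molecules(2000, roi=(5.0, 5.0), seed=7)
        g = pair_correlation(mols)
        assert classify_random(g) == "random"

    def test_domain_pattern_is_nonrandom(self):
        res = ensemble_analysis(PalmSimConfig(), n_rois=4, base_seed=50)
        assert classify_random(res.curve) == "nonrandom"

    def test_boundary_classified_random(self):
        """A curve whose mean excess sits exactly at 2 pooled SE, with an
        insignificant domain amplitude, takes the random side of the
        tie-break."""
        n = len(RADII)
        sem = np.full(n, 0.01)
        pooled = np.sqrt(np.sum(sem**2)) / n
        sel = RADII >= 25.0
        values = np.ones(n)
        values[sel] += 2.0 * pooled  # mean excess == 2 * pooled SE exactly
        curve = CorrelationCurve(RADII, values, sem=sem, kind="spatial")
        fit = SaccFit(
            a1=0.0, b=15.0, a2=0.001, xi_d=100.0, peak_max=0.0,
            r_squared=0.99, stderr={"a2": 0.01},
        )
        assert classify_random(curve, fit=fit) == "random"
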