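"""Pair-correlation PALM: from localization peak lists to nanodomain statistics.

A PALM acquisition yields a list of localized peaks (x, y, frame, photons,
precision).  A single fluorophore blinks and is localized several times, so
peaks are first grouped into detected molecules using a spatiotemporal rule:
successive peaks within ``3 * sigma_max`` of a molecule's running centroid
and with dark gaps no longer than the fluorophore's maximum blinking time
belong to the same molecule.

The spatial organization of the grouped molecules is quantified by the
radial distribution function g(r) — the probability, relative to complete
spatial randomness (CSR), of finding a second molecule at distance r from a
reference molecule.  Flat g(r) = 1 means random organization; an excess at
short r reveals clustering.  The estimator bins positions onto a fine grid,
autocorrelates with FFTs, divides by the autocorrelation of the ROI mask
(edge correction) and by the squared mean density, and radially averages.

Complex membrane organization produces a two-length-scale curve fitted with

    g(r) = A1 * exp(-(r - peak_max)^2 / (2 B^2)) + A2 * exp(-r / xi_D) + 1

whose Gaussian term captures short-range structure (residual overcounting,
oligomers; radius B) and whose exponential term captures nanodomains of
radius xi_D.  From the fit, the domain occupancy and the local density
enhancement follow:

    N_domain   ~= rho_avg * 2 pi (A1 B^2 + A2 xi_D^2)
    psi_domain  = N_domain / (pi xi_D^2 rho_avg) = 2 (A1 B^2 + A2 xi_D^2) / xi_D^2
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from lmfit import Parameters, minimize

from .correlate import CorrelationCurve
from .exceptions import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidRoiError,
)

__all__ = [
    "Peak",
    "PeakList",
    "MoleculeList",
    "SaccFit",
    "DomainStats",
    "group_peaks",
    "detected_density",
    "pair_correlation",
    "fit_exponential",
    "fit_complex",
    "domain_params",
    "classify_random",
]

R_SQUARED_ACCEPT = 0.98  # fits below this are flagged, not discarded
DENSITY_AREA_RANGE = (7.0, 18.0)  # um^2, typical analysis-region areas


@dataclass(frozen=True)
class Peak:
    """One localization event (position in nm, origin at ROI lower-left)."""

    x: float
    y: float
    frame: int
    photons: float
    sigma: float


@dataclass(frozen=True)
class PeakList:
    """Columnar localization dataset for one region of interest.

    ``x``/``y`` in nm, ``sigma`` the per-peak localization precision in nm,
    ``roi`` the (width, height) of the region in micrometres.
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    photons: np.ndarray
    sigma: np.ndarray
    roi: tuple[float, float]
    frame_time: float = 0.1
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("x", "y", "photons", "sigma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "frame", np.asarray(self.frame, dtype=int))
        n = len(self.x)
        if not all(len(getattr(self, f)) == n for f in ("y", "frame", "photons", "sigma")):
            raise ValueError("all peak columns must have equal length")
        if n and (np.any(self.photons <= 0) or np.any(self.sigma <= 0)):
            raise ValueError("photons and sigma must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def area_um2(self) -> float:
        return self.roi[0] * self.roi[1]

    def sigma_max(self, percentile: float = 95.0) -> float:
        """Dataset-level localization precision sigma_max.

        The grouping radius is defined from the dataset maximum precision;
        the 95th percentile is used as an outlier-robust maximum.
        """
        if len(self) == 0:
            raise InsufficientDataError("empty peak list")
        return float(np.percentile(self.sigma, percentile))


@dataclass(frozen=True)
class MoleculeList:
    """Detected molecules after peak grouping."""

    x: np.ndarray
    y: np.ndarray
    appearances: np.ndarray
    first_frame: np.ndarray
    last_frame: np.ndarray
    roi: tuple[float, float]
    frame_time: float = 0.1
    grouping: dict = field(default_factory=dict)
    label: str = ""

    def __len__(self) -> int:
        return len(self.x)

    @property
    def area_um2(self) -> float:
        return self.roi[0] * self.roi[1]


def group_peaks(
    peaks: PeakList,
    group_radius_factor: float = 3.0,
    max_dark_time: float = 5.0,
    group_radius_nm: float | None = None,
) -> MoleculeList:
    """Merge blinking appearances of one fluorophore into single molecules.

    Peaks are scanned in frame order.  A peak joins an existing molecule when
    it lies within the group radius (``group_radius_factor * sigma_max``, or
    ``group_radius_nm`` when given explicitly) of the molecule's running
    precision-weighted centroid and the dark gap since that molecule's last
    appearance does not exceed ``max_dark_time`` seconds.  Otherwise it
    founds a new molecule.
    """
    if len(peaks) == 0:
        return MoleculeList(
            np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int),
            np.empty(0, int), peaks.roi, peaks.frame_time,
            {"group_radius_nm": 0.0, "max_dark_time": max_dark_time},
        )
    if peaks.frame_time <= 0:
        raise ValueError("frame_time must be positive")
    radius = (
        group_radius_nm
        if group_radius_nm is not None
        else group_radius_factor * peaks.sigma_max()
    )
    max_dark_frames = max_dark_time / peaks.frame_time
    order = np.argsort(peaks.frame, kind="stable")
    px, py = peaks.x[order], peaks.y[order]
    pf = peaks.frame[order]
    pw = 1.0 / peaks.sigma[order] ** 2  # precision weights

    # molecule state, grown as python lists (datasets are a few 1e3 peaks)
    mx: list[float] = []   # weighted centroid x
    my: list[float] = []
    mw: list[float] = []   # accumulated weight
    mcount: list[int] = []
    mfirst: list[int] = []
    mlast: list[int] = []
    active: list[int] = []  # indices of molecules still within the dark window

    for i in range(len(px)):
        f = pf[i]
        # retire molecules whose dark gap already exceeds the window
        active = [j for j in active if f - mlast[j] <= max_dark_frames]
        best, best_d2 = -1, radius * radius
        for j in active:
            dx = px[i] - mx[j]
            dy = py[i] - my[j]
            d2 = dx * dx + dy * dy
            if d2 <= best_d2:
                best, best_d2 = j, d2
        if best >= 0:
            w = mw[best] + pw[i]
            mx[best] = (mx[best] * mw[best] + px[i] * pw[i]) / w
            my[best] = (my[best] * mw[best] + py[i] * pw[i]) / w
            mw[best] = w
            mcount[best] += 1
            mlast[best] = f
        else:
            mx.append(px[i])
            my.append(py[i])
            mw.append(pw[i])
            mcount.append(1)
            mfirst.append(f)
            mlast.append(f)
            active.append(len(mx) - 1)

    return MoleculeList(
        np.array(mx), np.array(my), np.array(mcount, int),
        np.array(mfirst, int), np.array(mlast, int),
        peaks.roi, peaks.frame_time,
        {"group_radius_nm": radius, "max_dark_time": max_dark_time},
        label=peaks.label,
    )


def detected_density(mols: MoleculeList) -> float:
    """Detected-molecule surface density in molecules per um^2."""
    area = mols.area_um2
    if area <= 0:
        raise InvalidRoiError("ROI area must be positive")
    if not DENSITY_AREA_RANGE[0] <= area <= DENSITY_AREA_RANGE[1]:
        warnings.warn(
            f"ROI area {area:.1f} um^2 outside the typical "
            f"{DENSITY_AREA_RANGE} um^2 analysis range",
            stacklevel=2,
        )
    return len(mols) / area


def pair_correlation(
    mols: MoleculeList,
    bin_nm: float = 5.0,
    r_max_nm: float = 500.0,
    min_molecules: int = 50,
) -> CorrelationCurve:
    """Radial distribution function g(r) of detected molecules.

    Positions are binned onto a ``bin_nm`` grid; the 2D pair histogram is
    computed by FFT autocorrelation (zero-padded, no periodic wrap), divided
    by the autocorrelation of the rectangular ROI mask and by the expected
    CSR pair count, and radially averaged into annuli of width ``bin_nm``.
    The self-pairs at zero offset are removed.  For a CSR pattern g(r) ~ 1
    at all r.
    """
    n = len(mols)
    if n < min_molecules:
        raise InsufficientDataError(f"{n} molecules < required {min_molecules}")
    w_nm = mols.roi[0] * 1000.0
    h_nm = mols.roi[1] * 1000.0
    if r_max_nm > min(w_nm, h_nm) / 4:
        raise ValueError("r_max must be at most a quarter of the ROI extent")
    nx = int(round(w_nm / bin_nm))
    ny = int(round(h_nm / bin_nm))
    hist, _, _ = np.histogram2d(
        mols.x, mols.y, bins=(nx, ny), range=((0, w_nm), (0, h_nm))
    )
    # zero-pad to avoid wrap-around; keep offsets up to r_max only
    pad = int(np.ceil(r_max_nm / bin_nm)) + 1
    fx = scipy.fft.next_fast_len(nx + pad)
    fy = scipy.fft.next_fast_len(ny + pad)
    fh = np.fft.rfft2(hist, s=(2 * fx, 2 * fy))
    corr = np.fft.irfft2(np.abs(fh) ** 2, s=(2 * fx, 2 * fy))
    mask = np.ones((nx, ny))
    fm = np.fft.rfft2(mask, s=(2 * fx, 2 * fy))
    mask_corr = np.fft.irfft2(np.abs(fm) ** 2, s=(2 * fx, 2 * fy))
    corr[0, 0] -= n  # remove self-pairs

    # offset grids (cyclic -> signed offsets), radial binning by offset length
    ox = np.fft.fftfreq(2 * fx, d=1.0 / (2 * fx)).round().astype(int)
    oy = np.fft.fftfreq(2 * fy, d=1.0 / (2 * fy)).round().astype(int)
    r_off = np.hypot(ox[:, None], oy[None, :]) * bin_nm
    edges = np.arange(0.0, r_max_nm + bin_nm, bin_nm)
    which = np.digitize(r_off.ravel(), edges) - 1
    nbins = len(edges) - 1
    valid = (which >= 0) & (which < nbins) & (mask_corr.ravel() > 0.5)
    pair_sum = np.bincount(which[valid], weights=corr.ravel()[valid], minlength=nbins)
    mask_sum = np.bincount(which[valid], weights=mask_corr.ravel()[valid], minlength=nbins)
    expected_per_pixelpair = n * (n - 1) / (nx * ny) ** 2
    g = pair_sum / (expected_per_pixelpair * mask_sum)
    # Poisson approximation to the per-bin standard error; pair_sum counts
    # ordered pairs, so the independent count is pair_sum / 2
    sem = np.where(
        pair_sum > 0,
        g / np.sqrt(np.maximum(pair_sum / 2.0, 1.0)),
        1.0 / (expected_per_pixelpair * np.maximum(mask_sum, 1.0)),
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CorrelationCurve(
        centers, g, sem=sem, n_averaged=1, kind="spatial", label=mols.label
    )


@dataclass(frozen=True)
class SaccFit:
    """Gaussian + exponential fit of a spatial autocorrelation curve.

    The two terms are separated by length scale, not by functional form: the
    component with the larger mean decay length carries the long-range
    (domain) correlations and the other the short-range structure.  The mean
    decay length of a component is its normalized radial integral
    (1/A) int_0^inf A f(r) dr — equal to xi_d for the exponential term and
    ~B sqrt(pi/2) for the Gaussian term.
    """

    a1: float
    b: float
    a2: float
    xi_d: float
    peak_max: float
    r_squared: float
    stderr: dict = field(default_factory=dict)

    @property
    def below_paper_quality(self) -> bool:
        """True when R^2 < 0.98, the reported quality floor for accepted fits."""
        return self.r_squared < R_SQUARED_ACCEPT

    @property
    def gaussian_scale(self) -> float:
        """Mean decay length of the Gaussian term (its normalized integral)."""
        from scipy.special import erf

        b = self.b
        pm = self.peak_max
        return float(
            b * np.sqrt(np.pi / 2.0) * (1.0 + erf(pm / (np.sqrt(2.0) * b)))
        )

    @property
    def domain_is_exponential(self) -> bool:
        """True when the exponential term is the long-range (domain) term."""
        if self.a2 <= 1e-12 * max(self.a1, 1.0):
            return False
        if self.a1 <= 1e-12 * max(self.a2, 1.0):
            return True
        return self.xi_d >= self.gaussian_scale

    @property
    def domain_radius(self) -> float:
        """Domain radius: mean decay length of the long-range component."""
        return self.xi_d if self.domain_is_exponential else self.gaussian_scale

    @property
    def domain_amplitude(self) -> float:
        """Zero-lag amplitude of the long-range (domain) component."""
        return self.a2 if self.domain_is_exponential else self.a1

    @property
    def domain_amplitude_stderr(self) -> float | None:
        key = "a2" if self.domain_is_exponential else "a1"
        return self.stderr.get(key)

    @property
    def pair_integral(self) -> float:
        """int (g(r) - 1) 2 pi r dr over the fitted model, in nm^2.

        Evaluates A1 * int exp(-(r-pm)^2/2B^2) 2 pi r dr
        + A2 * int exp(-r/xi) 2 pi r dr with exact radial integrals; for
        peak_max = 0 this reduces to 2 pi (A1 B^2 + A2 xi_d^2).
        """
        from scipy.special import erf

        b, pm = self.b, self.peak_max
        i_gauss = b * b * np.exp(-(pm * pm) / (2 * b * b)) + pm * b * np.sqrt(
            np.pi / 2.0
        ) * (1.0 + erf(pm / (np.sqrt(2.0) * b)))
        return float(2.0 * np.pi * (self.a1 * i_gauss + self.a2 * self.xi_d**2))


@dataclass(frozen=True)
class DomainStats:
    """Derived nanodomain statistics for one dataset."""

    radius: float        # xi_D, nm
    n_domain: float      # detected proteins per domain
    psi_domain: float    # in-domain density / average density
    rho_avg: float       # detected molecules per um^2
    rho_domain: float    # psi * rho_avg, per um^2


def _r_squared(data: np.ndarray, model: np.ndarray) -> float:
    ss_res = float(np.sum((data - model) ** 2))
    ss_tot = float(np.sum((data - np.mean(data)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_exponential(sacc: CorrelationCurve) -> tuple[float, float, float]:
    """Fit the single-length-scale model g(r) = A exp(-r/xi) + 1.

    Appropriate for randomly distributed oligomers; complex organization
    (domains plus short-range structure) is poorly described by it, which is
    detected by a lower R^2 than the Gaussian + exponential model.
    Returns (amplitude, correlation length, r_squared).
    """
    if len(sacc.lags) < 20:
        raise InsufficientDataError("need >= 20 radial bins")
    r = sacc.lags
    data = sacc.values
    pars = Parameters()
    amp0 = max(float(data[0] - 1.0), 1e-3)
    pars.add("a", value=amp0, min=0.0)
    pars.add("xi", value=float(r[len(r) // 4]), min=1e-3, max=float(r[-1] * 10))

    def residual(p):
        return p["a"].value * np.exp(-r / p["xi"].value) + 1.0 - data

    out = minimize(residual, pars, method="leastsq")
    if not out.success:
        raise FitFailureError(f"exponential fit failed: {out.message}")
    a = float(out.params["a"].value)
    xi = float(out.params["xi"].value)
    model = a * np.exp(-r / xi) + 1.0
    return a, xi, _r_squared(data, model)


def _complex_model(r, a1, b, peak_max, a2, xi_d):
    return (
        a1 * np.exp(-((r - peak_max) ** 2) / (2.0 * b * b))
        + a2 * np.exp(-r / xi_d)
        + 1.0
    )


def fit_complex(
    sacc: CorrelationCurve,
    peak_max_grid: np.ndarray | None = None,
) -> SaccFit:
    """Fit the two-length-scale model of complex membrane organization.

    ``peak_max`` (the abscissa of the short-range Gaussian maximum) is
    profiled over a grid — by default 0 to 3 grid bins in 1 nm steps — and
    the value minimizing the residual sum of squares is kept, mirroring the
    iterative optimization of the peak position.  Fits with R^2 below 0.98
    are flagged ``below_paper_quality`` but still returned.
    """
    if len(sacc.lags) < 20:
        raise InsufficientDataError("need >= 20 radial bins")
    r = sacc.lags
    data = sacc.values
    if r[-1] < 400.0:
        raise InsufficientDataError("radial range must extend to >= 400 nm")
    bin_nm = float(np.median(np.diff(r)))
    if peak_max_grid is None:
        peak_max_grid = np.arange(0.0, 3.0 * bin_nm + 0.5, 1.0)

    # multistart: the RSS surface has two basins (Gaussian carries the
    # domain core, or the exponential does); start from both assignments
    amp0 = max(float(data[0] - 1.0), 0.1)
    starts = [
        # blinking-scale Gaussian + domain-scale exponential
        {"a1": amp0, "b": 20.0, "a2": max(amp0 / 2, 0.05), "xi_d": 100.0},
        # domain-scale Gaussian + short-range exponential
        {"a1": amp0, "b": 80.0, "a2": max(amp0 / 4, 0.05), "xi_d": 20.0},
        {"a1": amp0 / 2, "b": 40.0, "a2": amp0 / 2, "xi_d": 150.0},
    ]
    best = None
    for peak_max in peak_max_grid:
        for start in starts:
            pars = Parameters()
            pars.add("a1", value=start["a1"], min=0.0)
            pars.add("b", value=start["b"], min=1.0, max=float(r[-1]))
            pars.add("a2", value=start["a2"], min=0.0)
            pars.add("xi_d", value=start["xi_d"], min=1.0, max=float(r[-1] * 4))

            def residual(p, peak_max=peak_max):
                return (
                    _complex_model(
                        r, p["a1"].value, p["b"].value, peak_max,
                        p["a2"].value, p["xi_d"].value,
                    )
                    - data
                )

            try:
                out = minimize(residual, pars, method="leastsq")
            except Exception:  # pragma: no cover - lmfit internal failure
                continue
            if not out.success:
                continue
            rss = float(np.sum(out.residual**2))
            if best is None or rss < best[0] * (1.0 - 1e-9):
                best = (rss, peak_max, out)
    if best is None:
        raise FitFailureError("complex model fit did not converge on any grid point")
    rss, peak_max, out = best
    p = out.params
    model = _complex_model(
        r, p["a1"].value, p["b"].value, peak_max, p["a2"].value, p["xi_d"].value
    )
    fit = SaccFit(
        a1=float(p["a1"].value),
        b=float(p["b"].value),
        a2=float(p["a2"].value),
        xi_d=float(p["xi_d"].value),
        peak_max=float(peak_max),
        r_squared=_r_squared(data, model),
        stderr={k: p[k].stderr for k in p},
    )
    if fit.below_paper_quality:
        warnings.warn(
            f"complex fit R^2 = {fit.r_squared:.3f} below the 0.98 quality floor",
            stacklevel=2,
        )
    return fit


def domain_params(fit: SaccFit, rho_avg: float) -> DomainStats:
    """Nanodomain radius, occupancy and density enhancement from a fit.

    ``rho_avg`` is the average detected density in molecules/um^2 (converted
    to nm^-2 internally for the occupancy integral).
    """
    if fit.xi_d <= 0:
        raise DegenerateInputError("degenerate fit: xi_d must be positive")
    if rho_avg <= 0:
        raise ValueError("rho_avg must be positive")
    radius = fit.domain_radius
    rho_nm = rho_avg * 1e-6  # molecules / nm^2
    n_domain = rho_nm * fit.pair_integral
    psi = fit.pair_integral / (np.pi * radius**2)
    return DomainStats(
        radius=radius,
        n_domain=float(n_domain),
        psi_domain=float(psi),
        rho_avg=rho_avg,
        rho_domain=float(psi * rho_avg),
    )


def classify_random(
    sacc: CorrelationCurve,
    r_min_nm: float = 25.0,
    fit: SaccFit | None = None,
) -> str:
    """Classify a region as "random" or "nonrandom" organization.

    Random when (a) the mean of g(r) - 1 over r in [r_min, r_max] lies within
    2 pooled standard errors of 0, and (b) the complex fit's domain-component
    amplitude is not significantly positive (> 2 its standard error).  A
    region sitting exactly on either boundary is called random.
    """
    sel = sacc.lags >= r_min_nm
    excess = sacc.values[sel] - sacc.baseline
    mean_excess = float(np.mean(excess))
    if sacc.sem is not None:
        pooled_se = float(np.sqrt(np.sum(sacc.sem[sel] ** 2)) / np.sum(sel))
    else:
        pooled_se = float(np.std(excess, ddof=1) / np.sqrt(np.sum(sel)))
    flat = abs(mean_excess) <= 2.0 * pooled_se
    if fit is None:
        try:
            fit = fit_complex(sacc)
        except (FitFailureError, InsufficientDataError):
            return "random" if flat else "nonrandom"
    amp_err = fit.domain_amplitude_stderr or 0.0
    amp_significant = amp_err > 0 and fit.domain_amplitude > 2.0 * amp_err
    return "random" if (flat and not amp_significant) else "nonrandom"
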