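"""FCS model functions and nonlinear fits for 2D membrane diffusion.

The workhorse model is free two-dimensional diffusion of two components with
intersystem crossing (triplet blinking):

    G(tau) = 1 + (1/N) * [ y/(1 + tau/tau_d1) + (1-y)/(1 + tau/tau_d2) ]
                 * [ 1 + T/(1-T) * exp(-tau/tau_t) ]

where N is the mean number of molecules in the observation volume element
(OVE), y the fraction of molecules with the short diffusion time tau_d1,
(1-y) the slow fraction with tau_d2, and T / tau_t the triplet equilibrium
fraction and correlation time.  Reduced variants (single component, no
triplet) are obtained by fixing y = 1 and/or T = 0.

Component numbers follow from the amplitude partition: N1 = y*N molecules
diffuse fast, N2 = (1-y)*N slow; across cells N2 scales linearly with N1 and
the regression slope estimates (1-y)/y for the population.

Dual-color cross-correlation (FCCS) quantifies co-diffusion through the
relative cross-correlation amplitude RCCA = A_CC / A_AC,green; for a fixed
number of labeled molecules the cross-amplitude grows with the number of
dual-labeled complexes N_gr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .correlate import CorrelationCurve
from .exceptions import (
    DegenerateInputError,
    DegenerateRegressionError,
    FitFailureError,
)

__all__ = [
    "FcsModelParams",
    "FcsFitResult",
    "RccaResult",
    "MODEL_TAGS",
    "eval_model",
    "fit_tacc",
    "rcca",
    "slow_fast_regression",
]

MODEL_TAGS = ("1comp", "1comp+triplet", "2comp", "2comp+triplet")

# fit bounds: the diffusion-time windows seen across cells, widened one octave
TAU_D1_BOUNDS = (50e-6, 5e-3)
TAU_D2_BOUNDS = (5e-3, 500e-3)
TAU_T_BOUNDS = (1e-6, 50e-6)
T_MAX = 0.5
TRIPLET_WARN_LEVEL = 0.2  # measurements kept triplet occupancy below 20%


@dataclass(frozen=True)
class FcsModelParams:
    """Parameters of the 2D diffusion + triplet model."""

    n: float
    tau_d1: float
    y: float = 1.0
    tau_d2: float = 1.0
    t_trip: float = 0.0
    tau_t: float = 5e-6
    model_tag: str = "2comp+triplet"

    def __post_init__(self) -> None:
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        if self.n <= 0:
            raise ValueError("N must be positive")
        if not 0.0 <= self.y <= 1.0:
            raise ValueError("y must lie in [0, 1]")
        if not 0.0 <= self.t_trip < 1.0:
            raise ValueError("T must lie in [0, 1)")
        if self.tau_d1 <= 0 or self.tau_d2 <= 0 or self.tau_t <= 0:
            raise ValueError("all characteristic times must be positive")
        if self.model_tag.startswith("2comp") and not self.tau_d1 < self.tau_d2:
            raise ValueError("two-component model requires tau_d1 < tau_d2")


@dataclass(frozen=True)
class FcsFitResult:
    """Weighted least-squares fit of a temporal autocorrelation curve."""

    params: FcsModelParams
    stderr: dict[str, float | None]
    reduced_chi2: float
    triplet_warning: bool = False

    @property
    def n1(self) -> float:
        """Number of fast-diffusing molecules in the OVE, y*N."""
        return self.params.y * self.params.n

    @property
    def n2(self) -> float:
        """Number of slow-diffusing molecules in the OVE, (1-y)*N."""
        return (1.0 - self.params.y) * self.params.n

    @property
    def amplitude(self) -> float:
        """Diffusion amplitude G(0) - 1 with the triplet factor excluded."""
        return 1.0 / self.params.n


@dataclass(frozen=True)
class RccaResult:
    """Relative cross-correlation amplitude and implied molecule numbers."""

    a_cc: float
    a_ac_green: float
    a_ac_red: float
    rcca: float
    n_g: float
    n_r: float
    n_gr: float


def eval_model(params: FcsModelParams, tau: float | np.ndarray) -> np.ndarray:
    """Evaluate G(tau) for the selected model variant.

    The two-component + triplet form reproduces the full model; reduced tags
    drop the slow component (y = 1) and/or the triplet factor (T = 0).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag times must be non-negative")
    p = params
    if p.model_tag.startswith("1comp"):
        diff = 1.0 / (1.0 + tau / p.tau_d1)
    else:
        diff = p.y / (1.0 + tau / p.tau_d1) + (1.0 - p.y) / (1.0 + tau / p.tau_d2)
    if p.model_tag.endswith("+triplet") and p.t_trip > 0:
        trip = 1.0 + p.t_trip / (1.0 - p.t_trip) * np.exp(-tau / p.tau_t)
    else:
        trip = 1.0
    return 1.0 + diff * trip / p.n


def _params_from_lmfit(pars, model_tag: str) -> FcsModelParams:
    return FcsModelParams(
        n=pars["n"].value,
        y=pars["y"].value if "y" in pars else 1.0,
        tau_d1=pars["tau_d1"].value,
        tau_d2=pars["tau_d2"].value if "tau_d2" in pars else 1.0,
        t_trip=pars["t_trip"].value if "t_trip" in pars else 0.0,
        tau_t=pars["tau_t"].value if "tau_t" in pars else 5e-6,
        model_tag=model_tag,
    )


def _fit_single_model(
    curve: CorrelationCurve,
    model_tag: str,
    init: FcsModelParams | None,
    weights: np.ndarray | None,
):
    amp0 = curve.values[0] - 1.0
    if amp0 <= 0 and init is None:
        raise DegenerateInputError("non-positive correlation amplitude")
    pars = Parameters()
    two_comp = model_tag.startswith("2comp")
    triplet = model_tag.endswith("+triplet")
    if init is None:
        n0 = 1.0 / max(amp0, 1e-6)
        init = FcsModelParams(
            n=n0,
            y=0.5 if two_comp else 1.0,
            tau_d1=5e-4,
            tau_d2=50e-3,
            t_trip=0.1 if triplet else 0.0,
            tau_t=5e-6,
            model_tag=model_tag,
        )
    pars.add("n", value=init.n, min=1e-4, max=1e6)
    pars.add("tau_d1", value=init.tau_d1, min=TAU_D1_BOUNDS[0], max=TAU_D1_BOUNDS[1])
    if two_comp:
        pars.add("y", value=init.y, min=0.0, max=1.0)
        pars.add("tau_d2", value=init.tau_d2, min=TAU_D2_BOUNDS[0], max=TAU_D2_BOUNDS[1])
    if triplet:
        pars.add("t_trip", value=max(init.t_trip, 0.01), min=0.0, max=T_MAX - 1e-6)
        pars.add("tau_t", value=init.tau_t, min=TAU_T_BOUNDS[0], max=TAU_T_BOUNDS[1])

    tau = curve.lags
    data = curve.values

    def residual(p):
        model = eval_model(_params_from_lmfit(p, model_tag), tau)
        res = model - data
        return res * weights if weights is not None else res

    out = minimize(residual, pars, method="leastsq")
    if not out.success:
        raise FitFailureError(f"fit of {model_tag} did not converge: {out.message}")
    return out


def fit_tacc(
    curve: CorrelationCurve,
    model_tag: str = "auto",
    init: FcsModelParams | None = None,
    chi2_improvement: float = 0.10,
) -> FcsFitResult:
    """Fit a temporal autocorrelation curve with a diffusion model.

    Weighted nonlinear least squares; inverse-sem weights are used when the
    curve is an average of >= 3 measurements, otherwise the fit is unweighted.
    With ``model_tag="auto"`` both the one- and two-component triplet models
    are fitted and the two-component one is kept only if it lowers the
    reduced chi^2 by more than ``chi2_improvement`` (parsimony: the simplest
    model that accounts for the curve).  A fitted triplet fraction above 20%
    sets ``triplet_warning`` — measurements are expected to stay below that.
    """
    if curve.kind != "temporal-auto":
        raise ValueError("fit_tacc expects a temporal autocorrelation curve")
    if len(curve.lags) < 20:
        raise DegenerateInputError("need >= 20 lag bins to fit the model")
    weights = None
    if curve.sem is not None and curve.n_averaged >= 3:
        floor = np.max(curve.sem) * 1e-3 + 1e-12
        weights = 1.0 / np.clip(curve.sem, floor, None)

    if model_tag == "auto":
        out1 = _fit_single_model(curve, "1comp+triplet", None, weights)
        out2 = _fit_single_model(curve, "2comp+triplet", init, weights)
        if out2.redchi < (1.0 - chi2_improvement) * out1.redchi:
            out, tag = out2, "2comp+triplet"
        else:
            out, tag = out1, "1comp+triplet"
    else:
        if model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model_tag {model_tag!r}")
        out = _fit_single_model(curve, model_tag, init, weights)
        tag = model_tag

    params = _params_from_lmfit(out.params, tag)
    stderr = {name: out.params[name].stderr for name in out.params}
    warn = params.t_trip >= TRIPLET_WARN_LEVEL
    if warn:
        warnings.warn(
            f"fitted triplet fraction {params.t_trip:.2f} >= {TRIPLET_WARN_LEVEL}",
            stacklevel=2,
        )
    return FcsFitResult(
        params=params,
        stderr=stderr,
        reduced_chi2=float(out.redchi),
        triplet_warning=warn,
    )


def rcca(
    tacc_g: CorrelationCurve,
    tacc_r: CorrelationCurve,
    tccc: CorrelationCurve,
) -> RccaResult:
    """Relative cross-correlation amplitude A_CC / A_AC,green.

    All three curves are fitted with the single-component + triplet model and
    amplitudes are taken as the fitted zero-lag diffusion amplitude 1/N
    (triplet factor excluded), which is robust to shot noise in the first
    bins.  Implied molecule numbers follow from the FCCS amplitude relations:
    N_gr = A_CC/(A_g A_r), N_g = 1/A_g - N_gr, N_r = 1/A_r - N_gr.
    """
    fit_g = fit_tacc(tacc_g, "1comp+triplet")
    fit_r = fit_tacc(tacc_r, "1comp+triplet")
    a_g = fit_g.amplitude
    a_r = fit_r.amplitude
    if a_g <= 0:
        raise DegenerateInputError("green autocorrelation amplitude <= 0")
    # the cross-curve of independent channels fluctuates around 1; fit may
    # push the amplitude to the floor, which is the correct answer (~0)
    try:
        cross = fit_tacc(
            CorrelationCurve(
                tccc.lags, tccc.values, sem=tccc.sem,
                n_averaged=tccc.n_averaged, kind="temporal-auto",
            ),
            "1comp+triplet",
        )
        a_cc = cross.amplitude
    except (DegenerateInputError, FitFailureError):
        a_cc = max(float(np.mean(tccc.values - 1.0)), 0.0)
    n_gr = a_cc / (a_g * a_r)
    n_g = 1.0 / a_g - n_gr
    n_r = 1.0 / a_r - n_gr
    return RccaResult(
        a_cc=a_cc,
        a_ac_green=a_g,
        a_ac_red=a_r,
        rcca=a_cc / a_g,
        n_g=n_g,
        n_r=n_r,
        n_gr=n_gr,
    )


def slow_fast_regression(fits: list[FcsFitResult]) -> tuple[float, float]:
    """OLS slope of N2 (slow) against N1 (fast) across cells, with stderr.

    The slope estimates the population-level ratio of slow to fast receptor
    fractions, (1-y)/y.
    """
    if len(fits) < 3:
        raise DegenerateInputError("need at least 3 fits for the regression")
    n1 = np.array([f.n1 for f in fits])
    n2 = np.array([f.n2 for f in fits])
    if np.ptp(n1) == 0:
        raise DegenerateRegressionError("all N1 values identical")
    res = stats.linregress(n1, n2)
    return float(res.slope), float(res.stderr)
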