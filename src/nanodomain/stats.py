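"""Acceptance statistics and colocalization metrics.

Curve-versus-curve agreement is judged with a one-sided variance-ratio
F-test at the 5% level (null: equal variances), the convention under which
the critical value at 281/281 degrees of freedom is 1.2172.  Fit quality is
summarized by the standard error of the estimate,
S = sqrt(sum(residual^2) / (n - p)).  Pixel-intensity colocalization counts
the pixels exceeding a relative cutoff (default 10% of each channel's
maximum) in both channels simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .correlate import CorrelationCurve
from .exceptions import DegenerateInputError, InsufficientDataError

__all__ = [
    "VarianceTestResult",
    "ColocResult",
    "f_test_variance",
    "s_value",
    "paired_t",
    "pixel_colocalization",
]

# free parameters of the complex spatial model: A1, A2, B, xi_D, peak_max
COMPLEX_MODEL_N_PARAMS = 5


@dataclass(frozen=True)
class VarianceTestResult:
    """One-sided variance-ratio test between two residual populations."""

    f_stat: float
    df1: int
    df2: int
    f_critical: float
    p_value: float

    @property
    def equal_variances(self) -> bool:
        """Null hypothesis (variances equal within 5%) accepted."""
        return self.f_stat <= self.f_critical


@dataclass(frozen=True)
class ColocResult:
    """Fraction of pixels above the relative cutoff in both channels."""

    cutoff_fraction: float
    percent_upper_right: float


def _as_samples(obj) -> np.ndarray:
    if isinstance(obj, CorrelationCurve):
        return obj.values - obj.baseline
    return np.asarray(obj, dtype=float)


def f_test_variance(curve_a, curve_b) -> VarianceTestResult:
    """Two-sample variance-ratio F-test, larger variance in the numerator.

    Inputs are correlation curves (their values above baseline are the
    samples — pass residual curves for an observed-versus-fit comparison) or
    plain arrays.  The critical value is the one-sided 95th percentile of
    the F distribution at (n_a - 1, n_b - 1) degrees of freedom; the test is
    symmetric under swapping the inputs.
    """
    a = _as_samples(curve_a)
    b = _as_samples(curve_b)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need at least 3 observations per sample")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0 or vb == 0:
        if va == vb:
            # identical constant samples: trivially equal variances
            df = len(a) - 1
            return VarianceTestResult(1.0, df, df, float(sps.f.ppf(0.95, df, df)), 1.0)
        raise DegenerateInputError("one sample has zero variance")
    if va >= vb:
        f_stat, df1, df2 = va / vb, len(a) - 1, len(b) - 1
    else:
        f_stat, df1, df2 = vb / va, len(b) - 1, len(a) - 1
    f_crit = float(sps.f.ppf(0.95, df1, df2))
    p = float(sps.f.sf(f_stat, df1, df2))
    return VarianceTestResult(f_stat, df1, df2, f_crit, p)


def s_value(
    observed: CorrelationCurve | np.ndarray,
    fitted: CorrelationCurve | np.ndarray,
    n_params: int = COMPLEX_MODEL_N_PARAMS,
) -> float:
    """Standard error of the estimate, sqrt(sum r^2 / (n - p)).

    ``n_params`` defaults to the five free parameters of the complex
    spatial model.
    """
    obs = observed.values if isinstance(observed, CorrelationCurve) else np.asarray(observed, float)
    fit = fitted.values if isinstance(fitted, CorrelationCurve) else np.asarray(fitted, float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must share the same grid")
    n = len(obs)
    if n <= n_params:
        raise InsufficientDataError(f"n = {n} must exceed n_params = {n_params}")
    return float(np.sqrt(np.sum((obs - fit) ** 2) / (n - n_params)))


def paired_t(sample_a, sample_b) -> tuple[float, float]:
    """Paired two-tailed t-test; returns (t statistic, p value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise InsufficientDataError("need equal-length samples of >= 3")
    diff = a - b
    if float(np.std(diff, ddof=1)) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        raise DegenerateInputError("constant nonzero differences: t is unbounded")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def pixel_colocalization(
    img_g: np.ndarray,
    img_r: np.ndarray,
    cutoff_fraction: float = 0.10,
) -> ColocResult:
    """Percent of pixels above the relative intensity cutoff in both channels.

    The cutoff is ``cutoff_fraction`` of each channel's own maximum, so the
    result is invariant to rescaling either image by a positive constant.
    """
    g = np.asarray(img_g, dtype=float)
    r = np.asarray(img_r, dtype=float)
    if g.shape != r.shape:
        raise ValueError("images must share the same shape")
    if g.size == 0 or g.max() <= 0 or r.max() <= 0:
        raise DegenerateInputError("empty or flat image")
    both = (g > cutoff_fraction * g.max()) & (r > cutoff_fraction * r.max())
    return ColocResult(cutoff_fraction, 100.0 * float(np.mean(both)))
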