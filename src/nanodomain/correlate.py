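"""Temporal auto- and cross-correlation of fluorescence intensity traces.

Fluorescence correlation spectroscopy (FCS) infers concentration and mobility
from spontaneous intensity fluctuations recorded in a small observation
volume.  The primitive here is the normalized correlation function

    G(tau) = <F(t) F(t+tau)> / <F>^2  =  1 + <dF(t) dF(t+tau)> / <F>^2,

estimated on a quasi-logarithmic (multi-tau) lag grid so that a single curve
spans sub-bin-time photophysics (microseconds) out to slow membrane diffusion
(hundreds of milliseconds).  The multi-tau scheme coarsens the trace by
binning pairs of samples once per octave, emulating hardware correlators.

Normalization is symmetric: for each lag the two shifted segments are divided
by their own means, which suppresses bias from slow drifts over a 10 s trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    DegenerateInputError,
    IncompatibleTracesError,
    InsufficientDataError,
    NonNormalizableError,
)

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "MultiTauScheme",
    "autocorrelate",
    "crosscorrelate",
    "normalize_curve",
    "average_curves",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Binned photon counts F(t) from one detection channel.

    Parameters
    ----------
    counts
        Photon counts per bin, non-negative.
    bin_time
        Seconds per bin.
    channel_label
        Free-text channel tag ("green", "red", ...).
    """

    counts: np.ndarray
    bin_time: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.bin_time <= 0:
            raise ValueError("bin_time must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def duration(self) -> float:
        """Total trace length in seconds."""
        return len(self.counts) * self.bin_time

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/s."""
        return float(np.mean(self.counts)) / self.bin_time


@dataclass(frozen=True)
class CorrelationCurve:
    """A correlation curve: temporal G(tau) or spatial g(r).

    ``lags`` is in seconds for temporal curves and nanometres for spatial
    ones.  ``baseline`` is the uncorrelated level: 1.0 for raw curves, 0.0
    after amplitude normalization (which maps G -> (G - 1)/(G(tau_ref) - 1)).
    """

    lags: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    n_averaged: int = 1
    kind: str = "temporal-auto"  # temporal-auto | temporal-cross | spatial
    baseline: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape:
            raise ValueError("lags and values must have the same shape")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("correlation values must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            if sem.shape != lags.shape:
                raise ValueError("sem must match lags in shape")
            if np.any(sem < 0):
                raise ValueError("sem must be non-negative")
            object.__setattr__(self, "sem", sem)

    @property
    def amplitude(self) -> float:
        """Correlation amplitude above baseline at the first lag."""
        return float(self.values[0] - self.baseline)

    def value_at(self, lag: float) -> float:
        """Value at ``lag``, interpolated linearly in log(lag) if between bins."""
        if lag < self.lags[0] or lag > self.lags[-1]:
            raise ValueError(f"lag {lag} outside curve range")
        if self.lags[0] > 0 and lag > 0:
            return float(np.interp(np.log(lag), np.log(self.lags), self.values))
        return float(np.interp(lag, self.lags, self.values))


@dataclass(frozen=True)
class MultiTauScheme:
    """Multi-tau correlator configuration.

    ``lags_per_octave`` linear lags are evaluated per octave; after each
    octave the trace is coarsened by averaging pairs of bins.  The lag grid
    stops at ``duration / max_lag_fraction_inv``.
    """

    lags_per_octave: int = 16
    max_lag_fraction_inv: int = 8

    def lag_plan(self, n_bins: int) -> list[tuple[int, int]]:
        """Return (level, lag_in_level_bins) pairs covering 1 bin .. n/8 bins.

        Level ``l`` works on the trace coarsened ``l`` times (bin width
        ``2**l`` original bins).
        """
        m = self.lags_per_octave
        max_lag_bins = n_bins // self.max_lag_fraction_inv
        plan: list[tuple[int, int]] = []
        level = 0
        # first octave: lags 1..m at full resolution
        lag_values = range(1, m + 1)
        while True:
            added = False
            for k in lag_values:
                if k * 2**level > max_lag_bins:
                    break
                plan.append((level, k))
                added = True
            if not added or (m * 2**level) >= max_lag_bins:
                break
            level += 1
            lag_values = range(m // 2 + 1, m + 1)
        return plan


def _coarsen(x: np.ndarray) -> np.ndarray:
    n = len(x) // 2 * 2
    return 0.5 * (x[0:n:2] + x[1:n:2])


def _correlate_pair(
    a: np.ndarray,
    b: np.ndarray,
    bin_time: float,
    scheme: MultiTauScheme,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric-normalized multi-tau correlation of two equal-length traces."""
    plan = scheme.lag_plan(len(a))
    if not plan:
        raise InsufficientDataError("trace too short for any correlator lag")
    lags = np.empty(len(plan))
    values = np.empty(len(plan))
    level_a, level_b, cur = a, b, 0
    for i, (level, k) in enumerate(plan):
        while cur < level:
            level_a = _coarsen(level_a)
            level_b = _coarsen(level_b)
            cur += 1
        left = level_a[:-k]
        right = level_b[k:]
        denom = left.mean() * right.mean()
        if denom <= 0:
            raise DegenerateInputError("zero-mean segment: correlation undefined")
        lags[i] = k * 2**level * bin_time
        values[i] = float(np.mean(left * right) / denom)
    return lags, values


def _check_trace(trace: IntensityTrace, scheme: MultiTauScheme) -> None:
    if float(np.mean(trace.counts)) <= 0:
        raise DegenerateInputError("all-zero trace: mean intensity is zero")
    # two octaves of usable lags requires n/8 >= 2 * lags_per_octave bins
    if len(trace.counts) < 16 * scheme.lags_per_octave:
        raise InsufficientDataError(
            f"trace of {len(trace.counts)} bins too short for two octaves of lags"
        )


def autocorrelate(
    trace: IntensityTrace, scheme: MultiTauScheme | None = None
) -> CorrelationCurve:
    """Normalized temporal autocorrelation G(tau) of one intensity trace.

    Returns G(tau) = 1 + <dF(t) dF(t+tau)>/<F>^2 on the multi-tau grid from
    one bin time up to duration/8.
    """
    scheme = scheme or MultiTauScheme()
    _check_trace(trace, scheme)
    counts = trace.counts.astype(float)
    lags, values = _correlate_pair(counts, counts, trace.bin_time, scheme)
    return CorrelationCurve(
        lags, values, kind="temporal-auto", label=trace.channel_label
    )


def crosscorrelate(
    trace_g: IntensityTrace,
    trace_r: IntensityTrace,
    scheme: MultiTauScheme | None = None,
) -> CorrelationCurve:
    """Normalized temporal cross-correlation between two detection channels.

    G_CC(tau) = 1 + <dF_g(t) dF_r(t+tau)> / (<F_g><F_r>).  Co-diffusing
    dual-labeled molecules produce G_CC > 1; independent channels give
    G_CC(tau) ~ 1 at all lags.
    """
    scheme = scheme or MultiTauScheme()
    if len(trace_g.counts) != len(trace_r.counts) or not np.isclose(
        trace_g.bin_time, trace_r.bin_time
    ):
        raise IncompatibleTracesError("traces must share bin_time and duration")
    _check_trace(trace_g, scheme)
    _check_trace(trace_r, scheme)
    lags, values = _correlate_pair(
        trace_g.counts.astype(float),
        trace_r.counts.astype(float),
        trace_g.bin_time,
        scheme,
    )
    label = f"{trace_g.channel_label}x{trace_r.channel_label}"
    return CorrelationCurve(lags, values, kind="temporal-cross", label=label)


def normalize_curve(curve: CorrelationCurve, tau_ref: float = 10e-6) -> CorrelationCurve:
    """Normalize a curve to unit amplitude at the reference lag.

    Maps values to (G - baseline)/(G(tau_ref) - baseline) so the value at
    ``tau_ref`` is 1 and the long-lag baseline is 0.  tau_ref falling between
    lag bins is interpolated linearly in log(lag).  Already-normalized curves
    (baseline 0) are returned unchanged, making the operation idempotent.
    """
    if curve.baseline == 0.0:
        return curve
    ref = curve.value_at(tau_ref) - curve.baseline
    if ref <= 0:
        raise NonNormalizableError(
            f"G(tau_ref={tau_ref}) does not exceed the baseline"
        )
    values = (curve.values - curve.baseline) / ref
    sem = None if curve.sem is None else curve.sem / ref
    return replace(curve, values=values, sem=sem, baseline=0.0)


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Per-lag mean of curves on a shared grid, with outlier screening.

    Curves whose first-lag amplitude deviates more than 3 robust standard
    deviations (median +/- 1.4826 MAD) from the set median are excluded, a
    reproducible proxy for discarding the occasional "obviously different"
    first measurement of a series.  Requires at least 2 surviving curves.
    """
    if not curves:
        raise InsufficientDataError("no curves to average")
    lags0 = curves[0].lags
    kind0 = curves[0].kind
    base0 = curves[0].baseline
    for c in curves[1:]:
        if c.kind != kind0 or c.baseline != base0 or not np.allclose(c.lags, lags0):
            raise IncompatibleTracesError(
                "curves must share lag grid, kind and baseline"
            )
    amps = np.array([c.amplitude for c in curves])
    med = np.median(amps)
    mad = np.median(np.abs(amps - med))
    robust_sd = 1.4826 * mad
    if robust_sd > 0:
        keep = np.abs(amps - med) <= 3 * robust_sd
    else:
        keep = amps == med
    kept = [c for c, k in zip(curves, keep) if k]
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 curves after outlier exclusion")
    stack = np.stack([c.values for c in kept])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(kept))
    return CorrelationCurve(
        lags0,
        mean,
        sem=sem,
        n_averaged=len(kept),
        kind=kind0,
        baseline=base0,
        label=curves[0].label,
    )
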