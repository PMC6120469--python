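import numpy as np
import pytest

from nanodomain import IntensityTrace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def poisson_trace():
    """IID Poisson photon-count trace: no correlations beyond shot noise."""
    counts = np.random.default_rng(42).poisson(5.0, size=4096)
    return IntensityTrace(counts=counts, bin_time=1e-6)


def direct_correlator(a, b, lags_bins, bin_time):
    """Brute-force symmetric-normalized correlator at explicit integer lags.

    Independent oracle for the multi-tau scheme: no coarsening, every lag
    evaluated on the full-resolution trace.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lags = []
    values = []
    for k in lags_bins:
        left, right = a[:-k], b[k:]
        lags.append(k * bin_time)
        values.append(np.mean(left * right) / (left.mean() * right.mean()))
    return np.array(lags), np.array(values)


def pairwise_g_oracle(x, y, w_nm, h_nm, bin_nm, r_max_nm):
    """O(N^2) translation-corrected pair-correlation estimator on a grid.

    Bins positions onto the same grid as the spectral estimator, then
    accumulates the pair histogram over all ordered pairs of occupied cells
    directly; normalization matches the spectral path (CSR expectation with
    the rectangular-mask pair counts).
    """
    nx = int(round(w_nm / bin_nm))
    ny = int(round(h_nm / bin_nm))
    hist, _, _ = np.histogram2d(x, y, bins=(nx, ny), range=((0, w_nm), (0, h_nm)))
    ii, jj = np.nonzero(hist)
    wts = hist[ii, jj]
    n = wts.sum()
    edges = np.arange(0.0, r_max_nm + bin_nm, bin_nm)
    nbins = len(edges) - 1
    pair_sum = np.zeros(nbins)
    mask_sum = np.zeros(nbins)
    # pair histogram over occupied cells (self-pairs removed at zero offset)
    for a in range(len(ii)):
        dx = (ii - ii[a]) * bin_nm
        dy = (jj - jj[a]) * bin_nm
        r = np.hypot(dx, dy)
        which = np.digitize(r, edges) - 1
        ok = (which >= 0) & (which < nbins)
        contrib = wts[a] * wts
        np.add.at(pair_sum, which[ok], contrib[ok])
    self_bin = np.digitize(0.0, edges) - 1
    pair_sum[self_bin] -= n  # remove self-pairs
    # mask pair counts per radial bin, brute force over all offsets
    max_off = int(np.ceil(r_max_nm / bin_nm)) + 1
    for dx in range(-max_off, max_off + 1):
        for dy in range(-max_off, max_off + 1):
            r = np.hypot(dx, dy) * bin_nm
            which = int(np.digitize(r, edges)) - 1
            if 0 <= which < nbins:
                mask_sum[which] += max(nx - abs(dx), 0) * max(ny - abs(dy), 0)
    expected = n * (n - 1) / (nx * ny) ** 2
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, pair_sum / (expected * mask_sum)
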