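"""Synthetic-data engines matched to the analysis pipeline.

Two generators are provided:

* :func:`simulate_palm` — ensemble Monte-Carlo of PALM peak lists.  True
  molecules are organized into circular nanodomains (domain centers
  homogeneous Poisson, per-domain occupancy Poisson, positions uniform in a
  disc) with a configurable fraction of free monomers, then convolved with
  the instrument response: a geometric number of blinking appearances per
  fluorophore, lognormal photon counts, localization precision
  sigma = s_psf / sqrt(photons), and isotropic Gaussian localization noise.
  Domain centers are laid down on the ROI dilated by one domain radius so
  the restriction to the ROI window is a stationary process (no edge
  density deficit).

* :func:`simulate_fcs_trace` — 2D Brownian dynamics of a two-component
  mixture in a periodic box with a Gaussian detection profile
  W(r) = exp(-2 r^2 / omega_xy^2) centered in the box, triplet blinking as
  an exact two-state telegraph process, and Poisson photon counts.  The
  diffusion time recovered by FCS obeys tau_D = omega_xy^2 / (4 D).

Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np

from .correlate import CorrelationCurve, IntensityTrace
from .exceptions import InvalidConfigError
from .pcpalm import MoleculeList, PeakList, detected_density, group_peaks, pair_correlation

__all__ = [
    "PalmSimConfig",
    "FcsSimConfig",
    "EnsembleResult",
    "simulate_palm",
    "ensemble_sacc",
    "ensemble_analysis",
    "simulate_fcs_trace",
]


@dataclass(frozen=True)
class PalmSimConfig:
    """Nanodomain PALM simulation settings.

    Defaults emulate the KOP-like condition: domains of ~100 nm radius
    holding ~9-10 detected proteins at ~51 detected molecules/um^2 with 10%
    free monomers, ~16 nm median localization precision, 100 ms frames and a
    20,000-frame acquisition.
    """

    roi: tuple[float, float] = (3.0, 3.0)   # um
    rho_avg: float = 51.0                   # detected molecules / um^2
    domain_radius: float = 101.0            # nm
    proteins_per_domain: float = 9.5        # Poisson mean occupancy
    free_fraction: float = 0.10
    s_psf: float = 160.0                    # nm PSF width
    photon_median: float = 100.0
    photon_shape: float = 0.5               # lognormal sigma
    mean_appearances: float = 4.0
    mean_dark_gap: float = 0.5              # s, exponential blink gap scale
    frame_time: float = 0.1                 # s
    n_frames: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        area = self.roi[0] * self.roi[1]
        if area <= 0 or self.rho_avg <= 0:
            raise InvalidConfigError("ROI area and density must be positive")
        if not 0.0 <= self.free_fraction <= 1.0:
            raise InvalidConfigError("free_fraction must lie in [0, 1]")
        if self.free_fraction < 1.0:
            n_domains = (
                self.rho_avg * (1 - self.free_fraction) * area / self.proteins_per_domain
            )
            if n_domains < 1:
                raise InvalidConfigError("configuration implies < 1 domain in the ROI")
            domain_area_nm2 = np.pi * self.domain_radius**2
            psi = self.proteins_per_domain / (domain_area_nm2 * 1e-6 * self.rho_avg)
            if psi < 1:
                raise InvalidConfigError(
                    f"implied in-domain enhancement psi = {psi:.2f} < 1"
                )

    @property
    def area_um2(self) -> float:
        return self.roi[0] * self.roi[1]


def _draw_appearance_frames(
    rng: np.random.Generator, n_mol: int, counts: np.ndarray, cfg: PalmSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Burst frame indices per molecule: uniform start, exponential dark gaps.

    Gaps are truncated at the grouping dark time (5 s) so one fluorophore is
    never split by the temporal rule; returns (molecule_index, frame).
    """
    max_gap_frames = max(int(5.0 / cfg.frame_time), 1)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    mol_idx = np.repeat(np.arange(n_mol), counts)
    starts = rng.integers(0, cfg.n_frames, size=n_mol)
    gaps_s = rng.exponential(cfg.mean_dark_gap, size=total)
    gap_frames = 1 + np.minimum(
        (gaps_s / cfg.frame_time).astype(int), max_gap_frames - 1
    )
    # first appearance of each molecule sits at its start frame
    first_of_mol = np.zeros(total, dtype=bool)
    first_of_mol[np.cumsum(counts)[:-1]] = True
    first_of_mol[0] = True
    gap_frames[first_of_mol] = 0
    frames = starts[mol_idx] + np.concatenate(
        [np.cumsum(g) for g in np.split(gap_frames, np.cumsum(counts)[:-1])]
    )
    keep = frames < cfg.n_frames
    return mol_idx[keep], frames[keep]


def simulate_palm(cfg: PalmSimConfig, return_truth: bool = False):
    """Monte-Carlo PALM peak list with nanodomain organization.

    Returns the localized peaks (one row per appearance) for one ROI;
    deterministic for a fixed ``cfg.seed``.  With ``return_truth`` a dict of
    ground-truth molecule positions, free flags and domain indices is
    returned alongside, for validating recovery pipelines.
    """
    rng = np.random.default_rng(cfg.seed)
    w_nm, h_nm = cfg.roi[0] * 1000.0, cfg.roi[1] * 1000.0
    r_nm = cfg.domain_radius

    # --- true molecule positions -----------------------------------------
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    dom_ids: list[np.ndarray] = []
    if cfg.free_fraction < 1.0:
        lam_domains = (
            cfg.rho_avg * (1 - cfg.free_fraction) / cfg.proteins_per_domain
        )  # per um^2
        # dilated window keeps the restriction to the ROI stationary
        dil_area = ((w_nm + 2 * r_nm) * (h_nm + 2 * r_nm)) * 1e-6
        n_dom = rng.poisson(lam_domains * dil_area)
        cx = rng.uniform(-r_nm, w_nm + r_nm, n_dom)
        cy = rng.uniform(-r_nm, h_nm + r_nm, n_dom)
        occ = rng.poisson(cfg.proteins_per_domain, n_dom)
        tot = int(occ.sum())
        theta = rng.uniform(0, 2 * np.pi, tot)
        rad = r_nm * np.sqrt(rng.uniform(0, 1, tot))
        xs.append(np.repeat(cx, occ) + rad * np.cos(theta))
        ys.append(np.repeat(cy, occ) + rad * np.sin(theta))
        dom_ids.append(np.repeat(np.arange(n_dom), occ))
    n_free = rng.poisson(cfg.rho_avg * cfg.free_fraction * cfg.area_um2)
    xs.append(rng.uniform(0, w_nm, n_free))
    ys.append(rng.uniform(0, h_nm, n_free))
    dom_ids.append(np.full(n_free, -1))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    domain_of = np.concatenate(dom_ids)
    inside = (x >= 0) & (x <= w_nm) & (y >= 0) & (y <= h_nm)
    x, y, domain_of = x[inside], y[inside], domain_of[inside]
    n_mol = len(x)

    # --- instrument response ---------------------------------------------
    appearances = rng.geometric(1.0 / cfg.mean_appearances, size=n_mol)
    mol_idx, frames = _draw_appearance_frames(rng, n_mol, appearances, cfg)
    n_peaks = len(mol_idx)
    photons = rng.lognormal(np.log(cfg.photon_median), cfg.photon_shape, n_peaks)
    sigma = cfg.s_psf / np.sqrt(photons)
    px = x[mol_idx] + rng.normal(0, 1, n_peaks) * sigma
    py = y[mol_idx] + rng.normal(0, 1, n_peaks) * sigma
    np.clip(px, 0, w_nm, out=px)
    np.clip(py, 0, h_nm, out=py)

    order = np.argsort(frames, kind="stable")
    peaks = PeakList(
        x=px[order], y=py[order], frame=frames[order],
        photons=photons[order], sigma=sigma[order],
        roi=cfg.roi, frame_time=cfg.frame_time,
        label=f"sim-seed{cfg.seed}",
    )
    if return_truth:
        centers = (
            np.column_stack((cx, cy)) if cfg.free_fraction < 1.0 else np.empty((0, 2))
        )
        truth = {
            "x": x, "y": y, "domain_of": domain_of,
            "is_free": domain_of < 0,
            "domain_centers": centers,
            "peak_molecule": mol_idx[order],
        }
        return peaks, truth
    return peaks


@dataclass(frozen=True)
class EnsembleResult:
    """Ensemble-averaged spatial autocorrelation and per-ROI summaries."""

    curve: CorrelationCurve
    densities: np.ndarray          # grouped detected density per ROI (um^-2)
    molecule_lists: tuple[MoleculeList, ...] = ()

    @property
    def mean_density(self) -> float:
        return float(np.mean(self.densities))


def ensemble_analysis(
    cfg: PalmSimConfig,
    n_rois: int = 40,
    base_seed: int = 0,
    bin_nm: float = 5.0,
    r_max_nm: float = 500.0,
    keep_molecules: bool = False,
) -> EnsembleResult:
    """Simulate ``n_rois`` ROIs and push each through grouping + g(r).

    Each ROI uses seed ``base_seed + i``; the per-bin average curve with SEM
    across ROIs is returned together with the grouped detected densities,
    exactly the ensemble quantities the domain fit consumes.
    """
    if n_rois < 2:
        raise InvalidConfigError("need at least 2 ROIs for an ensemble")
    curves = []
    densities = []
    mols_kept = []
    for i in range(n_rois):
        peaks = simulate_palm(replace(cfg, seed=base_seed + i))
        mols = group_peaks(peaks)
        densities.append(detected_density(mols))
        curves.append(pair_correlation(mols, bin_nm=bin_nm, r_max_nm=r_max_nm))
        if keep_molecules:
            mols_kept.append(mols)
    stack = np.stack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n_rois)
    curve = CorrelationCurve(
        curves[0].lags, mean, sem=sem, n_averaged=n_rois,
        kind="spatial", label=f"ensemble-{cfg.rho_avg:g}um2",
    )
    return EnsembleResult(curve, np.asarray(densities), tuple(mols_kept))


def ensemble_sacc(
    cfg: PalmSimConfig, n_rois: int = 40, base_seed: int = 0
) -> CorrelationCurve:
    """Ensemble-averaged spatial autocorrelation curve (mean with SEM)."""
    return ensemble_analysis(cfg, n_rois=n_rois, base_seed=base_seed).curve


# ---------------------------------------------------------------------------
# FCS trace simulation
# ---------------------------------------------------------------------------


@numba.njit(cache=True, fastmath=True)
def _accumulate_detection(
    intensity, dx, dy, emissive, step, x0, y0, box, two_over_omega2
):  # pragma: no cover - exercised through simulate_fcs_trace
    """Walk one molecule through the periodic box, adding W(r) per bin."""
    half = box / 2.0
    x = x0
    y = y0
    cutoff = 7.5 / two_over_omega2 * 2.0  # W < 1e-13 beyond this r^2
    for t in range(intensity.shape[0]):
        x += step * dx[t]
        y += step * dy[t]
        if x < 0.0:
            x += box
        elif x >= box:
            x -= box
        if y < 0.0:
            y += box
        elif y >= box:
            y -= box
        if emissive[t]:
            ux = x - half
            uy = y - half
            r2 = ux * ux + uy * uy
            if r2 < cutoff:
                intensity[t] += np.exp(-two_over_omega2 * r2)


@dataclass(frozen=True)
class FcsSimConfig:
    """Brownian-dynamics FCS settings.

    Defaults give tau_D1 = omega^2/(4 D_fast) = 0.5 ms and tau_D2 = 50 ms
    with ~1 molecule in the observation area on average (N = c pi omega^2),
    triplet occupancy 15% at 5 us, 2 us bins and 10 s traces.  The box is
    sized so the slowest periodic diffusion mode, (box/2 pi)^2 / D_slow,
    relaxes after the fitted lag window — a smaller box truncates the slow
    component's correlation tail and biases its amplitude downward.
    """

    d_fast: float = 31.25       # um^2/s
    d_slow: float = 0.3125      # um^2/s
    fraction_slow: float = 0.40
    omega_xy: float = 250.0     # nm, 1/e^2 radius of the detection profile
    n_molecules: int = 82
    box: float = 4.0            # um, periodic square box edge
    brightness: float = 30000.0  # counts/s per molecule at beam center
    t_triplet: float = 0.15
    tau_triplet: float = 5e-6   # s
    bin_time: float = 2e-6      # s
    duration: float = 10.0      # s
    seed: int = 0

    def __post_init__(self) -> None:
        omega_um = self.omega_xy / 1000.0
        if self.box < 10 * omega_um:
            raise InvalidConfigError("box edge must be >= 10 omega_xy")
        tau_d1 = omega_um**2 / (4 * self.d_fast)
        if self.bin_time > tau_d1 / 20:
            raise InvalidConfigError(
                f"bin_time {self.bin_time} too coarse for tau_d1 = {tau_d1:.2e}"
            )
        if not 0.0 <= self.t_triplet < 1.0:
            raise InvalidConfigError("t_triplet must lie in [0, 1)")
        if not 0.0 <= self.fraction_slow <= 1.0:
            raise InvalidConfigError("fraction_slow must lie in [0, 1]")

    @property
    def tau_d1(self) -> float:
        return (self.omega_xy / 1000.0) ** 2 / (4 * self.d_fast)

    @property
    def tau_d2(self) -> float:
        return (self.omega_xy / 1000.0) ** 2 / (4 * self.d_slow)


def _telegraph_emissive(
    rng: np.random.Generator, cfg: FcsSimConfig, n_bins: int
) -> np.ndarray:
    """Exact two-state triplet telegraph sampled at bin centers.

    Rates follow from the stationary dark fraction T and relaxation time
    tau_T: bright->dark at T/tau_T, dark->bright at (1-T)/tau_T; dwell times
    are exponential with means tau_T/T (bright) and tau_T/(1-T) (dark).
    """
    T, tau = cfg.t_triplet, cfg.tau_triplet
    if T <= 0:
        return np.ones(n_bins, dtype=bool)
    mean_bright = tau / T
    mean_dark = tau / (1 - T)
    start_bright = rng.random() >= T
    # draw dwell sequences in one batch with a safety margin
    mean_cycle = mean_bright + mean_dark
    n_cycles = int(cfg.duration / mean_cycle * 1.3) + 50
    while True:
        bright = rng.exponential(mean_bright, n_cycles)
        dark = rng.exponential(mean_dark, n_cycles)
        dwells = np.empty(2 * n_cycles)
        if start_bright:
            dwells[0::2], dwells[1::2] = bright, dark
        else:
            dwells[0::2], dwells[1::2] = dark, bright
        t_edges = np.cumsum(dwells)
        if t_edges[-1] >= cfg.duration:
            break
        n_cycles *= 2
    # rasterize alternating dwell segments onto the bin grid via run starts
    edges = np.concatenate(([0.0], t_edges))
    idx = np.minimum((edges / cfg.bin_time).astype(np.int64), n_bins)
    first_bright = 0 if start_bright else 1
    starts = np.bincount(idx[first_bright::2], minlength=n_bins + 1)
    ends = np.bincount(idx[first_bright + 1 :: 2], minlength=n_bins + 1)
    delta = (starts - ends)[:n_bins]
    return np.cumsum(delta, dtype=np.int32) > 0


def simulate_fcs_trace(cfg: FcsSimConfig) -> IntensityTrace:
    """One binned-photon-count trace from 2D Brownian dynamics.

    Each molecule performs Gaussian steps of variance 2 D dt per axis in a
    periodic box with the detection profile centered; expected counts per
    bin are brightness * sum_i W(r_i) * emissive_i * bin_time and realized
    counts are Poisson.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bins = int(round(cfg.duration / cfg.bin_time))
    box = cfg.box
    omega_um = cfg.omega_xy / 1000.0
    n_slow = int(round(cfg.fraction_slow * cfg.n_molecules))
    intensity = np.zeros(n_bins, dtype=np.float32)
    for i in range(cfg.n_molecules):
        d = cfg.d_slow if i < n_slow else cfg.d_fast
        step = float(np.sqrt(2 * d * cfg.bin_time))
        x0, y0 = rng.uniform(0, box, 2)
        dx = rng.standard_normal(n_bins, dtype=np.float32)
        dy = rng.standard_normal(n_bins, dtype=np.float32)
        emissive = _telegraph_emissive(rng, cfg, n_bins)
        _accumulate_detection(
            intensity, dx, dy, emissive, step, float(x0), float(y0),
            float(box), float(2.0 / omega_um**2),
        )
    counts = rng.poisson(intensity.astype(np.float64) * (cfg.brightness * cfg.bin_time))
    return IntensityTrace(counts=counts, bin_time=cfg.bin_time, channel_label="sim")
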