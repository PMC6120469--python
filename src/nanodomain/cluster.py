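"""Two-step clustering: blinking correction then DP-means domain identification.

Step 1 merges multiple appearances of one fluorophore into a single protein
(spatial merge radius + maximum blinking time), removing overcounting.

Step 2 groups proteins into circular nanodomains with DP-means, a k-means
variant that does not require the number of clusters in advance: a point
farther than the domain radius DR from every existing center founds a new
cluster.  DR is taken from the domain radius xi_D obtained by fitting the
spatial autocorrelation of the same dataset.  Clusters with fewer than
3 proteins are dissolved and their members counted as free floaters; the
per-region fraction of free floaters is the readout compared across
receptors.

DP-means is order-dependent, so points are processed in a canonical order
(first frame, then x, then y) to make results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ClusterFailureError, InsufficientDataError, InvalidConfigError
from .pcpalm import MoleculeList, PeakList, group_peaks

__all__ = [
    "ClusterConfig",
    "DomainAssignment",
    "FREE_FLOATER",
    "merge_appearances",
    "dpmeans_domains",
    "fraction_outside_report",
]

FREE_FLOATER = -1

HISTOGRAM_EDGES = (0.0, 0.10, 0.20, 0.30, 1.0)  # fraction-outside bins


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the two-step clustering.

    ``domain_radius`` (DR, nm) comes from the complex sACC fit of the same
    dataset; ``spatial_merge_radius`` quantifies the resolution-limited spot
    for appearance merging; ``max_blink_time`` is the fluorophore's maximum
    dark time in seconds; domains need ``min_proteins`` members to survive.
    """

    domain_radius: float
    spatial_merge_radius: float = 48.0  # nm; ~3 sigma_max at 16 nm precision
    max_blink_time: float = 5.0
    min_proteins: int = 3
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if min(self.domain_radius, self.spatial_merge_radius, self.max_blink_time) <= 0:
            raise InvalidConfigError("all radii and times must be positive")
        if self.domain_radius < self.spatial_merge_radius:
            raise InvalidConfigError(
                "domain radius must be at least the spatial merge radius"
            )


@dataclass(frozen=True)
class DomainAssignment:
    """Protein-to-domain labels for one region of interest.

    ``counted`` marks the proteins used for the fraction-outside readout:
    all proteins by default, or only those an edge margin away from the ROI
    boundary when border-corrected counting is enabled (domains straddling
    the window edge lose members to clipping and would otherwise inflate the
    free-floater count).
    """

    labels: np.ndarray        # per-protein domain index, FREE_FLOATER if free
    centers: np.ndarray       # (n_domains, 2) domain centroids in nm
    n_proteins: int
    counted: np.ndarray | None = None

    @property
    def n_domains(self) -> int:
        return len(self.centers)

    @property
    def n_free(self) -> int:
        return int(np.sum(self.labels == FREE_FLOATER))

    @property
    def fraction_outside(self) -> float:
        """Fraction of counted proteins not assigned to any domain."""
        if self.n_proteins == 0:
            return 0.0
        if self.counted is None:
            return self.n_free / self.n_proteins
        n_counted = int(np.sum(self.counted))
        if n_counted == 0:
            return 0.0
        free_counted = int(np.sum(self.counted & (self.labels == FREE_FLOATER)))
        return free_counted / n_counted


def merge_appearances(peaks: PeakList, cfg: ClusterConfig) -> MoleculeList:
    """Step 1: collapse repeated appearances of one fluorophore.

    Same contract as :func:`nanodomain.pcpalm.group_peaks` but with the
    resolution-limited spot quantified as a fixed merge radius.
    """
    return group_peaks(
        peaks,
        max_dark_time=cfg.max_blink_time,
        group_radius_nm=cfg.spatial_merge_radius,
    )


def _canonical_order(proteins: MoleculeList) -> np.ndarray:
    return np.lexsort((proteins.y, proteins.x, proteins.first_frame))


def dpmeans_domains(
    proteins: MoleculeList,
    cfg: ClusterConfig,
    edge_margin_nm: float | None = None,
) -> DomainAssignment:
    """Step 2: DP-means domain identification with the >= 3-protein rule.

    Points are swept in canonical order; a point farther than DR from every
    current center opens a new cluster seeded at the point, otherwise it
    joins the nearest center (ties to the lower index).  After each sweep,
    centers move to their members' means and empty clusters are removed;
    sweeps repeat until the labels are stable.

    A cluster survives as a domain when at least ``min_proteins`` proteins
    lie inside the confined space within DR of its center — counting every
    protein in that circle, not only the cluster's own sweep members, since
    a domain is a circular region of radius DR.  Members of dissolved
    clusters join the nearest surviving center when within DR of it,
    otherwise they are free floaters.

    ``edge_margin_nm`` enables border-corrected counting: every protein is
    classified, but the fraction-outside readout only counts proteins at
    least that margin inside the ROI boundary (use the domain radius to
    neutralize clipped-domain artifacts).  ``None`` counts all proteins.
    """
    n = len(proteins)
    if n == 0:
        return DomainAssignment(np.empty(0, int), np.empty((0, 2)), 0)
    order = _canonical_order(proteins)
    pts = np.column_stack((proteins.x, proteins.y))[order]
    dr2 = cfg.domain_radius**2

    centers: list[np.ndarray] = [pts[0].copy()]
    labels = np.full(n, -9, dtype=int)
    for _ in range(cfg.max_iterations):
        changed = False
        for i in range(n):
            carr = np.asarray(centers)
            d2 = np.sum((carr - pts[i]) ** 2, axis=1)
            j = int(np.argmin(d2))  # argmin takes the lowest index on ties
            if d2[j] > dr2:
                centers.append(pts[i].copy())
                j = len(centers) - 1
            if labels[i] != j:
                labels[i] = j
                changed = True
        # recentre on members; drop clusters that lost all members
        new_centers: list[np.ndarray] = []
        remap = {}
        for j in range(len(centers)):
            members = pts[labels == j]
            if len(members):
                remap[j] = len(new_centers)
                new_centers.append(members.mean(axis=0))
        labels = np.array([remap[l] for l in labels])
        centers = new_centers
        if not changed:
            break
    else:
        raise ClusterFailureError(
            f"DP-means did not stabilize in {cfg.max_iterations} iterations "
            f"({len(centers)} clusters, {n} points)"
        )

    # dissolve clusters whose DR-circle holds < min_proteins proteins;
    # dissolved members may re-attach to a surviving center within DR
    carr = np.asarray(centers)
    d2_all = (
        (pts[:, None, 0] - carr[None, :, 0]) ** 2
        + (pts[:, None, 1] - carr[None, :, 1]) ** 2
    )
    n_within = (d2_all <= dr2).sum(axis=0)
    survives = n_within >= cfg.min_proteins
    surviving = np.flatnonzero(survives)
    final = np.full(n, FREE_FLOATER, dtype=int)
    if len(surviving):
        new_index = {int(j): k for k, j in enumerate(surviving)}
        surv_centers = carr[surviving]
        d2_surv = d2_all[:, surviving]
        for i in range(n):
            if survives[labels[i]]:
                final[i] = new_index[int(labels[i])]
            else:
                j = int(np.argmin(d2_surv[i]))
                if d2_surv[i, j] <= dr2:
                    final[i] = j
        centers_out = surv_centers
    else:
        centers_out = np.empty((0, 2))

    # undo the canonical ordering so labels align with the input proteins
    inverse = np.empty(n, dtype=int)
    inverse[order] = np.arange(n)
    counted = None
    if edge_margin_nm is not None:
        w_nm = proteins.roi[0] * 1000.0
        h_nm = proteins.roi[1] * 1000.0
        counted = (
            (proteins.x >= edge_margin_nm)
            & (proteins.x <= w_nm - edge_margin_nm)
            & (proteins.y >= edge_margin_nm)
            & (proteins.y <= h_nm - edge_margin_nm)
        )
    return DomainAssignment(final[inverse], centers_out, n, counted)


@dataclass(frozen=True)
class OutsideFractionReport:
    """Aggregate of per-region free-floater fractions."""

    mean: float
    sem: float
    fractions: np.ndarray
    histogram: dict[str, float] = field(default_factory=dict)


def fraction_outside_report(
    assignments: list[DomainAssignment],
) -> OutsideFractionReport:
    """Mean +/- SEM of per-region outside-domain fractions, plus histogram.

    The histogram uses the four reporting bins <10%, 10-20%, 20-30%, >30%,
    normalized to the number of regions.
    """
    if not assignments:
        raise InsufficientDataError("no domain assignments to aggregate")
    fr = np.array([a.fraction_outside for a in assignments])
    sem = float(np.std(fr, ddof=1) / np.sqrt(len(fr))) if len(fr) > 1 else 0.0
    counts, _ = np.histogram(fr, bins=HISTOGRAM_EDGES)
    names = ("<10%", "10-20%", "20-30%", ">30%")
    hist = {k: c / len(fr) for k, c in zip(names, counts)}
    return OutsideFractionReport(float(np.mean(fr)), sem, fr, hist)
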