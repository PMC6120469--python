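"""End-to-end analysis of one PALM region: grouping to domain statistics.

Chains the standard path — group peaks, estimate density, compute g(r), fit
the complex model, derive domain statistics, classify randomness, and run
the two-step clustering with DR taken from the fit — and collects everything
in a machine-readable summary dict.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


from .cluster import ClusterConfig, DomainAssignment, dpmeans_domains, merge_appearances
from .correlate import CorrelationCurve
from .exceptions import FitFailureError
from .pcpalm import (
    DomainStats,
    PeakList,
    SaccFit,
    classify_random,
    detected_density,
    domain_params,
    fit_complex,
    group_peaks,
    pair_correlation,
)

__all__ = ["RoiReport", "analyze_roi"]


@dataclass(frozen=True)
class RoiReport:
    """Full single-ROI analysis output."""

    density: float
    sacc: CorrelationCurve
    fit: SaccFit | None
    domains: DomainStats | None
    organization: str
    assignment: DomainAssignment | None

    @property
    def fraction_outside(self) -> float | None:
        return None if self.assignment is None else self.assignment.fraction_outside

    def summary(self) -> dict:
        """JSON-serializable summary of the analysis."""
        out: dict = {"density_um2": self.density, "organization": self.organization}
        if self.fit is not None:
            out["sacc_fit"] = {
                k: v for k, v in asdict(self.fit).items() if k != "stderr"
            }
        if self.domains is not None:
            out["domain_stats"] = asdict(self.domains)
        if self.assignment is not None:
            out["n_domains"] = self.assignment.n_domains
            out["fraction_outside"] = self.assignment.fraction_outside
        return out


def analyze_roi(
    peaks: PeakList,
    bin_nm: float = 5.0,
    r_max_nm: float = 500.0,
    domain_radius_nm: float | None = None,
) -> RoiReport:
    """Run the full pipeline on one peak list.

    ``domain_radius_nm`` overrides the DP-means domain radius; by default it
    is the xi_D of this region's own complex fit.
    """
    mols = group_peaks(peaks)
    density = detected_density(mols)
    sacc = pair_correlation(mols, bin_nm=bin_nm, r_max_nm=r_max_nm)
    fit: SaccFit | None
    domains: DomainStats | None
    try:
        fit = fit_complex(sacc)
        domains = domain_params(fit, density)
    except FitFailureError:
        fit, domains = None, None
    organization = classify_random(sacc, fit=fit)
    assignment: DomainAssignment | None = None
    dr = domain_radius_nm if domain_radius_nm is not None else (
        fit.domain_radius if fit is not None else None
    )
    if dr is not None and dr > 0:
        cfg = ClusterConfig(
            domain_radius=float(dr),
            spatial_merge_radius=min(3.0 * peaks.sigma_max(), float(dr)),
        )
        proteins = merge_appearances(peaks, cfg)
        assignment = dpmeans_domains(proteins, cfg)
    return RoiReport(
        density=density,
        sacc=sacc,
        fit=fit,
        domains=domains,
        organization=organization,
        assignment=assignment,
    )
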