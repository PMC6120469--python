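"""Recover nanodomain size and occupancy from simulated PALM ensembles.

Simulates 40 regions with 101-nm membrane domains holding ~9-10 detected
receptors each, groups blinking localizations into molecules, computes the
radial distribution function g(r) per region, averages, and fits the
two-length-scale (Gaussian + exponential) model.  The derived statistics
are the domain radius, detected proteins per domain and the local density
enhancement psi.
"""

import nanodomain as nd

ensemble = nd.ensemble_analysis(nd.PalmSimConfig(), n_rois=40, base_seed=100)
fit = nd.fit_complex(ensemble.curve)
stats = nd.domain_params(fit, ensemble.mean_density)

print(f"grouped detected density  rho = {ensemble.mean_density:.1f} /um^2")
print(f"fit quality               R^2 = {fit.r_squared:.4f}")
print(f"domain radius                 = {stats.radius:.0f} nm  (generator: 101 nm)")
print(f"detected proteins per domain  = {stats.n_domain:.1f}  (generator mean: 9.5)")
print(f"local density enhancement psi = {stats.psi_domain:.1f}")
# radius ~ 100-110 nm and occupancy ~ 9 +/- 1 demonstrate that the pair-
# correlation pipeline reads the generated organization back out of the
# blinking, noisy localization data.
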