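# Methods

This note documents the models implemented in `nanodomain`, the choices made
where the underlying procedures are under-determined, and what the synthetic
generators do and do not emulate.

## Temporal correlation (FCS)

Intensity traces are binned photon counts `F(t)`. The normalized
autocorrelation `G(tau) = 1 + <dF(t) dF(t+tau)>/<F>^2` and two-channel
cross-correlation `G_CC` are estimated with a multi-tau correlator: 16
linearly spaced lags per octave, pairwise bin averaging per octave, lags from
one bin time up to `duration/8`. Normalization is symmetric — for every lag
the two overlapping segments are divided by their own means — which removes
first-order bias from slow drifts over a 10-s trace.

Averaging a measurement series excludes curves whose first-lag amplitude
deviates more than 3 robust standard deviations (median ± 1.4826·MAD) from
the series median. This is a reproducible stand-in for the manual practice of
discarding an occasional first measurement that is obviously different
(photobleaching of immobile background during the first exposure).

### Diffusion models

The fitting model family is free 2D diffusion with an optional second
component and an optional triplet (intersystem-crossing) factor:

```
G(tau) = 1 + (1/N) [ y/(1 + tau/tau_D1) + (1-y)/(1 + tau/tau_D2) ]
             [ 1 + T/(1-T) exp(-tau/tau_T) ]
```

`N` is the mean number of molecules in the observation area, `y` the fast
fraction, `tau_Di = omega_xy^2 / (4 D_i)` the diffusion times, `T`/`tau_T`
the triplet fraction and correlation time. Bounds reflect the plausible
windows for membrane receptors widened by one octave: `tau_D1` in
[50 µs, 5 ms], `tau_D2` in [5 ms, 500 ms], `tau_T` in [1 µs, 50 µs],
`T < 0.5`. A fitted `T >= 0.2` raises a warning flag — well-adjusted
measurements keep triplet occupancy below 20%. Sub-200-µs photophysics is
absorbed by the triplet-like factor rather than modeled separately. Fits are
weighted by inverse per-lag SEM when the curve is an average of at least 3
measurements, otherwise unweighted. Model selection under `model_tag="auto"`
keeps the two-component model only when it improves reduced chi-squared by
more than 10% — a quantitative reading of "the simplest model that accounts
for the curve". The slow fraction is fitted per averaged measurement and
averaged across measurements afterwards.

FCCS binding is summarized by the relative cross-correlation amplitude
`RCCA = A_CC / A_AC,green`, with all amplitudes taken from fitted
zero-lag diffusion amplitudes (`1/N`, triplet excluded) rather than raw
first bins, for shot-noise robustness.

## Pair-correlation analysis (PC-PALM)

Localization peaks are grouped into detected molecules when successive peaks
fall within `3 sigma_max` of the molecule's running precision-weighted
centroid and the dark gap does not exceed the maximum blinking time (5 s for
paGFP-class labels). `sigma_max` is the 95th percentile of per-peak
precision — a dataset-level maximum robust to outliers. Detected density is
the grouped count over the region area; areas far outside the typical
7-18 µm² analysis range trigger a warning.

`g(r)` is estimated spectrally: positions are binned on a 5-nm grid, the 2D
pair histogram is obtained by zero-padded FFT autocorrelation, divided by
the autocorrelation of the rectangular region mask (edge correction) and by
the CSR expectation, and radially averaged into 5-nm annuli out to 500 nm.
Self-pairs are removed at zero offset. Per-bin standard errors use a Poisson
approximation on the number of independent (unordered) pairs; calibrated
against complete-spatial-randomness ensembles the estimator is unbiased
(mean within 0.01 of 1 beyond 50 nm).

### The two-length-scale model

Complex membrane organization is fitted with

```
g(r) = A1 exp(-(r - peak_max)^2 / (2 B^2)) + A2 exp(-r / xi_D) + 1
```

`peak_max` is profiled over a 1-nm grid from 0 to 3 grid bins and the value
minimizing the residual sum of squares is kept. The least-squares surface
has two basins — the Gaussian term carrying the domain-scale correlations,
or the exponential doing so — so the fit multistarts from both assignments
and keeps the global optimum. Which fitted component is the *domain* term
is then decided by length scale, using each component's mean decay length
(its normalized radial integral): `xi_D` for the exponential and
`B sqrt(pi/2)` (erf-corrected for a shifted center) for the Gaussian. This
matters for simulated hard-disc domains, whose correlation kernel is the
disc set covariance: it is fitted far better by the Gaussian term, while
for blinking-dominated short-range structure plus diffuse domains the
classical assignment (Gaussian short, exponential long) emerges naturally.
Fits with R² below 0.98 are flagged as below the accepted quality floor but
still returned.

Domain statistics follow from the fitted components:

- radius = mean decay length of the long-range component;
- `N_domain = rho_avg * int (g - 1) 2 pi r dr`, evaluated with exact radial
  integrals of the two fitted terms (this reduces to the familiar
  `rho_avg 2 pi (A1 B^2 + A2 xi_D^2)` when `peak_max = 0`);
- `psi = N_domain / (pi radius^2 rho_avg)`, the in-domain density relative
  to the average density. The identity `psi · pi · radius² · rho = N` holds
  exactly by construction.

A region is classified `random` when the mean of `g(r) - 1` beyond 25 nm
lies within 2 pooled standard errors of zero and the domain-component
amplitude is not significantly positive (2-sigma); boundary cases are called
random.

## Two-step clustering and the outside-domain fraction

Step 1 merges appearances with a fixed resolution-limited merge radius
(default `3 sigma_max`) and the maximum blinking time. Step 2 runs DP-means:
points swept in a canonical order (first frame, then x, then y — the
algorithm is order-dependent and a fixed order makes results reproducible);
a point farther than the domain radius DR from every center founds a new
cluster; sweeps alternate with centroid updates until labels are stable
(cap 100 iterations, ties to the lower-index center). DR is the domain
radius from the complex fit of the same dataset.

A candidate domain survives when at least 3 proteins lie inside the circle
of radius DR around its center — counting *all* proteins in that circle,
not only the cluster's own sweep members. The distinction matters: DP-means
with penalty distance DR necessarily fragments a disc-shaped domain of
radius ≈ DR into two or more Voronoi cells, and judging survival on
fragment membership alone frees the small far-edge fragments, inflating the
outside-domain fraction by 4-6 percentage points against generator ground
truth. With the circle-count rule the recovery error is below 1 point.
Members of dissolved clusters join the nearest surviving center when within
DR; everything else is a free floater. Per-region fractions are aggregated
as mean ± SEM plus the four reporting bins (<10%, 10-20%, 20-30%, >30%).
An optional border margin can restrict counting to proteins away from the
region edge (domains clipped by the window otherwise lose members); the
recovery criteria are met without it and it defaults off.

## Synthetic-data generators

### PALM generator

True molecules are placed as a stationary process restricted to the region:
domain centers are homogeneous-Poisson on the region dilated by one domain
radius (so edge density is unbiased), per-domain occupancy is Poisson,
in-domain positions are uniform in a hard-edged disc, and a configurable
fraction of molecules are free monomers (CSR). The instrument response:
geometric number of appearances per fluorophore (memoryless blinking,
mean 4), burst frames with exponential dark gaps truncated at the 5-s
grouping dark time, lognormal photon counts (median 100, shape 0.5),
precision `sigma = s_psf / sqrt(photons)` with `s_psf = 160 nm` so the
median precision is ≈ 16 nm, and isotropic Gaussian localization noise.
Defaults emulate the KOP-like condition (101-nm domains, 9-10 detected
proteins per domain, ~51 detected molecules/µm², 10% free) on 3×3 µm
regions over 20,000 frames of 100 ms.

What the generator does *not* emulate: stage drift, fiducial residuals,
EMCCD noise beyond Poisson photons, radial domain substructure, dual-color
registration. Passing recovery tests therefore demonstrates correctness of
the estimators under blinking, localization noise and finite sampling — not
robustness to drift or detector artifacts.

### FCS generator

Two-component 2D Brownian dynamics in a periodic square box (edge ≥ 10
beam radii) with a Gaussian detection profile `W(r) = exp(-2 r²/omega²)`
centered in the box; triplet blinking is an exact two-state telegraph
process (exponential dwells with rates `T/tau_T` and `(1-T)/tau_T`)
rasterized to the bin grid; expected counts per bin are
`brightness · sum_i W(r_i) · emissive_i · bin_time`, realized counts are
Poisson. Defaults: `omega = 250 nm`, `tau_D1 = 0.5 ms`, `tau_D2 = 50 ms`,
40% slow, `T = 0.15`, `tau_T = 5 µs`, 2-µs bins, 10-s traces, 82 molecules
in a 4-µm box (≈ 1 molecule in the observation area). The brightness
default (30 kHz at beam center, ≈ 15 kHz mean per molecule in the
observation area) is a realistic fluorescent-protein brightness chosen to
give single-trace curves with noise comparable to averaged experimental
series; simulated fluorophores do not photobleach, so the anti-bleaching
laser-power compromise of live-cell work does not apply.

Finite-size caveat: the periodic box supports no concentration fluctuations
beyond its slowest diffusive mode (`(L/2pi)²/D`), so correlation tails are
truncated relative to the open-reservoir model the fits assume. The box
default (4 µm) puts that mode at ≈ 1.3 s for the slow component, past the
`duration/8` fitted window of a 10-s trace; a 2.5-µm box would place it at
≈ 0.5 s, inside the window, and measurably depress the fitted slow
fraction. Studies of even slower components need a proportionally larger
box.

## Acceptance statistics

Curve agreement uses the one-sided variance-ratio F-test at the 5% level
with the larger variance in the numerator (the one-sided reading is fixed
by the printed critical value 1.2172 at df 281/281; a two-sided 5% test
would give ≈ 1.26). Fit quality uses the standard error of the estimate
`S = sqrt(sum r² / (n - p))` with `p = 5` for the complex spatial model.
Paired t-tests are two-tailed; identical samples return `t = 0, p = 1`,
constant nonzero differences are flagged degenerate. Pixel colocalization
counts pixels above a relative cutoff (default 10% of each channel's
maximum) in both channels, and is invariant to per-channel rescaling.

## Problem sizes

The recovery analyses use 40 simulated regions per PALM condition, 12
ten-second traces per FCS condition, and 3×3-µm regions at the documented
densities — ensemble sizes comparable to the per-receptor region counts
(N = 42-44) and measurement series (8-10 cells × 10 traces) of the study
design they emulate.
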