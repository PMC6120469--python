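# nanodomain

Quantitative analysis of membrane-receptor organization at the nanoscale,
combining the two single-molecule readouts used for this problem in live- and
fixed-cell work:

* **FCS / FCCS** — fluorescence (cross-)correlation spectroscopy: temporal
  autocorrelation of intensity fluctuations in a diffraction-limited
  observation area yields the number of molecules `N` and their diffusion
  times; a two-component fit partitions receptors between fast (free) and
  slow (domain-associated) populations.
* **PC-PALM** — pair-correlation analysis of photoactivated localization
  microscopy: the radial distribution function g(r) of detected molecules
  quantifies nanodomain radius, occupancy and local density enhancement,
  and a DP-means clustering step counts the receptors left outside domains.

The package is aimed at quantitative microscopists who want the full desk
side of this workflow — correlators, model fits, spatial statistics,
clustering — together with Monte-Carlo generators of both data types that
emulate the instrument response (blinking, photon statistics, localization
precision, triplet kinetics), so every estimator can be validated end to end
against ground truth.

## Models

Temporal autocorrelation curves are fitted with free 2D diffusion of two
components plus intersystem crossing:

```
G(τ) = 1 + (1/N) [ y/(1 + τ/τ_D1) + (1−y)/(1 + τ/τ_D2) ] [ 1 + T/(1−T) e^(−τ/τ_T) ]
```

Spatial autocorrelation curves with two correlation lengths are fitted with
a Gaussian (short-range) plus exponential (long-range) model,

```
g(r) = A1 exp(−(r − peak_max)²/(2B²)) + A2 exp(−r/ξ_D) + 1
```

from which domain statistics follow: radius (mean decay length of the
long-range component), occupancy `N_domain = ρ_avg ∫(g−1) 2πr dr`, and the
local density enhancement `ψ = N_domain/(π radius² ρ_avg)`.

See `docs/methods.md` for estimator details, parameter defaults and the
design decisions behind the fit and clustering conventions.

## Worked example

Recover nanodomain organization from a simulated PALM ensemble
(`examples/pcpalm_domain_statistics.py`):

```python
import nanodomain as nd

ensemble = nd.ensemble_analysis(nd.PalmSimConfig(), n_rois=40, base_seed=100)
fit = nd.fit_complex(ensemble.curve)
stats = nd.domain_params(fit, ensemble.mean_density)
```

prints

```
grouped detected density  rho = 52.3 /um^2
fit quality               R^2 = 0.9970
domain radius                 = 110 nm  (generator: 101 nm)
detected proteins per domain  = 9.6  (generator mean: 9.5)
local density enhancement psi = 4.8
```

The generator placed 101-nm domains holding on average 9.5 detected
proteins at 51 molecules/µm²; after blinking, localization noise and
grouping, the pair-correlation fit reads back a 110-nm radius and 9.6
proteins per domain — agreement within the sensitivity of the method
(about 10 nm in radius and 1 protein in occupancy).

The other example scripts cover the FCS two-component fit
(`fcs_two_component_fit.py`), the outside-domain fraction via two-step
clustering (`outside_domain_fraction.py`), and the curve-agreement
statistics and pixel colocalization (`statistics_and_colocalization.py`).

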