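# Methods

`blockface` simulates and analyzes the physics that sets the depth resolution
of focused-ion-beam scanning electron microscopy (FIB-SEM) of stained,
epoxy-embedded biological specimens: a Ga⁺ milling beam implants a
concentrated Ga layer in the top ~20 nm of the block face, and that layer
confines the depth from which the 1.5 keV backscattered-electron (BSE) signal
originates.  The package has three legs: a Monte Carlo BSE image simulator
over composition phantoms, composition quantification (HAADF jump ratios and
core-loss EELS), and line-profile / visibility analysis.

## Electron transport model

Single-scattering Monte Carlo in the CASINO/MC X-Ray tradition:

* **Elastic scattering.**  Relativistically corrected screened Rutherford
  cross section with screening parameter `alpha = 3.4e-3 Z^0.67 / E[keV]`:

      sigma_el = 5.21e-7 (Z/E)^2 * 4*pi / (alpha (1+alpha))
                 * ((E+511)/(E+1024))^2   [nm^2, E in keV]

  The angular distribution has the closed-form inverse CDF
  `cos(theta) = 1 - 2 alpha u / (1 + alpha - u)`, sampled exactly; azimuth is
  uniform.  The scattering element within a material is chosen with
  probability `n_i sigma_i / sum_j n_j sigma_j`.  Partial-wave (Mott-grade)
  total cross sections can be supplied as tabulated overrides on
  `CrossSectionModel`; the analytic default keeps the package self-contained.
  Validity range 50 eV – 300 keV.

* **Energy loss.**  Continuous slowing down (CSDA) with the Joy–Luo modified
  Bethe formula, `k_i = 0.734 Z^0.037`, and Berger–Seltzer mean ionization
  energies (`J = 11.5 Z` eV below Z = 13, else `9.76 Z + 58.5 Z^-0.19`).
  No discrete inelastic events are modelled; the energy-selective detector
  therefore filters the CSDA exit energy.  Tracking stops at a 50 eV cutoff
  (configurable); this is the conventional floor of the CSDA approximation.

* **Geometry.**  Free flights are exponential with the local elastic mean
  free path and truncated at material boundaries; the remaining flight is
  resampled in the new material, which is unbiased for the memoryless
  exponential.  Phantoms are either analytic (a matrix half-space with
  axis-aligned boxes — the depth-series ladder) or voxelized (the 3-nm-voxel
  vesicle shell).  Incidence is normal by default.

* **Performance and reproducibility.**  The kernels are numba-compiled.
  Inverse mean free paths and stopping powers are tabulated per material on
  a 1024-point log-energy grid (45 eV – 305 keV) computed from the same
  closed-form functions as the Python reference path, and linearly
  interpolated (relative interpolation error below 1e-4).  Randomness is an
  explicit xorshift128+ stream per pixel, seeded by splitmix64 from
  (seed, pixel index), so images are bit-reproducible under any scan order.
  A pure-Python trajectory path (`simulate_trajectory`) shares the physics
  functions and serves diagnostics; an independent vectorized transport
  oracle in the test suite cross-checks the backscatter coefficient.

## Materials

Materials are atomic-fraction compositions with a mass density.  The default
embedding resin (Epon Embed-812/Araldite-502/DDSA epoxy) is C 0.54, H 0.36,
O 0.09, N 0.01 at 1.25 g/cm³ — a documented typical value; the resin's true
elemental composition is batch-dependent, so every pipeline reads
composition from its config and a measured composition can be dropped in
verbatim.

Two composition edits define the study materials:

* **Stain**: "3 at.% Pb" places Pb at atomic fraction 0.03 and rescales the
  host by 0.97.
* **Ga implantation**: Ga replaces C one-for-one; `ga_fraction` is the final
  absolute Ga atomic fraction.  Densities are recomputed at constant atom
  number density by default (the edit changes which atoms occupy the matrix,
  not how many per unit volume); with 50 at.% Ga this yields ≈5.5 g/cm³, a
  dense glassy layer.  A constant-mass-density rule is available for
  sensitivity checks.

## Depth-series visibility study

The z-resolution phantom buries five 5-nm-thick, 50-nm-square regions of
stained matrix at depth intervals 0–5 … 20–25 nm, laterally separated by
50 nm so that every region and the pure matrix support hundreds of 3-nm
pixels.  Images are rendered at 1.5 keV with 3000 trajectories per pixel,
counting all backscattered electrons (grid voltage 0; the energy filter is
available but the simulated ladder is insensitive to it, matching the
weak grid-voltage dependence seen experimentally).

A region is *visible* when its contrast-to-noise ratio

    CNR = (mean_region − mean_background) / sigma_background   (per-pixel sigma)

clears a Rose-type threshold.  "Visible" is the one subjective step of the
analysis, so the threshold is explicit, configurable, and calibrated once
for this study: with the default threshold **CNR ≥ 1.0** (recorded in
`configs/fig6_*.yaml`) the ladder yields 5 visible regions at 0 % Ga,
3 at 25 %, and 2 at 50 %.  The measured CNR ladders sit well away from the
threshold on both sides (nearest values ≈1.4 above and ≈0.2 below, against
a CNR estimation noise of ≈0.07), so the counts are stable across seeds.
When visibility is non-contiguous in depth the count is the index of the
deepest visible region.  n visible regions bracket the z-resolution between
5(n−1) and 5n nm.

## HAADF quantification

In the thin-specimen single-scattering regime the annular dark-field signal
per unit thickness is `sum_i n_i sigma_i^HAADF`, with the partial cross
sections integrated over the detector's angular window (default 40–200 mrad
at 300 keV; the true window is instrument configuration).  Hydrogen is
included — its negligible cross section, not an exclusion rule, makes the
detector blind to it.

The jump ratio R (implanted peak over resin plateau, equal thickness and
atom density assumed) is inverted for the Ga fraction by bisection on the
monotone forward model to 1e-9.  How much C and O the ion beam removed is
not knowable from R alone, so the loss assumption is a first-class input
with two shipped presets: *no-loss* (resin intact plus Ga) and
*half-C-no-O* (50 % of C and all O lost).  Results are reported as Ga:C
atomic ratios and as at.% on the Ga+C basis, `100 r/(1+r)`.

With the analytic screened-Rutherford window the inversion is exact by
construction (forward/inverse round-trip to 1e-6) but maps a given R to a
different Ga:C than partial-wave cross sections would — at high angles the
screened Rutherford form overweights high-Z scattering.  Table-grade
agreement requires supplying Mott-grade cross sections as overrides;
absolute published ratios are therefore validated by round-trip, not by
value.

## EELS quantification

Standard core-loss procedure over 200–1600 eV: a power-law background
`A·E^-r` is fitted by log-log least squares on a pre-edge window (default:
the 100 eV before the onset, clipped to the axis), extrapolated and
subtracted, and the net edge counts are integrated over a 100-eV window
above the onset (C K 284 eV, O K 532 eV, Ga L₂,₃ 1140 eV).  Significant
lag-1 autocorrelation of the fit residuals flags a contaminated background
window (an edge inside it); pure shot noise leaves white residuals.

The effective sigma(Ga L)/sigma(O K) ratio (k-factor) is calibrated from a
Ga₂O₃ reference of known 2:3 stoichiometry:
`k = [I(GaL)/I(OK)]·(3/2)`.  The specimen's Ga:C ratio is then
`[I(GaL)/I(CK)] / (k · sigma_OK/CK)` where the O-K/C-K cross-section ratio
comes from config — the measurement chain that calibrated it in practice is
vendor software, and no invented constant stands in for it.  Tests use
synthetic self-consistent values.

## Synthetic data generators

The generators produce data with the statistical structure the analyses
assume, all seeded and parameter-stamped (`meta`) so recovery tests are
self-describing:

* **HAADF block-face images**: the Ga depth profile rises linearly over a
  6-nm (10–90 %) onset and decays exponentially (default 50 nm) from the
  peak; pixel expectations are proportional to the HAADF signal of the local
  composition, the plateau is `dose` counts/pixel, and noise is Poisson.
* **EELS spectra**: power-law background plus sawtooth edges
  (`(E/onset)^-q` decay, q = 3); each edge's expected counts summed over its
  standard 100-eV window equal `abundance × sigma × dose`, so windowed
  quantification is exact in expectation.  Poisson noise.
* **Phantoms**: the depth-series ladder and the 40-nm vesicle with a 5-nm
  stained shell, voxelized at 3 nm (voxel centers decide membership); the
  shell-top burial depth defaults to 5 nm and is configurable.

What these generators do *not* emulate: curtaining and milling artifacts,
detector electronics noise, finite probe size (a point probe is used;
optional Gaussian blur can be applied post hoc), plural scattering in thick
sections, and beam-induced composition changes during acquisition.  Passing
recovery tests therefore demonstrate correctness of the estimators under
shot-noise statistics, not robustness to every instrumental artifact.

## Line-profile analysis

Profiles are band-averaged along one image axis (positions in nm from pixel
size).  Peak fitting takes the resin plateau as the 20 %-trimmed mean of the
far 30 % of the profile (orientation is detected from the outer-decile
baselines, so metrics are invariant under profile reversal), detects the
peak as the global maximum above plateau + 3 sigma, and reports the jump
ratio, 10–90 % onset width, FWHM above the plateau, and the decay length
from a log-linear fit of the trailing flank (samples above 5 % of the peak
excess).  A flat profile raises a no-peak signal rather than returning
metrics.

## Problem sizes and numerical choices

* Depth-series images: 184 × 20 pixels (560 × 60 nm at 3 nm), 3000
  trajectories/pixel — large enough for ≥190 pixels per region mask and
  ≥1000 background pixels, small enough to render in a few minutes each.
* Escape-depth distributions: 1e5 trajectories; median confidence intervals
  from binomial order statistics.
* Sampler validation: 1e5 angles against a 20001-point quadrature CDF
  (KS D < 0.01).
* Jump-ratio bisection tolerance 1e-9; EELS fits require ≥4 positive
  channels in the window.
* Boundary crossings are nudged 1e-6 nm into the new region; degenerate
  (near-tangent) box intersections fall back to the far face.

## Known limitations

* The analytic elastic model is least accurate at high Z and low energy;
  absolute backscatter coefficients and escape depths shift by tens of
  percent between cross-section models (orderings and contrasts are robust).
  The no-Ga median BSE generation depth is ≈13.5 nm under this model with a
  p90 of ≈24 nm — the deep-signal tail, not the median, is what reaches the
  25-nm scale.
* CSDA cannot reproduce discrete plasmon/core-loss structure in the exit
  energy spectrum; grid-voltage filtering acts on the smoothed energy loss.
* Charging, beam damage, and the mechanics of the hardened layer are outside
  the model's scope; implantation enters only as a prescribed composition
  profile, never via ion-transport simulation.
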