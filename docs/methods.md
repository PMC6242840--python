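# Methods

This note records the scientific and numerical choices behind
`pomstoich`: what each stage assumes, which parameters matter, what the
synthetic cruise does and does not emulate, and where the design was
genuinely open.

## Elemental ratios and their uncertainties

Stations carry analytical triplicates of POC and PON (µM) and POP (nM,
converted to µM before any ratio is formed). The ratio conventions are
deliberately asymmetric, mirroring how the filters are analysed:

* **C:N** — every filter is measured for both POC and PON, so each
  filter yields a C:N ratio; the station value is the mean of those
  per-filter ratios and its uncertainty the *population* standard
  deviation of the ratios (denominator n, configurable via `ddof`).
* **C:P and N:P** — POP comes from different filters, so these are
  ratios of mean concentrations with relative-error quadrature:
  σ_CP = (C̄/P̄)·√((σ_C/C̄)² + (σ_P/P̄)²), and likewise for N:P, where
  σ_C, σ_N, σ_P are replicate standard deviations (same n convention).

The quadrature form is the first-order delta-method variance of a
ratio of independent measurements; a Monte-Carlo test confirms it
matches the empirical SD of lognormal measurement ratios within 10%
at CVs up to 0.1, which is where the linearisation is trustworthy.
A uniform ratio-of-means mode (`mode="ratio_of_means"`) exists for
sensitivity analysis. Regional mean ratios are means of per-station
ratios, not ratios of regional mean concentrations (the alternative is
one `groupby` away if wanted).

QC drops individual replicates outside the analytical detection
windows — POC 0.43–43.13 µM and PON 0.037–7.39 µM (dry-combustion
protocol range in seawater), POP below the 0.1 nM ash-hydrolysis assay
limit — and rejects a station only when an element loses all
replicates. Rejections are logged with reasons, never silent.

## Hydrographic diagnostics

**Nutricline.** Z_nut is the shallowest depth where nitrate reaches
1 µM, found by scanning from the surface and interpolating linearly
within the first bracketing pair of samples. If the surface value
already exceeds the threshold, the shallowest sampled depth is
returned; if the threshold is never reached the result is flagged
undefined (`None`), not an error. Crossings are never bridged across
vertical gaps wider than `max_gap` (default 50 m), so sparse deep
bottle spacing cannot manufacture a spurious interpolated depth.

**Layer depths.** The mixed-layer criterion is a density increase of
ΔT·|dσ/dT| from the surface with ΔT = 0.5 °C; the isothermal-layer
criterion is a temperature decrease of ΔT. The printed forms of these
criteria are sign-ambiguous ("+ΔT"); the implementation adopts the
conventional density-increase/temperature-decrease reading (the layer
base is denser and cooler than the surface) and exposes the sign for
sensitivity checks. In-situ temperature stands in for potential
temperature — at the 0–300 m depths involved the adiabatic difference
is far below the 0.5 °C criterion. BLT = ITL − MLD exactly; negative
values (density-compensated layers) are reported and flagged rather
than clipped, since clipping would hide a physically meaningful state.

The thermal-expansion term dσ/dT is a centred finite difference
(half-step 0.1 °C) of σ_t from the one-atmosphere EOS-80 density
(Millero & Poisson 1981), implemented in `pomstoich.seawater` and
verified against the standard check values (e.g. ρ(35, 25, 0) =
1023.343 kg m⁻³). The finite difference keeps the criterion consistent
with whatever density formula is in use and is EOS-agnostic; full
TEOS-10 thermodynamics would change these layer depths by far less
than the bottle spacing resolves.

**Regions.** Latitude bands partition the transect: SIO gyre
[31°S, 12°S), EqIO [12°S, 5°N), BoB [5°N, 19°N]. The half-open bounds
make classification a true partition; 12°S (not 10°S) is the gyre's
northern cutoff because of the uncertain gyre/Indonesian-throughflow
transition.

## Diel decomposition

The transect trend is an 8-sample moving average. The window is
centred — position i averages samples i−4 … i+3 — because the edge
treatment (first and last few positions averaging over fewer than 8
points) implies symmetry; an even window cannot be perfectly centred,
so the window leans one sample left, which shifts the smooth by half a
sampling interval and is irrelevant after residualing. Residuals
default to data − smoothed; the orientation is configurable and all
amplitude results are invariant to it.

At the default cruise speed the sampling interval is ~3 h, so 8
samples span ~24 h and the moving average almost exactly annihilates a
24-h harmonic (discrete Dirichlet factor ≈ 0.01), leaving it in the
residuals. At substantially different sampling intervals the window
passes part of the diel cycle into the trend and the residual
amplitude is attenuated — a property of this detrending scheme users
should keep in mind with irregular station spacing.

The per-region fit is r(t) = A·sin(2πt/24 + φ) with the period fixed
at 24 h, solved exactly in the linear basis {sin, cos}: A = √(a²+b²) ≥ 0,
φ = atan2(b, a) wrapped to (−π, π], peak local hour = ((π/2 − φ)·24/2π)
mod 24. Fits require ≥ 6 points spanning ≥ 12 h of local time;
degenerate hour coverage raises. Local solar time is UTC + longitude/15
— the physically meaningful clock for day/night biology, since no
civil time zone is defined mid-ocean. Daily range is 2A. The POC
accumulation proxy is the per-local-day residual range divided by that
day's mean smoothed POC (2A/M for a clean sinusoid); day boundaries
are local midnight. That normalisation is an explicit convention of
this package.

## Environment models

y = p₁·sin(ωt + p₂) + p₃ + p₄·x with ω = 2π/24, t the cumulative cruise
hours from the first station (the phase origin, so p₂ is only
comparable between fits sharing a time base), and x one of SST, Z_nut
or MLD. The sine is linearised into {sin ωt, cos ωt, 1, x} and solved
by ordinary least squares, so the fit is exact and deterministic;
tests confirm agreement with brute-force nonlinear optimisation to
1e−6 and exact parameter recovery on noiseless data. A constant
predictor makes p₄ unidentifiable and raises. Predictor comparison
ranks by RMSE with R² reported alongside; fits whose RMSE is within 1%
(configurable) of the best are flagged statistically indistinguishable
— the pattern of interest when temperature and nutricline depth are
strongly anti-correlated along a transect and explain the data equally
well. A latitude-restricted refit (default south of 5°N) measures the
leverage of the Bay of Bengal on basin-wide slopes.

## Metropolis–Hastings slope regression

The slope comparisons use y ~ Normal(α + βx, σ) with x and y divided
by their maxima so slopes are comparable across datasets with
different units. Priors are Normal(0, 10²) on α and β (weak on the
normalised scale) and half-Normal(1) on σ; σ can be held fixed for the
known-noise case. The sampler is a vectorised random-walk
Metropolis–Hastings: 4 chains × 10,000 steps, first half discarded,
per-chain proposal scale adapted every 200 burn-in steps toward ~30%
acceptance (adaptation stops at burn-in end, so the retained chain is
Markov). Only the algorithm family is externally fixed; chain lengths,
priors and adaptation are this package's explicit, seeded defaults.
Calibration tests check the posterior against the closed-form
conjugate posterior (known-σ case) within 3 Monte-Carlo standard
errors and against OLS within 2, with effective sample sizes estimated
via arviz.

## Regional and gyre statistics

Regional differences use one-way ANOVA followed by pairwise Welch
t-tests with Holm correction (robust to unequal variances; Tukey HSD
is available), star-encoded at p < 0.05/0.01/0.001. The Holm step-down
is implemented in-package (five lines) and verified against
statsmodels' `multipletests` in a test; a calibration test confirms
the nominal 5% type-I error rate over 1000 simulated nulls. Regions
with fewer than 2 observations are excluded with a warning.

Subtropical gyres are grid cells with climatological nutricline depth
> 150 m inside fixed longitude blocks (North Atlantic 90°W–5°W, North
Pacific 120°E–100°W, South Atlantic 60°W–10°E, South Pacific
150°E–60°W, South Indian 30°E–150°E); the Pacific blocks wrap the
antimeridian and, because the two Pacific blocks overlap in longitude,
blocks named North/South are additionally restricted to their
hemisphere when latitude is available. Gyre anomalies are per-gyre
medians (means optional) minus the unweighted cross-gyre mean of those
medians, so fully reported variables have zero-sum anomalies; gyres
missing a variable are flagged and excluded from the mean. Global
observations are restricted to the top 30 m before comparison.

## The synthetic cruise: what it emulates, and what it does not

The generator reproduces the *structure* the analysis depends on:

* a constant-speed northward transect (default 238 stations, 31°S to
  19°N at 0.0703° lat h⁻¹ ≈ 3 h sampling, ~30 days — representative of
  a basin-crossing hydrographic section) with monotone timestamps and
  solar local hours;
* piecewise-linear latitudinal SST and nutricline maps with the
  basin's negative SST–Z_nut coupling (gyre: cool, Z_nut up to 129 m;
  north of 12°S: > 29 °C, Z_nut ≈ 61–62 m);
* POM baselines linear in nutricline depth (default; an SST-driven
  mode exists so predictor-discrimination tests have a known answer),
  with coefficients chosen so regional mean ratios land near observed
  basin values (gyre C:P ≈ 150, C:N ≈ 7.6; northern regions ≈ 127/7.1);
* multiplicative diel modulation with region-dependent fractional
  amplitude (smallest in the gyre; POC strongest) and element peak
  hours (POC and POP near dusk at 18:00, PON at 03:00);
* triplicate lognormal noise with mean 1 and configured CV (default
  0.05, a realistic analytical spread for these assays).

Profiles embed the configured nutricline exactly (nitrate ramps
linearly at 0.1 µM m⁻¹ through 1 µM at Z_nut), are mixed to 40 m with
a 0.08 °C m⁻¹ thermocline below, and have EOS-consistent σ_t. A
salinity-stratified option and the `make_blt_profile` constructor
produce barrier layers with analytically known MLD/ITL for round-trip
tests.

Not emulated: monsoon or Indian Ocean Dipole dynamics, mesoscale
variability, spatially correlated measurement error, gaps or
station-spacing irregularity, and any realistic covariance between the
diel phase of different elements and the environment. Consequently the
parameter-recovery tests demonstrate that the *estimators* are correct
and calibrated under the stated noise model — not that real-ocean
residual spectra are this clean. In particular, the ratio diel ranges
(C:P, C:N, N:P) are emergent from the configured element cycles rather
than independently set, so they are order-of-magnitude realistic
rather than matched to any specific field estimate.

## Numerical conventions and degenerate inputs

* All threshold crossings: first crossing scanning from the surface,
  ties broken shallow, linear interpolation, undefined (not an error)
  when the target is never reached, `InsufficientDataError` when the
  inputs cannot support the computation at all.
* σ_t monotonicity is not assumed; only the first crossing is used.
* The SST correction polynomial is evaluated exactly as printed;
  inputs outside −2…40 °C warn but still evaluate. Its derivative is
  positive on that range (asserted numerically in tests).
* p₁ ≥ 0 and p₂ ∈ (−π, π] are enforced to make the sinusoid
  parameterisation identifiable.
* Max-normalisation refuses zero maxima; constant x refuses a slope.
* Seeds: every stochastic component (generator, sampler) takes an
  explicit integer seed and is bit-reproducible; output CSVs carry the
  package version, seed and a config hash in a commented header.

## Problem sizes

Default test and reproduction sizes — 238–240 stations, 20 replicate
cruises for noisy recovery, 4 × 10,000 MH steps, 10⁵ Monte-Carlo draws
for error propagation, 1000 null simulations for ANOVA calibration —
were chosen as the smallest sizes at which the statistical tolerances
(±15% recovery, 3 MC standard errors, binomial CIs) are comfortably
resolvable; the full suite runs in well under a minute on one core,
apart from the ANOVA calibration (~4 s) and MH calibrations (~1 s).

## Known limitations

* The moving-average detrending attenuates the diel signal whenever 8
  samples do not span close to 24 h (see above); amplitude estimates
  from irregularly spaced transects carry that bias.
* The delta-method ratio sigmas degrade beyond CV ≈ 0.2; POP near the
  detection limit can exceed that.
* The MH sampler is a teaching-grade random-walk implementation —
  adequate for 3-parameter regressions, not a general-purpose PPL.
* Gyre selection is purely longitude-block + nutricline-threshold;
  no dynamic gyre boundaries.
* No netCDF input; real hydrographic data must be converted to the
  tidy CSV dialects (a column map for exchange-format bottle files is
  provided in `pomstoich.io`).
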