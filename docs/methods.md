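# Methods

## Physical model

The measured quantity in GASMAS is the equivalent gas pathlength: the mean
distance detected photons travelled through the gas phase inside a
scattering object. Both laser channels are treated as single, isolated
absorption lines with a Voigt profile — the convolution of Doppler
(Gaussian, σ_G = ν₀·√(k_B·T/(m·c²))) and collisional (Lorentzian, HWHM
scaled linearly with total pressure from the tabulated 1 atm value)
broadening — evaluated with the Faddeeva function
(`scipy.special.voigt_profile`). Line-strength temperature scaling is out of
scope: the whole protocol runs in a single ambient-temperature regime.

All inversions use the **peak** (line-center) absorbance rather than the
integrated area. Peak and area differ only by the fixed profile value
φ_V(0), and both simulation and inversion use the same convention, so the
choice does not bias recovery; it matches referencing everything to a quoted
peak absorption coefficient.

Water-vapor hygrometry uses the Buck (1996) over-liquid formula without the
pressure enhancement factor (< 0.5% at ambient conditions), restricted to
173–373 K; outside that window the code raises rather than extrapolates.
The O₂ mole fraction is defined on the **dry-gas basis**: the reference
number density is (P − e_w′)/(k_B·T), because delivered gas concentrations
are specified before humidification.

### Packaged line fixtures

`src/gasmas/data/spectral_lines.txt` ships one line per channel
(H₂O at 12195.16 cm⁻¹ ≈ 819.97 nm; O₂ A-band at 13091.75 cm⁻¹ ≈ 763.84 nm)
with HITRAN-plausible, rounded strength and broadening values. With the
packaged H₂O line, saturated vapor at 293 K / 1 atm has peak
μ_a ≈ 3.05×10⁻⁵ cm⁻¹. Every operation accepts caller-supplied
`SpectralLine` objects, so nothing is tied to the fixture.

## Synthetic scan generator

The generator emulates the bench campaign, not the instrument electronics:
direct-absorption sweeps are produced on a 512-point grid over ±0.6 cm⁻¹
(the wavelength-modulation/2f demodulation chain of the real instrument is
deliberately out of scope). Per channel,

    I(Δν) = I₀ · B(Δν) · T_tissue · exp(−μ_a(Δν) · L_cm) + ε(Δν)

with:

- `B`: quadratic injection-current ramp, 1 + 0.20·x + 0.05·x² on the
  normalized sweep coordinate (fixed, documented; real ramp shapes are
  instrument-specific).
- `T_tissue`: a single scalar per configuration, exp(−μ_eff·d) with
  μ_eff = √(3·μ_a·(μ_a+μ_s′)) from the muscle row of the phantom
  optical-property table at the phantom's wavelength set and thickness
  d ~ U(5, 25) mm. Collapsing the tissue stack to one diffusion-theory
  scalar reproduces the attenuation-vs-geometry phenomenology without
  photon-transport simulation (a non-goal).
- `ε`: Gaussian noise with standard deviation
  √((noise_rel·I)² + (dark_noise·I₀)²). The multiplicative term
  (default 10⁻⁵, typical TDLAS absorbance sensitivity) sets the baseline
  absorbance noise; the absolute dark-noise term (default 10⁻⁹ of channel
  power) is what makes the fitted-line SNR fall with tissue transmission,
  so strongly attenuated configurations fail their fits — with purely
  multiplicative noise, transmission would cancel out of the absorbance
  entirely and no configuration could ever be undetectable.

True pathlengths are drawn once per configuration from U(0.01, 0.20) m —
the upper edge deliberately below the 0.23 m outlier bound so honest
inversions rarely trip the filter — and reused across all four gas batches
(the constant-pathlength design assumption). Two of the 30 configurations
(configurable) are assigned a transmission far below the detectability
floor to populate the failed-inversion/outlier class. Duplicated detector
positions (10, 11) and (14, 15) within each illumination mode share one
truth draw, mirroring repeat placements at the same spot.

Gas batches are administered in order 21 → 30 → 50 → 100% O₂. The optional
mixing model `effective[k] = (1−β)·nominal[k] + β·effective[k−1]`
(anchored at air) emulates incomplete purging of the lung cavities; at
β = 0.2 the 100% batch is effectively 89.1% and the 30% batch 28.2%, which
reproduces the observed direction — near-nominal estimates at 21/30% and a
notable underestimation at 100%.

Determinism: each record's RNG seed is the first four bytes of a SHA-256
hash of (master seed, config id, replicate, concentration, channel), so any
single record — or the full dataset — regenerates bit-identically.

### What the generator does not emulate

Photon transport (pathlength distributions, geometry-dependent sampling
volumes), spectral baseline etalons/fringes, source wavelength jitter,
detector nonlinearity, and the time-multiplexed lock-in chain. Passing
tests therefore demonstrate correctness of the inversion and statistics
under the stated noise model, not robustness to every artifact of real
bench data.

## Absorbance extraction

Each sweep is fit with the multiplicative model
I(Δν) = B(Δν)·exp(−A·ψ(Δν)), where ψ is the unit-peak Voigt shape of the
target line at the ambient conditions and B a polynomial (default order 2,
on a scaled abscissa for conditioning). The fit is solved by variable
projection: for fixed A, B is a linear least-squares solve (3×3 normal
equations); the scalar A is minimized by bounded Brent search on
[−10⁻³, 0.5] with 10⁻¹² absolute tolerance. Slightly negative trial values
are allowed so zero-gas scans are not biased upward; a minimizer below
−10⁻⁶ is reported as non-converged and clipped to 0. Two signal-to-noise
figures are reported: the classic per-point ratio (line depth over residual
RMS) and the detection SNR — the fitted absorbance divided by its standard
error from the linearized fit covariance. Validity thresholds the detection
SNR at 3 (the 3σ detection-limit convention, configurable). The distinction
matters: a full line-shape fit averages hundreds of points, so its amplitude
precision is ~an order of magnitude better than the per-point noise, and
thresholding on the per-point ratio would censor replicates of weak-but-
recoverable lines in a way that correlates with their noise — biasing the
surviving replicate means upward. A failed 820 nm fit maps to pathlength 0 —
the same class the 0 m outlier rule removes. The fitter never raises on
noisy data.

## Statistics

- **Outlier rule**: pathlength ≤ 0 (+10⁻¹² m tolerance) or strictly
  > 0.23 m. 0.230 m is retained; 0.231 m is flagged. Outliers are excluded
  from the per-configuration means (the only reading that keeps aggregated
  means inside the physical range); sample SD uses the n−1 denominator.
- **Two-sample KS test** (from scratch): D is computed in exact integer
  arithmetic as max |n₂·F̂₁ − n₁·F̂₂|/(n₁·n₂) over the pooled sample. The
  p-value uses the exact permutation null — integer lattice-path counting
  of orderings staying inside the band — when max(n₁, n₂) ≤ 16 and the
  data are tie-free, and otherwise the asymptotic Kolmogorov series
  p = 2·Σ(−1)^(k−1)·exp(−2k²λ²) with Stephens' finite-sample correction
  λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = n₁n₂/(n₁+n₂), truncated at terms
  < 10⁻¹⁰. The hybrid exists because the asymptotic series is genuinely
  poor for tiny samples (for n₁ = n₂ = 2 with full separation the exact p
  is 1/3 versus 0.097 asymptotic); the pipeline's 21-vs-21 comparisons use
  the asymptotic branch. p > 0.05 ⇒ "comparable" (statistically
  indistinguishable pathlengths). No multiple-testing correction is applied
  across configuration pairs by default, matching the protocol's practice;
  `holm_adjust` is available for users who want family-wise control.
- **Box statistics**: type-7 (linear-interpolation) quantiles, 1.5·IQR
  whisker fences, flier values listed explicitly.

The constant-pathlength check runs all six pairwise KS comparisons between
the four concentration groups of each configuration and reports the
fraction of comparisons with p > 0.05. Under the null (identical truth per
configuration) individual 5%-level tests leave ~95% of comparisons passing;
requiring all six to pass per configuration would cap the per-configuration
rate near 74% even for a perfect implementation, so the rate is defined per
comparison.

## Problem sizes and numerical choices

Default analyses use the full design (30 × 21 × 4 × 2 = 5040 scans,
2520 inversions), which simulates in ~1 s and inverts in ~4 s on one core;
the exhaustive KS permutation oracle runs all sample-size pairs
n₁, n₂ ≤ 6 (two randomized datasets each, 72 total). Scan grids place 512
points over ±0.6 cm⁻¹; wide-grid line-integral checks use ±20 cm⁻¹, where
the Lorentzian wings leave < 0.4% of the area outside. Intensities are
floored at 10⁻¹² of channel power after noise (flagged when clipping
occurs). YAML `RunConfig` files round-trip losslessly and the pipeline
manifest hashes every artifact, so reruns are verifiable byte-for-byte.

## Known limitations

Single-line, single-temperature spectroscopy; scalar tissue attenuation
(no geometry-resolved light transport, so "transmittance" and "remittance"
differ only through their drawn parameters, not physics); idealized
direct-absorption detection; the constant-pathlength and shared-pathlength
assumptions are taken as exact, as the protocol assumes. Real-data
ingestion (instrument-native formats) is out of scope; the JSONL/CSV
interfaces are the extension point.
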