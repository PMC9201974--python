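# Methods

This note records the physical model behind `phantomqc`, the numerical
choices that shape its results, the default parameters with their
rationale, and the known limitations — both of the analysis and of the
synthetic-data generators.

## 1. Physical model

### 1.1 Geometry

All transport calculations treat the phantom as a homogeneous turbid
slab of thickness d (default 2 cm), illuminated by a pencil beam at
normal incidence and observed in transmittance by a coaxial disc
detector on the exit face. Times are picoseconds, lengths centimetres.
The speed of light in the medium is cM = c0/n_in with
c0 = 0.0299792458 cm/ps.

### 1.2 White Monte Carlo

`simulate_white_dtof` traces photon packets with scattering only
(μa = 0, the "white" mode). Because a photon's geometric path length
after time t is exactly cM·t, absorption for any μa can be applied
afterwards as the Beer–Lambert factor exp(−μa·cM·t) per time bin
(`apply_absorption`). One simulation therefore serves every absorption
value — the basis of the lookup-table inversion.

Monte Carlo details:

- **Unit-weight packets, probabilistic boundaries.** Each photon
  carries weight 1 and every Fresnel interaction is sampled as a
  random reflect/transmit decision rather than a weight split. Every
  launched photon ends in exactly one outcome bucket (detected,
  transmitted-undetected, reflected, side loss, residual), so energy
  bookkeeping is exact to round-off and no roulette termination is
  needed.
- **Scattering.** Henyey–Greenstein phase function for g > 0, isotropic
  for g = 0. The default simulation runs at g = 0 with μs = μs′; the
  similarity relation (g, μs = μs′/(1−g)) ≈ (0, μs′) is verified by
  test at g = 0.9.
- **Detection-time quantization.** Arrival times are binned at the
  acquisition bin width, emulating TCSPC timing discretization. The
  absorbing validation variant (`simulate_absorbing_dtof`) attenuates
  each detected packet at its *binned* flight time (bin centre), so it
  equals `apply_absorption` of the white histogram bin by bin to
  ≤ 1e-12 relative — the discretization is shared, not hidden.
- **Reproducibility.** A counter-based generator (splitmix64-seeded
  xoroshiro128+) gives every photon its own deterministic stream;
  identical (seed, substream) inputs reproduce histograms bitwise.
  Higher-level code uses numpy `SeedSequence` spawning via
  `RandomStream.child`.

### 1.3 Diffusion oracle

`diffusion_slab_dtof` evaluates the time-domain diffusion solution for
the slab with extrapolated-boundary image sources: D = 1/(3μs′),
isotropic source depth z0 = 1/μs′, extrapolation length ze = 2AD with
the mismatch factor A computed from angular moments of the internal
Fresnel reflectance — the same boundary physics the Monte Carlo code
samples. A finite detector disc multiplies the plane-integrated flux
by (1 − exp(−r²/4Dvt)). Absorption again enters only as
exp(−μa·cM·t) at bin centres, so it factorizes exactly from the white
curve. `cw_slab_transmittance` is the closed-form time integral
(μa > 0), used as an internal consistency oracle; the time-resolved
curve integrates to it within 0.1%.

Diffusion theory is an approximation: against Monte Carlo it deviates
by a few percent near the rise and in the deep tail even at
μs′·d = 20. The package flags μs′·d < 5 as non-diffusive
(`meta["non_diffusive"]`) but still evaluates the series.

## 2. Inversion

`build_lut` tabulates white DTOFs over a μs′ grid (default 0.1 to
20 cm⁻¹ in steps of 0.1 — 200 entries, matching the stated resolution
of the method). Either engine can populate it: Monte Carlo (physical,
noisy) or diffusion (fast, noise-free). For inverting data that were
themselves produced by a forward model, the table should come from the
same family to avoid model-mismatch bias.

`fit_dtof` evaluates, per table node: convolve with the IRF, apply a
candidate μa, scale by an amplitude, and compute a Poisson-weighted
χ² = Σ w (data − model)², w = 1/max(counts, 1), over the fit window.
The amplitude is closed-form (A = Σ w·m·d / Σ w·m²); μa is found by
bounded scalar minimization per node; the off-grid μs′ is refined by
parabolic interpolation of χ² through the best node and its
neighbours, with linear interpolation of μa and amplitude. The fit
window runs from the last leading bin at or below 80% of the peak down
to the first trailing bin at or below 1% of the peak — the early rise
is dominated by IRF and non-diffusive light, the deep tail by noise
and background. Results carry `converged` (False at a grid boundary)
and `low_counts` (window sum < 1000) flags.

## 3. Mapping and QC statistics

- **Integral maps** normalize per-position DTOF integrals by the
  maximum over the central region (edge margin 10 mm by default, i.e.
  cells at least that far from the phantom outline), recording the
  reference cell.
- **Central statistics** report the maximum relative deviation from
  the central mean, the relative sample standard deviation, and the
  extreme cell position. The edge margin excludes the rim, where
  partial-volume roll-off dominates.
- **Imaging QC** uses the mean of the 21 brightest ROI pixels as the
  per-frame statistic (robust to small pointing shifts, insensitive to
  pixel permutation), first-frame normalization, the sample (n−1)
  standard deviation in percent, an ordinary-least-squares drift, and
  the fraction of frames within a ±2% band. Bleaching series are
  fitted with I(t) = A·exp(−kt) + B (k ≥ 0); the reported drop is the
  fitted first-to-last relative loss.
- **Spectra**: straight-line background anchored in ≥ 2 windows
  outside the dye band (a window-mean offset larger than 3× the pooled
  within-window residual scatter flags misplaced anchors), parabolic
  sub-sample peak localization, trapezoidal band intensity above a
  long-pass cut-on (interpolated start point), linearity onset as the
  first concentration deviating more than 5% from a through-origin
  reference slope fitted on the lowest two points, and
  piecewise-linear equivalent-concentration lookup (no extrapolation).

## 4. Default parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| n_in | 1.54 | typical cured methacrylate resin; always explicit so cM is well defined |
| g | 0 | simulation under the similarity relation; configurable |
| slab thickness | 2 cm | finger-like phantom scale |
| detector radius | 0.25 cm | representative fibre/collection optics; `inf` collects the full exit plane |
| acceptance half-angle | 90° | collect all transmitted photons by default |
| TCSPC bin width / range | 10 ps / 6000 ps | resolves a 35-ps IRF; covers the tail at these optical properties |
| IRF | 35 ps FWHM Gaussian | typical system response of a TCSPC transmittance setup |
| LUT grid | 0.1–20 cm⁻¹, step 0.1 | stated working range and resolution of the LUT method |
| fit window | 80% rise / 1% tail | excludes IRF-dominated rise and noise-dominated tail |
| ROI statistic | mean of k = 21 brightest | standard fluorescence-imager QC statistic |
| stability band | ±2% | pass band for normalized intensity series |
| edge margin | 10 mm | excludes the rim roll-off from homogeneity statistics |

Generator presets (`phantomqc.synthetic`):

| Parameter | Default | Rationale |
| --- | --- | --- |
| phantom truth | μs′ = 9.5, μa = 0.08 cm⁻¹ | mid-range tissue-like target |
| Lumogen-like dye | abs 762/55 nm, em 790/60 nm, stable | photostable perylene-diimide preset |
| ICG-like dye | abs 784 nm, em 805 nm; 4.5%/100-frame bleach; 10%/month dark, 30%/month daylight decay | programmed-instability preset |
| reabsorption strength | 0.25 OD per (µg/g) at band peak | calibrated so the concentration response departs from linearity (5% threshold) at ≈ 1.5 µg/g, the intended linear-range boundary |
| imager | 740 nm excitation, 800 nm long-pass, 0.35% frame noise, 0.5% warm-up (τ = 30 frames), two-Gaussian illumination, 96×128 frames | hand-held fluorescence imager emulation |

Problem sizes used in tests and in `scripts/acceptance.py` (10⁶-photon
oracle comparison, 20 noise seeds for recovery statistics, 100 seeds
for the homogeneity pass rate) are package choices balancing
statistical power against runtime (< 1 min on one CPU for the full
script).

## 5. Generator realism and limitations

The synthetic generators are validation instruments, not instrument
simulations. Deliberate simplifications:

- DTOF noise is per-bin Poisson on an IRF-blurred diffusion curve;
  real TCSPC adds afterpulsing, dead-time and background that are not
  modelled.
- Scan grids modulate a single base curve (intensity mode) or
  recompute the diffusion shape per anomalous cell (μs′ mode); real
  inhomogeneity is continuous, not cell-aligned, and the rim roll-off
  is a smooth sine stand-in for partial-volume effects.
- Imager frames use a static per-pixel texture, a common multiplicative
  per-frame fluctuation, and an additive noise floor; real cameras have
  shot noise, fixed-pattern noise and vignetting beyond the
  two-Gaussian illumination model.
- Dye spectra are Gaussian bands with a single-path inner-filter law
  10^(−k·c·ε(λ)); real spectra are asymmetric and the reabsorption
  path depends on geometry.
- The transport model is a homogeneous slab: layered or laterally
  structured phantoms, fluorescence re-emission transport, and
  polarization are out of scope.

Analysis limitations worth keeping in mind: diffusion-based LUTs
inherit the few-percent diffusion error when fitting Monte Carlo or
measured data (use the MC engine for those); parabolic χ² refinement
can bias μs′ by a fraction of a grid step when the χ² valley is
asymmetric; the bleaching fit assumes a single-exponential mechanism.
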