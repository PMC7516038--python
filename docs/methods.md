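# Methods

## Problem and scope

Whole-canopy gas exchange in multi-chamber systems measures growth as CO₂
flux, but growth differences between light treatments can arise from three
distinct mechanisms: how many photons the canopy intercepts (capture), how
efficiently absorbed photons drive gross CO₂ fixation (canopy quantum
yield), and what fraction of fixed carbon is retained as biomass (carbon use
efficiency). `canopyflux` computes all three from raw instrument streams and
provides a generator of synthetic experiments with known truth so the whole
chain can be validated without hardware.

## Gas-exchange processing

**Demultiplexing.** A single differential analyzer samples chambers in
rotation (defaults: 4 chambers, 30 s sampling, 40 s purge, hence a 280 s
revisit period). Purge-window readings are discarded. Within each 30 s
sampling window the first 10 s (`window_discard_s`) are treated as
equilibration of the shared tubing and discarded, and the remainder is
averaged to one record per visit. The within-window rule is a package
choice; any value shorter than the window is accepted.

**Sign convention.** ΔCO₂ is stored as pre-chamber minus post-chamber mole
fraction, so canopy uptake gives positive net flux and dark respiration
negative flux. Net flux is `flow · ΔCO₂ / ground_area` (µmol m⁻² s⁻¹). No
water-vapour dilution correction is applied: the package assumes the sampled
air streams are dried before analysis, which is how such systems are
typically plumbed.

**Daily period means.** Days are delimited by the lights-on event, not
calendar midnight. Means of net flux are taken separately over the light
(default 14 h) and dark (10 h) periods after excluding a 10 min
(`transition_exclusion_min`) window following each light switch, because
chamber CO₂ is not at steady state immediately after a transition; records
whose averaged sampling window straddles a switch are likewise excluded. A
chamber-day must retain ≥ 80% of its expected light and dark records or it
raises an incomplete-day error rather than reporting a biased mean.

**Daily carbon equations.** With period means in mol m⁻² h⁻¹:

- `P_gross = (P_net,light + |R_dark|) · photoperiod_h · area · g_per_mol` (g d⁻¹)
- `DCG = (P_net,light · photoperiod_h − |R_dark| · dark_h) · area · g_per_mol`
- `CUE = DCG / P_gross`

This assumes respiration in the light equals dark respiration — the standard
assumption in canopy photosynthesis work; the package does not model
light/dark respiration differences. The identity
`P_gross − DCG = |R_dark| · 24 h · area · g_per_mol` holds algebraically and
is enforced by property tests. The factor 30 g mol⁻¹ encodes a tissue carbon
fraction of 0.4 g g⁻¹ (12 g C per mol CO₂ / 0.4); it is a configurable
`CarbonConversion` field because carbon fraction varies with species and
tissue composition.

**Mass balance.** Predicted harvest dry mass is initial mass + Σ DCG; the
ratio to measured mass is the closure diagnostic of the gas-exchange record.

## Spectra

Integrals are trapezoidal on the native wavelength grid with band edges
linearly interpolated; the default generator grid is 380–780 nm at 1 nm.
Wavebands partition 400–750 nm contiguously as blue [400,500), green
[500,600), red [600,700) and far-red [700,750] — the discrete-nm labels
(501–600, 601–700) conventional in the field denote the same partition — so
waveband fractions sum to 1 exactly. Daily light integral is
`PPFD × photoperiod × 3600 × 10⁻⁶` mol m⁻² d⁻¹ (350 µmol m⁻² s⁻¹ × 14 h =
17.64).

Phytochrome photoequilibrium is
`PPE = ∫N σ_r dλ / ∫N (σ_r + σ_fr) dλ`. The bundled coefficient table is a
**synthetic** Gaussian parameterization of the P_r/P_fr photoconversion
cross-sections (P_r peak 665 nm, P_fr peak 730 nm, equal blue lobes),
calibrated to canonical photoequilibrium behaviour — ≈ 0.9 under
monochromatic red, ≈ 0.5 under blue, strongly reduced under far-red-enriched
light. It reproduces the expected ordering and magnitudes across the bundled
treatments (high for red/blue, lowest for white + far-red) but is not a
measured dataset; users substitute measured tables via the
`wavelength_nm,sigma_r,sigma_fr` CSV interface. PPE and leaf photon
absorption are invariant to uniform spectrum scaling by construction.

## Photon capture

**Ground cover.** A pixel is classified as plant tissue iff G > R, G > B and
G > 0.15 of full scale. The rule is deliberately simple, documented and
swappable (threshold and ROI are arguments); it is exact on the generator's
images and adequate for well-lit nadir photographs of green canopies against
non-green substrate, but will misclassify strongly anthocyanic or senescent
tissue.

**Leaf-area interpolation.** Young canopies hold roughly one leaf layer, so
projected (covered) area estimates total leaf area. Between the young-canopy
phase and harvest, total area is interpolated by an exponential fit — OLS of
ln(area) on time — through the young-canopy projected areas plus the measured
harvest total. By default the final 7 days are treated as the overlap phase
and excluded from the fit's "young" points (`young_days`), since such
canopies typically begin overlapping about a week before harvest; this is a
package decision and is configurable.

**Beer–Lambert correction.** The extinction coefficient is anchored per
treatment at `k = −ln(1 − a)` from that treatment's spectrum-weighted
single-leaf absorption `a`, so one layer reproduces `a` exactly (the
round-trip is a property test at 1e-12). Within-cover absorption with L
layers is `1 − e^(−kL)`; the correction is applied only on days where
interpolated total area exceeds projected area, with layers floored at 1.
Capture = cover × within-cover absorption, hence capture ≤ cover ≤ 1 and
capture is monotone in cover, absorption and layers. No leaf-angle
distribution or 3-D radiative transfer is modelled; chambers are assumed
laterally reflective so a 1-D extinction law is appropriate.

## Quantum yield

P_gross (g d⁻¹) is converted to mol CO₂ per mol incident photons by dividing
by `g_per_mol`, the chamber area and the daily light integral; quantum yield
divides that by capture. Chamber area cancels through the chain, which is
asserted as an invariance test. The daily-mean aggregate excludes the first
7 days (`seedling_days`) because cover — the denominator — is smallest and
relatively least reliable there; the regression-through-origin slope of
P_gross,incident on capture is reported alongside as an alternative
estimator. The mature-plant CUE aggregate uses the final 6 days before
harvest (`cue_window_days`). The "common slope" assessment of the
P_gross-vs-capture regressions is a descriptive diagnostic (maximum pairwise
relative slope difference, optional bootstrap slope SEs), not a significance
procedure.

## Synthetic experiments

The generator emulates the study conditions end to end and records truth for
recovery tests.

- **Spectra.** Gaussian-mixture LED spectra; component weights are solved by
  nonnegative least squares so waveband fractions hit the treatment targets,
  then normalized so the 400–750 nm integral equals total PPFD exactly. The
  four bundled treatments (red/blue and white backgrounds, each with or
  without 50 µmol m⁻² s⁻¹ far-red substitution at equal 350 µmol m⁻² s⁻¹
  total and 31.5% blue; white green:red 45.2:23.3) reproduce their printed
  fractions within ±0.3 percentage points.
- **Leaf absorptance** is a chlorophyll-like synthetic curve: high blue/red
  absorptance, a Gaussian green dip, logistic red-edge decline to a low
  far-red level. Far-red-grown leaves get a lower peak, deeper dip and lower
  far-red absorptance (thinner, chlorophyll-diluted leaves), yielding
  spectrum-weighted absorptions near 0.93 (RB), 0.82 (RB+FR), 0.84 (white),
  0.72 (white+FR).
- **Growth** is logistic in total leaf area (early phase exponential,
  consistent with the pipeline's interpolation assumption): defaults
  A₀ = 0.004 m², r = 0.2817 d⁻¹, K = 0.6 m² for an 18-day run in a 0.17 m²
  chamber, reaching near canopy closure. Projected area equals total area
  until an overlap-onset area (0.08 m²), then saturates smoothly toward the
  chamber area, so leaf layers grow past 1 (≈ 1.7–2.3 at harvest). The
  far-red expansion multiplier (default 1.164 on r) is calibrated to a
  final-leaf-area ratio of ≈ 1.43 versus control.
- **Physiology.** True quantum yield 0.057 mol CO₂ per mol absorbed photons,
  spectrally flat across treatments; mature CUE 0.61, ramped from 0.40 over
  the first 10 days to emulate the seedling-phase rise. Respiration is set
  from the effective CUE by `resp = photoperiod · gross · (1 − CUE) / 24`,
  which makes the daily equations recover CUE exactly on clean data. Gross
  flux is `QY · PPFD · capture`, with capture computed from the same
  cover/Beer–Lambert model the pipeline uses.
- **Stream.** ΔCO₂ = flux · area / flow with i.i.d. Gaussian noise
  (default SD 0.5 µmol mol⁻¹ — a plausible differential-IRGA figure; no
  instrument spec is assumed) at 1 Hz, multiplexed by the sampling schedule;
  air flow ramps linearly from 11 to 37 mmol s⁻¹ over the run as real
  operators do to keep chamber drawdown in range. Purge-window seconds carry
  a contaminated mixture of adjacent chambers' signals, so a pipeline that
  failed to discard them would be visibly biased.
- **Images.** Green ellipses on a soil-colored background, placed until the
  realized green fraction is within 0.002 of the requested cover (the final
  ellipse is bisected in scale); texture noise is kept small enough never to
  flip the pixel classifier.

All randomness flows from a single seed (`numpy` `default_rng` /
`SeedSequence`); identical seeds give byte-identical streams and images.

**What the generator does not emulate.** Real leaves are not ellipses;
cover estimation error on real photographs (shadows, specular highlights,
substrate vegetation) is larger than the renderer's ±0.01. Gas-exchange
noise is i.i.d. Gaussian, with no drift, no CO₂-control-loop dynamics and no
pressure transients. Growth is a deterministic logistic with no day-to-day
weather in it, and quantum yield/CUE are constant (after the seedling ramp)
rather than responding to canopy microclimate. Passing recovery tests
therefore demonstrates the correctness of the computational chain under the
stated measurement model, not robustness to every field artifact.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use 18-day runs at 1 Hz (≈ 1.5 M
stream rows per 4-chamber experiment) with 200×200 px images — the package's
reference configuration, which generates in ~2 s and analyzes in < 1 s.
Noise-free recovery of P_gross and CUE is exact to < 0.5% (limited only by
window averaging); with default noise and image-based cover, recovered
quantum yield stays within ~1% of truth because the cover and interpolation
errors are small and nearly unbiased after the seedling window. Degenerate
inputs raise errors rather than returning NaN: zero total flux
(fractions/PPE/absorption), non-positive flow or area, absorption outside
(0,1), capture 0, P_gross 0, zero-variance regressors, incomplete days.

## Known limitations

- PPE from the synthetic coefficient table approximates, but cannot
  reproduce, values computed from measured photoconversion cross-sections;
  chlorophyll screening within leaves is explicitly out of scope.
- The exponential interpolation of total leaf area slightly underestimates
  late-phase leaf layers when growth has begun saturating; the effect on
  capture is damped by the Beer–Lambert saturation but is the dominant
  residual error in quantum-yield recovery.
- Whether capture should exclude far-red for non-far-red treatments is a
  definitional choice; the package uses the spectrum-weighted full 400–750 nm
  absorption throughout, so treatments are compared on a common photon basis.
- No treatment-statistics layer (ANOVA/mean separation) is included; the
  report is descriptive.
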