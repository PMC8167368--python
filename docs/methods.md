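# Methods

This note documents the model implemented in `spatialvision`: its equations
and assumptions, the parameters that matter, the synthetic-scene generator
and what it does and does not emulate, the numerical choices, and known
limitations.

## Contrast sensitivity over frequency, eccentricity and colour

Detection threshold (Michelson contrast) for channel-specific parameters:

    t(f, E) = t0 · exp( (f/f0) · (E + E2)/E2 ) · L(f),
    L(f)    = 1 + α / (1 + (f/f1)²).

| parameter | Achr | BY | RG | meaning |
|---|---|---|---|---|
| t0 | 0.0051 | 0.0051 | 0.0082 | threshold amplitude |
| E2 (deg) | 6.22 | 6.22 | 1.82 | eccentricity doubling constant |
| α | 5.26 | 5.26 | 2.53 | low-frequency threshold weight |
| f0 (cpd) | 4.51 | 4.51/6 | 5.37 | high-frequency decline constant |
| f1 (cpd) | 0.32 | 0.32 | 0.94 | low-frequency decline constant |
| g | 2.5 | 1 | 2 | linear filter gain |

The plateau form `L = 1 + α/(1 + (f/f1)²)` is one of several typographically
plausible readings of the published expression; it was chosen because it
produces a low-frequency roll-off to an eccentricity-independent plateau of
`t0·(1+α)` and the band-pass shape expected of the luminance channel. The
blue–yellow channel reuses the achromatic α and f1, since only its
high-frequency constant and gain are stated to differ. The gain g does not
enter the empirical threshold surface; it enters only transducer
calibration, where contrast and threshold always appear as g·c and g·t.

Acuity (t = 1) is found by bracketed root-finding on log-threshold
(tolerance 1e-6 cpd); log-threshold is monotone in f above the plateau so
the bracket is safe.

## Filter bank

Each channel's complement holds four orientations (0/45/90/135° from
vertical) at octave-spaced peak frequencies — the finest at acuity/3, i.e.
divisors {3, 6, 12, 24} of the local acuity, four scales for luminance and
three for chroma — plus an unoriented low-pass residual. Frequency profiles
are Gaussian in log2 frequency with 2σf = 1.4 octaves; orientation profiles
are raised cosines with exactly 45° full width at half maximum on support
±45° (the printed orientation constant is inconsistent with the stated 45°
bandwidth; the bandwidth statement wins). With 45° spacing the four
orientation profiles tile to unit total gain, and a filter is blind to the
orthogonal orientation.

Eccentricity scaling is discretized: the finest peak frequency is quantized
onto a global lattice of 1/8 octave (configurable, at most 1/4), and zone
boundaries fall where any channel's lattice index changes — so adjacent
zones' peaks differ by at most one step, far below the 1.4-octave bandwidth.
Because band ladders are exact octave divisions of lattice values, the same
physical filter recurs across zones and is computed once per image
(frequency-domain product, complex response via the analytic-signal
half-plane; magnitudes equal Michelson contrast for gratings, phase is the
local phase). The low-pass residual gain is max(0, 1 − Σ band gains) below
the finest band's peak, guaranteeing no spectral hole.

Images are mirror-padded by half the coarsest wavelength before filtering;
for FFT-periodic synthetic scenes a periodic ("wrap") mode is exact and is
used by the scene-statistics analyses.

Opponent coordinates come from CIELAB: Achr = (L* − mean)/mean,
RG = (a* − mean)/100, BY = (b* − mean)/100, with the means kept as DC terms.
The 1/100 chroma scaling is a convention chosen so that a full-range
achromatic sinusoid has contrast ≈ 1, matching the filter normalization; the
original scaling is not published.

## Transduction, calibration, attention

    d'θ = Rmax_eff · (g c_θ)^(p+q) / ( z^p + Σθ' (g c_θ')^p ),   Rmax = 30, p = 2, q = 0.4.

The orientation sum contains the target's own response plus the other
orientations at weight w_x (default 1 — deliberately unrealistic, matching
the source model's acknowledged over-strong cross-orientation masking; the
weight is exposed). z is set per (zone, channel, band) by inverting the
mask-free transducer at the empirical threshold and criterion d' = 2:
z^p = (Rmax/d')(g t)^(p+q) − (g t)^p. The low-pass residual calibrates at
the plateau threshold t0(1+α), identical at all eccentricities. Attention
withdrawal multiplies Rmax by 0.75 (effective 22.5) with z frozen: a
response-state change, not a re-calibration. Responses pool across scale —
the band scales plus the low-pass residual — with an M-norm, M = 4; the
cross-frequency response is the maximum of the pooled values over channel
and orientation. Accuracy is Φ(d'/2) − Φ(−d'/2).

Because the orientation pool includes the 45° neighbours (gain 0.5 to the
target's orientation), simulated grating thresholds sit ~5–9% above the
closed form even at band peaks; the calibration deliberately ignores these
terms, as thresholds are established without masks. Between band peaks the
quantized complement deviates more (up to ~±35% at plateau frequencies or
above the finest peak, where detection is mediated off-peak); the
self-consistency tests therefore compare at the frequencies the bank
actually represents.

## Simulated experiments

*Thresholds.* Stimulus contrast is adjusted (Newton in log contrast,
numerical derivative, bisection fallback, ≤50 iterations) until the peak
cross-frequency response equals d' = 2 within 0.01. The linear front end is
computed once at unit contrast and rescaled inside the iteration. The probe
region is confined to within one envelope σ (at most 0.5°) of the stimulus
centre: a wider probe would read out mechanisms centred at lower
eccentricities. CSF simulations use vertical Gabors with envelope
σ = clip(3/f, 0.25°, 4°); vertical gratings continue exactly under mirror
padding, so the generous vertical extent is free. Acuity is extrapolated by
regressing plateau-corrected log threshold (log t − log L) linearly against
f over the simulated points and solving t = 1 — the parametric form of the
exponential limb, which is robust to the few-percent calibration ripple that
wrecks a naive two-point extrapolation.

*Dippers.* Increment thresholds use a response-difference criterion
(Δd' = 2 between pedestal-plus-increment and pedestal, at the target-centred
probe); pedestal and target share tuning and phase; an optional orthogonal
mask at the same frequency superposes on both intervals.

*Apparent blur.* β = m / R̄, with m the least-squares slope of the per-scale
luminance response (maximum over orientation of band d') against ln f_peak
and R̄ the M-norm across bands; β = 0 when R̄ = 0. Probe responses average
over ±0.25° vertically at the edge's centre column. The eleven-level
Gaussian-blur edge series spans 0–12 arcmin: within that range β falls
monotonically with blur at every test eccentricity {0, 8.3, 16.7, 24, 32,
40}°; beyond ~13 arcmin even the coarsest foveal filters stop responding and
the statistic folds back toward zero, which is why the series stops there.
β-versus-blur curves are fit with a three-parameter Gaussian (amplitude,
width, offset; width reported as its absolute value since it enters
squared); fovea/periphery matches invert the foveal curve at the peripheral
β, clamped and flagged outside its range. The blur experiments run on a
dedicated horizontal strip, 0–42° at 32 px/deg.

*Attention elevation.* Mechanism-level: z from the closed-form threshold at
the attended Rmax, thresholds re-solved through the transducer at both Rmax
values. For a single mask-free mechanism this inversion coincides exactly
with the Newton threshold search. Elevation is bounded analytically between
(4/3)^(1/(p+q)) − 1 ≈ 12.7% (linear regime) and (4/3)^(1/q) − 1 ≈ 105%
(saturated regime); the foveal luminance complement's median comes out near
17%.

## Scene statistics

The visible image weights each filter's band-limited contribution (real part
of the complex response) by its accuracy, sums over bands, orientations and
the residual, and divides zone-wise by the bank's composite transfer
max(T, 1) — the analysis gains overlap (~1.6 at band peaks), and without
this synthesis normalization fully-visible content would come back
overweighted; content above the local finest scale stays attenuated. DC
means pass through; conversion to RGB clips to the sRGB gamut and logs the
clipped fraction; HSV derives from the clipped RGB.

Midline sampling windows are circular, at 1° steps: the scaled rule
r = k0(1 + E/E2_attn) + kc with k0 = 5 arcmin, E2_attn = 0.34° (attention
spotlight scaling; distinct from the CSF E2) and kc = 1°; the fixed rule
r = 3.75° (taken literally — the stated derivation as a median of the scaled
window does not reproduce it from the stated constants). Saturation
quantiles {0.5, 0.75, 0.9, 0.95, 0.99} use all window pixels; hue entropy
uses 256 half-open bins over pixels with saturation > 0.2 and is *undefined*
(excluded, not zero) when no pixel qualifies; edge density is the fraction
of pixels with filter completeness FCθ = Π accuracies > 0.96 at any
orientation, luminance channel only; β is averaged per window. Windows
extending outside the field are flagged invalid and excluded from summaries.
Parafoveal/peripheral summaries average E < 5° and E > 15°; the unattended
β is additionally reported multiplied by the attention factor (the
statistic's normalization otherwise cancels the response reduction —
in this implementation d' scales exactly linearly with Rmax, so raw β is
attention-invariant).

## Synthetic scenes

The generator emulates colourful panoramic photographs *statistically*:

- HSV value: 1/f^1 Gaussian field (std 0.30 around 0.55, clipped to
  [0.02, 0.98]) plus 12 embedded oriented step edges (blur 0.5–8 arcmin,
  amplitude 0.15–0.30, random positions/orientations under a broad window) —
  contrasts deep into the suprathreshold regime, as real panoramas are for
  this model.
- Saturation: rank-preserving Beta(2, 5) transform of a 1/f^2 field.
- Hue: piecewise palette (six hues by default) assigned by the argmax of one
  1/f^1.3 field per palette entry — piecewise constant, so a single-hue
  palette has exactly zero hue entropy.

Chromatic fields are steeper than the luminance field because chromatic
spectra of natural scenes fall faster than luminance spectra; with
equal-energy-per-octave chroma the periphery would necessarily lose the
chroma above its (much lower) chromatic coverage and no stationary
colourfulness profile could exist. All statistics are spatially stationary
and approximately self-similar; everything is deterministic given the seed.
Scenes are FFT-periodic, so the analyses use periodic filtering (exact).

What the generator does *not* emulate: photometric realism, perspective and
sky/ground structure, occlusion edges, the luminance–chroma correlations of
real materials, and heavy-tailed contrast statistics. Passing stationarity
tests on these scenes shows the *model* introduces no strong eccentricity
artifact for scale-invariant input; it does not show that real panoramas are
statistically stationary (they are not — e.g. sky).

## Problem sizes

Scene analyses run at 512×512 px over the standard 32° square field (fixation
1° from the left edge, 16 px/deg), zoning step 1/4 octave; threshold and
blur experiments run on horizontal strips at 48 and 32 px/deg. These sizes
keep a full scene pass around ten seconds while leaving every band of every
channel resolvable; the construction is resolution-independent apart from
the Nyquist limit, which at 16 px/deg grazes the foveal finest luminance
band (peak 8 cpd) and slightly weakens near-foveal fine-scale responses.

## Known limitations

- Cross-orientation masking at w_x = 1 is far stronger than human masking;
  broadband content self-suppresses, so re-running the model on its own
  visible image shrinks broadband (but not narrowband) content by ~10% per
  pass, and a strong orthogonal mask can slightly *lower* the increment
  threshold at pedestals near the mask contrast.
- The low-frequency plateau is eccentricity-independent, so band-ladder
  thresholds are not scale-invariant: peripheral complements, living at
  lower frequencies, are relatively less sensitive. On the synthetic scenes
  this leaves a small negative eccentricity trend in edge density
  (≈ −0.5%/deg relative, borderline significant over twenty scenes) that no
  other statistic shows.
- Acuity above the finest band is mediated by the finest filter's Gaussian
  tail, which declines more slowly than the closed form's exponential;
  simulated thresholds well above the local finest peak undercut the closed
  form by up to ~2×.
- No optics, temporal factors, crowding, or perceptual organization; cone
  sampling is not modelled and CIELAB stands in for cone-contrast space.
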