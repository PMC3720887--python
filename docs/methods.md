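# Methods

## Forward model

A scene is a pair of non-negative maps on the pixel grid: in-focus
fluorescence `f(x,y)` and out-of-focus background `d(x,y)`, plus a
reduced scattering coefficient µs′ (cm⁻¹) and, optionally, the axial
offset `z` of a thin fluorescent sheet. Each phase frame is

    I_i = d/2 + f/2 · [1 + m_eff · cos(2π x / T + φ_i)],

with the grid along image x, period `T = 1000/(ν·pixel_size)` px
(rejected below 2 px), and phases fixed at (0, 2π/3, 4π/3). Only the
in-focus component is modulated; the background receives the DC half of
the pattern. The effective modulation depth factorizes as

    m_eff = m0 · T(ν̃) · A(µs′, ν̃) · I(z),

* `m0` — nominal pattern contrast (0–1);
* `T(ν̃) = 1 − 0.69ν̃ + 0.0076ν̃² + 0.043ν̃³` — the z-independent
  Stokseth in-focus transfer of the grid. It is what makes the measured
  modulation depth fall with frequency even in a clear sample; being
  constant in z it cancels from peak-normalized axial profiles and never
  affects section thickness.
* `A(µs′, ν̃) = exp[−µs′(0.02 + 0.05ν̃)]` — scattering attenuation of
  the grid contrast. No closed form for this exists in the regime of
  interest; the chosen exponential is the simplest form that is 1 in a
  clear medium, strictly decreasing in turbidity, and decreasing in
  frequency, reproducing the qualitative ordering seen on bench
  phantoms (µs′ = 0 vs 10 vs 20 cm⁻¹). Absolute attenuation values are
  instrument- and sample-specific and are not modeled.
* `I(z) = |2J₁(a)/a|`, `a = 4kz sin²(α/2) · ν̃(1−ν̃/2)` — the Stokseth
  axial response for a thin sheet at defocus z (below).

Noise is the standard CCD model: Poisson shot noise at `photon_scale`
expected photons per intensity unit, then additive Gaussian read noise,
then clipping at zero; a fixed generator seed makes every triplet
bit-reproducible. `photon_scale = mean_counts / intensity`, so a frame
of mean intensity 0.5 with `photon_scale = 1800` carries per-pixel SNR
√(0.5·1800) = 30.

## Optics: units, conventions, calibration

`OpticalConfig` carries NA (dimensionless, (0,1)), emission wavelength
(nm), magnification, and sample-plane pixel pitch (µm/px; default
1.5 µm/px as for a 4×/NA 0.1 objective on the reference system).
Frequencies are mm⁻¹ at the sample plane; ν̃ = νλ/NA.

Defocus convention: `u = 4kz·sin²(α/2)` with `α = arcsin(NA)` computed
exactly (no NA²/4 small-angle shortcut), and section thickness defined
one-sidedly as the first |z| where the peak-normalized response reaches
50 %. Under this convention the thickness is `a₀·λ/[8π sin²(α/2)·M]`
with `a₀ = 2.2151` (the jinc half-maximum argument) and
`M = ν̃(1−ν̃/2)`; for NA 0.1 and 520 nm this yields 36.6 µm at ν̃ = 1,
the calibration anchor, with 40.6 µm at 132 mm⁻¹ and 45.8 µm at
106 mm⁻¹ on the same curve. The crossing is located numerically by a
doubling bracket plus Brent refinement (well below 1e−3 µm), which is
equivalent to, and tighter than, grid-scan + bisection; the 1/M scaling
makes the product thickness×M a constant of the optics, a property the
tests enforce. The minimum over ν̃ ∈ (0,2) sits at ν̃ = 1 (M maximal);
the sidelobes of |2J₁(a)/a| peak near 0.13, so the 50 % crossing is
unique.

Resolution converters: USAF-1951 period 1000/2^(g+(e−1)/6) µm and
Rayleigh limit 0.61λ/NA.

## Reconstruction and estimators

Square law: `I_sect = (√2/3)·√Σ(pairwise differences)²`. For exact
three-phase sinusoids the squared differences sum to (9/2)B²
independently of position, so the output is exactly the modulated
amplitude `B = m_eff·f/2` (κ = 1/2 relative to `m_eff·f`). All
arithmetic is floating point regardless of input bit depth. The
widefield image is the phase average `A = d/2 + f/2`.

Modulation depth per pixel is the AC/DC ratio `m = I_sect/I_W`, clipped
to [0,1]; pixels with non-positive widefield intensity are flagged
invalid and excluded from the ROI median (the median, not the mean,
summarizes a region, and is meaningful where fluorescent targets are
present — the pipeline runner restricts its summary to pixels above
20 % of the ROI's peak sectioned signal for that reason). The tests pin
both reconstructions against an independent 3-point discrete-Fourier
cosine fit.

SNR: for per-frame noise std σ, the three-frame average has noise
σ/√3 and first-order propagation through the square law gives sectioned
noise σ√(2/3) (position-independent for 2π/3 steps), hence

    SNR_u = √3·Ī_W/σ,  SNR_s = √(3/2)·m·Ī_W/σ,  ratio = √2/m.

The ratio depends only on the measured modulation depth — not on
whether frequency or turbidity produced it — which is the design
insight the characterization reproduces. A Monte-Carlo empirical SNR
over seeded noise realizations validates the constants to a few
percent. Note the ratio is a first-order result: at very low m·SNR the
square law rectifies noise and the sectioned image acquires a positive
bias this formula ignores.

Axial profiles: sectioned ROI mean per z, peak-normalized, peak
re-centered to z = 0; thickness by linear interpolation to the 50 %
crossing on each side of the peak, averaged when both exist. At the
10 µm scan step the interpolation error is ≲0.2 µm, comfortably inside
the 2 % agreement with the closed form demonstrated across the whole
instrument frequency set at µs′ ∈ {0, 10, 20} cm⁻¹ (scattering scales
the profile but not its shape, so measured thickness is
turbidity-independent by construction — matching the bench finding).
Error bars mirror the bench procedure: the std of thickness over a 4×2
tile grid of sub-ROIs.

Frequency calibration: row-averaged, Hann-windowed, 8×-zero-padded
power spectrum along the pattern axis; dominant non-DC peak, local
log-quadratic sub-bin refinement, conversion via the pixel pitch.
Images whose best peak fails a 10× margin over the median spectral
floor are flagged and report frequency 0.

## Synthetic nuclei fields

`make_nuclei_scene` emulates a stained tumor surface: nucleus count
drawn Poisson at the requested density over the field, diameters
uniform in 5–15 µm (3–10 px at 1.5 µm/px), non-overlapping placement by
random sequential adsorption (largest first, 1 px edge clearance;
packing beyond the feasible fraction raises an error), each nucleus a
1 px linear-taper disk with peak intensity uniform in 0.7–1.0.
Ground-truth centers/diameters are recorded. The background map is
`background_level` (default 6) times the unit focal amplitude with a
±30 % large-scale (σ = 60 px) texture: in thick tissue the out-of-focus
volume contributes several-fold the focal layer's signal, which is
precisely the regime in which sectioning matters. Defaults µs′ =
10 cm⁻¹ (typical soft tissue).

What the generator does *not* emulate: nucleus shape irregularity and
intensity heterogeneity, touching/overlapping nuclei, stain uptake by
muscle and stroma, depth-dependent blur of the background, speckle.
Passing recovery tests therefore demonstrate the pipeline's behavior
under the stated two-component image model, not segmentation accuracy
on real tissue — where cluster splitting (an explicit non-goal) would
dominate the error budget.

## Segmentation

Pipeline: divide by the image maximum (optionally a robust percentile,
clipping to 1) → subtract a σ = 20 px Gaussian blur (the high-pass
residual keeps ≥60 % of a 3–10 px object's contrast while flattening
structure much larger than σ) → threshold the residual at 0.1 →
8-connected components → drop components under 3 px (sub-resolution
specks). Defaults are configurable. Components are labeled on the full
filtered image and attributed to the analysis ROI by centroid; this
matches the generator's center-in-ROI ground-truth convention and
avoids counting slivers of border-straddling nuclei. Density =
count/ROI area (350×350 px at 1.5 µm/px = 0.2756 mm²). Group
comparisons use the two-sided Wilcoxon rank-sum (exact enumeration for
combined n ≤ 12 without ties, normal approximation with tie correction
otherwise), significance at p < 0.05.

On noise-free sectioned input the pipeline recovers ground-truth counts
within ~5 % at the 3561 /mm² tumor benchmark (misses come from merged
close pairs and threshold-marginal dim nuclei); on widefield input with
the default 6× background, nucleus residuals after max-normalization
fall below the 0.1 threshold and counts collapse — the ordering that
makes sectioning necessary for in-situ density quantification.

## Problem sizes and determinism

Default analyses use 400×400 px fields (350×350 px ROI), five images
per group, 10 µm axial steps over ±2.2 predicted thicknesses, and
200-realization Monte-Carlo noise checks — sizes chosen so a full suite
plus demo runs in well under a minute on one core while keeping
sampling error far from every asserted tolerance. Every stochastic
element (scene layout, noise, Monte-Carlo) is driven by explicit
integer seeds recorded in output sidecars; two runs from the same
config+seed are byte-identical.

## Known limitations

* The Stokseth thin-sheet model predicts ~121 µm at the 31.7 mm⁻¹
  operating point, ~6 % below the 128–129 µm a real instrument measures
  there; the model value is reported as-is.
* ν̃ = 1 corresponds to NA/λ = 192.3 mm⁻¹ at 520 nm (sometimes rounded
  to 191 mm⁻¹ elsewhere).
* The √2/m SNR ratio is first-order; empirical ratios at very low
  modulation exceed it.
* Scattering attenuation is qualitative (ordering and monotonicity
  only); no photon-transport simulation is attempted, and µs′ =
  20 cm⁻¹ behavior is a monotone extension.
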