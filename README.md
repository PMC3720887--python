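# simsect

Structured-illumination optical sectioning for thick, turbid fluorescent
samples: forward simulation, three-phase square-law reconstruction,
system characterization, and nuclear-density quantification.

## The problem

Widefield fluorescence microscopy of intact tissue drowns the focal
plane in out-of-focus background. Structured illumination microscopy
(SIM) projects a sinusoidal grid

    S_i(x) = 1/2 [1 + m cos(2π ν x + φ_i)],   φ_i ∈ {0, 2π/3, 4π/3}

so that only in-focus fluorescence `f(x,y)` is modulated while the
out-of-focus background `d(x,y)` is not:

    I_i = d/2 + f/2 [1 + m cos(2π ν x + φ_i)].

Square-law detection on the three phase-shifted frames rejects the
background and recovers the focal plane:

    I_sectioned = (√2/3) √[(I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²] = m f / 2
    I_widefield = (I₁+I₂+I₃)/3 = d/2 + f/2

Choosing the grid frequency is a trade-off. The Stokseth approximation
of the defocused OTF gives the axial response `I(u) = |2J₁(a)/a|` with
`a = 4kz sin²(α/2) · ν̃(1−ν̃/2)` and `ν̃ = νλ/NA`; the optical section
thickness (defocus at 50 % response) therefore shrinks as 1/[ν̃(1−ν̃/2)]
and is thinnest at ν̃ = 1 — but the measured modulation depth `m`, and
with it the sectioned-image SNR (the SNR penalty relative to widefield
is √2/m, a function of m alone), degrades as frequency and sample
turbidity rise. This package exists to let you explore that trade-off,
and the downstream nuclear-density quantification it serves, entirely in
software: virtual phantoms (thin fluorescent sheets under scattering
media, tissue-like nuclei fields at 5–15 µm diameter with dominant
out-of-focus background) stand in for the bench samples.

Nuclei are segmented the way the intraoperative-margin application
demands: maximum-intensity normalization, subtraction of a σ = 20 px
Gaussian blur (a high-pass residual that passes 3–10 px nuclei nearly
untouched), a 0.1 threshold, connected components, and density in
nuclei/mm²; groups are compared with a two-sided Wilcoxon rank-sum test.

Audience: microscopists designing or characterizing grid-projection
sectioning systems, and image-analysis folk who need a controlled
test bed for background-rejection and density-quantification pipelines.

## Worked example

Predicted section thickness across the instrument's 4× frequency set:

```sh
$ simsect theory
nu_abs_mm,nu_norm,section_thickness_um
101.0,0.5251999999999999,47.2168539357525
67.0,0.34839999999999993,63.558241439633036
50.3,0.26155999999999996,80.43107218760551
47.7,0.24803999999999998,84.16063119375944
40.7,0.21163999999999997,96.62782244412536
31.7,0.16484,120.89778734651354
24.1,0.12532,155.6708728830581
19.6,0.10192,189.05186451112885
```

At the 31.7 mm⁻¹ operating point (ν̃ = 0.165 for NA 0.1 and λ = 520 nm)
the model predicts a 121 µm section — strong background rejection while
retaining a workable modulation depth; pushing to ν̃ = 1 (≈192 mm⁻¹)
would reach 36.6 µm but at a crippling SNR cost.

The full synthetic pipeline — five tumor-density nuclei fields imaged
through the forward model, reconstructed both ways, quantified with the
high-pass-filter pipeline, compared by rank-sum:

```sh
$ simsect -v run examples/demo.yaml
INFO simsect: simulate: image 1/5 (seed 1)
...
INFO simsect: pipeline done: sectioned 3521 /mm^2 vs uniform 4 /mm^2 (p=0.01116)
run complete; results in scratch/demo_run
```

`density.csv` holds the per-image numbers; e.g. image 0 carries 999
ground-truth nuclei in its 350×350 px ROI, of which the sectioned
reconstruction recovers 960 (3483 /mm², −3.9 %) while the widefield
(uniform-illumination) reconstruction finds 3: with the out-of-focus
background several-fold brighter than the focal layer, un-sectioned
imaging misses essentially all nuclei, and the rank-sum p = 0.011
confirms the sectioned/uniform difference across the five fields.

Library use mirrors the CLI: `make_nuclei_scene` → `render_triplet` →
`sectioned_image` / `widefield_image` → `segment_nuclei`, with
`modulation_map`, `snr_report`, `axial_profile` /
`section_thickness_from_profile` and `estimate_frequency` for
characterization.

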