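# Full synthetic demo: tumor-density nuclei fields imaged through the
# three-phase structured-illumination forward model, reconstructed both
# ways, quantified with the HPF pipeline, and compared by rank-sum.
frequency: 31.7        # grid frequency, mm^-1 (the selected operating point)
m0: 1.0                # nominal pattern modulation depth
density: 3561          # nuclei per mm^2 (sarcoma benchmark)
mus_prime: 10.0        # reduced scattering coefficient, cm^-1
background_level: 6.0  # out-of-focus fluorescence, x focal amplitude
fov: [400, 400]        # field size in pixels (1.5 um/px)
n_images: 5
seed: 1
out_dir: scratch/demo_run
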