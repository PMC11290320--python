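# collimap

Analysis pipeline for studying how the mouse **superior colliculus (SC)**
represents visual space, and what happens to that representation — and to
visually driven behavior — when astroglial gap-junction networks are
perturbed.  The package re-implements, as a tested and reusable library,
four analysis stages that such a study needs:

1. **Periodic-stimulation Fourier phase mapping** (`phasemap`, `mapstats`) —
   intrinsic optical imaging movies recorded while a bar sweeps the screen
   at 1/8 Hz (or a grating rotates at 2 rpm) are demodulated pixel-by-pixel
   at the stimulation frequency.  With the convention
   `x(t) = M cos(2πft − Φ)`, the phase `Φ` encodes the visual-field
   position (azimuth over 110°, elevation over 60°) or the preferred
   orientation (180°-periodic, analysed at 1/15 Hz).  Pairing sessions with
   opposite stimulus directions cancels the hemodynamic delay `δ`: half the
   wrapped phase **sum** isolates `2πfδ`, and the delay-corrected phase of
   one direction reads out the map.
2. **Cross-animal registration and reproducibility** (`mapstats`,
   `circstats`) — per-animal azimuth/elevation map pairs are rigidly
   aligned (rotation + shift minimising the summed squared circular
   position difference), averaged in the common frame, and tested per
   pixel with the **Moore-Rayleigh test**, the rank-weighted Rayleigh
   statistic `R* = |Σ rᵢ e^{iθᵢ}| / n^{3/2}` with a seeded Monte-Carlo
   null.  Selective domains (p < 0.05 inside the structure border) and the
   visual-field coverage they represent are then quantified.
3. **Dye-coupling geometry** (`coupling`) — biocytin-filled astroglial
   networks are summarised by their directional extents (median or max
   projection of coupled cells onto dorsal/ventral/medial/lateral axes
   anchored to the tissue-surface polyline), the isotropy ratio
   `a/(a+b)` (0.5 = isotropic), coupled-cell counts, and the regression
   of dorsal extent on injection depth.
4. **Light-induced arrest behavior** (`behavior`) — pose-tracked
   trajectories (25 fps; snout, barycenter, tail base with likelihoods)
   are cleaned (likelihood < 0.9 dropped, 5-frame smoothing),
   differentiated with a Savitzky-Golay filter, and each trial is scored
   by the speed-modulation index
   `(V_baseline − V_arrest) / V_baseline`, with `V_baseline` the mean
   speed in the 1 s before the first flash and `V_arrest` the mean speed
   in the 3 s window starting 1 s after it (index 1 = complete stop).

Because no raw recordings ship with the package, `synthgen` generates all
three input modalities with planted ground truth (phase-encoded maps with
delay, drift and noise; truncated Gaussian cell clouds; arrest
trajectories), so every stage is validated by parameter recovery.

## Worked example

Simulate a three-animal cohort at desk scale (32×32 pixels, full
protocol timing) and run every stage:

```bash
cat > demo.yaml <<EOF
frame_rate_hz: 5.0
n_repeats: 30
n_cycles: 20
seed: 1
EOF
collimap all --config demo.yaml --outdir demo_out --n-animals 3 --size 32
```

prints

```
coverage_deg2: 6000.0000
domain_area_mm2_azimuth: 0.1129
domain_area_mm2_elevation: 0.1129
domain_area_mm2_orientation: 0.1129
domain_fraction_azimuth: 1.0000
domain_fraction_elevation: 1.0000
domain_fraction_orientation: 1.0000
mean_dorsal_lateral_ratio: 0.3254
mean_modulation_index: 0.7500
sem_modulation_index: 0.0000
```

Reading the numbers: the three simulated animals share noiseless planted
maps, so after registration every pixel inside the structure border is
reproducible (`domain_fraction_* = 1`) and the represented visual field
covers the planted spans (6000 deg² of 5°×5° cells).  The default
coupling networks are injected 200 µm below the surface with σ = 150 µm,
so surface truncation compresses the dorsal extent and the
dorsal/(dorsal+lateral) ratio falls below 0.5.  The default planted
arrest fraction is 0.75, which the behavior pipeline recovers exactly
(`mean_modulation_index = 0.7500`).

The same stages are available individually (`collimap simulate`,
`retinotopy`, `orientation`, `register`, `reproducibility`, `domains`,
`coverage`, `coupling`, `behavior`) and as library functions
(`collimap.analyze_retinotopy_pair`, `collimap.pixelwise_reproducibility`,
…).

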