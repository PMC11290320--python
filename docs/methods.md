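# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Phase mapping of periodic-stimulation imaging

**Signal model.**  Under continuous periodic stimulation, a responsive
pixel's reflectance contains a stimulus-locked component
`x(t) ≈ M cos(2πft − Φ)` riding on a large slow baseline.  The analysis
frequency `f` is the sweep repetition rate (1/8 Hz) for retinotopy and
the orientation repetition rate for rotating gratings.  Because a
grating is 180°-periodic, the orientation stimulus repeats twice per
rotation: at 2 rpm the rotation frequency is 1/30 Hz and the analysis
frequency is 1/15 Hz.  (The conventional label "half the frequency of
rotation" for 1/15 Hz refers to the half-turn periodicity of the
grating; numerically 1/15 Hz is twice the full-rotation frequency.  The
implementation uses the value, 1/15 Hz.)

**Slow-component removal** (`remove_slow_components`).  Each pixel's
time course has its temporal mean and least-squares linear trend
subtracted, then all rFFT components strictly below `f/2` are zeroed.
The linear trend is fitted on the residual after removing a provisional
estimate of the `f` component, so a strong response cannot leak into
the fitted slope.  For records covering an integer number of stimulus
cycles — guaranteed by the protocol — `f` falls exactly on a retained
FFT bin, so the passband is untouched (the contract: sub-`f/2` power
removed entirely, amplitude at `f` preserved within 1%, zero temporal
mean).  A spectral projection was chosen over moving-average subtraction
because it satisfies this contract with no edge artifacts on short
records.

**Demodulation** (`extract_fourier_component`).  The complex demodulate
`C = (2/N) Σ xₙ e^{−i2πf tₙ}` is evaluated at the exact analysis
frequency over the largest integer-cycle prefix (truncation is logged),
not at the nearest FFT bin — 1/15 Hz need not align with the FFT grid of
an arbitrary record and bin rounding would cause leakage.  `M = |C|`,
`Φ = (−arg C) mod 2π`; all downstream math assumes this convention.

**Map construction.**  Forward/reverse sweep sessions carry phases
`±2π·pos/span + 2πfδ` with a shared hemodynamic delay `δ`.  The
half-difference of wrapped phases is ambiguous modulo half the span, so
the implementation instead forms the per-pixel wrapped phase **sum**,
whose half is `2πfδ` provided `δ` is below half the stimulus period
(< 4 s for 1/8 Hz — hemodynamic delays of 1–3 s satisfy this), and reads
the position from the delay-corrected forward phase.  This is equivalent
in intent to the half-difference but with an explicit wrap convention;
round-trip tests validate it, including delays up to 3.9 s.  The
per-pixel sums are unwrapped around their global circular mean so a
delay numerically at 0 cannot flip individual pixels across the wrap.
Orientation pairs (anticlockwise/clockwise rotation) are treated the
same way with a doubled-angle code (`Φ± = 2πfδ ± 2θ`); the common delay
phase is the magnitude-weighted circular mean over pixels, and the two
delay-corrected estimates are averaged on the 180° circle.  Degrees and
phase interconvert linearly over the printed spans (110° azimuth, 60°
elevation).

## Cross-animal registration and reproducibility

**Registration** objective: the summed squared circular position
difference between an animal's (azimuth, elevation) map pair and the
reference, over jointly valid pixels.  Maps are represented as complex
fields `e^{i2π·pos/span}`; the optimizer is a coarse rotation grid
(±10°, 0.5° steps) with, per rotation, an FFT-based search over integer
shifts (±20 px) that minimises the mean `1 − cos` mismatch normalised by
the overlap size (normalisation matters: the raw correlation of smooth
maps just counts overlapping pixels), followed by a local rotation
refinement at 0.1°.  The first pass registers to animal 1; a second pass
re-registers everyone to the running circular-mean average.  Planted
transforms (5°, 3 px, −2 px) are recovered exactly on noiseless maps,
and registering already-registered maps returns identity transforms.

**Averaging** is the per-pixel magnitude-weighted circular mean (period
= span for retinotopy, 180° for orientation); pixels with fewer than two
contributing animals or a degenerate (antipodal) resultant are flagged
invalid.

**Moore-Rayleigh test.**  At each pixel the registered per-animal
(phase, magnitude) vectors form the sample; magnitudes are converted to
ranks (ties get average ranks) and
`R* = hypot(Σ rᵢcosθᵢ, Σ rᵢsinθᵢ) / n^{3/2}`.  Orientation values are
mapped onto the full circle through their 180° period, i.e.
angle-doubled, before testing.  The null distribution is a seeded
Monte-Carlo sample (default 100,000 draws of `n` iid uniform angles with
ranks 1..n, cached per sample size) rather than printed critical-value
tables; this handles any `n` and ties uniformly, and the p-value
`(1 + #{R*₀ ≥ R*})/(1 + n_mc)` is always in (0, 1].  Calibration checks:
null rejection at α = 0.05 is 0.05 ± 0.01 over 10,000 pixels, null
p-values pass a Kolmogorov–Smirnov uniformity test for n ∈ {3, 5, 8},
and power for concentrated phases (von Mises κ = 20, n = 5) exceeds
0.99.  No multiple-testing correction is applied — α is the per-pixel
threshold, matching how such maps are conventionally thresholded — and
this is exposed in configuration.  Per-animal phases are not centred
before testing and the weights are the demodulated magnitudes; both
defaults are configuration-exposed since other conventions are
defensible.

**Domains and coverage.**  The structure border is the largest connected
component of pixels whose averaged response magnitude exceeds half the
maximum (configurable), morphologically closed.  The selective-domain
fraction is significant pixels over border pixels; areas in mm² use the
configured pixel pitch (10.5 µm at full scale).  Visual-field coverage
collects the averaged (azimuth, elevation) coordinates of pixels
significant in both maps onto a 5°×5° grid; the covered area is the
occupied cell count times the cell area.

## Dye-coupling geometry

Coordinates are micrometres in the slice plane, x medio-lateral, y
increasing ventrally.  The direction frame is anchored to the tissue
surface rather than the image axes: dorsal is the unit vector from the
injection site to the foot of its perpendicular on the surface polyline,
and medio-lateral is the surface tangent there (signed by a hemisphere
flag, re-orthogonalised at polyline corners).  Extents are the median or
the max of the positive projections of (cell − injection) per direction
— both statistics are provided because network spread is reported both
ways; cells on the negative side of a direction do not contribute to it.
The isotropy ratio `a/(a+b)` defaults to dorsal vs lateral (the pairing
used for the isotropy comparison in the text; a ventral vs medio-lateral
pairing appears in some figure legends, so the operation is
direction-parameterised).  The extent-versus-depth relationship is
ordinary least squares with R², F(1, n−2) and a two-sided p-value; a
constant response returns slope 0 and R² = 0 rather than NaN.
Coupled-cell counts exclude the patched cell by default.  Group-level
hypothesis tests between genotypes (Mann-Whitney, Wilcoxon, one-sample
t) are left to standard statistical routines; the pipeline reports the
per-network summaries they consume.

## Arrest behavior

Body parts below likelihood 0.9 are masked per frame; interior gaps up
to 0.5 s are linearly interpolated, longer gaps stay masked entirely
(partial filling of a long gap would fabricate positions).  Positions
are smoothed with a centred 5-frame moving average, then differentiated
with a Savitzky-Golay filter (window 7, order 2 — unreported upstream,
so exposed as configuration; the derivative is exact for straight-line
motion) applied per contiguous valid run; speed is the Euclidean norm of
the x/y derivatives.  The barycenter is the analysis body part.
`V_baseline` averages the speed over the 1 s before the first flash,
`V_arrest` over the 3 s window starting 1 s after it, and the index is
`(V_baseline − V_arrest)/V_baseline`, unclipped (speeding up yields a
negative index).  Trials whose baseline speed falls below a minimum
running speed (default 2 cm/s, the "in motion" requirement made
explicit; px→cm from the 30-cm arena) raise a distinct
`TrialRejectedError` so callers can drop them without confusing
rejection with computation failure.

## Synthetic-data generators

The generators plant known parameters and return them for recovery
testing; all are deterministic given their seed.

* **Imaging** — per-pixel sinusoids at the analysis frequency with the
  planted phase code, plus slow drift (per-pixel linear trend + 0.005 Hz
  sinusoid, amplitude `drift_amp`) and white Gaussian noise
  (`noise_sd`).  An optional gamma impulse response (shape 4, scale
  0.6 s, off by default) adds kernel realism; the analysis measures only
  the phase-level model, so the sinusoidal default is sufficient.
  Default desk-scale geometry is 64×64 pixels at 5 Hz (the acquisition
  frame rate is not a protocol constant and is exposed as a parameter);
  the full-scale pixel pitch lives in configuration only.  "SNR" for
  noisy recovery tests is defined in the time domain as response
  amplitude over broadband noise sd; demodulating over 30 cycles of a
  240-s record then concentrates the effective single-bin SNR by
  √(N/2) ≈ 24, which is what makes phase maps recoverable from movies
  whose single frames look like noise.  Not emulated: vascular
  artifacts, eye movements, photobleaching, spatial noise correlations —
  recovery results bound algorithmic error, not biological variability.
* **Coupling** — cell clouds from a bivariate Gaussian (σ_ml, σ_dv)
  centred on the injection site, rejection-truncated at the surface
  polyline; the patched cell sits at the injection site.  Deep isotropic
  clouds give a directional ratio of 0.5 in expectation; shallow
  injections reproduce the surface-truncation signature (dorsal extent
  tracking depth).
* **Behavior** — constant-speed, gently curving trajectories whose speed
  drops by `arrest_fraction` from 0.2 s after the flash for 5 s,
  covering the whole 1–4 s analysis window, so the planted index equals
  `arrest_fraction` exactly; dropout frames get likelihoods uniform on
  [0, 0.9), valid frames on [0.95, 1].  A zero turn amplitude gives a
  straight line on which the Savitzky-Golay derivative is exact, used
  for the analytic index checks.

## Problem sizes and numerical details

Round-trip and calibration suites run at 64×64 pixels (full protocol
timing: 240-s sweeps, 600-s rotations at 5 Hz), 10,000 test pixels for
calibration, 200 networks × 300 cells for the isotropy Monte Carlo, and
30-s pose recordings — sizes chosen so the whole suite completes in well
under a minute while keeping Monte-Carlo errors small against the stated
tolerances.  Null tables are cached per (n, n_mc, seed).  Ties in
magnitudes receive average ranks.  Degenerate circular means (antipodal
inputs) return NaN or raise, per configuration.  Registration reports
integer shifts; sub-pixel alignment is beyond the stated 0.5-px
tolerance and left out.  File writers document the image convention (row
0 = top, x rightward); anatomical orientation is supplied via
configuration, never inferred.

## Known limitations

* The structure border derives from response magnitude, so a weakly
  responsive but genuine region can be excluded; anatomical masks can be
  supplied instead through `pixelwise_reproducibility(border_mask=...)`.
* Registration assumes rigid misalignment between animals; non-rigid
  inter-individual differences register imperfectly and inflate the
  pixel-wise p-values.
* The Monte-Carlo null assumes exchangeable, independent animals per
  pixel; spatially correlated noise across animals would make the
  per-pixel test anti-conservative.
* The behavior index uses fixed windows relative to the first flash;
  latency differences between animals are not modelled.
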