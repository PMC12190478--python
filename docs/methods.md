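# Methods

This note documents the model, the numerical choices, and the design
decisions behind `scorimap`, in the order the pipeline runs.

## Visual field and stimuli

The visual field is a 200 × 200 pixel lattice spanning −60° to +60°
(0.6°/px, Nyquist 0.83 cycles/°). Pixel centers follow a half-open
convention, −60 + 0.6k for k = 0…199, so the exact origin is a pixel
center and the stated pixel count and Nyquist frequency are reproduced
exactly; the grid is therefore symmetric only on its interior (the tests
account for this). All RF and stimulus frequencies (≤ 0.32 cycles/°) are
far below Nyquist.

Gratings are rendered as cos(2πv(cos θ_g x + sin θ_g y) + φ) with the wave
vector at θ_g = θ_c + 90°, so a grating's orientation label θ_c equals the
polar angle of its spectral energy in a y-up Cartesian frame, with
counterclockwise-positive angles. Orientation labels are reported modulo
180°. Whether the underlying imaging data follow y-up or y-down is a pure
mirror ambiguity; a mirror maps radial patterns to radial patterns, so none
of the package's conclusions depend on it, but label/geometry consistency
*within* the simulator is essential (an inconsistent sign scrambles the
radial alignment score) and is covered by tests.

Apertures have hard boundaries; a pixel belongs to the aperture iff its
center is strictly inside. The same signed-distance functions that build
masks also provide edge bands and local edge normals for scoring. The
half-circle conditions keep the top (horizontal straight edge) or right
(vertical straight edge) half.

## Receptive fields

Gaussians use the standard-deviation convention exp(−r²/2σ²) throughout.
The center-surround RF's surround weight is w_s = CS_ratio·σ_c²/σ_s², which
makes CS_ratio the surround-to-center *volume* ratio; only this reading
makes the five grid-search pairs (σ_s, CS) = (3, 0.2) … (5.7, 1.0) share a
preferred spatial frequency of 0.08 cycles/° and reproduces the printed
0.04 cycles/° for the (1.5°, 11.4°, 0.8) family, so it is the default (a
peak-amplitude reading is available via `make_dog(..., amplitude_ratio=True)`).
The preferred SF is measured by slicing the 2-D discrete amplitude spectrum
along the horizontal frequency axis (any axis through the origin is
equivalent for a circularly symmetric RF) and refining the peak bin
parabolically; it agrees with the closed-form argmax within one frequency
bin (0.0083 cycles/°) on the default grid, and a peak at the Nyquist edge
raises instead of returning an unreliable value.

Gabor envelopes use σ_min = n_sub/(4√2 f_pref) and σ_maj = (LW/n_sub)·σ_min
(defaults n_sub = 2, LW = 4, giving 4.42° and 8.84° at 0.08 cycles/°); the
alternative reading σ_maj = LW·n_sub·σ_min is exposed as
`aspect_convention="ratio_times_n"`. The carrier's phase is referenced at
the RF center, so quadrature pairing and orientation tuning are independent
of absolute RF position.

## Response pipeline

Raw responses are dot products between RF and stimulus images. For
center-surround RFs the On/Off mirrored pair is collapsed by rectify-and-
sum, which equals |r_On| exactly; for V1-like RFs the 0°/90° quadrature
pair is collapsed to energy r₀² + r₉₀². Responses are then jointly min-max
normalized over the entire experiment tensor (normalizing per stimulus
would equate all orientations at the normalization stage and, for exactly
mirrored On/Off pairs, make rectification vacuous — the raw response
ensemble is antisymmetric under a 180° phase shift, so a per-set min-max
maps every rectified pair sum to a constant). The total response is
R_t = α·R_Δ + β + w with defaults α = β = 1 (100% maximum increase over
baseline) and w ~ N(0, 0.01) i.i.d. with a per-experiment seed.

**Phase collapse.** Four stimulus phases (0°, 90°, 180°, 270°) exist to
remove phase dependence from the readout. Because responses are linear in
the stimulus, r(φ_g) = A·cos(φ₀ + φ_g): the *RMS* of the rectified
responses over this quadrature cycle equals A/√2 exactly and is the
default collapse (`phase_mode="rms"`, applied before normalization). The
simpler arithmetic mean of rectified responses equals
A·(|cos φ₀| + |sin φ₀|)/2, which retains a ±17% dependence on the grating
phase φ₀ at the RF center. That residual is not noise: along a curved
aperture edge the radial orientation is systematically phase-locked
(φ₀ = 0, the minimum of the factor) while edge-parallel orientations
float, so the residual biases preference maps toward anti-radial by more
than the genuine few-percent edge-driven amplitude modulation of a
center-surround RF. The mean mode is retained (`phase_mode="mean"`,
applied after noise, matching the simplest reading of the procedure) for
sensitivity analysis; the map-level phenomenology reported by the package
requires the phase-invariant readout.

**Fast paths.** Center-surround lattice responses exploit separability:
the response surface over RF centers is G_c S G_cᵀ − w_s G_s S G_sᵀ with
1-D Gaussian weight matrices evaluated analytically at the continuous
(sub-pixel) lattice centers; this agrees with direct per-RF dot products
to machine precision relative to the response scale. V1-like lattice
responses are FFT cross-correlations of each stimulus with the centered
kernel, sampled at lattice centers by bicubic spline; the spline step
introduces ≲10⁻³ relative error on the smooth correlation surface (tested
against direct dot products). Envelope tails beyond the field of view are
below 10⁻²⁰, so circular wraparound is negligible.

## Retinotopy

The anatomical window is ±0.83 mm, sampled 241 × 241 (58,081 locations);
the visual window is ±40°. The anatomical→visual transform is learned from
10 control points by Clough–Tocher (C1, exact at nodes) scattered
interpolation, with a piecewise-linear option; both satisfy the same
exact-at-nodes contract and the tests run against both. Natural-neighbor
interpolation shares these properties; the results depend on smoothness
and node-exactness, not the specific scheme. Samples outside the
control-point hull are flagged and excluded from maps, mirroring the
exclusion of visual coordinates outside the RF lattice.

The synthetic control-point generator places a jittered 3 × 3 grid plus a
tenth interior point in the anatomical window and maps it by a 90°
clockwise rotation, mm→deg scaling (48.2°/mm), and a smooth quadratic warp
bounded by `warp_amplitude` × 40° (default 0.1). A grid (rather than ring)
layout keeps large apertures inside the interpolation hull. Measured
control points can be supplied as CSV. With `warp_amplitude=0` the
generator is an exact similarity transform, which the fit must recover
within 1% of the field width — the parameter-recovery contract.

Responses at transformed coordinates are bilinear in the enclosing lattice
cell (exact for linear fields; equivalent to the distance-weighted average
of the four surrounding nodes). For V1-like tensors the interpolation runs
per RF orientation and one random orientation is then selected per
coordinate from a seeded generator, emulating a population with random
intrinsic orientations.

## Population maps and scores

Population responses are the anatomical samples smoothed with a Gaussian
kernel of sd 0.0083 mm (≈ 0.44° of visual space), with kernel
renormalization over valid neighbors so invalid samples neither leak zeros
nor dim the map border. Preference and selectivity use doubled-angle
circular statistics on the smoothed responses; the baseline β shifts all
responses equally and therefore leaves the preferred angle unchanged while
shrinking gOSI uniformly. gOSI is additionally min-max normalized across
each map for display/thresholding only; the raw values are retained.

**Edge band.** The ±2° strip around the aperture boundary straddles two
physically distinct unit populations: units centered within ~σ_c of the
boundary (or outside it) respond through the vignette stripe itself and
prefer edge-parallel orientations, while units σ_c–σ_s inside have a fully
stimulated center and an edge-overlapping surround, and these are the
units whose preferences are radial at the preferred spatial frequency.
The package therefore defines the center-surround edge band as signed
distance ∈ [σ_center, σ_surround] inside the aperture (3σ_center for the
no-surround control, whose reach is the center alone) and the V1-like band
as |d| ≤ σ_min (the envelope straddles the edge). The radial alignment
score is measured against the *local edge normal* — identical to the polar
angle for circles and the correct "orthogonal to the edge" for squares and
diamonds — and is gOSI-weighted, matching how a transparency-rendered map
is read: weakly tuned samples carry little evidence. The unweighted,
center-referenced, symmetric-strip variant remains available through the
function's arguments.

Single-unit tuning uses 36 orientations; von Mises fits on doubled angles
(R(θ) = b + a·exp(κ(cos 2(θ−μ) − 1))) are initialized from the circular
mean and response range, bounded to κ ∈ [0, 500], and recover noiseless
parameters within 1%. Curves are duplicated over 180–360° for polar
display.

## Experiments and problem sizes

Three drivers mirror the study designs: aperture shape (five apertures,
0.04 cycles/°, σ_c = 1.5°/σ_s = 11.4°/CS = 0.8), spatial frequency (30°
circle, six frequencies 0.01–0.32 cycles/°, σ_c = 0.8°/σ_s = 4.7°/CS = 0.4),
and RF structure (53 single units in a 4° × 4° patch 2.5–6.5° from the
center — on the stimulated side of both half apertures — plus population
maps for both families). The grid search runs the five iso-preferred
(σ_s, CS) pairs and the no-surround control. The RF lattice spans ±30/±40/
±50° depending on aperture (58,081/103,041/160,801 locations at the full
0.25° step). The default problem size for tests and examples uses a 1°
lattice step (≈ 3.7–10 k locations), at which every map-level score agrees
with the 0.25° lattice within 0.1; full scale is a config option
(`scale="full"`). One master seed per experiment spawns all substreams
(noise, retinotopy, orientation picks), so a stored config re-runs to
identical outputs.

## What the synthetic data do and do not emulate

The synthetic retinotopy reproduces the qualitative geometry of the
measured mapping (≈90° rotation with smooth warping) but not its measured
control points, so map geometry matches real anatomical maps only up to
that warp. The noise model is additive i.i.d. Gaussian on normalized
responses; real imaging noise is correlated and signal-dependent. Pixel
discretization leaves each unit a small deterministic orientation residue;
with the default noise (σ = 0.01) this residue, not the noise, dominates
the scatter of no-aperture center-surround preferences, so those
preferences are idiosyncratic across units but reproducible across noise
seeds. Passing tests therefore demonstrate the vignetting mechanism and
pipeline correctness, not quantitative agreement with any particular
imaging dataset — the model's RFs are deliberately uniform, whereas real
sSC populations mix RF sizes, tuning widths, and temporal dynamics that
this purely spatial model does not represent (no direction selectivity).

## Known limitations

* The literal arithmetic-mean phase collapse does not reproduce the radial
  map phenomenology (see *Phase collapse*); it is kept only for
  sensitivity analysis.
* The radial and anti-radial zones of a center-surround population are
  spatially offset (radial σ_c–σ_s inside the edge, anti-radial in a thin
  strip at the boundary); at high spatial frequency the anti-radial rim
  dominates the edge-band score. Published anatomical maps have neither
  the spatial resolution nor the printed numbers to pin the band geometry,
  so band bounds are package design choices, stated above and fixed before
  scoring.
* Clough–Tocher is C1 but not the Sibson (natural-neighbor) interpolant;
  both are exact at nodes and the package's contracts do not distinguish
  them.
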