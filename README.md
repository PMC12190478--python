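# scorimap

Population receptive-field simulator for stimulus-dependent orientation
selectivity in mouse superficial superior colliculus (sSC).

Widefield calcium imaging of mouse sSC shows maps of orientation preference
that change with the stimulus: gratings vignetted by an aperture evoke
*radial* orientation preferences (orthogonal to the aperture edge) at
retinotopic locations along the edge, and the preference flips to
*anti-radial* (parallel to the edge) when the grating's spatial frequency is
raised. `scorimap` reproduces this phenomenology with populations of
**fixed, stimulus-invariant** receptive fields — no change in intrinsic
tuning is required. It is aimed at visual-system modelers who want a
transparent, linear-filter account of aperture (vignetting) effects on
population orientation maps.

## Model

Two classic RF families tile the visual field:

* **Center-surround (difference-of-Gaussians).** With unit-peak Gaussians
  G(r; σ) = exp(−r²/2σ²),

  f(x, y) = G(r; σ_c) − w_s · G(r; σ_s),  w_s = CS_ratio · σ_c²/σ_s²,

  so the surround-to-center *volume* ratio equals CS_ratio. The amplitude
  spectrum is again a difference of Gaussians with preferred spatial
  frequency

  f\* = sqrt( ln(CS_ratio σ_s²/σ_c²) / (2π² (σ_s² − σ_c²)) ),

  e.g. 0.08 cycles/° for (σ_c, σ_s, CS) = (0.8°, 4.7°, 0.4) and 0.04
  cycles/° for (1.5°, 11.4°, 0.8). These RFs are bandpass in spatial
  frequency and untuned for orientation.

* **V1-like (Gabor).** An oriented carrier at f_pref under an elongated
  Gaussian envelope (σ_min = n_sub/(4√2 f_pref), σ_maj = (LW/n_sub)·σ_min);
  0°/90° carrier-phase pairs give phase-invariant energy responses
  (r₀² + r₉₀²), as in complex cells.

Stimuli are static sinusoidal gratings (12 orientations × 4 phases, 100%
contrast) vignetted by hard-edged apertures (circles of radius 20/30/40°,
square and diamond of side 40°, half-circles, or none) on a 200 × 200 pixel
grid spanning ±60°. Responses are dot products of RF and stimulus, combined
across On/Off polarity (rectify-and-sum) or quadrature phase (energy),
collapsed across stimulus phase, jointly min-max normalized, and given a
baseline plus Gaussian noise (R_t = α·R_Δ + β + w). A scattered-data
retinotopy (exact at control points) maps the anatomical sampling grid
(241 × 241 over ±0.83 mm) into visual coordinates, responses are sampled
bilinearly from the RF lattice, smoothed with a small Gaussian kernel to
emulate widefield pixels, and summarized per sample by the doubled-angle
circular statistics

  gOSI = |Σ_θ R(θ) e^{2iθ}| / Σ_θ R(θ),  preferred = arg(Σ_θ R(θ) e^{2iθ}) / 2.

A map-level *radial alignment score* — the gOSI-weighted mean of
cos 2(preferred − edge-normal) over an aperture-edge band — summarizes each
map: +1 is perfectly radial, −1 perfectly anti-radial.

## Worked example

```python
from scorimap import DoGParams, make_grid, dog_preferred_sf
from scorimap.experiments import ExperimentConfig, run_sf_experiment

grid = make_grid()                                   # 200 px over +/-60 deg
rf = DoGParams(sigma_center=0.8, sigma_surround=4.7, cs_ratio=0.4)
print(f"preferred SF: {dog_preferred_sf(rf, grid):.4f} cycles/deg")

cfg = ExperimentConfig(experiment="spatial_frequency", seed=1)
maps, scores = run_sf_experiment(cfg)
print(scores.round(4).to_string(index=False))
```

prints

```
preferred SF: 0.0789 cycles/deg
 sf_cpd  radial_score  edge_gosi  interior_gosi
   0.01        0.1117     0.0007         0.0007
   0.02        0.4462     0.0010         0.0007
   0.04        0.8364     0.0027         0.0008
   0.08        0.9811     0.0049         0.0007
   0.16       -0.6461     0.0022         0.0006
   0.32       -0.9352     0.0098         0.0007
```

The Fourier-slice peak of the rendered RF (0.0789 → 0.08 cycles/°) matches
the closed-form spectrum argmax. In the frequency sweep (30°-radius
circular aperture), edge-band preferences are strongly radial at the RF's
preferred frequency (scores +0.84 and +0.98 at 0.04 and 0.08 cycles/°),
reverse to anti-radial at higher frequencies (−0.65, −0.94), and the map
fades at low frequency (edge gOSI drops toward the interior level at
0.01 cycles/°) — the stimulus-dependent reorganization seen in imaging,
from RFs whose tuning never changed.

From a shell, the same run is

```bash
scorimap simulate --config sf.yaml --seed 1   # writes map CSVs + run log
scorimap render --map-csv out/map_sf0.08.csv --out map.png
```

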