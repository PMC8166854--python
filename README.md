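# fluoragg

Detection and sizing of sub-visible therapeutic-antibody aggregates in
widefield fluorescence microscope images.

Therapeutic monoclonal antibodies form aggregates (roughly 0.1–50 µm and
larger) during production, transport and storage; once spiked into serum,
their evolution is hard to follow with chromatography or light-scattering
instruments because serum proteins swamp the signal. Tagging the antibody
with FITC and imaging it under a fluorescence microscope sidesteps that —
but the images carry Poisson shot noise, Gaussian read noise, uneven
illumination and out-of-focus blur, and naive thresholding either inflates
particles or deletes them. `fluoragg` implements a full image-analysis
chain for this problem, aimed at anyone who needs per-particle
morphometrics and size distributions from noisy fluorescence images of
bright particles on a dim background.

## The method

For the green channel g(x, y) of each frame:

1. **Denoise**: 3×3 median filter, then total-variation gradient descent
   (TV(g) = ‖∇g‖₁, step by line search, early stopping when the relative
   image change drops below 0.005).
2. **Flatten illumination**: an ideal FFT low-pass (default cutoff 0.02 ×
   Nyquist) estimates the background, removed by division (or subtraction);
   the result is quantized to 0–255.
3. **Threshold** with one of: weighted median (T = 4.5 × MAD), 1D Otsu, 2D
   Otsu on the joint (grayscale, neighborhood-mean) histogram — maximizing
   tr σ_B(s, t) — or the default **modified 2D Otsu**: keep the 2D-Otsu
   grayscale threshold S, then tune the neighborhood-mean threshold T
   iteratively until the detected particle count matches an independent
   weighted-median estimate N_e, starting from
   T_guess = 0.6·T_min + 0.2·T_max + 0.2·T_otsu (T_min/T_max from a cubic
   fit to the log-frequency curve). Foreground: g ≥ S and h ≥ T.
4. **Clean up**: remove isolated pixels, fill holes, drop components under
   20 px.
5. **Measure**: per particle, area A = N̂·l·b (µm²), perimeter P,
   circularity 4πA/P², equivalent circle radius √(A/π); radii pooled over
   images and binned in 10 µm steps.

See `docs/methods.md` for the full model, parameters, and limitations.

## Worked example

Everything runs on generated scenes with exact ground truth — no data
download. Process one synthetic serum-like frame with six aggregates:

```python
import fluoragg as fa
from fluoragg.features import records_to_frame

scene = fa.high_snr_scene(seed=7, n_particles=6, shape=(256, 256))
result = fa.process_image(scene.image, fa.PipelineConfig())

thr = result.threshold
print(f"S={thr.S:.0f} T={thr.T:.0f} N_e={thr.diagnostics['N_e']} "
      f"iterations={thr.diagnostics['iterations']}")
print(f"particles: {result.particle_count} (truth: {len(scene.particles)})")
print(records_to_frame(result.records).round(2).to_string(index=False))
```

which prints:

```
S=105 T=1 N_e=9 iterations=21
particles: 6 (truth: 6)
 label  n_pixels  area_um2  perimeter_um  circularity  eq_radius_um
     1       250   1778.22        149.46         1.00         23.79
     2       308   2190.77        166.11         1.00         26.41
     3       236   1678.64        144.78         1.01         23.12
     4       156   1109.61        114.60         1.06         18.79
     5       213   1515.05        139.44         0.98         21.96
     6       152   1081.16        116.81         1.00         18.55
```

All six aggregates are recovered. `S=105` is the grayscale gate from 2D
Otsu; the count-matching iteration walked the neighborhood-mean threshold
down to `T=1`, i.e. to the bottom of the count plateau, where particle
extents are fully retained (areas here are in µm² at the default 4×
magnification, 2.667 µm/pixel). The size distribution puts 2 particles in
[10, 20) µm and 4 in [20, 30) µm equivalent radius.

From the shell, the same pipeline is:

```sh
fluoragg fixtures --out fx --n-images 3 --n-particles 10 --seed 1
fluoragg process fx/scene_*.tiff --magnification 4x --out run1   # masks, CSVs, report.json
fluoragg compare run1/report.json run2/report.json --out deltas.csv
```

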