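# Methods

`fluoragg` detects and sizes fluorescently tagged protein aggregates in
widefield microscope images. This note documents the processing model, the
parameters that matter, the synthetic data used for validation, and the
numerical choices made where the design was genuinely open.

## Processing model

An acquisition is a `J × K × 3` uint8 RGB frame. FITC-tagged protein emits
at ~519 nm, so only the green plane `g(x, y)` is analyzed. The chain is:

1. **Median filter** (3×3, replicate borders) — removes impulsive,
   long-tailed detector noise without inventing new gray values.
2. **Total-variation flow** — TV(g) = Σ √(|∇x g|² + |∇y g|²) with forward
   differences (replicate edge) is reduced by explicit gradient descent,
   `g ← g − τ ∇TV(g)`, where `∇TV = −div(∇g / √(|∇g|² + ε²))` and the
   divergence is the negative adjoint of the forward difference. There is no
   data-fidelity term: regularization comes from early stopping when the
   relative image change `E_n = ‖g⁽ⁿ⁺¹⁾ − g⁽ⁿ⁾‖_F / ‖g⁽ⁿ⁾‖_F` drops below a
   tolerance (default 0.005). The step τ is found by backtracking line
   search (start 0.25 × dynamic range, halved until TV decreases), so TV is
   non-increasing across accepted steps. On realistic frames this converges
   in ~10–20 steps.
3. **Illumination correction** — an ideal low-pass of the image (2D FFT,
   radial cutoff `cutoff_fraction` × Nyquist, default 0.02) estimates the
   slowly varying background, which is removed either by per-pixel division
   (default) or by clipped subtraction. Both conventions are kept because
   shading can be modeled as multiplicative (vignetting) or additive (stray
   light); the choice is a config switch and is logged.
4. **Quantization** — the normalized image is linearly rescaled to 0–255
   (min→0, max→255, round half away from zero). All threshold selection
   operates on this scale.
5. **Threshold selection** — one of four methods (below), default the
   modified 2D Otsu.
6. **Binary cleanup** — `clean` (drop isolated single pixels) → `fill`
   (fill enclosed holes) → optional `close` (3×3 closing, off by default) →
   size filter (drop components under 20 px; a 20 px component is kept).
7. **Morphometrics** — 8-connected labeling; per particle: pixel count N̂,
   area A = N̂·l·b (l = b = µm/pixel), perimeter P (weighted boundary-step
   estimator, in µm), circularity 4πA/P², equivalent circle diameter
   φ̄ = √(4A/π) and radius φ̄/2. Equivalent radii are pooled across images
   and binned in 10 µm steps from 0, with an overflow bin at ≥100 µm.

### Threshold methods

**Weighted median.** The deviation image D = |g − median(g)| is thresholded
at T = w · median(D) with w = 4.5. This is a robust z-score rule
(T ≈ 3 robust σ): insensitive to the overall background level, generous at
particle edges. If more than half the pixels equal the median (clipped
backgrounds), median(D) = 0 and the rule falls back to the mean deviation.

**1D Otsu.** The integer gray level maximizing the between-class variance
of the 256-bin histogram, computed from zeroth/first cumulative moments.
Background is `{g < S}`; ties go to the smallest S.

**2D Otsu.** The pair image is (g, h) where h is the n×n (default 3)
neighborhood mean of g, rounded to uint8. With joint probabilities
p_ij = r_ij / JK over bins 0..L (L = max pixel value of g or h), the pair
(S, T) maximizes

    tr σ_B(s, t) = [(μ_Ti ω₀ − μ_i)² + (μ_Tj ω₀ − μ_j)²] / (ω₀ (1 − ω₀)),

where ω₀, μ_i, μ_j are the background-quadrant mass and first moments and
μ_T the global means. The formula treats the two off-diagonal quadrants of
the joint histogram (edge and noise pixels) as negligible — valid after
denoising. The search is exhaustive over (s, t) ∈ [1, L]², vectorized with
2D cumulative sums; ties break to the smallest s, then t. Binarization is
joint: foreground iff g ≥ S **and** h ≥ T.

**Modified 2D Otsu.** Plain 2D Otsu systematically overestimates T when the
object-to-background ratio is small, deleting true particles. The modified
method keeps S and re-derives T from a particle-count consistency
condition:

1. *Reference count* N_e: particles found by weighted-median thresholding,
   post-processed with the same morphology as the main pipeline.
2. *Initial guess*: the frequency histogram of h is fitted (log10 counts vs
   pixel value, zero bins excluded) with a cubic; T_min < T_max are the two
   pixel values where the fitted slope equals a set value (−0.05). Then
   T_guess = 0.6·T_min + 0.2·T_max + 0.2·T_otsu — weighted toward T_min to
   counter the overestimation.
3. *Iteration*: binarize with (S, T), post-process, count N_g; with error
   e = N_e − N_g, step T ← T − α where α = clip(η·e, ±α_max), η = 0.5,
   α_max = 8, and |α| ≥ 1 whenever e ≠ 0. Stop when N_g = N_e, when N_g has
   been constant for `stall_limit` (20) consecutive iterations, or at
   `max_iters` (50). While N_g repeats, the step grows geometrically
   (capped at α_max): a constant count carries no gradient information, so
   the iteration accelerates across count plateaus and settles at their
   lower edge, where particles retain their full extent. The returned T is
   the visited value with the smallest |e| (latest on ties); a
   non-converged run is flagged in the diagnostics, which also carry
   T_otsu, T_min/T_max, T_guess, N_e and the full trajectory.

Two documented fallbacks keep the method total: if the set slope is crossed
fewer than twice inside the fitted domain, it is relaxed toward zero (up to
six halvings); if no pair exists at any tested slope (monotone
log-frequency curves), the iteration is seeded at T_otsu directly.

### Empty-field guard

Because quantization stretches min→max to 0→255, a particle-free field of
view would have its residual noise amplified to full contrast and *no*
threshold method can then return zero particles. The pipeline therefore
applies a detection-limit test before quantization, where intensities are
still absolute: a field whose background-removed residual peaks below
`empty_field_snr` (default 10) robust standard deviations
(1.4826 × MAD) above the residual median is declared empty. Fields with
real particles exceed this margin by an order of magnitude; setting the
parameter to 0 disables the guard.

## Parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| `magnification` | `4x` (2.667), `10x` (1.0416) | µm/px | pixel calibration; custom values accepted |
| `median_window` | 3 | px | median filter neighborhood |
| `tv.tolerance` | 0.005 | – | relative-change stop for the TV flow |
| `tv.max_iters` | 200 | – | TV iteration cap |
| `background_cutoff_fraction` | 0.02 | × Nyquist | low-pass radius; captures ≳100 px illumination structure |
| `background_mode` | `divide` | – | or `subtract` |
| `empty_field_snr` | 10 | robust σ | empty-field guard; 0 disables |
| `threshold_weight` | 4.5 | – | weighted-median multiplier |
| `n_avg` | 3 | px | neighborhood for the average-grayscale image |
| `slope_set_value` | −0.05 | dex/gray | slope defining T_min/T_max |
| `guess_weights` | (0.6, 0.2, 0.2) | – | weights of T_min, T_max, T_otsu |
| `alpha_eta`, `alpha_max` | 0.5, 8 | – | proportional gain and step cap of the T iteration |
| `stall_limit`, `threshold_max_iters` | 20, 50 | – | stop rules of the T iteration |
| `morphology.min_pixels` | 20 | px | size cut (142 µm² at 4×, 21.7 µm² at 10×) |
| `morphology.apply_close` | off | – | 3×3 closing (clean and fill are on) |
| `bin_width_um` | 10 | µm | size-distribution bin width |

## Synthetic validation data

No raw microscope images are redistributable, so all tests run on generated
scenes with exact ground truth. The generator emulates: bright particles
(disks, or compact irregular unions of jittered disks) at 180–230 counts on
a serum-like autofluorescent background of ~20 counts; a Gaussian PSF
(σ = 0.8 px) softening edges; multiplicative illumination (sinusoidal
field, amplitude 0.25); Poisson shot noise plus Gaussian read noise
(σ = 6); and dim, heavily blurred out-of-focus distractors that must be
rejected by thresholding. One integer seed fully determines a scene; truth
masks and per-particle pixel counts are exact by construction.

What the generator does **not** model: serum spectral autofluorescence
structure, optically accurate defocus, camera fixed-pattern noise, touching
or overlapping aggregates, and motion. Passing tests therefore demonstrate
the algorithm's correctness and its behavior in a realistic noise regime,
not performance on any particular instrument.

Problem sizes used in the test battery — 256²–448² px scenes with 10–30
particles, and 100 random 16×16 images for the exhaustive Otsu
cross-checks — were chosen to exercise every code path at desk scale; the
pipeline itself is routinely run on full 1536×2048 frames.

## Numerical choices and degenerate inputs

- Quantization rounds half away from zero; constant images map to all
  zeros. 16-bit inputs are linearly rescaled.
- TV gradient: forward differences with replicate boundary; the divergence
  uses the adjoint backward difference so the discrete gradient of TV is
  exact. ε = 10⁻⁶ × dynamic range guards flat regions only.
- FFT low-pass: no padding (periodic boundary); the operator is linear and
  exactly preserves on-grid pass-band components.
- Otsu maximizations skip cells with ω₀ ∈ {0, 1} and break ties toward the
  smallest threshold; constant images raise a degenerate-histogram error
  (1D returns the constant with a warning).
- The cubic log-frequency fit needs ≥4 populated bins; zero bins are
  excluded rather than pseudo-counted.
- A constant image has no particles: the count estimator returns 0, while
  the weighted-median *mask* of a constant image is all-ones (T = 0) with a
  warning.
- Single-pixel components get the 4-sided pixel outline as their perimeter.

## Known limitations

- Per-particle areas of **irregular** aggregates can deviate by up to
  ~30% even at the optimal threshold: thin lobes of a blob straddle the
  grayscale gate S, so boundary pixels dominate. Counts remain exact; disk
  areas are recovered within 10%. Area fidelity is shape-limited, not
  threshold-limited.
- The weighted-median reference count N_e is a *rough* estimate: on
  ratio-normalized images it over-counts by a few smooth residual blobs.
  The modified 2D Otsu is designed to tolerate this — the grayscale gate S
  blocks sub-threshold junk regardless of how far T descends.
- Whether shading should be divided or subtracted is left configurable; the
  two conventions disagree in the method's own description and produce
  different residual statistics (subtraction centers the background at
  zero, which is also where the weighted-median estimator is most
  accurate).
- Touching aggregates are not split (no watershed); a single label covers
  them.
- Distributions from fewer than ~150 fields of view may not represent the
  sample; the pipeline warns but does not enforce a minimum.
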