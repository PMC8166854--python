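"""Threshold selection for aggregate segmentation.

Four methods convert the denoised grayscale image g(x, y) into a binary
mask:

* **weighted median** — T = weight × median(|g − median(g)|); a robust
  absolute-deviation rule that keeps every bright outlier.
* **1D Otsu** — the integer gray level maximizing the between-class variance
  of the 256-bin histogram.
* **2D Otsu** — joint thresholding of the pair (g, h) where h is the n×n
  neighborhood-mean image.  The background class is {g < s, h < t}; the pair
  (S, T) maximizes the trace of the between-class scatter

      tr σ_B(s, t) = [(μ_Ti ω0 − μ_i)² + (μ_Tj ω0 − μ_j)²] / (ω0 (1 − ω0)),

  which assumes the edge/noise quadrants of the joint histogram are
  negligible (ω0 + ω1 ≈ 1) — a good approximation after denoising.
* **modified 2D Otsu** — keeps S from 2D Otsu but replaces the overestimated
  average-grayscale threshold T by an iteratively tuned one: starting from a
  guess T_guess = w1·T_min + w2·T_max + w3·T_otsu (T_min/T_max from the
  slope of a cubic fit to the log10 frequency curve of h), T is stepped by a
  tuning parameter α proportional to the error between the particle count at
  the current T and an independent estimate N_e obtained from weighted-median
  thresholding, until the counts agree or stall.

Binarization conventions: a pixel is foreground when its value is **greater
than or equal to** the threshold (1D), or when g ≥ S and h ≥ T jointly (2D).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .morphology import MorphologySettings, postprocess

logger = logging.getLogger(__name__)

__all__ = [
    "JointHistogram",
    "ThresholdResult",
    "CubicLogFit",
    "ModifiedOtsuConfig",
    "DegenerateHistogramError",
    "FitError",
    "apply_threshold",
    "apply_threshold_2d",
    "weighted_median_threshold",
    "weighted_median_mask",
    "otsu_1d",
    "average_grayscale",
    "joint_histogram",
    "otsu_2d",
    "fit_log_counts",
    "fit_log_frequency",
    "guess_threshold",
    "estimate_particle_count",
    "modified_otsu_2d",
]


class DegenerateHistogramError(ValueError):
    """Raised when no threshold separates two non-empty classes."""


class FitError(ValueError):
    """Raised when the cubic log-frequency fit cannot be computed or has no
    usable roots at the requested slope."""


@dataclass
class JointHistogram:
    """Joint frequency r_ij and probability p_ij of (g = i, h = j) pairs.

    Bins are indexed 0..L where L = max pixel value over g and h; the
    histogram is (L+1)×(L+1) and p sums to 1.
    """

    r: np.ndarray
    p: np.ndarray
    L: int


@dataclass
class ThresholdResult:
    """Outcome of a threshold-selection method.

    ``S`` is the grayscale threshold; ``T`` the average-grayscale threshold
    (None for the 1D methods).  ``diagnostics`` carries method-specific
    values such as T_otsu, T_min/T_max, T_guess, N_e and the iteration
    trajectory of the modified method.
    """

    method: str
    S: float
    T: float | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)


@dataclass
class CubicLogFit:
    """Cubic fit P(n) of log10 frequency vs pixel value and its slope roots."""

    coefficients: np.ndarray  # highest power first, as numpy.polyfit returns
    slope_set_value: float
    domain: tuple[float, float]
    T_min: float
    T_max: float

    def __call__(self, n: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coefficients, n)

    def slope(self, n: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(np.polyder(self.coefficients), n)


def _as_uint8_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {img.shape}")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            return img.astype(np.uint8)
        raise ValueError(f"{name} must be uint8 on the 0-255 scale (run to_uint8 first)")
    return img


def apply_threshold(img: np.ndarray, T: float) -> np.ndarray:
    """Binarize: 1 where g(x, y) >= T, else 0."""
    return (np.asarray(img) >= T).astype(np.uint8)


def apply_threshold_2d(g: np.ndarray, h: np.ndarray, S: float, T: float) -> np.ndarray:
    """Binarize jointly: 1 iff g(x, y) >= S and h(x, y) >= T."""
    g = np.asarray(g)
    h = np.asarray(h)
    if g.shape != h.shape:
        raise ValueError(f"shape mismatch: g {g.shape} vs h {h.shape}")
    return ((g >= S) & (h >= T)).astype(np.uint8)


def weighted_median_threshold(img: np.ndarray, weight: float = 4.5) -> ThresholdResult:
    """Threshold at ``weight`` times the median absolute deviation of the image.

    The deviation matrix is D = |g − median(g)| and T = weight × median(D);
    the binary image marks pixels whose deviation reaches T (see
    :func:`weighted_median_mask`), i.e. a robust z-score rule that is
    insensitive to the overall background level.  On a constant image T = 0
    (all-ones mask); a warning is logged.
    """
    img = _as_uint8_image(img)
    m = float(np.median(img))
    deviation = np.abs(img.astype(np.float64) - m)
    mad = float(np.median(deviation))
    fallback = False
    if mad == 0 and img.max() != img.min():
        # More than half the pixels sit exactly at the median (e.g. a clipped
        # background): the median deviation is blind, so fall back to the
        # mean deviation, which still reflects the positive residual tail.
        mad = float(deviation.mean())
        fallback = True
    T = weight * mad
    if T == 0:
        logger.warning("weighted median threshold is 0 (flat image); mask will be all ones")
    return ThresholdResult(
        method="weighted_median",
        S=T,
        diagnostics={"median": m, "mad": mad, "weight": weight, "mean_fallback": fallback},
    )


def weighted_median_mask(img: np.ndarray, result: ThresholdResult) -> np.ndarray:
    """Binarize by thresholding the deviation matrix: 1 iff |g − median| >= T."""
    img = _as_uint8_image(img)
    deviation = np.abs(img.astype(np.float64) - result.diagnostics["median"])
    return apply_threshold(deviation, result.S)


def otsu_1d(img: np.ndarray) -> ThresholdResult:
    """1D Otsu: integer threshold S maximizing the between-class variance.

    The background class is {g < S}, the object class {g >= S}; ties are
    broken toward the smallest S.  ``diagnostics["S_normalized"]`` reports
    S/255 on the unit scale.
    """
    img = _as_uint8_image(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    if np.count_nonzero(hist) < 2:
        s = int(img.flat[0])
        logger.warning("otsu_1d: constant image, degenerate threshold %d", s)
        return ThresholdResult(
            method="otsu1d", S=s, diagnostics={"S_normalized": s / 255.0, "degenerate": True}
        )
    values = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)
    mu = np.cumsum(values * p)
    mu_total = mu[-1]
    # Split at s: class0 holds values < s, i.e. cumulants up to index s-1.
    w0 = omega[:-1]
    m0 = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - m0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[(w0 <= 0) | (w0 >= 1)] = -np.inf
    s = int(np.argmax(sigma_b)) + 1
    return ThresholdResult(
        method="otsu1d",
        S=s,
        diagnostics={"S_normalized": s / 255.0, "sigma_b_max": float(sigma_b[s - 1])},
    )


def average_grayscale(img: np.ndarray, n: int = 3) -> np.ndarray:
    """Neighborhood-mean image h(x, y): mean of the n×n window around each
    pixel (replicate-padded borders), rounded to the nearest integer, uint8."""
    img = _as_uint8_image(img)
    if n % 2 == 0 or n < 1:
        raise ValueError(f"window size must be odd and >= 1, got {n}")
    if n > min(img.shape):
        raise ValueError(f"window size {n} exceeds image extent {img.shape}")
    kernel = np.ones((n, n), dtype=np.float64)
    sums = ndimage.convolve(img.astype(np.float64), kernel, mode="nearest")
    return np.floor(sums / (n * n) + 0.5).astype(np.uint8)


def joint_histogram(g: np.ndarray, h: np.ndarray) -> JointHistogram:
    """Joint (g, h) histogram over bins 0..L, L = max pixel value of g or h."""
    g = _as_uint8_image(g, "g")
    h = _as_uint8_image(h, "h")
    if g.shape != h.shape:
        raise ValueError(f"shape mismatch: g {g.shape} vs h {h.shape}")
    L = int(max(g.max(), h.max()))
    r = np.zeros((L + 1, L + 1), dtype=np.int64)
    np.add.at(r, (g.ravel().astype(np.intp), h.ravel().astype(np.intp)), 1)
    return JointHistogram(r=r, p=r / g.size, L=L)


def otsu_2d(g: np.ndarray, h: np.ndarray) -> ThresholdResult:
    """2D Otsu: exhaustive maximization of tr σ_B(s, t) over (s, t) ∈ [1, L]².

    The background class is {g < s, h < t}; cells with ω0 ∈ {0, 1} are
    skipped (undefined denominator); ties break toward the smallest s, then
    the smallest t.
    """
    jh = joint_histogram(g, h)
    p = jh.p
    L = jh.L
    idx = np.arange(L + 1, dtype=np.float64)
    P = p.cumsum(axis=0).cumsum(axis=1)
    Mi = (idx[:, None] * p).cumsum(axis=0).cumsum(axis=1)
    Mj = (idx[None, :] * p).cumsum(axis=0).cumsum(axis=1)
    mu_ti = Mi[-1, -1]
    mu_tj = Mj[-1, -1]
    # ω0(s, t) = Σ_{i<s, j<t} p_ij for s, t in 1..L → cumulative index s-1, t-1.
    w0 = P[:-1, :-1] if L >= 1 else P
    mi = Mi[:-1, :-1]
    mj = Mj[:-1, :-1]
    valid = (w0 > 0) & (w0 < 1)
    if not valid.any():
        raise DegenerateHistogramError(
            "joint histogram admits no (s, t) with two non-empty classes "
            "(image is constant in g and h)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tr = ((mu_ti * w0 - mi) ** 2 + (mu_tj * w0 - mj) ** 2) / (w0 * (1.0 - w0))
    tr[~valid] = -np.inf
    flat = int(np.argmax(tr))  # row-major → smallest s, then smallest t
    s_idx, t_idx = divmod(flat, tr.shape[1])
    return ThresholdResult(
        method="otsu2d",
        S=s_idx + 1,
        T=t_idx + 1,
        diagnostics={"tr_sigma_b_max": float(tr[s_idx, t_idx]), "L": L},
    )


def fit_log_counts(counts: np.ndarray, slope_set_value: float = -0.05) -> CubicLogFit:
    """Fit log10 frequency vs pixel value with a cubic and locate the two
    pixel values where the fitted slope equals ``slope_set_value``.

    ``counts[n]`` is the frequency of pixel value n; zero-count bins are
    excluded (log undefined).  The smaller root is T_min, the larger T_max.
    """
    counts = np.asarray(counts, dtype=np.float64)
    ns = np.nonzero(counts > 0)[0].astype(np.float64)
    if ns.size < 4:
        raise FitError(f"cubic fit needs >= 4 populated bins, got {ns.size}")
    logk = np.log10(counts[ns.astype(int)])
    coeffs = np.polyfit(ns, logk, 3)
    deriv = np.polyder(coeffs)
    roots = np.roots(deriv - np.array([0.0, 0.0, slope_set_value]))
    real = roots[np.abs(roots.imag) < 1e-9].real
    lo, hi = float(ns.min()), float(ns.max())
    in_domain = np.sort(real[(real >= lo) & (real <= hi)])
    if in_domain.size < 2:
        raise FitError(
            f"slope {slope_set_value} is crossed {in_domain.size} time(s) inside the "
            f"fit domain [{lo:g}, {hi:g}]; relax slope_set_value"
        )
    return CubicLogFit(
        coefficients=coeffs,
        slope_set_value=slope_set_value,
        domain=(lo, hi),
        T_min=float(in_domain[0]),
        T_max=float(in_domain[-1]),
    )


def fit_log_frequency(h: np.ndarray, slope_set_value: float = -0.05) -> CubicLogFit:
    """Cubic log-frequency fit of the average-grayscale image h(x, y)."""
    h = _as_uint8_image(h, "h")
    counts = np.bincount(h.ravel(), minlength=256)
    return fit_log_counts(counts, slope_set_value)


def guess_threshold(
    T_min: float,
    T_max: float,
    T_otsu: float,
    w1: float = 0.6,
    w2: float = 0.2,
    w3: float = 0.2,
) -> float:
    """Initial average-grayscale threshold: w1·T_min + w2·T_max + w3·T_otsu.

    The default weights (0.6, 0.2, 0.2) bias the guess toward T_min because
    plain 2D Otsu systematically overestimates T on low object-to-background
    images.
    """
    if min(w1, w2, w3) < 0:
        raise ValueError("weights must be non-negative")
    return w1 * T_min + w2 * T_max + w3 * T_otsu


def _count_particles(mask: np.ndarray, morphology: MorphologySettings) -> int:
    cleaned = postprocess(mask, morphology)
    structure = ndimage.generate_binary_structure(2, 2 if morphology.connectivity == 8 else 1)
    _, n = ndimage.label(cleaned, structure=structure)
    return int(n)


def estimate_particle_count(
    img: np.ndarray,
    weight: float = 4.5,
    morphology: MorphologySettings | None = None,
) -> int:
    """Independent particle-count estimate N_e from weighted-median thresholding.

    The binarization is post-processed with the *same* morphology settings as
    the main pipeline so that the count comparison inside the modified 2D
    Otsu iteration is like-for-like.
    """
    morphology = morphology or MorphologySettings()
    img = _as_uint8_image(img)
    if img.max() == img.min():
        return 0  # featureless image: nothing deviates from the background
    res = weighted_median_threshold(img, weight)
    mask = weighted_median_mask(img, res)
    return _count_particles(mask, morphology)


@dataclass(frozen=True)
class ModifiedOtsuConfig:
    """Knobs of the modified 2D Otsu iteration.

    α is a clamped proportional rule on the count error e = N_e − N_g:
    α = clip(η·e, ±alpha_max), with |α| forced to at least one gray level
    whenever e ≠ 0, so every non-converged iteration moves T.
    """

    weight: float = 4.5
    n_avg: int = 3
    slope_set_value: float = -0.05
    weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    eta: float = 0.5
    alpha_max: float = 8.0
    stall_limit: int = 20
    max_iters: int = 50
    morphology: MorphologySettings = field(default_factory=MorphologySettings)


def modified_otsu_2d(
    g: np.ndarray,
    h: np.ndarray,
    config: ModifiedOtsuConfig | None = None,
) -> ThresholdResult:
    """Modified 2D Otsu: S from 2D Otsu, T tuned to match an independent count.

    Starting from T_guess, each iteration binarizes with (S, T), applies the
    pipeline morphology, counts particles N_g, and steps T by α (sign of the
    error N_e − N_g).  The iteration stops when N_g == N_e, when N_g has been
    constant for ``stall_limit`` consecutive iterations, or at ``max_iters``;
    in the two non-exact cases the best-visited T (minimal |N_e − N_g|,
    earliest on ties) is returned and flagged accordingly.
    """
    cfg = config or ModifiedOtsuConfig()
    g = _as_uint8_image(g, "g")
    h = _as_uint8_image(h, "h")
    base = otsu_2d(g, h)
    S = float(base.S)
    T_otsu = float(base.T)
    L = base.diagnostics["L"]
    # The set slope may be crossed fewer than twice inside the populated
    # domain (short or flat histogram tails); relax it toward zero until the
    # fit yields a (T_min, T_max) pair.  The fit only seeds T_guess — the
    # count-matching iteration below is what fixes T.
    slope = cfg.slope_set_value
    fit = None
    for _ in range(6):
        try:
            fit = fit_log_frequency(h, slope)
            break
        except FitError:
            slope /= 2.0
    w1, w2, w3 = cfg.weights
    if fit is not None:
        if slope != cfg.slope_set_value:
            logger.warning(
                "slope_set_value relaxed from %g to %g to locate (T_min, T_max)",
                cfg.slope_set_value,
                slope,
            )
        T_min, T_max = fit.T_min, fit.T_max
        T_guess = guess_threshold(T_min, T_max, T_otsu, w1, w2, w3)
    else:
        # The fitted slope crosses the set value fewer than twice anywhere in
        # the populated domain (monotone log-frequency curve): no (T_min,
        # T_max) pair exists.  Start the iteration at the plain 2D Otsu value
        # instead — the refinement below walks T down from there.
        logger.warning(
            "log-frequency fit has no (T_min, T_max) pair at any tested slope; "
            "seeding the iteration at T_otsu = %g",
            T_otsu,
        )
        T_min = T_max = float("nan")
        T_guess = T_otsu
    N_e = estimate_particle_count(g, cfg.weight, cfg.morphology)

    T = float(T_guess)
    trajectory: list[dict[str, float]] = []
    best_T, best_err = T, math.inf
    converged = False
    stall = 0
    prev_ng: int | None = None
    for _ in range(cfg.max_iters):
        mask = apply_threshold_2d(g, h, S, T)
        N_g = _count_particles(mask, cfg.morphology)
        e = N_e - N_g
        trajectory.append({"T": T, "N_g": N_g, "error": e})
        # Ties prefer the latest (lowest) T: a lower threshold on the count
        # plateau retains more of each particle's true extent.
        if abs(e) <= best_err:
            best_T, best_err = T, abs(e)
        if e == 0:
            converged = True
            break
        if prev_ng is not None and N_g == prev_ng:
            stall += 1
            if stall >= cfg.stall_limit:
                converged = True  # N_g constant over consecutive steps
                break
        else:
            stall = 0
        prev_ng = N_g
        alpha = float(np.clip(cfg.eta * e, -cfg.alpha_max, cfg.alpha_max))
        if abs(alpha) < 1.0:
            alpha = math.copysign(1.0, e)
        if stall:
            # Accelerate across count plateaus: while N_g repeats, the count
            # carries no gradient information, so grow the step geometrically
            # (capped) to reach the plateau edge before the stall cutoff.
            alpha = math.copysign(min(abs(alpha) * 2.0**stall, cfg.alpha_max), alpha)
        T = float(np.clip(round(T - alpha), 1.0, float(L)))
    final_T = best_T
    if not converged:
        logger.warning(
            "modified 2D Otsu did not converge in %d iterations; returning best T=%g "
            "(|N_e - N_g| = %g)",
            cfg.max_iters,
            final_T,
            best_err,
        )
    return ThresholdResult(
        method="modified_otsu2d",
        S=S,
        T=final_T,
        diagnostics={
            "T_otsu": T_otsu,
            "T_min": T_min,
            "T_max": T_max,
            "slope_set_value_used": fit.slope_set_value if fit is not None else None,
            "T_guess": T_guess,
            "N_e": N_e,
            "L": L,
            "iterations": len(trajectory),
            "trajectory": trajectory,
            "converged": converged,
            "tr_sigma_b_max": base.diagnostics["tr_sigma_b_max"],
        },
    )
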