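"""Denoising chain: median filtering, total-variation flow, FFT background removal.

The chain targets the three dominant corruptions of widefield fluorescence
images of aggregates: impulsive/long-tailed detector noise (median filter),
Poisson/Gaussian shot and read noise (total-variation gradient descent), and
slowly varying illumination (ideal FFT low-pass background estimate, removed
by per-pixel division or subtraction).

Total variation here is the L1 norm of the discrete image gradient,

    TV(g) = sum_i sqrt(|∇x g_i|^2 + |∇y g_i|^2),

with forward differences and replicate boundary (the last row/column
difference is zero).  TV is reduced by explicit gradient descent

    g <- g - τ ∇_g TV(g),   ∇_g TV(g) = -div( ∇g / sqrt(|∇g|^2 + ε^2) ),

where the divergence is the negative adjoint of the forward difference, τ is
chosen by backtracking line search, and ε only guards flat regions against
division by zero.  The flow has no data-fidelity term; early stopping on the
relative image change E_n = ||g^(n+1) - g^(n)|| / ||g^(n)|| (Frobenius norms)
below a tolerance acts as the regularizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "TVParams",
    "TVTrace",
    "BackgroundModel",
    "median_filter",
    "total_variation",
    "tv_denoise",
    "estimate_background",
    "normalize_background",
]


@dataclass(frozen=True)
class TVParams:
    """Parameters of the TV gradient-descent flow.

    tolerance
        Convergence bound on the relative image change E_n (default 0.005).
    epsilon_scale
        ε = epsilon_scale × dynamic range of the input; regularizes the
        gradient magnitude at flat regions.
    max_iters
        Iteration cap.
    step_rule
        ``"line_search"`` (backtracking, TV non-increasing per accepted step)
        or ``"fixed"`` (constant τ = ``fixed_tau``).
    tau0_scale
        Initial line-search step as a fraction of the dynamic range.
    """

    tolerance: float = 0.005
    epsilon_scale: float = 1e-6
    max_iters: int = 200
    step_rule: str = "line_search"
    tau0_scale: float = 0.25
    fixed_tau: float = 0.1

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if not self.epsilon_scale > 0:
            raise ValueError("epsilon_scale must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.step_rule not in ("line_search", "fixed"):
            raise ValueError(f"unknown step_rule {self.step_rule!r}")


@dataclass
class TVTrace:
    """Per-iteration record of the TV flow."""

    tv_values: list[float] = field(default_factory=list)
    rel_change: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


@dataclass
class BackgroundModel:
    """Low-pass illumination estimate and how to remove it.

    ``mode`` is ``"divide"`` (ratio normalization) or ``"subtract"``
    (shading subtraction, clipped at zero).
    """

    background: np.ndarray
    cutoff_fraction: float
    mode: str = "divide"


def median_filter(img: np.ndarray, n: int = 3) -> np.ndarray:
    """Replace every pixel with the median of its n×n neighborhood.

    Borders use replicate padding; the output keeps the input dtype and shape.
    """
    if n % 2 == 0 or n < 1:
        raise ValueError(f"window size must be odd and >= 1, got {n}")
    return ndimage.median_filter(np.asarray(img), size=n, mode="nearest")


def _forward_gradient(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences along columns (x) and rows (y), replicate edge."""
    gx = np.zeros_like(g)
    gy = np.zeros_like(g)
    gx[:, :-1] = g[:, 1:] - g[:, :-1]
    gy[:-1, :] = g[1:, :] - g[:-1, :]
    return gx, gy


def _adjoint_x(p: np.ndarray) -> np.ndarray:
    """Adjoint of the forward column-difference operator (K >= 2)."""
    out = np.empty_like(p)
    out[:, 0] = -p[:, 0]
    out[:, 1:-1] = p[:, :-2] - p[:, 1:-1]
    out[:, -1] = p[:, -2]
    return out


def _adjoint_y(p: np.ndarray) -> np.ndarray:
    out = np.empty_like(p)
    out[0, :] = -p[0, :]
    out[1:-1, :] = p[:-2, :] - p[1:-1, :]
    out[-1, :] = p[-2, :]
    return out


def total_variation(img: np.ndarray) -> float:
    """Total variation of the image: Σ sqrt(|∇x g|² + |∇y g|²)."""
    g = np.asarray(img, dtype=np.float64)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("total_variation requires at least a 2x2 image")
    gx, gy = _forward_gradient(g)
    return float(np.sum(np.hypot(gx, gy)))


def _tv_gradient(g: np.ndarray, eps: float) -> np.ndarray:
    gx, gy = _forward_gradient(g)
    norm = np.sqrt(gx * gx + gy * gy + eps * eps)
    return _adjoint_x(gx / norm) + _adjoint_y(gy / norm)


def tv_denoise(img: np.ndarray, params: TVParams | None = None) -> tuple[np.ndarray, TVTrace]:
    """Run the TV gradient-descent flow with early stopping.

    Returns the denoised image (float64) and the iteration trace.  An image
    with zero TV (constant) or zero norm is returned unchanged, converged at
    iteration 0.
    """
    params = params or TVParams()
    g = np.asarray(img, dtype=np.float64).copy()
    trace = TVTrace()
    rng = float(g.max() - g.min())
    if rng == 0 or np.linalg.norm(g) == 0:
        trace.converged = True
        return g, trace
    eps = params.epsilon_scale * rng
    tau0 = params.tau0_scale * rng
    tv_cur = total_variation(g)
    for _ in range(params.max_iters):
        if tv_cur == 0:
            trace.converged = True
            break
        d = _tv_gradient(g, eps)
        if params.step_rule == "fixed":
            g_new = g - params.fixed_tau * d
            tv_new = total_variation(g_new)
        else:
            tau = tau0
            g_new = None
            for _half in range(40):
                cand = g - tau * d
                tv_cand = total_variation(cand)
                if tv_cand < tv_cur:
                    g_new, tv_new = cand, tv_cand
                    break
                tau *= 0.5
            if g_new is None:
                # No descent step exists at any tested τ: stationary point.
                trace.converged = True
                break
        denom = np.linalg.norm(g)
        e_n = np.linalg.norm(g_new - g) / denom
        g = g_new
        tv_cur = tv_new
        trace.tv_values.append(tv_new)
        trace.rel_change.append(float(e_n))
        trace.iterations += 1
        if e_n < params.tolerance:
            trace.converged = True
            break
    return g, trace


def estimate_background(
    img: np.ndarray, cutoff_fraction: float = 0.02, mode: str = "divide"
) -> BackgroundModel:
    """Estimate the slowly varying illumination by ideal FFT low-pass filtering.

    All 2D frequency components with radial frequency above
    ``cutoff_fraction`` × Nyquist are zeroed; the real part of the inverse
    transform is the background.  The operation is linear in the input.
    """
    if not 0 < cutoff_fraction <= 1:
        raise ValueError("cutoff_fraction must lie in (0, 1]")
    if mode not in ("divide", "subtract"):
        raise ValueError(f"unknown background mode {mode!r}")
    g = np.asarray(img, dtype=np.float64)
    fy = np.fft.fftfreq(g.shape[0])[:, None]
    fx = np.fft.fftfreq(g.shape[1])[None, :]
    radius = np.sqrt(fx * fx + fy * fy)
    keep = radius <= cutoff_fraction * 0.5  # Nyquist = 0.5 cycles/pixel
    bg = np.fft.ifft2(np.fft.fft2(g) * keep).real
    return BackgroundModel(background=bg, cutoff_fraction=cutoff_fraction, mode=mode)


def normalize_background(img: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """Remove the illumination background and quantize onto 0–255.

    ``divide`` mode returns ``to_uint8(img / background)`` (background floored
    to a small positive value where necessary, with a warning); ``subtract``
    mode returns ``to_uint8(max(img - background, 0))``.
    """
    from .imgio import to_uint8

    g = np.asarray(img, dtype=np.float64)
    b = np.asarray(bg.background, dtype=np.float64)
    if g.shape != b.shape:
        raise ValueError(f"shape mismatch: image {g.shape} vs background {b.shape}")
    if bg.mode == "divide":
        floor = 1e-6 * max(1.0, float(np.abs(b).max()))
        if np.any(b < floor):
            logger.warning(
                "background has %d non-positive pixels; flooring to %.3g",
                int(np.sum(b < floor)),
                floor,
            )
            b = np.maximum(b, floor)
        out = g / b
    else:
        out = np.maximum(g - b, 0.0)
    return to_uint8(out)
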