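"""Restoration quality metrics: PSNR and mean SSIM.

Both assume the 0-255 intensity convention (``peak = 255``).  SSIM follows
the standard configuration: 11-tap Gaussian window with sigma 1.5,
stability constants K1 = 0.01, K2 = 0.03, population (Gaussian-weighted)
local statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .forward_model import as_image

__all__ = ["psnr", "ssim"]


def psnr(x, ref, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    x = as_image(x, "x")
    ref = as_image(ref, "ref")
    if x.shape != ref.shape:
        raise ValueError("shapes differ")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def _gaussian_window_filter(img: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma, mode="reflect", truncate=truncate)


def ssim(x, ref, peak: float = 255.0) -> float:
    """Mean structural similarity index over an 11x11 Gaussian window."""
    x = as_image(x, "x")
    ref = as_image(ref, "ref")
    if x.shape != ref.shape:
        raise ValueError("shapes differ")
    win = 11
    if min(x.shape) < win:
        raise ValueError(f"images must be at least {win} pixels per side")
    sigma = 1.5
    truncate = (win - 1) / 2 / sigma  # 11-tap kernel
    k1, k2 = 0.01, 0.03
    c1, c2 = (k1 * peak) ** 2, (k2 * peak) ** 2

    mu_x = _gaussian_window_filter(x, sigma, truncate)
    mu_y = _gaussian_window_filter(ref, sigma, truncate)
    var_x = _gaussian_window_filter(x * x, sigma, truncate) - mu_x**2
    var_y = _gaussian_window_filter(ref * ref, sigma, truncate) - mu_y**2
    cov = _gaussian_window_filter(x * ref, sigma, truncate) - mu_x * mu_y

    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    ssim_map = num / den
    # crop the window margin so boundary handling does not bias the mean
    pad = (win - 1) // 2
    return float(ssim_map[pad:-pad, pad:-pad].mean())
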