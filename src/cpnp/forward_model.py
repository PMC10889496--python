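"""Gaussian blur forward model and its exact frequency-domain solves.

Images are plain 2-D ``float64`` arrays on the 0-255 intensity convention.
The blur operator ``A`` is circular (periodic) convolution with a centred,
normalised point-spread function, realised as pointwise multiplication by
an optical transfer function (OTF) in the discrete Fourier domain.  Under
periodic boundary conditions ``A^T A`` is diagonalised by the DFT, so the
quadratic x-subproblem of the constrained ADMM solver is solved exactly by
one FFT round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

__all__ = [
    "PSFKernel",
    "BlurOperator",
    "DegradationSpec",
    "as_image",
    "gaussian_psf",
    "make_operator",
    "degrade",
    "solve_x_update",
]


def as_image(x, name: str = "image") -> np.ndarray:
    """Validate and coerce ``x`` to a finite 2-D float64 array."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have at least one pixel per axis")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class PSFKernel:
    """Sampled point-spread function with odd side length, summing to 1."""

    weights: np.ndarray
    sigma_a: float

    def __post_init__(self):
        w = as_image(self.weights, "psf weights")
        if w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("PSF side lengths must be odd")
        if np.any(w < 0):
            raise ValueError("PSF weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("PSF weights must sum to 1")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class BlurOperator:
    """Circular-convolution blur ``A`` stored as its frequency response.

    ``otf`` is the DFT of the zero-padded, centre-shifted kernel; ``apply``
    multiplies by it, ``adjoint`` by its complex conjugate (circular
    correlation).  For a normalised non-negative kernel ``|otf| <= 1``.
    """

    otf: np.ndarray
    shape: tuple[int, int]

    def apply(self, x) -> np.ndarray:
        x = as_image(x, "x")
        self._check_shape(x)
        return np.real(spfft.ifft2(spfft.fft2(x) * self.otf))

    def adjoint(self, y) -> np.ndarray:
        y = as_image(y, "y")
        self._check_shape(y)
        return np.real(spfft.ifft2(spfft.fft2(y) * np.conj(self.otf)))

    def _check_shape(self, x: np.ndarray) -> None:
        if x.shape != self.shape:
            raise ValueError(f"image shape {x.shape} does not match operator shape {self.shape}")


@dataclass(frozen=True)
class DegradationSpec:
    """Degradation settings: Gaussian PSF width, AWGN level, RNG seed."""

    sigma_a: float
    sigma_eta: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be positive")
        if self.sigma_eta < 0:
            raise ValueError("sigma_eta must be non-negative")


def gaussian_psf(sigma_a: float, size: int | None = None) -> PSFKernel:
    """Sample an isotropic Gaussian PSF, truncate it and renormalise to sum 1.

    Parameters
    ----------
    sigma_a : float
        Standard deviation of the Gaussian in pixels; must be positive.
    size : int, optional
        Odd side length of the sampled kernel.  When omitted, the smallest
        odd integer >= ``8 * sigma_a + 1`` is used (about 4 sigma of support
        on each side of the centre).
    """
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    if size is None:
        size = int(np.ceil(8.0 * sigma_a + 1.0))
        if size % 2 == 0:
            size += 1
    if size % 2 == 0:
        raise ValueError("PSF size must be odd")
    half = size // 2
    idx = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(idx**2) / (2.0 * sigma_a**2))
    kernel = np.outer(g1, g1)
    kernel /= kernel.sum()
    return PSFKernel(weights=kernel, sigma_a=float(sigma_a))


def make_operator(psf: PSFKernel, shape: tuple[int, int]) -> BlurOperator:
    """Embed a PSF into a frequency-domain circular-convolution operator."""
    h, w = shape
    kh, kw = psf.weights.shape
    if kh > h or kw > w:
        raise ValueError(f"kernel shape {psf.weights.shape} exceeds image shape {shape}")
    padded = np.zeros((h, w), dtype=np.float64)
    padded[:kh, :kw] = psf.weights
    # centre the kernel at the origin so convolution does not translate
    padded = np.roll(padded, shift=(-(kh // 2), -(kw // 2)), axis=(0, 1))
    otf = spfft.fft2(padded)
    return BlurOperator(otf=otf, shape=(h, w))


def degrade(x, spec: DegradationSpec, op: BlurOperator | None = None) -> np.ndarray:
    """Simulate the acquisition b = A x + eta.

    ``eta`` is i.i.d. zero-mean Gaussian with standard deviation
    ``spec.sigma_eta``; the draw is reproducible given ``spec.seed``.  No
    clipping is applied — degraded values may leave [0, 255].
    """
    x = as_image(x, "x")
    if op is None:
        op = make_operator(gaussian_psf(spec.sigma_a), x.shape)
    blurred = op.apply(x)
    if spec.sigma_eta == 0:
        return blurred
    rng = np.random.default_rng(spec.seed)
    return blurred + rng.normal(0.0, spec.sigma_eta, size=x.shape)


def solve_x_update(
    op: BlurOperator,
    b,
    r,
    v,
    lam_r,
    lam_v,
    beta_r: float,
    beta_v: float,
) -> np.ndarray:
    """Exact minimiser of the quadratic x-subproblem of the constrained ADMM.

    Solves ``argmin_x  beta_r/2 ||Ax - b - r + lam_r/beta_r||^2
    + beta_v/2 ||x - v + lam_v/beta_v||^2`` via the normal equations
    ``((beta_r/beta_v) A^T A + I) x = rhs`` with
    ``rhs = (beta_r/beta_v) A^T (b + r - lam_r/beta_r) + v - lam_v/beta_v``,
    inverted by pointwise division in the Fourier domain (exact under
    periodic boundaries).
    """
    if beta_r <= 0 or beta_v <= 0:
        raise ValueError("penalties beta_r, beta_v must be positive")
    b = as_image(b, "b")
    op._check_shape(b)
    for arr, name in ((r, "r"), (v, "v"), (lam_r, "lam_r"), (lam_v, "lam_v")):
        arr = np.asarray(arr)
        if arr.shape != b.shape:
            raise ValueError(f"{name} shape {arr.shape} does not match b shape {b.shape}")
    ratio = beta_r / beta_v
    rhs = ratio * op.adjoint(np.asarray(b) + r - lam_r / beta_r) + (v - lam_v / beta_v)
    denom = ratio * np.abs(op.otf) ** 2 + 1.0
    return np.real(spfft.ifft2(spfft.fft2(rhs) / denom))
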