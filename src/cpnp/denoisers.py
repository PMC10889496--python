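"""Pluggable denoisers used as implicit priors inside the ADMM solvers.

A denoiser ``D`` stands in for the proximity operator of an unknown
regulariser.  Two families are provided:

* exact convex proxes (``tikhonov``, ``soft_threshold``) for which the
  implied prior is known in closed form — these make the solver verifiable
  against independent convex oracles;
* practical image denoisers (``tv``, ``nlm``, optionally ``bm3d``) whose
  prior is only implicit.

All denoisers are deterministic, shape-preserving maps on 2-D float arrays
using the 0-255 intensity convention.  A registration hook lets learned
denoisers (e.g. a trained CNN) be plugged in without the package shipping
any weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from skimage.restoration import denoise_nl_means, denoise_tv_chambolle

from .errors import UnavailableDenoiserError
from .forward_model import as_image

__all__ = [
    "Denoiser",
    "tikhonov_denoise",
    "soft_threshold_denoise",
    "tv_denoise",
    "nlm_denoise",
    "bm3d_denoise",
    "make_denoiser",
    "register_plugin",
    "available_denoisers",
]


@dataclass(frozen=True)
class Denoiser:
    """A named denoiser with a scalar strength and an optional schedule.

    ``strength`` semantics depend on the backend: prox weight for the convex
    proxes, TV weight for ``tv``, assumed noise standard deviation for
    ``nlm``/``bm3d``.  ``strength_schedule`` is either ``"fixed"`` or
    ``"inv-sqrt-beta"``; in the latter case the solver rescales strength by
    ``1/sqrt(beta_v_k / beta_v_0)`` as the penalty grows, consistent with
    the denoiser standing in for a prox under penalty ``beta_v``.
    """

    name: str
    strength: float
    fn: Callable[[np.ndarray, float], np.ndarray]
    strength_schedule: str = "fixed"
    params: Mapping[str, object] = field(default_factory=dict)

    def __call__(self, u: np.ndarray, strength: float | None = None) -> np.ndarray:
        s = self.strength if strength is None else strength
        out = self.fn(as_image(u, "u"), s)
        out = np.asarray(out, dtype=np.float64)
        if out.shape != np.asarray(u).shape:
            raise ValueError(f"denoiser '{self.name}' changed the image shape")
        if not np.all(np.isfinite(out)):
            raise ValueError(f"denoiser '{self.name}' produced non-finite values")
        return out


def tikhonov_denoise(u, alpha: float) -> np.ndarray:
    """Exact prox of the quadratic prior ``(alpha/2)||.||^2``: a rescaling."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return as_image(u, "u") / (1.0 + alpha)


def soft_threshold_denoise(u, t: float) -> np.ndarray:
    """Exact prox of ``t ||.||_1``: elementwise soft thresholding."""
    if t < 0:
        raise ValueError("t must be non-negative")
    u = np.asarray(u, dtype=np.float64)
    return np.sign(u) * np.maximum(np.abs(u) - t, 0.0)


def tv_denoise(u, weight: float) -> np.ndarray:
    """Approximate prox of ``weight * TV(.)`` via Chambolle's dual scheme."""
    if weight < 0:
        raise ValueError("weight must be non-negative")
    u = as_image(u, "u")
    if weight == 0:
        return u.copy()
    return denoise_tv_chambolle(u, weight=weight, eps=1e-5, max_num_iter=200)


def nlm_denoise(u, strength: float) -> np.ndarray:
    """Non-local means; ``strength`` is the assumed noise std on 0-255."""
    if strength < 0:
        raise ValueError("strength must be non-negative")
    u = as_image(u, "u")
    if strength == 0:
        return u.copy()
    return denoise_nl_means(
        u, h=0.8 * strength, sigma=strength,
        patch_size=5, patch_distance=6, fast_mode=True,
    )


def bm3d_denoise(u, strength: float) -> np.ndarray:
    """BM3D collaborative filtering; requires the optional ``bm3d`` package."""
    try:
        import bm3d  # noqa: PLC0415
    except ImportError as exc:
        raise UnavailableDenoiserError(
            "the 'bm3d' denoiser requires the optional 'bm3d' package "
            "(pip install bm3d)"
        ) from exc
    if strength < 0:
        raise ValueError("strength must be non-negative")
    u = as_image(u, "u")
    if strength == 0:
        return u.copy()
    return np.asarray(bm3d.bm3d(u, sigma_psd=strength), dtype=np.float64)


def _identity(u, _strength: float) -> np.ndarray:
    return np.asarray(u, dtype=np.float64).copy()


_PLUGINS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {}

_BUILTINS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "identity": _identity,
    "tikhonov": tikhonov_denoise,
    "soft_threshold": soft_threshold_denoise,
    "tv": tv_denoise,
    "nlm": nlm_denoise,
    "bm3d": bm3d_denoise,
}


def register_plugin(name: str, fn: Callable[[np.ndarray, float], np.ndarray]) -> None:
    """Register a learned-denoiser backend under ``name`` (e.g. ``dncnn-plugin``).

    The callable must map ``(image, strength) -> image`` deterministically,
    preserving shape and finiteness.
    """
    if not callable(fn):
        raise ValueError("plugin must be callable")
    _PLUGINS[name] = fn


def available_denoisers() -> list[str]:
    return sorted(set(_BUILTINS) | set(_PLUGINS) | {"dncnn-plugin"})


def make_denoiser(name: str, params: Mapping[str, object] | None = None) -> Denoiser:
    """Look up a denoiser by name and configure its strength/schedule.

    ``params`` accepts ``strength`` (aliases: ``alpha``, ``t``, ``weight``,
    ``sigma``) and ``strength_schedule``.
    """
    params = dict(params or {})
    strength = params.pop("strength", None)
    for alias in ("alpha", "t", "weight", "sigma"):
        if alias in params:
            strength = params.pop(alias)
    schedule = params.pop("strength_schedule", "fixed")
    if schedule not in ("fixed", "inv-sqrt-beta"):
        raise ValueError("strength_schedule must be 'fixed' or 'inv-sqrt-beta'")

    if name in _PLUGINS:
        fn = _PLUGINS[name]
    elif name == "dncnn-plugin":
        raise UnavailableDenoiserError(
            "no backend registered for 'dncnn-plugin'; call "
            "cpnp.denoisers.register_plugin('dncnn-plugin', fn) with a callable "
            "wrapping trained DnCNN weights"
        )
    elif name in _BUILTINS:
        fn = _BUILTINS[name]
    else:
        raise ValueError(
            f"unknown denoiser '{name}'; available: {', '.join(available_denoisers())}"
        )
    if strength is None:
        strength = 0.0 if name == "identity" else 1.0
    return Denoiser(name=name, strength=float(strength), fn=fn,
                    strength_schedule=schedule, params=params)
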