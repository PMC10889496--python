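"""Constrained Plug-and-Play ADMM and the unconstrained baselines.

The constrained solver (``cpnp_restore``) minimises an implicit
denoiser-induced prior subject to the residual-ball constraint
``||Ax - b||_2 <= R``.  Splitting ``r = Ax - b`` and ``x = v``, the
augmented Lagrangian with penalties ``beta_r``, ``beta_v`` is optimised by
block sweeps:

1. x-update — exact frequency-domain solve of the coupled quadratic;
2. v-update — ``v = D(x + lam_v / beta_v)``, the denoiser standing in for
   the prox of the unknown prior;
3. r-update — Euclidean projection of ``Ax - b + lam_r / beta_r`` onto the
   residual ball;
4. dual ascent on both multipliers, followed by geometric growth of the
   penalties (``beta <- gamma * beta``).

The dual update for the residual constraint uses the ascent direction
``lam_r <- lam_r + beta_r (Ax - b - r)``, i.e. the sign consistent with the
penalty term ``||Ax - b - r + lam_r/beta_r||^2`` of the augmented
Lagrangian.

Two unconstrained baselines share the same diagnostics: plug-and-play via
half-quadratic splitting (``pnp_hqs_restore``) and regularisation by
denoising via ADMM (``red_admm_restore``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import ConstraintSpec, project_residual, residual_sigma
from .denoisers import Denoiser
from .errors import NumericalFailureError
from .forward_model import BlurOperator, as_image, solve_x_update

__all__ = [
    "SolverConfig",
    "SolverState",
    "RestorationResult",
    "init_state",
    "cpnp_step",
    "update_penalties",
    "cpnp_restore",
    "pnp_hqs_restore",
    "red_admm_restore",
]

_EPS = 1e-12  # guard for the relative-change denominator


@dataclass(frozen=True)
class SolverConfig:
    """ADMM penalty schedule and stopping rule.

    Defaults follow the robust operating point of the method: unit initial
    penalties grown by 1% per iteration, stopping when the relative change
    of the iterates falls below 1e-4 or after 100 iterations.
    """

    beta_r0: float = 1.0
    beta_v0: float = 1.0
    gamma: float = 1.01
    tol: float = 1e-4
    max_iter: int = 100
    red_inner_steps: int = 1

    def __post_init__(self):
        if self.beta_r0 <= 0 or self.beta_v0 <= 0:
            raise ValueError("initial penalties must be positive")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class SolverState:
    """One ADMM iterate: primal blocks, unscaled multipliers, penalties."""

    x: np.ndarray
    v: np.ndarray
    r: np.ndarray
    lam_r: np.ndarray
    lam_v: np.ndarray
    beta_r: float
    beta_v: float
    k: int = 0


@dataclass(frozen=True)
class RestorationResult:
    """Solver output with per-iteration diagnostics.

    ``history`` holds one record per completed iteration with keys
    ``rel_change``, ``residual_norm``, ``sigma_x``, ``beta_r``, ``beta_v``.
    ``sigma_x_star`` is the residual-based noise estimate at ``x_star``.
    """

    x_star: np.ndarray
    iterations: int
    converged: bool
    history: list[dict] = field(default_factory=list)
    sigma_x_star: float = float("nan")
    method: str = ""
    metadata: dict = field(default_factory=dict)


def _check_finite(arr: np.ndarray, step: str) -> np.ndarray:
    if not np.all(np.isfinite(arr)):
        raise NumericalFailureError(step)
    return arr


def init_state(b: np.ndarray, op: BlurOperator, constraint: ConstraintSpec,
               cfg: SolverConfig, x0: np.ndarray | None = None) -> SolverState:
    """Initial state: ``x0 = b`` (unless supplied), ``v0 = 0``, zero duals,
    and ``r0`` the feasibility projection of the initial residual."""
    b = as_image(b, "b")
    x0 = b.copy() if x0 is None else as_image(x0, "x0").copy()
    zero = np.zeros_like(b)
    r0 = project_residual(op.apply(x0) - b, constraint.radius)
    return SolverState(x=x0, v=zero.copy(), r=r0, lam_r=zero.copy(),
                       lam_v=zero.copy(), beta_r=cfg.beta_r0, beta_v=cfg.beta_v0, k=0)


def cpnp_step(state: SolverState, op: BlurOperator, b: np.ndarray,
              constraint: ConstraintSpec, D: Denoiser,
              strength: float | None = None) -> SolverState:
    """One full sweep of the constrained ADMM (x, v, r, dual updates)."""
    x = _check_finite(
        solve_x_update(op, b, state.r, state.v, state.lam_r, state.lam_v,
                       state.beta_r, state.beta_v),
        "x-update",
    )
    try:
        v = _check_finite(D(x + state.lam_v / state.beta_v, strength), "v-update")
    except ValueError as exc:
        raise NumericalFailureError("v-update", str(exc)) from exc
    ax = op.apply(x)
    r = _check_finite(
        project_residual(ax - b + state.lam_r / state.beta_r, constraint.radius),
        "r-projection",
    )
    lam_r = _check_finite(state.lam_r + state.beta_r * (ax - b - r), "dual-r")
    lam_v = _check_finite(state.lam_v + state.beta_v * (x - v), "dual-v")
    return SolverState(x=x, v=v, r=r, lam_r=lam_r, lam_v=lam_v,
                       beta_r=state.beta_r, beta_v=state.beta_v, k=state.k + 1)


def update_penalties(state: SolverState, gamma: float) -> SolverState:
    """Grow both penalties geometrically; multipliers are left untouched."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    return replace(state, beta_r=state.beta_r * gamma, beta_v=state.beta_v * gamma)


def _denoiser_strength(D: Denoiser, beta_v: float, beta_v0: float) -> float | None:
    if D.strength_schedule == "inv-sqrt-beta":
        return D.strength / np.sqrt(beta_v / beta_v0)
    return None  # use the denoiser's own fixed strength


def cpnp_restore(b, op: BlurOperator, constraint: ConstraintSpec, D: Denoiser,
                 cfg: SolverConfig | None = None,
                 x0: np.ndarray | None = None) -> RestorationResult:
    """Run the constrained Plug-and-Play solver to convergence.

    Deterministic: no internal randomness, so identical inputs give
    bit-identical results.
    """
    cfg = cfg or SolverConfig()
    b = as_image(b, "b")
    state = init_state(b, op, constraint, cfg, x0)
    history: list[dict] = []
    converged = False
    for _ in range(cfg.max_iter):
        x_prev = state.x
        state = cpnp_step(state, op, b, constraint, D,
                          _denoiser_strength(D, state.beta_v, cfg.beta_v0))
        rel = np.linalg.norm(state.x - x_prev) / max(np.linalg.norm(x_prev), _EPS)
        history.append({
            "rel_change": float(rel),
            "residual_norm": float(np.linalg.norm(op.apply(state.x) - b)),
            "sigma_x": residual_sigma(op, state.x, b),
            "beta_r": state.beta_r,
            "beta_v": state.beta_v,
        })
        state = update_penalties(state, cfg.gamma)
        if rel <= cfg.tol:
            converged = True
            break
    x_star = _check_finite(state.x, "final")
    return RestorationResult(
        x_star=x_star, iterations=len(history), converged=converged,
        history=history, sigma_x_star=residual_sigma(op, x_star, b),
        method="cpnp",
        metadata={"tau": constraint.tau, "sigma_eta": constraint.sigma_eta,
                  "radius": constraint.radius, "beta_r0": cfg.beta_r0,
                  "beta_v0": cfg.beta_v0, "gamma": cfg.gamma, "tol": cfg.tol,
                  "max_iter": cfg.max_iter, "denoiser": D.name,
                  "denoiser_strength": D.strength,
                  "strength_schedule": D.strength_schedule},
    )


def pnp_hqs_restore(b, op: BlurOperator, D: Denoiser,
                    mu_schedule: float | list[float] = 1.0,
                    cfg: SolverConfig | None = None) -> RestorationResult:
    """Unconstrained plug-and-play baseline via half-quadratic splitting.

    Alternates the quadratic data-fit solve
    ``x = (A^T A + mu I)^{-1}(A^T b + mu z)`` (exact in the Fourier domain)
    with the denoising step ``z = D(x)``.  ``mu_schedule`` is either a fixed
    penalty or a per-iteration list (cycled if shorter than the run).
    """
    cfg = cfg or SolverConfig()
    b = as_image(b, "b")
    mus = [mu_schedule] if np.isscalar(mu_schedule) else list(mu_schedule)
    if any(m <= 0 for m in mus):
        raise ValueError("HQS penalties must be positive")
    from scipy import fft as spfft

    atb_hat = np.conj(op.otf) * spfft.fft2(b)
    z = b.copy()
    x = b.copy()
    history: list[dict] = []
    converged = False
    for k in range(cfg.max_iter):
        mu = mus[min(k, len(mus) - 1)]
        x_prev = x
        x = np.real(spfft.ifft2((atb_hat + mu * spfft.fft2(z))
                                / (np.abs(op.otf) ** 2 + mu)))
        _check_finite(x, "hqs-x-update")
        try:
            z = _check_finite(D(x), "hqs-denoise")
        except ValueError as exc:
            raise NumericalFailureError("hqs-denoise", str(exc)) from exc
        rel = np.linalg.norm(x - x_prev) / max(np.linalg.norm(x_prev), _EPS)
        history.append({
            "rel_change": float(rel),
            "residual_norm": float(np.linalg.norm(op.apply(x) - b)),
            "sigma_x": residual_sigma(op, x, b),
            "mu": float(mu),
        })
        if rel <= cfg.tol:
            converged = True
            break
    return RestorationResult(
        x_star=x, iterations=len(history), converged=converged, history=history,
        sigma_x_star=residual_sigma(op, x, b), method="pnp-hqs",
        metadata={"mu_schedule": mus, "tol": cfg.tol, "max_iter": cfg.max_iter,
                  "denoiser": D.name, "denoiser_strength": D.strength},
    )


def red_admm_restore(b, op: BlurOperator, D: Denoiser, mu: float,
                     cfg: SolverConfig | None = None) -> RestorationResult:
    """Regularisation-by-denoising baseline solved by ADMM.

    Minimises ``1/2 ||Ax - b||^2 + mu/2 x^T (x - D(x))`` with the splitting
    ``x = v``.  The v-subproblem is handled by the RED fixed-point iteration
    ``v <- (beta (x + lam/beta) + mu D(v)) / (beta + mu)`` run for
    ``cfg.red_inner_steps`` inner steps (1 is standard).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    cfg = cfg or SolverConfig()
    b = as_image(b, "b")
    from scipy import fft as spfft

    atb_hat = np.conj(op.otf) * spfft.fft2(b)
    x = b.copy()
    v = b.copy()
    lam = np.zeros_like(b)
    beta = cfg.beta_v0
    history: list[dict] = []
    converged = False
    for _ in range(cfg.max_iter):
        x_prev = x
        x = np.real(spfft.ifft2((atb_hat + beta * spfft.fft2(v - lam / beta))
                                / (np.abs(op.otf) ** 2 + beta)))
        _check_finite(x, "red-x-update")
        x_tilde = x + lam / beta
        try:
            for _ in range(cfg.red_inner_steps):
                v = (beta * x_tilde + mu * D(v)) / (beta + mu)
            _check_finite(v, "red-v-update")
        except ValueError as exc:
            raise NumericalFailureError("red-v-update", str(exc)) from exc
        lam = _check_finite(lam + beta * (x - v), "red-dual")
        rel = np.linalg.norm(x - x_prev) / max(np.linalg.norm(x_prev), _EPS)
        history.append({
            "rel_change": float(rel),
            "residual_norm": float(np.linalg.norm(op.apply(x) - b)),
            "sigma_x": residual_sigma(op, x, b),
            "beta": float(beta), "mu": float(mu),
        })
        beta *= cfg.gamma
        if rel <= cfg.tol:
            converged = True
            break
    return RestorationResult(
        x_star=x, iterations=len(history), converged=converged, history=history,
        sigma_x_star=residual_sigma(op, x, b), method="red",
        metadata={"mu": mu, "beta0": cfg.beta_v0, "gamma": cfg.gamma,
                  "inner_steps": cfg.red_inner_steps, "tol": cfg.tol,
                  "max_iter": cfg.max_iter, "denoiser": D.name,
                  "denoiser_strength": D.strength},
    )
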