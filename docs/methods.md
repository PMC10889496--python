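# Methods

## Problem and model

The toolkit restores a 2-D image `x ∈ R^n` from a degraded measurement

    b = A x + η,

where `A` is a known Gaussian blur (point-spread function with standard
deviation `σ_A` pixels) and `η` is additive white Gaussian noise with
standard deviation `σ_η` on the 0–255 intensity scale.  Deconvolution is
ill-posed, so a prior is needed.  Instead of writing the prior down, the
plug-and-play approach represents it implicitly by a denoiser `D`: inside a
splitting algorithm, the proximal step of the unknown regulariser is
replaced by one application of `D`.

The distinguishing choice here is the **constrained** formulation

    min_x  ρ(x)   subject to   ‖A x − b‖₂ ≤ R,      R = τ √n σ_η,

with `ρ` the implicit denoiser-induced prior.  Because
`E‖η‖₂² = n σ_η²`, the true image is feasible in expectation at `τ = 1`:
the single free parameter is a physically interpretable noise level, not an
abstract regularisation weight.  This is the discrepancy principle encoded
as a hard constraint.

## The ADMM solver

With splitting variables `r = A x − b` and `v = x`, the augmented
Lagrangian with penalties `β_r`, `β_v` is optimised by block sweeps
(`cpnp_restore`):

1. **x-update** — exact minimiser of the coupled quadratic,
   `((β_r/β_v) AᵀA + I) x = (β_r/β_v) Aᵀ(b + r − λ_r/β_r) + v − λ_v/β_v`,
   solved by pointwise division in the DFT domain.  Periodic boundary
   conditions are used throughout precisely so that `AᵀA` is diagonal
   there and this step is exact to machine precision.
2. **v-update** — `v = D(x + λ_v/β_v)`.
3. **r-update** — Euclidean projection of `A x − b + λ_r/β_r` onto the
   centred ℓ2-ball of radius `R`.
4. **dual ascent** — `λ_r += β_r (A x − b − r)`, `λ_v += β_v (x − v)`,
   the signs consistent with the penalty terms of the augmented
   Lagrangian; then both penalties grow geometrically, `β ← γ β`.

Initialisation: `x₀ = b`, `v₀ = 0`, zero multipliers, and `r₀` the
projection of `A x₀ − b` onto the ball so the state starts feasible.
Stopping: relative iterate change `‖x_{k+1} − x_k‖ / max(‖x_k‖, 1e-12)`
below `tol`, or `max_iter` sweeps.

When `D` is an exact proximity operator the algorithm has a well-defined
limit.  For `D(u) = u/(1+α)` (prox of the quadratic `α/2‖·‖²`) the limit
solves the constrained quadratic programme; for elementwise soft
thresholding it solves the constrained ℓ1 programme.  Both facts are used
as test oracles: the quadratic case against a dense discrepancy-bisection
solve, the ℓ1 case against FISTA (proximal gradient — a different
algorithm family) combined with bisection on the constraint multiplier.
These oracle checks run the solver with `γ = 1` (constant penalties), where
the fixed point is stationary; oracle agreement is ≤1e-3 relative ℓ2.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `τ` | constraint scaling | 1.0 known σ, 0.98 estimated | τ=1 makes the truth feasible in expectation; the wavelet-MAD estimator tends to overestimate on textured scenes, so the radius is trimmed by 2% |
| `σ_η` | noise std, 0–255 scale | user-supplied or estimated | defines the physical radius |
| `β_r0, β_v0` | initial ADMM penalties | 1, 1 | quality is insensitive across [0.2, 1]² (tested: PSNR std ≤ 0.5 dB) |
| `γ` | penalty growth per sweep | 1.01 | mild growth speeds constraint activation without destabilising the denoiser step |
| `tol` | relative-change stop | 1e-4 | balances runtime against residual calibration |
| `max_iter` | sweep cap | 100 | diminishing returns beyond this on the tested tasks |
| denoiser `strength` | prox weight / TV weight / assumed noise std | per denoiser | semantics documented in `denoisers` |

The denoiser strength is fixed across iterations by default.  An optional
schedule (`inv-sqrt-beta`) rescales it by `1/√(β_v,k/β_v,0)`, consistent
with `D` standing in for a prox under the growing penalty `β_v`; the choice
is recorded in the result metadata.

## Noise estimation

`estimate_sigma` uses the robust wavelet estimator: median absolute
deviation of the finest diagonal detail band of a single-level Daubechies-8
transform divided by 0.6745.  On flat content it is accurate to a few
percent; on textured content the detail band carries signal, so the
estimate is biased upward — which is why the default constraint scaling
drops to τ = 0.98 when σ_η is estimated rather than known.

## Baselines

* **PnP-HQS** — the unconstrained plug-and-play model solved by
  half-quadratic splitting: alternate the exact quadratic data-fit solve
  `(AᵀA + μI)⁻¹(Aᵀb + μ z)` with `z = D(x)`.  Needs its weight `μ`
  tuned.
* **RED-ADMM** — regularisation by denoising with explicit prior
  `μ/2 xᵀ(x − D(x))`, solved by ADMM with the v-subproblem handled by the
  RED fixed-point iteration (1 inner step by default; the fixed point of
  the outer iteration satisfies the exact RED stationarity condition
  regardless of the inner step count).

Both produce the same diagnostics object as the constrained solver so
sweeps and comparisons are uniform.

## Synthetic phantoms

The generator produces seeded, deterministic scenes in [0, 255]: `beads`
(hard-edged disks, loosely fluorescent microspheres), `filaments`
(random-walk curves, cytoskeleton-like), `blobs` (smooth cell-like
patches) and `checkers` (alternating squares, a worst case for periodic
deconvolution).  The kinds deliberately mix sharp edges and fine curvilinear
detail so that over-smoothing (large τ) and noise artifacts (small τ) are
both visible in PSNR/SSIM.

What the phantoms do **not** emulate: natural-image statistics (the
photographic test sets the method is usually benchmarked on), camera
pipelines (demosaicing, compression), signal-dependent noise, and
non-periodic boundary content.  Passing tests therefore establish the
solver's mathematical behaviour — oracle agreement, constraint calibration,
parameter robustness — not photographic benchmark numbers, which also
depend on a trained learned denoiser that this package exposes only as a
plugin interface.

## Numerical choices

* Intensities are float64 on the 0–255 convention; nothing in the solver
  clips — clipping happens only when images are written to disk.
* The PSF is truncated at about 4σ per side (odd support, smallest odd
  integer ≥ 8σ+1 by default) and renormalised to unit sum.
* The TV prox uses Chambolle's dual scheme run to tolerance 1e-5.
* Projection with radius 0 returns the zero image; the stopping-rule
  denominator is guarded by 1e-12.
* The x-update divides by `(β_r/β_v)|OTF|² + 1 ≥ 1`, so it is
  unconditionally well-posed even where the OTF vanishes.
* Everything is deterministic: phantoms and noise draws are seeded
  (`numpy.random.default_rng`), solvers contain no randomness, so repeated
  runs are bit-identical.

## Test problem sizes

Oracle-equivalence checks run on 32×32 scenes (dense algebra stays exact
and fast); constraint-activity and robustness studies on 64×64; noise
recovery and quality reporting on 128×128.  These sizes are where the dense
independent oracles are tractable while every qualitative behaviour of the
method (constraint activity, τ trade-off, penalty robustness) is already
fully expressed; the solver itself is FFT-based and scales to megapixel
images.

## Known limitations

* Periodic (circular) convolution only; real microscope frames with bright
  structure at the border will show wrap-around bias unless padded by the
  caller.
* Gaussian PSF constructor only, though any normalised user kernel is
  accepted by `make_operator`.
* AWGN fidelity only (no Poisson/mixed noise).
* BM3D and learned denoisers are optional/plugin backends; the shipped,
  tested denoisers are Tikhonov, soft-threshold, TV and NLM.
* With non-prox denoisers (TV/NLM at fixed strength) the "prior" is only
  implicit; convergence is empirical (monitored via the relative-change
  history), not certified.
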