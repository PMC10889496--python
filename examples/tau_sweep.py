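"""Sweep the constraint scaling tau and watch the residual/quality trade-off.

tau scales the residual-ball radius R = tau * sqrt(n) * sigma_eta.  Small
tau forces the solver to explain noise as signal (artifacts); large tau
lets it discard real detail (oversmoothing).  sigma_x* grows monotonically
with tau and crosses the true noise level at tau = 1; restoration quality
peaks for tau close to, but typically just below, 1.
"""

from cpnp import (
    DegradationSpec,
    PhantomSpec,
    cpnp_restore,
    degrade,
    gaussian_psf,
    generate_phantom,
    make_constraint,
    make_denoiser,
    make_operator,
    psnr,
)

sigma_eta = 30.0
x = generate_phantom(PhantomSpec("beads", (64, 64), seed=1))
op = make_operator(gaussian_psf(1.2), x.shape)
b = degrade(x, DegradationSpec(1.2, sigma_eta, seed=1), op)
D = make_denoiser("tv", {"strength": 8.0})

print(f"true noise level sigma_eta = {sigma_eta}")
print(" tau   sigma_x*   PSNR (dB)")
for tau in (0.8, 0.9, 0.96, 0.98, 1.0, 1.1, 1.2):
    res = cpnp_restore(b, op, make_constraint(tau, sigma_eta, x.size), D)
    print(f"{tau:5.2f}   {res.sigma_x_star:7.2f}   {psnr(res.x_star, x):8.2f}")
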