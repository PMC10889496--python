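"""Compare CPnP against unconstrained plug-and-play (HQS) and RED baselines.

The baselines minimise a weighted sum of data fit and denoiser prior, so
their quality depends on the regularisation weight mu; here mu is tuned by
a small grid search for each.  CPnP needs no such weight — its single
parameter is the physically meaningful noise level.
"""

import numpy as np

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
    pnp_hqs_restore,
    psnr,
    red_admm_restore,
)

sigma_a, sigma_eta = 1.2, 25.0
x = generate_phantom(PhantomSpec("filaments", (64, 64), seed=3))
op = make_operator(gaussian_psf(sigma_a), x.shape)
b = degrade(x, DegradationSpec(sigma_a, sigma_eta, seed=3), op)
D = make_denoiser("tv", {"strength": 8.0})

res = cpnp_restore(b, op, make_constraint(1.0, sigma_eta, x.size), D)
print(f"cpnp           : PSNR {psnr(res.x_star, x):6.2f} dB   (no weight to tune)")

mus = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)
best_pnp = max((psnr(pnp_hqs_restore(b, op, D, mu).x_star, x) for mu in mus))
print(f"pnp-hqs (tuned): PSNR {best_pnp:6.2f} dB   over mu grid {mus}")

best_red = max((psnr(red_admm_restore(b, op, D, mu).x_star, x) for mu in mus))
print(f"red (tuned)    : PSNR {best_red:6.2f} dB   over mu grid {mus}")

print(f"degraded input : PSNR {psnr(b, x):6.2f} dB")
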