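import numpy as np
import pytest

from cpnp import (
    DegradationSpec,
    PhantomSpec,
    degrade,
    gaussian_psf,
    generate_phantom,
    make_operator,
)


def dense_matrix(op):
    """Assemble the blur operator column by column into a dense matrix."""
    h, w = op.shape
    n = h * w
    A = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        A[:, j] = op.apply(e.reshape(h, w)).ravel()
    return A


@pytest.fixture(scope="session")
def checkers32():
    return generate_phantom(PhantomSpec("checkers", (32, 32), seed=0))


@pytest.fixture(scope="session")
def beads64():
    return generate_phantom(PhantomSpec("beads", (64, 64), seed=1))


@pytest.fixture(scope="session")
def deblur_task_64(beads64):
    """A fixed 64x64 deconvolution task: moderately strong blur and noise."""
    sigma_a, sigma_eta = 1.2, 30.0
    op = make_operator(gaussian_psf(sigma_a), beads64.shape)
    b = degrade(beads64, DegradationSpec(sigma_a, sigma_eta, seed=1), op)
    return {"x_true": beads64, "op": op, "b": b,
            "sigma_a": sigma_a, "sigma_eta": sigma_eta}
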