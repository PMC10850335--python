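import numpy as np
import pytest

from pmmnet.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def relative_grad_error(loss_fn, tensors, eps=1e-5, max_coords=6, seed=0):
    """Compare autodiff gradients with central finite differences.

    ``loss_fn`` recomputes the scalar loss from the current ``tensors`` data.
    Returns the worst relative error over sampled coordinates of every
    tensor (denominator guarded for near-zero gradients).
    """
    loss = loss_fn()
    for t in tensors:
        t.grad = None
    loss.backward()
    grads = [t.grad.copy() if t.grad is not None else np.zeros_like(t.data)
             for t in tensors]
    sampler = np.random.default_rng(seed)
    worst = 0.0
    for t, g in zip(tensors, grads):
        flat = t.data.reshape(-1)
        n = flat.size
        coords = sampler.choice(n, size=min(max_coords, n), replace=False)
        for c in coords:
            orig = flat[c]
            flat[c] = orig + eps
            up = float(loss_fn().data)
            flat[c] = orig - eps
            down = float(loss_fn().data)
            flat[c] = orig
            numeric = (up - down) / (2 * eps)
            analytic = g.reshape(-1)[c]
            denom = max(abs(numeric), abs(analytic), 1e-4)
            worst = max(worst, abs(numeric - analytic) / denom)
    return worst


@pytest.fixture
def grad_check():
    return relative_grad_error


def leaf(data):
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)
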