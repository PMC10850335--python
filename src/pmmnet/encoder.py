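"""Positional feature encoding.

The encoder is a stack of positional feature encoding blocks (PFEBlocks),
each followed by non-overlapping 1-D max pooling.  A PFEBlock is a residual
convolution block whose refinement branch (conv - RReLU - conv) is gated
elementwise by a logistic sigmoid of the block input, so positions whose raw
activation is large let more of the refined feature through:

    X_o   = conv1(F_e)
    X_o'  = conv2(RReLU(X_o))
    W_pos = sigma(F_e)
    F_o   = W_pos * X_o' + F_e

Feature maps are [batch, channels, length] float arrays (wrapped in autodiff
tensors so gradients flow through the whole chain).  When ``conv2_weights``
is ``None`` the block degrades to a plain conv - RReLU unit with no gated
residual branch, which is the "no positional encoding" ablation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor


@dataclass
class PFEBlockParams:
    """Parameters of one positional feature encoding block.

    ``rrelu_low``/``rrelu_high`` are the (p, q) bounds of the uniform
    distribution the negative slope of the randomized leaky ReLU is drawn
    from during training; evaluation uses the deterministic midpoint.
    """

    conv1_weights: Tensor
    conv1_bias: Tensor
    conv2_weights: Tensor | None = None
    conv2_bias: Tensor | None = None
    rrelu_low: float = 0.125
    rrelu_high: float = 1.0 / 3.0
    pool_window: int = 2
    projection: Tensor | None = None  # 1x1 conv matching channels for the residual add

    def __post_init__(self):
        _check_rrelu_bounds(self.rrelu_low, self.rrelu_high)
        if self.pool_window < 1:
            raise ValueError("pool_window must be a positive integer")
        k = self.conv1_weights.shape[-1]
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric same-length padding")

    @property
    def gated(self) -> bool:
        return self.conv2_weights is not None

    def parameters(self) -> list[Tensor]:
        out = [self.conv1_weights, self.conv1_bias]
        if self.conv2_weights is not None:
            out += [self.conv2_weights, self.conv2_bias]
        if self.projection is not None:
            out.append(self.projection)
        return out


def _check_rrelu_bounds(p: float, q: float) -> None:
    if not (0.0 <= p < q < 1.0):
        raise ValueError(f"RReLU bounds must satisfy 0 <= p < q < 1, got p={p}, q={q}")


def conv1d(x, weights, bias=None, padding: str = "same") -> Tensor:
    """1-D cross-correlation of a [batch, channels, length] feature map."""
    return ad.conv1d(x, weights, bias, padding=padding)


def rrelu(x, p: float, q: float, training: bool = False,
          rng: np.random.Generator | None = None) -> Tensor:
    """Randomized leaky ReLU.

    Training draws the negative slope a ~ U(p, q) independently per element;
    evaluation uses the deterministic midpoint (p + q) / 2.
    """
    _check_rrelu_bounds(p, q)
    x = astensor(x)
    if training:
        if rng is None:
            raise ValueError("training-mode RReLU needs an explicit rng")
        slope = rng.uniform(p, q, size=x.shape)
    else:
        slope = 0.5 * (p + q)
    return ad.leaky(x, slope)


def positional_gate(fe) -> Tensor:
    """Elementwise position weight W_pos = e^F / (e^F + 1), the logistic sigmoid."""
    return ad.sigmoid(fe)


def pfe_block_forward(fe, params: PFEBlockParams, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
    """One positional feature encoding block (without the trailing pool)."""
    fe = astensor(fe)
    xo = conv1d(fe, params.conv1_weights, params.conv1_bias, padding="same")
    activated = rrelu(xo, params.rrelu_low, params.rrelu_high, training, rng)
    if not params.gated:
        return activated
    xo_prime = conv1d(activated, params.conv2_weights, params.conv2_bias, padding="same")
    residual = fe
    if params.projection is not None:
        residual = conv1d(fe, params.projection, None, padding="same")
    if xo_prime.shape != residual.shape:
        raise ad.ShapeError(
            f"residual add mismatch: branch {xo_prime.shape} vs input {residual.shape}; "
            "set a 1x1 projection when conv2 changes the channel count")
    gate = positional_gate(residual)
    return gate * xo_prime + residual


def encoder_forward(x, blocks: Sequence[PFEBlockParams], training: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
    """Run the stack of (PFEBlock -> max-pool) stages, producing F_pos."""
    out = astensor(x)
    required = int(np.prod([b.pool_window for b in blocks])) if blocks else 1
    if out.shape[-1] < required:
        raise ValueError(
            f"input length {out.shape[-1]} shorter than total pooling factor {required}")
    for block in blocks:
        out = pfe_block_forward(out, block, training, rng)
        if block.pool_window > 1:
            out = ad.max_pool1d(out, block.pool_window)
    return out


def init_encoder(n_in: int, channels: Sequence[int], kernel_size: int, pool_window: int,
                 rng: np.random.Generator, gated: bool = True,
                 rrelu_low: float = 0.125, rrelu_high: float = 1.0 / 3.0) -> list[PFEBlockParams]:
    """He-initialised encoder stack; gated=False builds the plain-conv baseline.

    Gated blocks keep channels unchanged inside the block (so the residual add
    needs no projection) and widen on conv1; the plain baseline widens on its
    single conv.
    """
    blocks = []
    cin = n_in
    for cout in channels:
        w1 = Tensor(rng.normal(0.0, np.sqrt(2.0 / (cin * kernel_size)), (cout, cin, kernel_size)),
                    requires_grad=True)
        b1 = Tensor(np.zeros(cout), requires_grad=True)
        if gated:
            w2 = Tensor(rng.normal(0.0, np.sqrt(2.0 / (cout * kernel_size)), (cout, cout, kernel_size)),
                        requires_grad=True)
            b2 = Tensor(np.zeros(cout), requires_grad=True)
            proj = None
            if cin != cout:
                proj = Tensor(rng.normal(0.0, np.sqrt(1.0 / cin), (cout, cin, 1)),
                              requires_grad=True)
            block = PFEBlockParams(w1, b1, w2, b2, rrelu_low, rrelu_high, pool_window, proj)
        else:
            block = PFEBlockParams(w1, b1, None, None, rrelu_low, rrelu_high, pool_window)
        blocks.append(block)
        cin = cout
    return blocks
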