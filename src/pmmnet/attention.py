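"""Mutual-attention feature reinforcement.

The three hidden-sequence taps of the dilated recurrent stack are batch
normalized, projected to query/key/value streams, and combined by three
*mutual* scaled-dot attentions in which every stream takes each role once:

    A_qk = softmax(Q K^T / S) V
    A_qv = softmax(Q V^T / S) K
    A_vk = softmax(V K^T / S) Q

(The second attends queries against values and aggregates keys — that cross
pairing is the point of the mutual scheme.)  Each attention is run with T
heads over feature slices, head outputs are concatenated and linearly mixed
per pair, and the three mixed maps are concatenated along the feature axis
and fused by a width-1 convolution into the reinforced map F_at.

Time is the attention axis: feature maps [batch, channels, length] are
transposed to [batch, length, channels] so positions attend over positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor


@dataclass
class BatchNormParams:
    """Per-channel batch normalization over (batch, time)."""

    scale: Tensor
    shift: Tensor
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1
    initialized: bool = False

    def parameters(self) -> list[Tensor]:
        return [self.scale, self.shift]


@dataclass
class AttentionParams:
    """Projections, scaling, head count and fusion weights of the block."""

    norm_q: BatchNormParams
    norm_k: BatchNormParams
    norm_v: BatchNormParams
    W_q: Tensor
    b_q: Tensor
    W_k: Tensor
    b_k: Tensor
    W_v: Tensor
    b_v: Tensor
    scaling: float
    heads: int
    W_qk_multi: Tensor
    W_qv_multi: Tensor
    W_vk_multi: Tensor
    fusion_weights: Tensor
    fusion_bias: Tensor

    def __post_init__(self):
        if self.scaling <= 0:
            raise ValueError("scaling S must be > 0")
        if self.heads < 1:
            raise ValueError("head count T must be >= 1")
        if self.W_q.shape[0] % self.heads != 0:
            raise ValueError(
                f"projection dim {self.W_q.shape[0]} not divisible by T={self.heads}")

    def parameters(self) -> list[Tensor]:
        out = (self.norm_q.parameters() + self.norm_k.parameters() + self.norm_v.parameters()
               + [self.W_q, self.b_q, self.W_k, self.b_k, self.W_v, self.b_v,
                  self.W_qk_multi, self.W_qv_multi, self.W_vk_multi,
                  self.fusion_weights, self.fusion_bias])
        return out


def softmax_rows(z) -> Tensor:
    """Row-wise softmax along the last axis, shift-invariant and stable."""
    z = astensor(z)
    shifted = z - z.data.max(axis=-1, keepdims=True)  # constant shift: same gradient
    ez = ad.exp(shifted)
    return ez / ez.sum(axis=-1, keepdims=True)


def batch_norm(x, params: BatchNormParams, training: bool = False) -> Tensor:
    """Normalize a [batch, channels, length] map per channel.

    Training normalizes with batch statistics (gradients flow through them)
    and updates the running averages; evaluation uses the stored averages and
    requires at least one prior training pass.
    """
    x = astensor(x)
    if training:
        mean = x.mean(axis=(0, 2), keepdims=True)
        var = ((x - mean) ** 2).mean(axis=(0, 2), keepdims=True)
        m = params.momentum
        if not params.initialized:
            params.running_mean = mean.data.reshape(-1).copy()
            params.running_var = var.data.reshape(-1).copy()
            params.initialized = True
        else:
            params.running_mean = (1 - m) * params.running_mean + m * mean.data.reshape(-1)
            params.running_var = (1 - m) * params.running_var + m * var.data.reshape(-1)
    else:
        if not params.initialized:
            raise RuntimeError("batch norm evaluated before any running statistics exist")
        mean = Tensor(params.running_mean[None, :, None])
        var = Tensor(params.running_var[None, :, None])
    norm = (x - mean) * ((var + params.eps) ** -0.5)
    return norm * ad.reshape(params.scale, (1, -1, 1)) + ad.reshape(params.shift, (1, -1, 1))


def project_qkv(f_q, f_k, f_v, params: AttentionParams,
                training: bool = False) -> tuple[Tensor, Tensor, Tensor]:
    """Normalize the taps and apply the three linear projections.

    Input taps are [batch, channels, length]; outputs are time-major
    [batch, length, proj] so rows are positions.
    """
    fq = ad.swapaxes(batch_norm(f_q, params.norm_q, training), 1, 2)
    fk = ad.swapaxes(batch_norm(f_k, params.norm_k, training), 1, 2)
    fv = ad.swapaxes(batch_norm(f_v, params.norm_v, training), 1, 2)
    q = ad.linear(fq, params.W_q, params.b_q)
    k = ad.linear(fk, params.W_k, params.b_k)
    v = ad.linear(fv, params.W_v, params.b_v)
    return q, k, v


def mutual_scaled_attention(a, b, c, scaling: float) -> Tensor:
    """softmax(a b^T / S) c for time-major [.., positions, features] maps."""
    if scaling <= 0:
        raise ValueError("scaling S must be > 0")
    a, b, c = astensor(a), astensor(b), astensor(c)
    if a.shape[-1] != b.shape[-1]:
        raise ad.ShapeError(f"feature dims differ: {a.shape[-1]} vs {b.shape[-1]}")
    if b.shape[-2] != c.shape[-2]:
        raise ad.ShapeError(f"row counts differ: {b.shape[-2]} vs {c.shape[-2]}")
    scores = (a @ b.T) * (1.0 / scaling)
    return softmax_rows(scores) @ c


def _heads(x: Tensor, n: int) -> list[Tensor]:
    width = x.shape[-1]
    if width % n != 0:
        raise ValueError(f"feature dim {width} not divisible by {n} heads")
    step = width // n
    return [x[..., i * step:(i + 1) * step] for i in range(n)]


def multi_head_mutual_attention(q, k, v, params: AttentionParams) -> tuple[Tensor, Tensor, Tensor]:
    """T-head mutual attention: per-head slices, concat, per-pair linear mix."""
    q, k, v = astensor(q), astensor(k), astensor(v)
    qh, kh, vh = _heads(q, params.heads), _heads(k, params.heads), _heads(v, params.heads)
    s = params.scaling
    a_qk = ad.concatenate([mutual_scaled_attention(qi, ki, vi, s)
                           for qi, ki, vi in zip(qh, kh, vh)], axis=-1)
    a_qv = ad.concatenate([mutual_scaled_attention(qi, vi, ki, s)
                           for qi, ki, vi in zip(qh, kh, vh)], axis=-1)
    a_vk = ad.concatenate([mutual_scaled_attention(vi, ki, qi, s)
                           for qi, ki, vi in zip(qh, kh, vh)], axis=-1)
    return (ad.linear(a_qk, params.W_qk_multi),
            ad.linear(a_qv, params.W_qv_multi),
            ad.linear(a_vk, params.W_vk_multi))


def fuse_attention(a_qk, a_qv, a_vk, params: AttentionParams) -> Tensor:
    """Concatenate the three attention maps featurewise and fuse by conv.

    Inputs are time-major [batch, length, features]; the fused output is a
    [batch, channels, length] feature map.
    """
    a_qk, a_qv, a_vk = astensor(a_qk), astensor(a_qv), astensor(a_vk)
    if not (a_qk.shape[-2] == a_qv.shape[-2] == a_vk.shape[-2]):
        raise ad.ShapeError("attention maps must share the time length")
    stacked = ad.concatenate([ad.swapaxes(a, 1, 2) for a in (a_qk, a_qv, a_vk)], axis=1)
    return ad.conv1d(stacked, params.fusion_weights, params.fusion_bias, padding="same")


def attention_forward(f_q, f_k, f_v, params: AttentionParams,
                      training: bool = False) -> Tensor:
    """Full block: normalize/project -> mutual multi-head attention -> fuse."""
    q, k, v = project_qkv(f_q, f_k, f_v, params, training)
    a_qk, a_qv, a_vk = multi_head_mutual_attention(q, k, v, params)
    return fuse_attention(a_qk, a_qv, a_vk, params)


def init_attention(n_channels: int, proj_dim: int | None, heads: int,
                   scaling: float | None, rng: np.random.Generator,
                   fusion_channels: int | None = None) -> AttentionParams:
    """Glorot-style init; S defaults to sqrt(per-head feature dim)."""
    proj = proj_dim or n_channels
    if proj % heads != 0:
        raise ValueError(f"projection dim {proj} not divisible by T={heads}")
    if scaling is None:
        scaling = float(np.sqrt(proj // heads))
    fusion_out = fusion_channels or proj

    def norm():
        return BatchNormParams(
            scale=Tensor(np.ones(n_channels), requires_grad=True),
            shift=Tensor(np.zeros(n_channels), requires_grad=True),
            running_mean=np.zeros(n_channels),
            running_var=np.ones(n_channels),
        )

    def lin(nout, nin):
        s = np.sqrt(1.0 / nin)
        return Tensor(rng.uniform(-s, s, (nout, nin)), requires_grad=True)

    return AttentionParams(
        norm_q=norm(), norm_k=norm(), norm_v=norm(),
        W_q=lin(proj, n_channels), b_q=Tensor(np.zeros(proj), requires_grad=True),
        W_k=lin(proj, n_channels), b_k=Tensor(np.zeros(proj), requires_grad=True),
        W_v=lin(proj, n_channels), b_v=Tensor(np.zeros(proj), requires_grad=True),
        scaling=scaling, heads=heads,
        W_qk_multi=lin(proj, proj), W_qv_multi=lin(proj, proj), W_vk_multi=lin(proj, proj),
        fusion_weights=Tensor(rng.uniform(-np.sqrt(1.0 / (3 * proj)), np.sqrt(1.0 / (3 * proj)),
                                          (fusion_out, 3 * proj, 1)), requires_grad=True),
        fusion_bias=Tensor(np.zeros(fusion_out), requires_grad=True),
    )
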