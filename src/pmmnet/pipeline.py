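"""Full model assembly, softmax classification and training.

The forward pass chains positional feature encoding, the hierarchical
residual dilated LSTM stack, mutual-attention feature reinforcement, global
average pooling over time, and a dense softmax classifier.  Training is
minibatch Adam on categorical cross-entropy with a multiplicative per-epoch
learning-rate decay: lr_e = lr0 * (1 - decay)^e.

Ablation flags reconstruct the component study variants:

==========  =======  ==========  =======  =============
variant     use_pfe  use_rdlstm  use_mfl  use_attention
==========  =======  ==========  =======  =============
original    no       no          no       no
+rdlstm     no       yes         no       no
+pfeblock   yes      no          no       no
+mfl        no       yes         yes      no
+mfr        no       yes         yes      yes
full        yes      yes         yes      yes
==========  =======  ==========  =======  =============

"original" (no proposed component) is the plain convolutional encoder with
global average pooling and a dense softmax; "+rdlstm" adds a single residual
dilated LSTM layer; "+mfl" the three-layer dilation-1/2/4 stack; "+mfr" the
mutual-attention reinforcement on the stack's three taps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import attention as attn
from . import encoder as enc
from . import recurrent as rec
from .autodiff import Tensor, astensor

VARIANTS = ("original", "+rdlstm", "+pfeblock", "+mfl", "+mfr", "full")


@dataclass
class PMMConfig:
    """Everything needed to build and train one model."""

    n_classes: int = 2
    encoder_channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    pool_window: int = 2
    rrelu_low: float = 0.125
    rrelu_high: float = 1.0 / 3.0
    hidden_size: int | None = None  # defaults to encoder_channels[-1]
    dilations: tuple[int, ...] = (1, 2, 4)
    heads: int = 4
    attn_scale: float | None = None  # defaults to sqrt(proj_dim / heads)
    use_pfe: bool = True
    use_rdlstm: bool = True
    use_mfl: bool = True
    use_attention: bool = True
    lr: float = 3e-4
    lr_decay: float = 0.001
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.use_attention and not self.use_mfl:
            raise ValueError("the attention stage needs the multi-length stack (use_mfl)")
        if self.use_mfl and not self.use_rdlstm:
            raise ValueError("the multi-length stack is built from RDLSTM layers (use_rdlstm)")
        if self.use_mfl and len(self.dilations) < 3:
            raise ValueError("the multi-length stack needs at least 3 dilation rates")
        if self.use_attention and len(set(self.dilations)) != len(self.dilations):
            raise ValueError("dilation rates must be pairwise distinct when attention is enabled")

    @property
    def hidden(self) -> int:
        return self.hidden_size if self.hidden_size is not None else self.encoder_channels[-1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_channels"] = list(self.encoder_channels)
        d["dilations"] = list(self.dilations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PMMConfig":
        d = dict(d)
        for key in ("encoder_channels", "dilations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def variant_config(name: str, **overrides) -> PMMConfig:
    """Config for one component-study variant (see module docstring)."""
    flags = {
        "original": dict(use_pfe=False, use_rdlstm=False, use_mfl=False, use_attention=False),
        "+rdlstm": dict(use_pfe=False, use_rdlstm=True, use_mfl=False, use_attention=False),
        "+pfeblock": dict(use_pfe=True, use_rdlstm=False, use_mfl=False, use_attention=False),
        "+mfl": dict(use_pfe=False, use_rdlstm=True, use_mfl=True, use_attention=False),
        "+mfr": dict(use_pfe=False, use_rdlstm=True, use_mfl=True, use_attention=True),
        "full": dict(use_pfe=True, use_rdlstm=True, use_mfl=True, use_attention=True),
    }
    if name not in flags:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(flags)}")
    kwargs = {**flags[name], **overrides}
    return PMMConfig(**kwargs)


@dataclass
class PMMModel:
    """Parameter container for the assembled network."""

    config: PMMConfig
    blocks: list[enc.PFEBlockParams]
    layers: list[rec.RDLSTMLayerParams]
    attention: attn.AttentionParams | None
    classifier_weights: Tensor
    classifier_bias: Tensor

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for b in self.blocks:
            out += b.parameters()
        for l in self.layers:
            out += l.parameters()
        if self.attention is not None:
            out += self.attention.parameters()
        out += [self.classifier_weights, self.classifier_bias]
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def init_model(config: PMMConfig, rng: np.random.Generator | None = None) -> PMMModel:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    blocks = enc.init_encoder(
        1, config.encoder_channels, config.kernel_size, config.pool_window, rng,
        gated=config.use_pfe, rrelu_low=config.rrelu_low, rrelu_high=config.rrelu_high)
    feat = config.encoder_channels[-1]
    layers: list[rec.RDLSTMLayerParams] = []
    if config.use_mfl:
        if config.hidden != feat:
            raise ValueError(
                f"the bottom RDLSTM residual shortcut needs hidden size == encoder "
                f"channels ({config.hidden} != {feat})")
        layers = rec.init_stack(feat, config.hidden, config.dilations[:3] if config.use_attention
                                else config.dilations, rng)
        feat = config.hidden
    elif config.use_rdlstm:
        if config.hidden != feat:
            raise ValueError("RDLSTM residual shortcut needs hidden size == encoder channels")
        layers = rec.init_stack(feat, config.hidden, (config.dilations[0],), rng)
        feat = config.hidden
    attention = None
    if config.use_attention:
        attention = attn.init_attention(feat, None, config.heads, config.attn_scale, rng)
        # identity running stats so an untrained model is evaluable
        for bn in (attention.norm_q, attention.norm_k, attention.norm_v):
            bn.initialized = True
        feat = attention.fusion_weights.shape[0]
    s = np.sqrt(1.0 / feat)
    weights = Tensor(rng.uniform(-s, s, (config.n_classes, feat)), requires_grad=True)
    bias = Tensor(np.zeros(config.n_classes), requires_grad=True)
    return PMMModel(config, blocks, layers, attention, weights, bias)


# ---------------------------------------------------------------------------
# forward pass and losses
# ---------------------------------------------------------------------------

def _pooled_features(batch, model: PMMModel, training: bool,
                     rng: np.random.Generator | None) -> Tensor:
    x = astensor(batch)
    if x.ndim == 2:  # [batch, length] -> single channel
        x = ad.reshape(x, (x.shape[0], 1, x.shape[1]))
    cfg = model.config
    fpos = enc.encoder_forward(x, model.blocks, training, rng)
    if model.layers:
        taps = rec.multi_length_forward(fpos, model.layers, residual=cfg.use_rdlstm)
        if model.attention is not None:
            f_at = attn.attention_forward(taps[0], taps[1], taps[2], model.attention, training)
            return f_at.mean(axis=2)
        return taps[-1].mean(axis=2)
    return fpos.mean(axis=2)


def _logits(batch, model: PMMModel, training: bool = False,
            rng: np.random.Generator | None = None) -> Tensor:
    pooled = _pooled_features(batch, model, training, rng)
    return ad.linear(pooled, model.classifier_weights, model.classifier_bias)


def softmax_classify(s, theta, bias=None) -> Tensor:
    """P(y=c|s) = exp(theta_c^T s) / sum_j exp(theta_j^T s), rows of theta per class."""
    logits = ad.linear(astensor(s), astensor(theta), bias)
    return attn.softmax_rows(logits)


def pmm_forward(batch, model: PMMModel, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
    """Class-probability matrix [batch, n_classes]."""
    return attn.softmax_rows(_logits(batch, model, training, rng))


def cross_entropy_loss(y_true, y_prob, clip: float = 1e-12) -> float:
    """Mean -log p(true class) of a row-stochastic probability matrix."""
    y_prob = np.asarray(y_prob.data if isinstance(y_prob, Tensor) else y_prob, dtype=float)
    y_true = np.asarray(y_true, dtype=np.intp)
    if y_prob.ndim != 2:
        raise ValueError("probability matrix must be 2-D")
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of the probability matrix must sum to 1")
    if y_true.min() < 0 or y_true.max() >= y_prob.shape[1]:
        raise ValueError("label outside the class range")
    p = np.clip(y_prob[np.arange(len(y_true)), y_true], clip, 1.0)
    return float(-np.log(p).mean())


def predict(model: PMMModel, batch) -> np.ndarray:
    """Argmax class labels; ties break toward the lowest class index."""
    probs = pmm_forward(batch, model, training=False)
    return probs.data.argmax(axis=1)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


@dataclass
class TrainResult:
    model: PMMModel
    loss_trace: list[float]
    epoch: int


def train(model: PMMModel, X: np.ndarray, y: np.ndarray,
          config: PMMConfig | None = None,
          callback=None) -> TrainResult:
    """Minibatch Adam training with per-epoch multiplicative lr decay.

    Fully deterministic given ``config.seed``: the same seed drives parameter
    noise (RReLU sampling) and the shuffling order.
    """
    config = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if len(X) == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() >= config.n_classes:
        raise ValueError("labels must lie in [0, n_classes)")
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.lr)
    trace: list[float] = []
    n = len(X)
    for epoch in range(config.epochs):
        opt.lr = config.lr * (1.0 - config.lr_decay) ** epoch
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = _logits(X[idx], model, training=True, rng=rng)
            loss = ad.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}; "
                    "lower the learning rate or check the inputs")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
        if callback is not None:
            callback(epoch, trace[-1])
    return TrainResult(model, trace, config.epochs)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _tensor_list(model: PMMModel) -> list[Tensor]:
    return model.parameters()


def save_checkpoint(model: PMMModel, path, epoch: int = 0,
                    rng_state: dict | None = None) -> None:
    """JSON checkpoint: config, every parameter array, batch-norm state."""
    payload = {
        "config": model.config.to_dict(),
        "epoch": epoch,
        "rng_state": rng_state,
        "params": [p.data.tolist() for p in _tensor_list(model)],
    }
    if model.attention is not None:
        payload["norm_state"] = [
            {"mean": bn.running_mean.tolist(), "var": bn.running_var.tolist(),
             "initialized": bn.initialized}
            for bn in (model.attention.norm_q, model.attention.norm_k, model.attention.norm_v)
        ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[PMMModel, int, dict | None]:
    with open(path) as fh:
        payload = json.load(fh)
    config = PMMConfig.from_dict(payload["config"])
    model = init_model(config)
    params = _tensor_list(model)
    saved = payload["params"]
    if len(saved) != len(params):
        raise ValueError("checkpoint does not match the configured architecture")
    for p, values in zip(params, saved):
        arr = np.asarray(values, dtype=float)
        if arr.shape != p.data.shape:
            raise ValueError(f"parameter shape mismatch: {arr.shape} vs {p.data.shape}")
        p.data = arr
    if model.attention is not None and "norm_state" in payload:
        for bn, state in zip((model.attention.norm_q, model.attention.norm_k,
                              model.attention.norm_v), payload["norm_state"]):
            bn.running_mean = np.asarray(state["mean"], dtype=float)
            bn.running_var = np.asarray(state["var"], dtype=float)
            bn.initialized = bool(state["initialized"])
    return model, payload.get("epoch", 0), payload.get("rng_state")
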