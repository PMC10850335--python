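"""Multi-length feature learning with residual dilated LSTMs.

A residual dilated LSTM (RDLSTM) layer is an LSTM whose recurrent
connections reach back ``d`` time steps instead of one (dilation), and whose
hidden output adds a shortcut from the layer below inside the output gate:

    z' = tanh(W'_z h_below + R'_z h_{t-d} + b'_z)
    i' = sigma(W'_i h_below + R'_i h_{t-d} + b'_i)
    f' = sigma(W'_f h_below + R'_f h_{t-d} + b'_f)
    o' = sigma(W'_o h_below + R'_o h_{t-d} + b'_o)
    c'_t = f' * c_{t-d} + i' * z'
    h'_t = o' * (tanh(c'_t) + h_below)

Stacking layers with dilations 1, 2, 4 grows the temporal receptive field
exponentially; each layer's hidden sequence is kept as a tap for the
mutual-attention stage.  States at t <= d are zero vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor


@dataclass
class LSTMCellParams:
    """The twelve parameter arrays of one LSTM cell (block input z, gates i/f/o)."""

    W_z: Tensor
    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    R_z: Tensor
    R_i: Tensor
    R_f: Tensor
    R_o: Tensor
    b_z: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor

    def __post_init__(self):
        h, n_in = self.W_z.shape
        for name in ("W_i", "W_f", "W_o"):
            if getattr(self, name).shape != (h, n_in):
                raise ad.ShapeError(f"{name} shape {getattr(self, name).shape} != {(h, n_in)}")
        for name in ("R_z", "R_i", "R_f", "R_o"):
            if getattr(self, name).shape != (h, h):
                raise ad.ShapeError(f"{name} shape {getattr(self, name).shape} != {(h, h)}")
        for name in ("b_z", "b_i", "b_f", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ad.ShapeError(f"{name} shape {getattr(self, name).shape} != {(h,)}")

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_z.shape[1]

    def parameters(self) -> list[Tensor]:
        return [self.W_z, self.W_i, self.W_f, self.W_o,
                self.R_z, self.R_i, self.R_f, self.R_o,
                self.b_z, self.b_i, self.b_f, self.b_o]


@dataclass
class RDLSTMLayerParams:
    """One residual dilated LSTM layer: a cell plus its dilation rate."""

    cell: LSTMCellParams
    dilation: int = 1
    layer_index: int = 0

    def __post_init__(self):
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")

    def parameters(self) -> list[Tensor]:
        return self.cell.parameters()


@dataclass
class RecurrentState:
    hidden: Tensor
    cell: Tensor


def _gate_drive(x, h, W: Tensor, R: Tensor, b: Tensor) -> Tensor:
    return ad.linear(x, W) + ad.linear(h, R) + b


def lstm_cell_step(x_t, h_prev, c_prev, params: LSTMCellParams) -> RecurrentState:
    """One plain LSTM step: inputs/state are [batch, dim] arrays."""
    x_t, h_prev, c_prev = astensor(x_t), astensor(h_prev), astensor(c_prev)
    z = ad.tanh(_gate_drive(x_t, h_prev, params.W_z, params.R_z, params.b_z))
    i = ad.sigmoid(_gate_drive(x_t, h_prev, params.W_i, params.R_i, params.b_i))
    f = ad.sigmoid(_gate_drive(x_t, h_prev, params.W_f, params.R_f, params.b_f))
    o = ad.sigmoid(_gate_drive(x_t, h_prev, params.W_o, params.R_o, params.b_o))
    c = f * c_prev + i * z
    h = ad.tanh(c) * o
    return RecurrentState(h, c)


def rdlstm_cell_step(h_below, h_dilated, c_dilated,
                     params: RDLSTMLayerParams | LSTMCellParams) -> RecurrentState:
    """One residual dilated LSTM step.

    ``h_below`` is the layer-below hidden state at time t (the raw input for
    the bottom layer); ``h_dilated``/``c_dilated`` are this layer's states at
    time t - d.  The residual shortcut adds ``h_below`` inside the output
    gate, so the hidden size must equal the input size.
    """
    cell = params.cell if isinstance(params, RDLSTMLayerParams) else params
    h_below, h_dilated, c_dilated = astensor(h_below), astensor(h_dilated), astensor(c_dilated)
    if h_below.shape[-1] != cell.hidden_size:
        raise ad.ShapeError(
            f"residual shortcut needs input size == hidden size "
            f"({h_below.shape[-1]} != {cell.hidden_size})")
    z = ad.tanh(_gate_drive(h_below, h_dilated, cell.W_z, cell.R_z, cell.b_z))
    i = ad.sigmoid(_gate_drive(h_below, h_dilated, cell.W_i, cell.R_i, cell.b_i))
    f = ad.sigmoid(_gate_drive(h_below, h_dilated, cell.W_f, cell.R_f, cell.b_f))
    o = ad.sigmoid(_gate_drive(h_below, h_dilated, cell.W_o, cell.R_o, cell.b_o))
    c = f * c_dilated + i * z
    h = o * (ad.tanh(c) + h_below)
    return RecurrentState(h, c)


def _iterate_layer(seq_below, params: RDLSTMLayerParams, residual: bool) -> Tensor:
    """Run a cell over a [batch, dim, length] sequence, dilated recurrence."""
    seq_below = astensor(seq_below)
    if seq_below.ndim != 3:
        raise ad.ShapeError("sequence must be [batch, channels, length]")
    d = params.dilation
    batch, _, length = seq_below.shape
    hidden = params.cell.hidden_size
    zero_h = Tensor(np.zeros((batch, hidden)))
    zero_c = Tensor(np.zeros((batch, hidden)))
    hs: list[Tensor] = []
    cs: list[Tensor] = []
    for t in range(length):
        x_t = seq_below[:, :, t]
        if t - d >= 0:
            h_past, c_past = hs[t - d], cs[t - d]
        else:
            h_past, c_past = zero_h, zero_c
        if residual:
            state = rdlstm_cell_step(x_t, h_past, c_past, params.cell)
        else:
            state = lstm_cell_step(x_t, h_past, c_past, params.cell)
        hs.append(state.hidden)
        cs.append(state.cell)
    return ad.concatenate([ad.reshape(h, (batch, hidden, 1)) for h in hs], axis=2)


def rdlstm_layer_forward(seq_below, params: RDLSTMLayerParams) -> Tensor:
    """Hidden sequence [batch, hidden, length] of one RDLSTM layer."""
    return _iterate_layer(seq_below, params, residual=True)


def lstm_layer_forward(seq_below, params: RDLSTMLayerParams) -> Tensor:
    """Plain LSTM layer (no shortcut), used by the ablation baselines."""
    return _iterate_layer(seq_below, params, residual=False)


def multi_length_forward(f_pos, layers: Sequence[RDLSTMLayerParams],
                         residual: bool = True) -> tuple[Tensor, ...]:
    """Hierarchical stack: each layer consumes the hidden sequence below.

    Returns one hidden-sequence tap per layer, bottom-up; with the default
    dilation schedule (1, 2, 4) these are the query/key/value streams
    F_q, F_k, F_v of the mutual-attention stage.
    """
    if not layers:
        raise ValueError("at least one recurrent layer is required")
    taps: list[Tensor] = []
    below = astensor(f_pos)
    for layer in layers:
        below = _iterate_layer(below, layer, residual=residual)
        taps.append(below)
    return tuple(taps)


def init_lstm_cell(n_in: int, hidden: int, rng: np.random.Generator,
                   forget_bias: float = 1.0) -> LSTMCellParams:
    """Uniform(-1/sqrt(h), 1/sqrt(h)) init; forget bias offset aids learning."""
    s = 1.0 / np.sqrt(hidden)

    def w(shape):
        return Tensor(rng.uniform(-s, s, shape), requires_grad=True)

    return LSTMCellParams(
        W_z=w((hidden, n_in)), W_i=w((hidden, n_in)), W_f=w((hidden, n_in)), W_o=w((hidden, n_in)),
        R_z=w((hidden, hidden)), R_i=w((hidden, hidden)), R_f=w((hidden, hidden)), R_o=w((hidden, hidden)),
        b_z=w((hidden,)), b_i=w((hidden,)),
        b_f=Tensor(rng.uniform(-s, s, hidden) + forget_bias, requires_grad=True),
        b_o=w((hidden,)),
    )


def init_stack(n_in: int, hidden: int, dilations: Sequence[int],
               rng: np.random.Generator) -> list[RDLSTMLayerParams]:
    layers = []
    size = n_in
    for idx, d in enumerate(dilations):
        layers.append(RDLSTMLayerParams(init_lstm_cell(size, hidden, rng), int(d), idx))
        size = hidden
    return layers
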