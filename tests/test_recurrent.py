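"""LSTM / residual dilated LSTM cells and the hierarchical stack."""

import math

import numpy as np
import pytest

from pmmnet import recurrent as rec
from pmmnet.autodiff import ShapeError, Tensor

from conftest import relative_grad_error


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def scalar_lstm_reference(x, h, c, w, r, b):
    """Independent per-element plain-Python LSTM step (the cross-check oracle)."""
    z = math.tanh(w["z"] * x + r["z"] * h + b["z"])
    i = _sigmoid(w["i"] * x + r["i"] * h + b["i"])
    f = _sigmoid(w["f"] * x + r["f"] * h + b["f"])
    o = _sigmoid(w["o"] * x + r["o"] * h + b["o"])
    c_new = f * c + i * z
    return math.tanh(c_new) * o, c_new


def _cell_from_scalars(w, r, b):
    t = lambda v: Tensor(np.array([[float(v)]]), requires_grad=True)
    tb = lambda v: Tensor(np.array([float(v)]), requires_grad=True)
    return rec.LSTMCellParams(
        W_z=t(w["z"]), W_i=t(w["i"]), W_f=t(w["f"]), W_o=t(w["o"]),
        R_z=t(r["z"]), R_i=t(r["i"]), R_f=t(r["f"]), R_o=t(r["o"]),
        b_z=tb(b["z"]), b_i=tb(b["i"]), b_f=tb(b["f"]), b_o=tb(b["o"]))


def _zero_cell(n_in, hidden):
    z = lambda shape: Tensor(np.zeros(shape), requires_grad=True)
    return rec.LSTMCellParams(
        W_z=z((hidden, n_in)), W_i=z((hidden, n_in)), W_f=z((hidden, n_in)), W_o=z((hidden, n_in)),
        R_z=z((hidden, hidden)), R_i=z((hidden, hidden)), R_f=z((hidden, hidden)), R_o=z((hidden, hidden)),
        b_z=z(hidden), b_i=z(hidden), b_f=z(hidden), b_o=z(hidden))


class TestLSTMCell:
    def test_all_zero_parameters_give_zero_state(self):
        cell = _zero_cell(3, 2)
        state = rec.lstm_cell_step(np.zeros((1, 3)), np.zeros((1, 2)), np.zeros((1, 2)), cell)
        np.testing.assert_allclose(state.hidden.data, 0.0, atol=1e-15)
        np.testing.assert_allclose(state.cell.data, 0.0, atol=1e-15)

    def test_scalar_hand_computation(self):
        w = dict.fromkeys("zifo", 1.0)
        r = dict.fromkeys("zifo", 0.0)
        b = dict.fromkeys("zifo", 0.0)
        cell = _cell_from_scalars(w, r, b)
        state = rec.lstm_cell_step([[1.0]], [[0.0]], [[1.0]], cell)
        h_ref, c_ref = scalar_lstm_reference(1.0, 0.0, 1.0, w, r, b)
        assert state.cell.data.ravel()[0] == pytest.approx(c_ref, abs=1e-15)
        assert state.hidden.data.ravel()[0] == pytest.approx(h_ref, abs=1e-15)
        assert c_ref == pytest.approx(1.2878, abs=1e-4)
        assert h_ref == pytest.approx(0.6277, abs=1e-4)

    def test_saturated_forget_gate_preserves_cell_state(self):
        cell = _zero_cell(1, 2)
        cell.b_f.data[:] = 50.0
        c_prev = np.array([[0.7, -1.3]])
        state = rec.lstm_cell_step(np.zeros((1, 1)), np.zeros((1, 2)), c_prev, cell)
        np.testing.assert_allclose(state.cell.data, c_prev, atol=1e-9)

    def test_matches_scalar_reference_on_random_draws(self, rng):
        for _ in range(100):
            w, r, b = ({k: rng.normal() for k in "zifo"} for _ in range(3))
            x, h, c = rng.normal(size=3)
            cell = _cell_from_scalars(w, r, b)
            state = rec.lstm_cell_step([[x]], [[h]], [[c]], cell)
            h_ref, c_ref = scalar_lstm_reference(x, h, c, w, r, b)
            assert abs(state.hidden.data.ravel()[0] - h_ref) < 1e-12
            assert abs(state.cell.data.ravel()[0] - c_ref) < 1e-12

    def test_shape_mismatch_raises(self):
        cell = _zero_cell(3, 2)
        with pytest.raises((ShapeError, ValueError)):
            rec.lstm_cell_step(np.zeros((1, 4)), np.zeros((1, 2)), np.zeros((1, 2)), cell)


class TestRDLSTMCell:
    def test_zero_parameters_halve_the_shortcut(self, rng):
        cell = _zero_cell(4, 4)
        h_below = rng.normal(size=(2, 4))
        state = rec.rdlstm_cell_step(h_below, np.zeros((2, 4)), np.zeros((2, 4)), cell)
        np.testing.assert_allclose(state.hidden.data, 0.5 * h_below, atol=1e-14)

    def test_zero_shortcut_reduces_to_plain_cell(self, rng):
        cell = rec.init_lstm_cell(3, 3, rng)
        h_d = rng.normal(size=(1, 3))
        c_d = rng.normal(size=(1, 3))
        plain = rec.lstm_cell_step(np.zeros((1, 3)), h_d, c_d, cell)
        residual = rec.rdlstm_cell_step(np.zeros((1, 3)), h_d, c_d, cell)
        np.testing.assert_allclose(residual.cell.data, plain.cell.data, atol=1e-14)
        # h' = o*(tanh(c') + 0) equals the plain h = tanh(c)*o
        np.testing.assert_allclose(residual.hidden.data, plain.hidden.data, atol=1e-14)

    def test_scalar_hand_computation(self):
        ones = dict.fromkeys("zifo", 1.0)
        zeros = dict.fromkeys("zifo", 0.0)
        cell = _cell_from_scalars(ones, ones, zeros)
        state = rec.rdlstm_cell_step([[1.0]], [[0.0]], [[0.0]], cell)
        sig1 = 1 / (1 + math.exp(-1))
        c_ref = sig1 * math.tanh(1.0)
        h_ref = sig1 * (math.tanh(c_ref) + 1.0)
        assert state.cell.data.ravel()[0] == pytest.approx(c_ref, abs=1e-15)
        assert state.hidden.data.ravel()[0] == pytest.approx(h_ref, abs=1e-15)
        assert c_ref == pytest.approx(0.5568, abs=1e-4)
        assert h_ref == pytest.approx(1.1010, abs=1e-3)

    def test_residual_requires_matching_dims(self, rng):
        cell = rec.init_lstm_cell(3, 4, rng)
        with pytest.raises(ShapeError):
            rec.rdlstm_cell_step(np.zeros((1, 3)), np.zeros((1, 4)), np.zeros((1, 4)), cell)


def _layer(n, hidden, d, rng, index=0):
    return rec.RDLSTMLayerParams(rec.init_lstm_cell(n, hidden, rng), d, index)


def interleaved_oracle(seq, layer):
    """Dilation-d layer == d independent d=1 passes over the strided subsequences."""
    d = layer.dilation
    base = rec.RDLSTMLayerParams(layer.cell, 1, layer.layer_index)
    out = np.zeros((seq.shape[0], layer.cell.hidden_size, seq.shape[2]))
    for offset in range(d):
        sub = seq[:, :, offset::d]
        if sub.shape[2] == 0:
            continue
        out[:, :, offset::d] = rec.rdlstm_layer_forward(sub, base).data
    return out


class TestRDLSTMLayer:
    @pytest.mark.parametrize("d,length", [(2, 6), (2, 7), (3, 11), (4, 24)])
    def test_dilation_decomposition(self, d, length, rng):
        layer = _layer(4, 4, d, rng)
        seq = rng.normal(size=(2, 4, length))
        direct = rec.rdlstm_layer_forward(seq, layer).data
        np.testing.assert_allclose(direct, interleaved_oracle(seq, layer), atol=1e-6)

    def test_dilation_beyond_length_is_feedforward(self, rng):
        layer = _layer(3, 3, 10, rng)
        seq = rng.normal(size=(1, 3, 5))
        out = rec.rdlstm_layer_forward(seq, layer).data
        for t in range(5):
            step = rec.rdlstm_cell_step(seq[:, :, t], np.zeros((1, 3)), np.zeros((1, 3)),
                                        layer.cell)
            np.testing.assert_allclose(out[:, :, t], step.hidden.data, atol=1e-14)

    def test_zero_parameter_layer_halves_sequence(self, rng):
        layer = rec.RDLSTMLayerParams(_zero_cell(3, 3), 2)
        seq = rng.normal(size=(2, 3, 6))
        out = rec.rdlstm_layer_forward(seq, layer).data
        np.testing.assert_allclose(out, 0.5 * seq, atol=1e-14)

    def test_invalid_dilation_rejected(self, rng):
        with pytest.raises(ValueError):
            _layer(3, 3, 0, rng)

    def test_states_bounded_over_long_sequences(self, rng):
        layer = _layer(2, 2, 2, rng)
        seq = np.clip(rng.normal(size=(1, 2, 2000)), -3, 3)
        out = rec.rdlstm_layer_forward(seq, layer).data
        assert np.all(np.isfinite(out))


class TestMultiLength:
    def test_zero_parameter_taps_are_geometric(self, rng):
        layers = [rec.RDLSTMLayerParams(_zero_cell(3, 3), d, i)
                  for i, d in enumerate((1, 2, 4))]
        f_pos = rng.normal(size=(2, 3, 8))
        taps = rec.multi_length_forward(f_pos, layers)
        for k, tap in enumerate(taps, start=1):
            np.testing.assert_allclose(tap.data, 0.5 ** k * f_pos, atol=1e-14)

    def test_single_timestep_collapses_dilation(self, rng):
        cell = rec.init_lstm_cell(3, 3, rng)
        seq = rng.normal(size=(1, 3, 1))
        outs = [rec.rdlstm_layer_forward(seq, rec.RDLSTMLayerParams(cell, d)).data
                for d in (1, 2, 4)]
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-14)
        np.testing.assert_allclose(outs[0], outs[2], atol=1e-14)

    def test_unit_dilations_equal_plain_stack_with_shortcut(self, rng):
        layers = [_layer(3, 3, 1, rng, i) for i in range(3)]
        seq = rng.normal(size=(2, 3, 5))
        taps = rec.multi_length_forward(seq, layers)
        below = seq
        for layer, tap in zip(layers, taps):
            manual = rec.rdlstm_layer_forward(below, layer).data
            np.testing.assert_allclose(tap.data, manual, atol=1e-12)
            below = manual

    def test_gradient_check_two_layer_stack(self, rng):
        layers = [_layer(4, 4, 1, rng, 0), _layer(4, 4, 2, rng, 1)]
        seq = rng.normal(size=(1, 4, 8))
        params = [p for l in layers for p in l.parameters()]

        def loss():
            taps = rec.multi_length_forward(seq, layers)
            return (taps[-1] ** 2).sum()

        assert relative_grad_error(loss, params, max_coords=3) < 1e-4
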