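# Methods

## The model

`pmmnet` classifies fixed-length single-channel EEG segments with a network
built from three stages.

**Positional feature encoding.** Each encoder stage is a residual
convolution block followed by non-overlapping 1-D max pooling. Inside a
block the input `F_e` passes a conv → randomized-leaky-ReLU → conv chain to
give a refined map `X_o'`, and a *positional gate* — the logistic sigmoid of
`F_e` itself — scales that refinement elementwise before the residual add:

    F_o = sigmoid(F_e) ⊙ X_o' + F_e

Positions with strong raw activation therefore admit more refinement, which
is what lets shallow layers emphasize short, subtle transients. The RReLU
draws its negative slope per element from U(p, q) during training and uses
the midpoint (p+q)/2 in evaluation.

**Multi-length feature learning.** The encoded sequence feeds a hierarchy of
residual dilated LSTM (RDLSTM) layers. An RDLSTM cell is a standard LSTM
whose recurrent connections reach back `d` steps (dilation) and whose output
gate wraps a shortcut from the layer below:

    c'_t = f' ⊙ c_{t−d} + i' ⊙ z'
    h'_t = o' ⊙ (tanh(c'_t) + h_below)

Stacking dilations 1, 2, 4 grows the temporal receptive field exponentially;
the three per-layer hidden sequences are kept as taps. The residual shortcut
requires the hidden size to equal the per-step input size, so the last
encoder channel count and the recurrent hidden size are tied (validated at
construction). States at t ≤ d are zero vectors, and the bottom layer uses
the encoded signal itself as its shortcut input. One published form of the
cell writes the recurrent drive of the block input with an un-primed hidden
state; we read that as a typo and use the layer's own dilated hidden state in
all four gates.

**Mutual-attention feature reinforcement.** The three taps are batch
normalized per channel, projected to Q/K/V, and combined by three *mutual*
scaled-dot attentions in which each stream takes every role once:
`softmax(QKᵀ/S)V`, `softmax(QVᵀ/S)K`, `softmax(VKᵀ/S)Q`. The second pairing
deliberately attends queries against values and aggregates keys — the cross
pairings are the mechanism by which the differently-dilated streams reinforce
each other. Each attention runs with T heads over feature slices; head
outputs are concatenated and linearly mixed per pair, the three mixed maps
are concatenated featurewise and fused by a width-1 convolution. Time is the
attention axis (positions attend over positions).

**Classification.** The fused map is globally averaged over time and passed
through a dense softmax; training minimizes categorical cross-entropy. A
published variant of the loss mixes in a binary term; we use the standard
categorical form. Adam with a multiplicative per-epoch decay
`lr_e = lr0 · (1 − 0.001)^e` optimizes all parameters. The phrase "decayed by
a factor of 0.001" is ambiguous (multiplicative vs divisive); the
multiplicative reading keeps the rate in a usable range over 100 epochs and
is exposed as `lr_decay` config.

## Numerical implementation

The network runs on a small reverse-mode autodiff engine over NumPy
(`pmmnet.autodiff`): double precision throughout, define-by-run graph,
textbook backward rules, a fused log-sum-exp cross-entropy, and
stride-trick-based 1-D cross-correlation. Double precision is what makes the
finite-difference gradient checks in the test suite meaningful (relative
error < 1e-4 end to end). Softmax and sigmoid are evaluated in their
shift-invariant / branch-stable forms, so ±1000-scale logits do not overflow.
Argmax ties break toward the lowest class index. Probability inputs to the
standalone cross-entropy are clipped at 1e-12.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| encoder channels | 16, 32, 64 | three stages, doubling width, standard for short 1-D signals |
| kernel size | 3 | smallest odd kernel with same-length padding |
| pool window | 2 | halves length per stage; 178 → 22 at the recurrent input |
| RReLU (p, q) | (1/8, 1/3) | the common convention for randomized leaky units |
| hidden size | last encoder width | tied by the residual shortcut |
| dilations | 1, 2, 4 | exponential receptive-field schedule; pairwise distinct rates are required when attention is enabled |
| heads T | 4 | divides the default projection widths |
| scale S | √(features per head) | the standard scaled-dot normalizer |
| batch-norm ε, momentum | 1e-5, 0.1 | standard values |
| lr, decay, batch | 3e-4, 0.001, 64 | Adam with gentle multiplicative decay |
| forget-gate bias | +1 | standard initialization aiding early memory retention |

When a block widens its channel count the residual add uses a learned 1×1
projection of the block input (and the positional gate is computed on that
projection so shapes agree).

## Ablation variants

The component study is reconstructed from four flags (`use_pfe`,
`use_rdlstm`, `use_mfl`, `use_attention`). "original" — no proposed
component — is a plain conv → RReLU → pool encoder with global average
pooling and a dense softmax; it contains no recurrent layer, since the
residual dilated LSTM is itself one of the studied components. "+rdlstm"
adds a single RDLSTM layer, "+pfeblock" the gated residual encoder blocks,
"+mfl" the three-layer dilation stack, "+mfr" the mutual attention on the
stack's taps, and "full" everything. The six configurations have pairwise
distinct parameter counts.

## Synthetic data

The generator emulates what matters for this classifier: class-dependent
high-amplitude low-frequency spike-wave bursts on top of colored background
noise. Background options are pink (default; EEG-like 1/f spectrum,
renormalized to the requested marginal SD), white, or AR(1). A burst is a
sinusoid sharpened by the sign-preserving map `sign(sin)·|sin|^(1/s)`,
placed at a seeded random offset and covering a configurable duty fraction.
Segments are grouped into pseudo-recordings of 23 windows, mirroring the
23-chunks-per-recording structure of the real corpora, so group-aware
cross-validation has genuine groups to respect.

What it does *not* emulate: electrode artifacts, non-stationary background,
inter-subject variability, or realistic ictal waveform diversity. Passing
the synthetic benchmark shows the pipeline can learn amplitude/morphology
differences under its own protocol; it is not evidence of clinical-grade
accuracy on real EEG.

The "binary" preset (burst amplitude 5 vs 0, unit noise SD, 200 segments per
class, length 178) is deliberately well-separated; its companion "null"
preset (both classes pure noise) must sit at chance and guards against
leakage through the protocol.

## Evaluation protocol

Metrics are computed from one-vs-rest confusion counts; multi-class tasks
are macro-averaged. Zero-denominator metrics are reported as 0 and flagged.
Cross-validation is stratified 10-fold by default (5-fold in the reduced
benchmark), seed-deterministic, and group-aware whenever windows share a
source recording — window-level splitting of the real corpora would leak
within-recording correlation between train and test.

## Problem sizes in the shipped checks

The automated checks train a reduced model (encoder 8/16/32, hidden 32,
20 epochs) under 5-fold CV on 400 synthetic segments of length 178, with
three seeds for the separable task and one for the null control, and
exercise the Bonn-format A-E pipeline on a synthesized stand-in corpus of
8 recordings per set. These sizes keep a full run in the minutes range on a
single CPU core while still training ~10^5 parameters end to end.

## Known limitations

- CPU-only and pure NumPy: throughput is orders of magnitude below a GPU
  framework; whole-corpus training at publication scale is out of scope.
- Unidirectional recurrence; single-channel signals only.
- The real Bonn/UCI corpora are not bundled; readers and task construction
  are fully tested against synthesized fixtures in their exact on-disk
  formats.
- Batch-norm running statistics use the biased batch variance with momentum
  0.1; models are evaluable before training via identity statistics.
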