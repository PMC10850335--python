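# pmmnet

Automatic classification of epileptic-seizure EEG from single-channel
recordings. Seizure events show up in scalp and intracranial EEG as subtle,
short transients riding on long-range temporal structure — hard for plain
convolutions (too local) and plain LSTMs (receptive field grows only
linearly). `pmmnet` implements a positional multi-length and mutual-attention
network addressing both:

1. **Positional feature encoding** — residual 1-D conv blocks whose
   refinement branch is gated elementwise by `σ(F_e)`, the sigmoid of the
   block input, so informative positions pass more refinement:
   `F_o = σ(F_e) ⊙ X_o' + F_e`.
2. **Multi-length feature learning** — hierarchically stacked residual
   dilated LSTMs with dilation rates 1, 2, 4: recurrence reaches back `d`
   steps (`c'_t = f'⊙c_{t−d} + i'⊙z'`) and the output gate wraps a shortcut
   from the layer below (`h'_t = o'⊙(tanh(c'_t) + h_below)`).
3. **Mutual-attention feature reinforcement** — the three per-layer taps are
   projected to Q/K/V and combined by three cross scaled-dot attentions
   `softmax(QKᵀ/S)V`, `softmax(QVᵀ/S)K`, `softmax(VKᵀ/S)Q`, multi-headed,
   concatenated and fused by convolution.

A global time-average and dense softmax produce class probabilities;
training is Adam on categorical cross-entropy with per-epoch learning-rate
decay, evaluated by stratified (optionally group-aware) 10-fold
cross-validation with accuracy, precision, sensitivity, specificity and F1.

The whole network — including gradients — runs on NumPy via a small
reverse-mode autodiff engine shipped in the package; there is no deep
learning framework dependency. The package is aimed at researchers studying
seizure-detection architectures who want a transparent, fully-tested
reference implementation that runs anywhere.

## Worked example

```python
import numpy as np
from pmmnet import PMMClassifier, binary_preset, generate, cross_validate

# synthetic benchmark: spike-wave bursts (amplitude 5) vs pure pink noise
ds = generate(binary_preset(n_per_class=200, seed=0))

clf = PMMClassifier(encoder_channels=(8, 16, 32), hidden_size=32,
                    epochs=20, batch_size=64, random_state=0)
result = cross_validate(clf, ds.X, ds.y, k=5, seed=0, group_ids=ds.record_ids)
print({k: round(v, 4) for k, v in result.mean.as_dict().items()})
```

Output:

```
{'accuracy': 1.0, 'precision': 1.0, 'sensitivity': 1.0, 'specificity': 1.0, 'f1': 1.0}
```

Every held-out segment is classified correctly: the benchmark's burst
amplitude (5× the noise SD) makes the two classes cleanly separable, and
five-fold group-aware cross-validation confirms the network learns the
morphology rather than memorizing recordings. The companion null preset
(both classes pure noise) sits at chance accuracy ≈ 0.5, which guards the
protocol against leakage.

The estimator is scikit-learn compatible (`fit` / `predict` /
`predict_proba`, `get_params`/`set_params`, works with `clone` and
`cross_val_score`). Lower-level functional APIs live in `pmmnet.encoder`,
`pmmnet.recurrent`, `pmmnet.attention`, `pmmnet.pipeline`,
`pmmnet.evaluation`, `pmmnet.data_io` and `pmmnet.synthetic`.

## Real corpora

Readers are included for the Bonn corpus (five sets A–E, 100 plain-text
recordings of 4097 samples each; tasks like `A-E` or `AB-CD-E` are built by
windowing each recording into 23 segments of 178 samples) and for the UCI
epileptic-seizure-recognition CSV (11 500 rows × 178 samples, label 1 =
seizure). Neither corpus is bundled; point the CLI or `pmmnet.data_io` at a
local copy.

## Command line

```bash
pmm synth --preset binary --n 200 --seed 0 --out data.csv
pmm train --data data.csv --seed 0 --out model.json
pmm eval  --ckpt model.json --data data.csv
pmm cv    --data /path/to/bonn --task A-E --folds 10 --seed 0
```

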