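"""scikit-learn estimator facade over the network.

``PMMClassifier`` exposes the full positional multi-length mutual-attention
classifier as an sklearn-compatible estimator, so it composes with
``sklearn.base.clone``, pipelines and model selection.  ``X`` is a 2-D array
of single-channel segments [n_samples, segment_length]; labels may be any
hashable class values and are mapped through ``classes_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import pipeline as pl


class PMMClassifier(ClassifierMixin, BaseEstimator):
    """Positional multi-length and mutual-attention EEG classifier.

    Parameters mirror :class:`pmmnet.pipeline.PMMConfig`; see that class and
    the methods note for defaults and their rationale.  ``variant`` selects a
    component-study configuration ("original", "+rdlstm", "+pfeblock",
    "+mfl", "+mfr", "full") and overrides the four ablation flags.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of the sorted unique class labels
    model_ : the trained parameter container
    loss_trace_ : per-epoch mean training cross-entropy
    n_features_in_ : segment length seen during fit
    """

    def __init__(self, *, encoder_channels=(16, 32, 64), kernel_size=3,
                 pool_window=2, rrelu_low=0.125, rrelu_high=1.0 / 3.0,
                 hidden_size=None, dilations=(1, 2, 4), heads=4,
                 attn_scale=None, variant="full", lr=3e-4, lr_decay=0.001,
                 epochs=100, batch_size=64, random_state=0):
        self.encoder_channels = encoder_channels
        self.kernel_size = kernel_size
        self.pool_window = pool_window
        self.rrelu_low = rrelu_low
        self.rrelu_high = rrelu_high
        self.hidden_size = hidden_size
        self.dilations = dilations
        self.heads = heads
        self.attn_scale = attn_scale
        self.variant = variant
        self.lr = lr
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self, n_classes: int) -> pl.PMMConfig:
        return pl.variant_config(
            self.variant,
            n_classes=n_classes,
            encoder_channels=tuple(self.encoder_channels),
            kernel_size=self.kernel_size,
            pool_window=self.pool_window,
            rrelu_low=self.rrelu_low,
            rrelu_high=self.rrelu_high,
            hidden_size=self.hidden_size,
            dilations=tuple(self.dilations),
            heads=self.heads,
            attn_scale=self.attn_scale,
            lr=self.lr,
            lr_decay=self.lr_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=int(self.random_state) if self.random_state is not None else 0,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("PMMClassifier needs at least two classes")
        self.n_features_in_ = X.shape[1]
        config = self._config(len(self.classes_))
        model = pl.init_model(config)
        result = pl.train(model, X, y_idx, config)
        self.model_ = result.model
        self.loss_trace_ = result.loss_trace
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        return pl._logits(X, self.model_, training=False).data

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        return pl.pmm_forward(X, self.model_, training=False).data

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
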