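"""scikit-learn estimator facade over the parallel cross network."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_is_fitted

from .cwt import ScalogramTransformer
from .network import ModelConfig, ParallelCrossNetwork
from .train_eval import Dataset, TrainConfig, train

__all__ = ["CrossFusionEcgClassifier"]


class CrossFusionEcgClassifier(ClassifierMixin, BaseEstimator):
    """Two-branch LSTM/CNN heartbeat classifier with cross-fused features.

    ``X`` is an ``(n_samples, seq_len)`` array of fixed-length beat
    waveforms; the CWT scalogram each beat's convolutional branch
    consumes is computed internally during ``fit`` and ``predict``, so
    the estimator composes with ordinary sklearn pipelines and model
    selection.

    Parameters
    ----------
    lstm_units, conv_filters : triples
        Layer widths; the cross-fusion rule requires them equal
        stage-by-stage.  ``conv_filters=None`` mirrors ``lstm_units``.
    image_shape : tuple, default (100, 100)
        Scalogram image size fed to the convolutional branch.
    wavelet : str, default "gaus8"
        Mother wavelet for the scalograms.
    n_scales, scale_lo, scale_hi :
        CWT scale grid (defaults: 100 scales, 2.16 to 216).
    fs : float, default 360
        Sampling rate of the beat waveforms (Hz).
    learning_rate, batch_size, epochs :
        Adam optimization protocol.
    dropout_rate, dense_units :
        Head regularization and width.
    random_state : int or None
        Seeds weight initialization, batching and dropout.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    model_ : ParallelCrossNetwork
        The trained network.
    history_ : pandas.DataFrame
        Per-epoch training loss/accuracy.
    """

    def __init__(
        self,
        lstm_units=(16, 32, 64),
        conv_filters=None,
        image_shape=(100, 100),
        wavelet="gaus8",
        n_scales=100,
        scale_lo=2.16,
        scale_hi=216.0,
        fs=360.0,
        learning_rate=1e-4,
        batch_size=512,
        epochs=60,
        dropout_rate=0.1,
        dense_units=128,
        random_state=None,
    ):
        self.lstm_units = lstm_units
        self.conv_filters = conv_filters
        self.image_shape = image_shape
        self.wavelet = wavelet
        self.n_scales = n_scales
        self.scale_lo = scale_lo
        self.scale_hi = scale_hi
        self.fs = fs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.random_state = random_state

    def _scalograms(self, X: np.ndarray) -> np.ndarray:
        tf = ScalogramTransformer(
            wavelet=self.wavelet, n_scales=self.n_scales,
            scale_lo=self.scale_lo, scale_hi=self.scale_hi, fs=self.fs,
            out_shape=tuple(self.image_shape),
        )
        flat = tf.fit_transform(X)
        return flat.reshape(X.shape[0], *self.image_shape)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, seq_len)")
        self._label_encoder = LabelEncoder()
        y_idx = self._label_encoder.fit_transform(np.asarray(y))
        self.classes_ = self._label_encoder.classes_
        self.n_features_in_ = X.shape[1]

        cfg = ModelConfig(
            seq_len=X.shape[1],
            image_shape=tuple(self.image_shape),
            lstm_units=tuple(self.lstm_units),
            conv_filters=tuple(self.conv_filters or self.lstm_units),
            dropout_rate=self.dropout_rate,
            dense_units=self.dense_units,
            n_classes=len(self.classes_),
        )
        seed = self.random_state if self.random_state is not None else 0
        self.model_ = ParallelCrossNetwork(cfg, seed=seed)
        dataset = Dataset(
            beats=X, scalograms=self._scalograms(X), labels=y_idx,
            class_names=tuple(str(c) for c in self.classes_),
        )
        self.history_ = train(
            self.model_, dataset,
            TrainConfig(batch_size=self.batch_size,
                        learning_rate=self.learning_rate,
                        epochs=self.epochs, seed=seed),
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must be (n_samples, {self.n_features_in_})"
            )
        return self.model_.predict_proba(X, self._scalograms(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]
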