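"""scikit-learn estimator for the spatial-temporal transformer classifier.

:class:`TSTNClassifier` bundles the OVR-CSP spatial filter bank with the
attention network of :mod:`tstn_bci.nn` and trains the whole stack with
mini-batch Adam on cross-entropy (learning rate 2e-4, batch size 50 by
default).  A stratified hold-out fraction of the training set drives early
stopping on validation loss; the parameters from the best epoch are kept.
Evaluation-mode prediction is deterministic; probability ties are broken
toward the lowest class index by ``argmax``.

The estimator composes with scikit-learn model selection (``clone``,
``cross_val_score``) since all hyperparameters are constructor arguments
and all fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from . import nn
from .csp import OvrCspBank
from .io import DataError

MODEL_FORMAT_VERSION = 1


class TSTNClassifier(BaseEstimator, ClassifierMixin):
    """Spatial-temporal transformer for 3-class motor-imagery epochs.

    Parameters
    ----------
    learning_rate, batch_size : Adam settings.
    max_epochs, early_stop_patience, min_delta, validation_fraction :
        training-loop control; early stopping monitors hold-out loss.
    dropout_spatial, dropout_temporal : dropout on the spatial-attention and
        temporal-attention outputs, training mode only.
    conv_activation : ``"elu"`` (default) or ``"linear"`` after each
        convolution layer.
    attention_lr_scale, embed_lr_scale, head_lr_scale : layer-group
        learning-rate multipliers on the base Adam rate (see
        :class:`~tstn_bci.nn.Adam` for why the attention projections train
        at a reduced rate).
    warm_start : when True, a refit continues from the current network
        parameters (the CSP bank is still refit on the new data).
    dtype : network dtype; float32 by default for speed, float64 for
        verification work.
    random_state : seeds initialization, batching, dropout, and the
        validation split.

    Attributes
    ----------
    bank_ : fitted :class:`~tstn_bci.csp.OvrCspBank`.
    params_ : network parameter dict.
    net_config_ : :class:`~tstn_bci.nn.NetConfig`.
    input_scale_ : scalar normalizer (median RMS of training features).
    history_ : per-epoch training/validation loss records.
    n_iter_ : training epochs actually run.
    classes_ : sorted class codes seen in ``y``.
    """

    def __init__(self, learning_rate: float = 2e-4, batch_size: int = 50,
                 max_epochs: int = 100, early_stop_patience: int = 20,
                 min_delta: float = 0.0, validation_fraction: float = 0.1,
                 dropout_spatial: float = 0.3, dropout_temporal: float = 0.5,
                 conv_activation: str = "elu", csp_reg: float = 1e-9,
                 attention_lr_scale: float = 0.02, embed_lr_scale: float = 2.0,
                 head_lr_scale: float = 10.0,
                 warm_start: bool = False, dtype: str = "float32",
                 random_state: int | None = None):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.dropout_spatial = dropout_spatial
        self.dropout_temporal = dropout_temporal
        self.conv_activation = conv_activation
        self.csp_reg = csp_reg
        self.attention_lr_scale = attention_lr_scale
        self.embed_lr_scale = embed_lr_scale
        self.head_lr_scale = head_lr_scale
        self.warm_start = warm_start
        self.dtype = dtype
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _net_config(self, n_samples: int) -> nn.NetConfig:
        return nn.NetConfig(
            d=n_samples,
            dropout_spatial=self.dropout_spatial,
            dropout_temporal=self.dropout_temporal,
            activation=self.conv_activation,
        )

    def _features(self, X: np.ndarray) -> np.ndarray:
        S = self.bank_.transform(X)
        return (S / self.input_scale_).astype(self.dtype)

    def fit(self, X, y):
        """Fit bank and network on epochs ``X`` (trials x channels x samples)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise DataError("X must be trials x channels x samples")
        if len(y) != len(X):
            raise DataError("label count must equal trial count")
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)

        cfg = self._net_config(X.shape[2])
        self.bank_ = OvrCspBank(reg=self.csp_reg).fit(X, y)
        S_raw = self.bank_.transform(X)
        self.input_scale_ = float(
            np.median(np.sqrt(np.mean(S_raw**2, axis=(1, 2)))) or 1.0
        )
        S = (S_raw / self.input_scale_).astype(self.dtype)

        resume = (
            self.warm_start
            and getattr(self, "params_", None) is not None
            and self.net_config_ == cfg
        )
        if not resume:
            self.params_ = nn.init_params(cfg, rng, dtype=np.dtype(self.dtype))
            self.net_config_ = cfg
        # head-normalization statistics of the pooled features on this
        # training set (data constants; refreshed on warm-start refits)
        pool_t = nn.pooled_features(S, self.params_, cfg)
        self.params_["bn_mean"] = pool_t.mean(axis=0).astype(self.dtype)
        self.params_["bn_var"] = np.maximum(
            pool_t.var(axis=0), 1e-8
        ).astype(self.dtype)

        # Stratified hold-out for early stopping (skipped when the set is
        # too small to spare one trial per class).
        n_val = int(np.floor(self.validation_fraction * len(X)))
        counts = np.bincount(np.searchsorted(self.classes_, y))
        if (0 < self.validation_fraction < 1
                and n_val >= len(self.classes_) and counts.min() >= 2):
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=n_val,
                random_state=int(rng.integers(2**31)),
            )
            train_idx, val_idx = next(splitter.split(S, y))
        else:
            train_idx = np.arange(len(X))
            val_idx = np.empty(0, dtype=int)

        opt = nn.Adam(
            self.params_, lr=self.learning_rate,
            multipliers=nn.group_multipliers(
                self.attention_lr_scale, self.embed_lr_scale,
                self.head_lr_scale,
            ),
        )
        best_loss, best_params, patience = np.inf, None, 0
        self.history_ = []
        n_train = len(train_idx)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_train)
            epoch_loss = 0.0
            for start in range(0, n_train, self.batch_size):
                idx = train_idx[order[start : start + self.batch_size]]
                loss, grads = nn.loss_and_grads(
                    self.params_, cfg, S[idx], y[idx], train=True, rng=rng
                )
                opt.step(self.params_, grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= n_train

            if len(val_idx):
                val_probs = nn.forward(S[val_idx], self.params_, cfg)
                val_loss = nn.cross_entropy(val_probs, y[val_idx])
            else:
                val_loss = epoch_loss
            self.history_.append(
                {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss}
            )
            if val_loss < best_loss - self.min_delta:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params_.items()}
                patience = 0
            else:
                patience += 1
                if patience >= self.early_stop_patience:
                    break
        if best_params is not None:
            self.params_ = best_params
        self.n_iter_ = len(self.history_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        S = self._features(X)
        return np.asarray(
            nn.forward(S, self.params_, self.net_config_), dtype=float
        )

    def predict(self, X):
        proba = self.predict_proba(X)
        return np.argmax(proba, axis=1)  # ties -> lowest class index

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize bank, parameters, shapes, and lineage to one archive."""
        check_is_fitted(self, "params_")
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "net_config": self.net_config_.__dict__,
            "hyperparams": self.get_params(),
            "input_scale": self.input_scale_,
            "classes": self.classes_.tolist(),
            "lineage": getattr(self, "lineage_", "initial"),
        }
        arrays = {f"param_{k}": v for k, v in self.params_.items()}
        arrays["csp_Z"] = self.bank_.Z_
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TSTNClassifier":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            if meta["format_version"] != MODEL_FORMAT_VERSION:
                raise DataError(
                    f"model format version {meta['format_version']} not supported"
                )
            clf = cls(**meta["hyperparams"])
            clf.net_config_ = nn.NetConfig(**meta["net_config"])
            clf.params_ = {
                k[len("param_"):]: archive[k]
                for k in archive.files if k.startswith("param_")
            }
            from .csp import SpatialFilterBank
            bank = OvrCspBank()
            bank.Z_ = archive["csp_Z"]
            bank.bank_ = SpatialFilterBank(Z=archive["csp_Z"], solutions=[])
            clf.bank_ = bank
            clf.input_scale_ = float(meta["input_scale"])
            clf.classes_ = np.asarray(meta["classes"])
            clf.lineage_ = meta["lineage"]
            clf.history_ = []
        return clf
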