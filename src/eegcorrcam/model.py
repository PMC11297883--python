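"""The correlation-image CNN: architecture, training and cross-validation.

The default architecture is a five-block convolutional stack (8, 16, 32,
64, 128 same-padded 3x3 filters, each followed by 2x2 max pooling), global
max pooling to a 128-vector, dropout 0.2, a 32-unit dense layer with batch
normalisation, and a 3-way softmax head.  On a 360 x 360 x 1 correlation
image the spatial trace is 360 -> 180 -> 90 -> 45 -> 22 -> 11.  Training
uses Adam (lr 1e-4), sparse categorical cross-entropy with inverse-
frequency class weights, 700 epochs at batch size 15, and keeps a
checkpoint of the best-validation-accuracy weights.

Cross-validation follows a k-fold protocol (default k=10): for each
iteration one fold is the test set, one of the remaining folds is held out
as the validation set that drives checkpointing, and the checkpointed
model is evaluated on the test fold.  Folds are stratified by class;
``grouping="subject"`` additionally keeps all epochs of a subject in the
same fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import nn
from .metrics import FoldResult, confusion, summarize


@dataclass(frozen=True)
class LayerSpec:
    """One architecture row: a layer kind plus its size parameters."""

    kind: str  # conv2d | maxpool2d | globalmaxpool2d | dropout | dense | batchnorm | softmax-dense
    filters: int | None = None
    kernel: int | None = None
    pool: int | None = None
    units: int | None = None
    rate: float | None = None
    activation: str | None = None

    def __post_init__(self) -> None:
        needs = {
            "conv2d": ("filters", "kernel"),
            "maxpool2d": ("pool",),
            "globalmaxpool2d": (),
            "dropout": ("rate",),
            "dense": ("units",),
            "batchnorm": (),
            "softmax-dense": ("units",),
        }
        if self.kind not in needs:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for attr in needs[self.kind]:
            if getattr(self, attr) is None:
                raise ValueError(f"{self.kind} layer requires {attr}")


def default_layers(dropout_rate: float = 0.2, n_classes: int = 3,
                   conv_filters: Sequence[int] = (8, 16, 32, 64, 128),
                   dense_units: int = 32) -> tuple[LayerSpec, ...]:
    """The 15-row default architecture (conv/pool x5, GMP, dropout, dense,
    batchnorm, softmax)."""
    rows: list[LayerSpec] = []
    for f in conv_filters:
        rows.append(LayerSpec("conv2d", filters=f, kernel=3, activation="relu"))
        rows.append(LayerSpec("maxpool2d", pool=2))
    rows += [
        LayerSpec("globalmaxpool2d"),
        LayerSpec("dropout", rate=dropout_rate),
        LayerSpec("dense", units=dense_units, activation="relu"),
        LayerSpec("batchnorm"),
        LayerSpec("softmax-dense", units=n_classes),
    ]
    return tuple(rows)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture plus training hyper-parameters.

    The defaults are the full-scale settings (360 x 360 input, 700 epochs,
    batch 15, Adam lr 1e-4). :meth:`scaled` returns a reduced spec for
    small synthetic studies.
    """

    input_shape: tuple[int, int, int] = (360, 360, 1)
    layers: tuple[LayerSpec, ...] = field(default_factory=default_layers)
    learning_rate: float = 1e-4
    loss: str = "sparse_categorical_crossentropy"
    epochs: int = 700
    batch_size: int = 15
    dropout_rate: float = 0.2
    n_classes: int = 3

    def __post_init__(self) -> None:
        last = self.layers[-1]
        if last.kind != "softmax-dense" or last.units != self.n_classes:
            raise ValueError("final layer must be softmax-dense with n_classes units")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def scaled(cls, input_side: int, n_classes: int = 3,
               conv_filters: Sequence[int] = (4, 8, 16, 32, 64),
               dense_units: int = 32, epochs: int = 30, batch_size: int = 16,
               learning_rate: float = 1e-3, dropout_rate: float = 0.2) -> "ModelSpec":
        """A reduced spec (fewer filters, fewer epochs, larger lr) for
        scaled-down simulation studies on smaller correlation images."""
        return cls(
            input_shape=(input_side, input_side, 1),
            layers=default_layers(dropout_rate, n_classes, conv_filters, dense_units),
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            dropout_rate=dropout_rate,
            n_classes=n_classes,
        )


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Network:
    """Instantiate an untrained network from a spec."""
    mapping: list[nn.Layer] = []
    for row in spec.layers:
        if row.kind == "conv2d":
            mapping.append(nn.Conv2D(row.filters, row.kernel,
                                     row.activation or "relu"))
        elif row.kind == "maxpool2d":
            mapping.append(nn.MaxPool2D(row.pool))
        elif row.kind == "globalmaxpool2d":
            mapping.append(nn.GlobalMaxPool2D())
        elif row.kind == "dropout":
            mapping.append(nn.Dropout(row.rate))
        elif row.kind == "dense":
            mapping.append(nn.Dense(row.units, row.activation))
        elif row.kind == "batchnorm":
            mapping.append(nn.BatchNorm())
        elif row.kind == "softmax-dense":
            mapping.append(nn.Dense(row.units, "softmax"))
    return nn.Network(mapping, spec.input_shape, seed=seed)


def class_weights(labels: Sequence[int], n_classes: int | None = None
                  ) -> dict[int, float]:
    """Inverse-frequency class weights ``w_c = N / (K * N_c)``.

    Satisfies ``sum_c N_c * w_c = N``: the total loss mass is unchanged,
    only redistributed toward minority classes.
    """
    labels = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes)
    for c in range(n_classes):
        if counts[c] == 0:
            raise ValueError(f"class {c} has no samples")
    n = len(labels)
    return {c: n / (n_classes * counts[c]) for c in range(n_classes)}


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def _evaluate(network: nn.Network, X: np.ndarray, y: np.ndarray,
              batch_size: int = 32) -> tuple[float, float]:
    probs = network.predict_proba(X, batch_size)
    loss, _ = nn.weighted_sparse_crossentropy(probs, y)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train(network: nn.Network, X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray, spec: ModelSpec,
          seed: int = 0, use_class_weights: bool = True,
          verbose: bool = False) -> TrainingHistory:
    """Train with Adam and keep a best-validation checkpoint.

    The checkpoint criterion is maximum validation accuracy, ties broken by
    lower validation loss; after training the checkpointed weights are
    stored on the network as ``checkpoint_weights`` and can be restored
    with :func:`restore_checkpoint`.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    rng = np.random.default_rng(seed)
    optimizer = nn.Adam(network, lr=spec.learning_rate)
    weights = class_weights(y_train, spec.n_classes) if use_class_weights else None
    sw = (np.array([weights[c] for c in y_train])
          if weights is not None else np.ones(len(y_train)))

    history = TrainingHistory()
    best = (-np.inf, np.inf)  # (val acc, -val loss) maximised lexicographically
    network.checkpoint_weights = network.get_weights()
    n = len(X_train)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb, wb = X_train[idx], y_train[idx], sw[idx]
            probs = network.forward(xb, training=True, rng=rng)
            loss, dlogits = nn.weighted_sparse_crossentropy(probs, yb, wb)
            network.backward(dlogits)
            optimizer.step()
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum(probs.argmax(axis=1) == yb))
        val_loss, val_acc = _evaluate(network, X_val, y_val)
        history.loss.append(ep_loss / n)
        history.accuracy.append(ep_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if (val_acc, -val_loss) > best:
            best = (val_acc, -val_loss)
            network.checkpoint_weights = network.get_weights()
        if verbose:
            print(f"epoch {epoch + 1}/{spec.epochs} "
                  f"loss={history.loss[-1]:.4f} acc={history.accuracy[-1]:.3f} "
                  f"val_loss={val_loss:.4f} val_acc={val_acc:.3f}")
    network.best_val_accuracy = best[0]
    network.best_val_loss = -best[1]
    return history


def restore_checkpoint(network: nn.Network) -> nn.Network:
    """Load the best-validation weights saved during training."""
    network.set_weights(network.checkpoint_weights)
    return network


def _validation_split(train_idx: np.ndarray, y: np.ndarray,
                      groups: np.ndarray | None, k: int, seed: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Hold one stratified fold of the training indices out for validation."""
    y_tr = y[train_idx]
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k - 1, shuffle=True, random_state=seed)
        fit_rel, val_rel = next(splitter.split(train_idx[:, None], y_tr,
                                               groups[train_idx]))
    else:
        splitter = StratifiedKFold(n_splits=k - 1, shuffle=True, random_state=seed)
        fit_rel, val_rel = next(splitter.split(train_idx[:, None], y_tr))
    return train_idx[fit_rel], train_idx[val_rel]


def cross_validate(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                   k: int = 10, grouping: str = "epoch",
                   groups: Sequence | None = None, seed: int = 0,
                   use_class_weights: bool = True, verbose: bool = False,
                   return_models: bool = False):
    """Stratified k-fold cross-validation with validation-fold checkpointing.

    Parameters
    ----------
    X : ndarray, shape (N, H, W) or (N, H, W, 1)
        Correlation images.
    y : integer class labels.
    grouping : {"epoch", "subject"}
        "epoch" stratifies individual epochs over folds; "subject" keeps
        all epochs of a subject in one fold (no subject appears in both
        the train and test side of any iteration) and requires ``groups``.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if grouping not in ("epoch", "subject"):
        raise ValueError("grouping must be 'epoch' or 'subject'")
    groups_arr: np.ndarray | None = None
    if grouping == "subject":
        if groups is None:
            raise ValueError("grouping='subject' requires groups")
        groups_arr = np.asarray(groups)
        if len(np.unique(groups_arr)) < k:
            raise ValueError(f"need at least {k} subjects for {k} folds")
        outer = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = outer.split(X, y, groups_arr)
    else:
        if len(X) < k:
            raise ValueError(f"need at least {k} samples for {k} folds")
        outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = outer.split(X, y)

    results: list[FoldResult] = []
    models: list[nn.Network] = []
    for fold, (train_idx, test_idx) in enumerate(split_iter):
        fold_seed = seed * 10_000 + fold
        fit_idx, val_idx = _validation_split(train_idx, y, groups_arr, k, fold_seed)
        network = build_model(spec, seed=fold_seed)
        train(network, X[fit_idx], y[fit_idx], X[val_idx], y[val_idx],
              spec, seed=fold_seed, use_class_weights=use_class_weights)
        restore_checkpoint(network)
        probs = network.predict_proba(X[test_idx])
        y_pred = probs.argmax(axis=1)
        cm = confusion(y[test_idx], y_pred, spec.n_classes)
        result = summarize(cm)
        result.fold = fold
        result.test_indices = test_idx
        results.append(result)
        if return_models:
            models.append(network)
        if verbose:
            print(f"fold {fold + 1}/{k}: accuracy={result.accuracy:.2f}%")
    return (results, models) if return_models else results


class CorrelationCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the correlation-image CNN.

    Parameters
    ----------
    spec : ModelSpec or None
        Architecture and training settings; ``None`` uses the full-scale
        default (360 x 360 input, 700 epochs).
    validation_fraction : float
        Share of the training data held out (stratified) to drive
        checkpointing when ``fit`` is not given an explicit validation set.
    use_class_weights : bool
        Weight the loss by inverse class frequency.
    seed : int
        Controls initialisation, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in ``fit``.
    network_ : Network
        The trained network (checkpoint restored).
    history_ : TrainingHistory
        Per-epoch train/validation loss and accuracy.
    """

    def __init__(self, spec: ModelSpec | None = None,
                 validation_fraction: float = 0.1,
                 use_class_weights: bool = True, seed: int = 0,
                 verbose: bool = False):
        self.spec = spec
        self.validation_fraction = validation_fraction
        self.use_class_weights = use_class_weights
        self.seed = seed
        self.verbose = verbose

    def _resolve_spec(self, X: np.ndarray, n_classes: int) -> ModelSpec:
        spec = self.spec if self.spec is not None else ModelSpec()
        side = X.shape[1]
        if spec.input_shape[0] != side or spec.n_classes != n_classes:
            # re-derive the spec for the observed input size / label set
            spec = replace(spec, input_shape=(X.shape[1], X.shape[2], 1),
                           layers=tuple(
                               r if r.kind != "softmax-dense"
                               else LayerSpec("softmax-dense", units=n_classes)
                               for r in spec.layers),
                           n_classes=n_classes)
        return spec

    def fit(self, X: np.ndarray, y,
            validation_data: tuple[np.ndarray, np.ndarray] | None = None
            ) -> "CorrelationCNNClassifier":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3:
            raise ValueError("X must have shape (n_samples, height, width)")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        spec = self._resolve_spec(X, len(self.classes_))
        self.spec_ = spec
        self.network_ = build_model(spec, seed=self.seed)
        if validation_data is not None:
            Xv, yv = validation_data
            Xv = np.asarray(Xv, dtype=np.float32)
            yv_idx = np.searchsorted(self.classes_, np.asarray(yv))
            Xt, yt = X, y_idx
        else:
            splitter = StratifiedKFold(
                n_splits=max(2, int(round(1 / self.validation_fraction))),
                shuffle=True, random_state=self.seed)
            fit_rel, val_rel = next(splitter.split(X, y_idx))
            Xt, yt = X[fit_rel], y_idx[fit_rel]
            Xv, yv_idx = X[val_rel], y_idx[val_rel]
        self.history_ = train(self.network_, Xt, yt, Xv, yv_idx, spec,
                              seed=self.seed,
                              use_class_weights=self.use_class_weights,
                              verbose=self.verbose)
        restore_checkpoint(self.network_)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        return self.network_.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
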