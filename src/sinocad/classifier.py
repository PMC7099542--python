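"""CNN false-positive reduction: network specs, ROI-level split, estimators.

Two architectures are provided.  The single-input network is
Conv 7x7x32 (LeakyReLU) -> maxpool 2x2/s2 -> Conv 5x5x64 (LeakyReLU) ->
maxpool 2x2/s2 -> FC 1000 (LeakyReLU) -> FC 2 (softmax); it accepts image
patches, sinograms or multi-channel stacks (the first convolution's
channel depth follows the input).  The dual-input network runs a
sinogram branch (conv 7x7x32 / 5x5x64) and an image branch (conv 7x7x64 /
5x5x64) and fuses their flattened outputs into the shared FC 1000 ->
FC 2 head.  Convolutions are stride 1 with same padding, so a 40-wide
input follows the 40 -> 20 -> 10 spatial schedule.

Training uses Adam (lr 1e-4, beta1 0.9, beta2 0.999), batch size 30, up
to 25 epochs, with early stopping on a held-out slice of the training
data.  Datasets are always split at ROI level so that no candidate's
representations leak across the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn


@dataclass
class NetSpec:
    """Topology description for ``build_net``.

    ``conv_layers`` is an ordered list of (kernel_size, filter_count)
    pairs, each followed by a 2x2/stride-2 max pool; for two-branch specs
    ``conv_layers_image`` describes the image branch.  All hidden
    activations are LeakyReLU; the output is a 2-way softmax head.
    """

    input_shape: tuple[int, int, int] = (40, 40, 1)
    branches: int = 1
    conv_layers: list[tuple[int, int]] = field(default_factory=lambda: [(7, 32), (5, 64)])
    conv_layers_image: list[tuple[int, int]] = field(default_factory=lambda: [(7, 64), (5, 64)])
    image_input_shape: tuple[int, int, int] = (40, 40, 1)
    fc_width: int = 1000
    leaky_alpha: float = 0.01

    def validate(self) -> None:
        if self.branches not in (1, 2):
            raise ValueError("branches must be 1 or 2")
        for shape in ([self.input_shape, self.image_input_shape][: self.branches]):
            h, w = shape[0], shape[1]
            n_pools = len(self.conv_layers)
            m = 2 ** n_pools
            if h % m or w % m or h < m or w < m:
                raise ValueError(
                    f"input {shape} cannot survive {n_pools} 2x2 pools; "
                    f"height and width must be multiples of {m} (minimum {m})")


def single_input_spec(input_shape: tuple[int, int, int] = (40, 40, 1)) -> NetSpec:
    """The single-input architecture (conv 32/64, FC 1000, softmax 2)."""
    return NetSpec(input_shape=input_shape, branches=1)


def dual_input_spec(sinogram_shape: tuple[int, int, int] = (40, 40, 16),
                    image_shape: tuple[int, int, int] = (40, 40, 1)) -> NetSpec:
    """The combined architecture: sinogram branch 32/64, image branch 64/64."""
    return NetSpec(input_shape=sinogram_shape, branches=2,
                   conv_layers=[(7, 32), (5, 64)],
                   conv_layers_image=[(7, 64), (5, 64)],
                   image_input_shape=image_shape)


def _conv_stack(conv_layers, c_in, alpha, rng) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    for k, f in conv_layers:
        layers += [nn.Conv2D(c_in, f, k, rng), nn.LeakyReLU(alpha), nn.MaxPool2()]
        c_in = f
    return layers


def build_net(spec: NetSpec, seed: int = 0):
    """Instantiate an untrained network from a spec (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w, c = spec.input_shape
    m = 2 ** len(spec.conv_layers)
    feat = (h // m) * (w // m) * spec.conv_layers[-1][1]
    if spec.branches == 1:
        layers = _conv_stack(spec.conv_layers, c, spec.leaky_alpha, rng)
        layers += [nn.Flatten(),
                   nn.Dense(feat, spec.fc_width, rng), nn.LeakyReLU(spec.leaky_alpha),
                   nn.Dense(spec.fc_width, 2, rng)]
        return nn.Sequential(layers)
    hi, wi, ci = spec.image_input_shape
    feat_img = (hi // m) * (wi // m) * spec.conv_layers_image[-1][1]
    branch_a = nn.Sequential(_conv_stack(spec.conv_layers, c, spec.leaky_alpha, rng))
    branch_b = nn.Sequential(_conv_stack(spec.conv_layers_image, ci, spec.leaky_alpha, rng))
    head = nn.Sequential([
        nn.Dense(feat + feat_img, spec.fc_width, rng), nn.LeakyReLU(spec.leaky_alpha),
        nn.Dense(spec.fc_width, 2, rng)])
    return nn.DualBranch(branch_a, branch_b, head)


@dataclass
class TrainConfig:
    """Training protocol defaults (all overridable)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 25
    batch_size: int = 30
    val_fraction: float = 0.1      # carved from the training split for early stop
    patience: int = 5
    split_fraction: float = 0.8    # ROI-level train fraction
    seed: int = 0


def split_dataset(records, fraction: float = 0.8, seed: int = 0):
    """Stratified ROI-level train/test split.

    Splitting is performed over distinct ``roi_id`` values, never over
    derived representations, so every representation of one ROI lands on
    the same side.  Deterministic per seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[str]] = {}
    label_of: dict[str, int] = {}
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.roi_id} has no label")
        if r.roi_id in label_of:
            if label_of[r.roi_id] != r.label:
                raise ValueError(f"inconsistent labels for ROI {r.roi_id}")
            continue
        label_of[r.roi_id] = r.label
        by_label.setdefault(r.label, []).append(r.roi_id)
    train_ids: set[str] = set()
    for label, ids in sorted(by_label.items()):
        if len(ids) < 2:
            raise ValueError(f"class {label} has fewer than 2 ROIs")
        ids = sorted(ids)
        rng.shuffle(ids)
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.update(ids[:n_train])
    train = [r for r in records if r.roi_id in train_ids]
    test = [r for r in records if r.roi_id not in train_ids]
    return train, test


def _as_input(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[..., None]
    if X.ndim != 4:
        raise ValueError("inputs must be (n, H, W) or (n, H, W, C)")
    return X


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Single-input CNN estimator for patches, sinograms or channel stacks.

    ``fit(X, y)`` accepts ``(n, H, W)`` or ``(n, H, W, C)`` arrays; the
    network's first-layer channel depth follows the input.  Fitted
    attributes: ``model_``, ``classes_``, ``training_log_``.
    """

    def __init__(self, learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, epochs: int = 25, batch_size: int = 30,
                 val_fraction: float = 0.1, patience: int = 5,
                 min_delta: float = 0.0, leaky_alpha: float = 0.01,
                 random_state: int = 0):
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.leaky_alpha = leaky_alpha
        self.random_state = random_state

    def _check_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        return np.searchsorted(self.classes_, y).astype(np.int64)

    def fit(self, X, y) -> "CNNClassifier":
        X = _as_input(X)
        yi = self._check_y(y)
        if len(X) != len(yi):
            raise ValueError("X and y length mismatch")
        spec = single_input_spec(input_shape=X.shape[1:])
        spec.leaky_alpha = self.leaky_alpha
        self.spec_ = spec
        self.model_ = build_net(spec, seed=self.random_state)
        self.training_log_ = nn.fit(
            self.model_, X, yi,
            epochs=self.epochs, batch_size=self.batch_size,
            lr=self.learning_rate, beta1=self.beta1, beta2=self.beta2,
            val_fraction=self.val_fraction, patience=self.patience,
            min_delta=self.min_delta, seed=self.random_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _as_input(X)
        if X.shape[1:] != self.spec_.input_shape:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match fitted {self.spec_.input_shape}")
        return nn.predict_proba(self.model_, X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (highest) class per sample."""
        return self.predict_proba(X)[:, 1]


class DualInputCNNClassifier(BaseEstimator, ClassifierMixin):
    """Combined sinogram + image CNN estimator.

    ``fit((X_sino, X_img), y)``: the first element feeds the sinogram
    branch (conv 32/64), the second the image branch (conv 64/64); the
    flattened branch outputs are concatenated into the shared FC head.
    """

    def __init__(self, learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, epochs: int = 25, batch_size: int = 30,
                 val_fraction: float = 0.1, patience: int = 5,
                 min_delta: float = 0.0, leaky_alpha: float = 0.01,
                 random_state: int = 0):
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.leaky_alpha = leaky_alpha
        self.random_state = random_state

    def fit(self, X, y) -> "DualInputCNNClassifier":
        xs, xi = (_as_input(X[0]), _as_input(X[1]))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        yi = np.searchsorted(self.classes_, y).astype(np.int64)
        if not (len(xs) == len(xi) == len(yi)):
            raise ValueError("input/label length mismatch")
        spec = dual_input_spec(sinogram_shape=xs.shape[1:], image_shape=xi.shape[1:])
        spec.leaky_alpha = self.leaky_alpha
        self.spec_ = spec
        self.model_ = build_net(spec, seed=self.random_state)
        self.training_log_ = nn.fit(
            self.model_, (xs, xi), yi,
            epochs=self.epochs, batch_size=self.batch_size,
            lr=self.learning_rate, beta1=self.beta1, beta2=self.beta2,
            val_fraction=self.val_fraction, patience=self.patience,
            min_delta=self.min_delta, seed=self.random_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        xs, xi = (_as_input(X[0]), _as_input(X[1]))
        return nn.predict_proba(self.model_, (xs, xi))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]
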