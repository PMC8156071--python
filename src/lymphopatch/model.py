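"""Compound-scaled convolutional patch classifier.

The classifier family mirrors the compound-scaling idea behind modern
efficient CNNs: one small baseline network (index phi = 0) whose depth,
width and input resolution grow jointly by fixed coefficients
``alpha**phi``, ``beta**phi`` and ``gamma**phi``. Member phi = 0 is sized
for desk-scale CPU training; higher phi trades compute for capacity in the
same controlled way larger family members would.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``predict_proba``; fitted attributes carry a trailing underscore) so it
composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from lymphopatch._nn import (
    Adam,
    Conv3x3,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    cross_entropy_grad,
    softmax,
)

#: Canonical compound-scaling coefficients (depth, width, resolution).
DEFAULT_ALPHA, DEFAULT_BETA, DEFAULT_GAMMA = 1.2, 1.1, 1.15


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ScalingSpec:
    """Compound-scaling description of one classifier-family member.

    Derived sizes: depth = round(base_depth * alpha**phi), width =
    round(base_width * beta**phi), resolution = round(base_resolution *
    gamma**phi); rounding is half away from zero.
    """

    phi: int = 0
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    base_depth: int = 2
    base_width: int = 8
    base_resolution: int = 32

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be a nonnegative integer")
        if min(self.alpha, self.beta, self.gamma) < 1:
            raise ValueError("scaling coefficients must be >= 1")

    @property
    def depth(self) -> int:
        return _round_half_up(self.base_depth * self.alpha**self.phi)

    @property
    def width(self) -> int:
        return _round_half_up(self.base_width * self.beta**self.phi)

    @property
    def resolution(self) -> int:
        return _round_half_up(self.base_resolution * self.gamma**self.phi)


class _Net:
    """Conv stem + ``depth`` conv/pool blocks + global pool + linear head."""

    def __init__(self, scaling: ScalingSpec, n_classes: int, rng: np.random.Generator):
        res, width, depth = scaling.resolution, scaling.width, scaling.depth
        if res < 32:
            raise ValueError(f"derived resolution {res} is below the minimum of 32")
        if res // 2**depth < 1:
            raise ValueError("too many pooling blocks for this resolution")
        self.scaling = scaling
        self.n_classes = n_classes
        self.layers: list = [Conv3x3(3, width, rng), ReLU()]
        for _ in range(depth):
            self.layers += [Conv3x3(width, width, rng), ReLU(), MaxPool2()]
        self.layers += [GlobalAvgPool(), Dense(width, n_classes, rng)]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params_grads(self):
        out = []
        for layer in self.layers:
            if hasattr(layer, "params_grads"):
                out.extend(layer.params_grads())
        return out

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "state"):
                out.extend(layer.state())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.state()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for w, new in zip(self.state(), weights):
            w[...] = new


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Desk-scale compound-scaled CNN for image-patch classification.

    Parameters
    ----------
    scaling : ScalingSpec, optional
        Family member to build; defaults to the phi = 0 baseline
        (depth 2, width 8, resolution 32).
    learning_rate : float
        Adam step size. The default suits the baseline member on the
        synthetic cohorts; a sweep (``lymphopatch.trainer.lr_sweep``)
        selects it per member.
    batch_size : int
        Must be a power of two.
    epochs : int
        Maximum training epochs; 0 returns the freshly initialized net.
    patience : int or None
        Early stopping: stop after this many epochs without a validation
        accuracy improvement (requires validation data). None disables.
    random_state : int
        Seeds initialization and batch shuffling; fixed seed on one thread
        reproduces training exactly.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    curves_ : DataFrame with per-epoch ``train_accuracy``,
        ``val_accuracy`` and ``overfit_gap`` (train minus validation).
    best_epoch_ : int or None — epoch (1-based) of peak validation
        accuracy; the fitted weights are that epoch's checkpoint.
    n_params_ : trainable parameter count.
    """

    def __init__(
        self,
        scaling: ScalingSpec | None = None,
        learning_rate: float = 3e-3,
        batch_size: int = 32,
        epochs: int = 30,
        patience: int | None = None,
        random_state: int = 0,
    ):
        self.scaling = scaling
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _scaling(self) -> ScalingSpec:
        return self.scaling if self.scaling is not None else ScalingSpec()

    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(
                f"expected (n, H, W, 3) RGB patches, got shape {X.shape}"
            )
        return X

    def _prep(self, X: np.ndarray) -> np.ndarray:
        """Resize to the model resolution (bilinear) and center to ~[-0.5, 0.5]."""
        X = self._validate_images(X)
        res = self._scaling().resolution
        if X.shape[1] != res or X.shape[2] != res:
            X = np.stack(
                [
                    _sk_resize(img, (res, res), order=1, preserve_range=True,
                               anti_aliasing=False)
                    for img in X
                ]
            )
        X = X.astype(np.float64)
        if X.max() > 1.5:  # 8-bit input
            X = X / 255.0
        return X - 0.5

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        bs = self.batch_size
        if bs < 1 or (bs & (bs - 1)) != 0:
            raise ValueError(f"batch_size must be a power of two, got {bs}")
        y = np.asarray(y)
        if len(y) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        rng = np.random.default_rng(self.random_state)
        self.net_ = _Net(self._scaling(), n_classes, rng)
        self.n_params_ = self.net_.n_params

        Xp = self._prep(X)
        have_val = X_val is not None and y_val is not None
        if have_val:
            Xv = self._prep(X_val)
            yv = np.asarray(y_val)

        onehot = np.eye(n_classes)[y_idx]
        opt = Adam(self.learning_rate)
        rows = []
        best_acc, best_weights, best_epoch, since_best = -np.inf, None, None, 0
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(len(Xp))
            correct = 0
            for start in range(0, len(order), bs):
                sel = order[start : start + bs]
                logits = self.net_.forward(Xp[sel], train=True)
                correct += int((logits.argmax(axis=1) == y_idx[sel]).sum())
                _, dlogits = cross_entropy_grad(logits, onehot[sel])
                self.net_.backward(dlogits)
                opt.step(self.net_.params_grads())
            train_acc = correct / len(order)
            if have_val:
                val_acc = float(
                    (self._predict_idx(Xv) == np.searchsorted(self.classes_, yv)).mean()
                )
            else:
                val_acc = np.nan
            rows.append(
                {
                    "epoch": epoch,
                    "train_accuracy": train_acc,
                    "val_accuracy": val_acc,
                    "overfit_gap": train_acc - val_acc,
                }
            )
            if have_val and val_acc > best_acc:
                best_acc, best_epoch, since_best = val_acc, epoch, 0
                best_weights = self.net_.get_weights()
            else:
                since_best += 1
            if self.patience is not None and have_val and since_best >= self.patience:
                break
        if best_weights is not None:
            self.net_.set_weights(best_weights)
        self.best_epoch_ = best_epoch
        self.best_val_accuracy_ = best_acc if have_val else None
        self.curves_ = pd.DataFrame(
            rows, columns=["epoch", "train_accuracy", "val_accuracy", "overfit_gap"]
        )
        return self

    def _predict_idx(self, Xp: np.ndarray, chunk: int = 256) -> np.ndarray:
        return np.concatenate(
            [
                self.net_.forward(Xp[i : i + chunk]).argmax(axis=1)
                for i in range(0, len(Xp), chunk)
            ]
        )

    def predict_proba(self, X, chunk: int = 256) -> np.ndarray:
        check_is_fitted(self, "net_")
        Xp = self._prep(X)
        logits = np.concatenate(
            [self.net_.forward(Xp[i : i + chunk]) for i in range(0, len(Xp), chunk)]
        )
        return softmax(logits)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.classes_[self._predict_idx(self._prep(X))]

    # -- saliency hook ---------------------------------------------------

    def class_score_gradient(self, patch: np.ndarray, target_index: int) -> np.ndarray:
        """Gradient of the target class's logit w.r.t. the input pixels.

        ``patch`` must already be at the model resolution, shape
        (res, res, 3); the returned gradient has the same shape.
        """
        check_is_fitted(self, "net_")
        patch = np.asarray(patch)
        res = self._scaling().resolution
        if patch.shape != (res, res, 3):
            raise ValueError(
                f"patch must have shape ({res}, {res}, 3), got {patch.shape}"
            )
        scale = 1.0 / 255.0 if patch.max() > 1.5 else 1.0
        x = patch.astype(np.float64)[None] * scale - 0.5
        logits = self.net_.forward(x, train=True)
        d = np.zeros_like(logits)
        d[0, int(target_index)] = 1.0
        return self.net_.backward(d)[0] * scale

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint weights + configuration to an .npz file."""
        check_is_fitted(self, "net_")
        meta = {
            "scaling": asdict(self._scaling()),
            "classes": [str(c) for c in self.classes_],
            "params": {
                k: v
                for k, v in self.get_params().items()
                if k != "scaling"
            },
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.net_.state())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNNClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        est = cls(scaling=ScalingSpec(**meta["scaling"]), **meta["params"])
        est.classes_ = np.asarray(meta["classes"])
        rng = np.random.default_rng(0)
        est.net_ = _Net(est._scaling(), len(est.classes_), rng)
        est.net_.set_weights([data[f"w{i}"] for i in range(len(est.net_.state()))])
        est.n_params_ = est.net_.n_params
        est.curves_ = pd.DataFrame(
            columns=["epoch", "train_accuracy", "val_accuracy", "overfit_gap"]
        )
        est.best_epoch_ = None
        return est


def build_model(
    scaling: ScalingSpec, n_classes: int, seed: int = 0
) -> PatchCNNClassifier:
    """Instantiate an untrained family member with initialized weights.

    The returned estimator is usable for forward passes immediately
    (``net_`` is set); calling :meth:`~PatchCNNClassifier.fit` re-trains
    it. Parameter count strictly increases with ``scaling.phi``.
    """
    est = PatchCNNClassifier(scaling=scaling, random_state=seed)
    est.classes_ = np.arange(n_classes)
    est.net_ = _Net(scaling, n_classes, np.random.default_rng(seed))
    est.n_params_ = est.net_.n_params
    est.curves_ = pd.DataFrame(
        columns=["epoch", "train_accuracy", "val_accuracy", "overfit_gap"]
    )
    est.best_epoch_ = None
    return est
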