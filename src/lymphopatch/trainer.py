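"""Training protocol: learning-rate screening, training, model selection.

The protocol mirrors standard practice for compound-scaled families:
candidate learning rates are screened for a fixed number of epochs from
identical initializations, the best-performing rate is kept, the model is
trained further with early stopping on validation accuracy, and family
members are compared by best validation accuracy (ties within 0.25
percentage points broken by validation BACC, then by the smaller family
index). Training refuses to start if any case appears in more than one
subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lymphopatch import cohort as cohort_mod
from lymphopatch import qcagg
from lymphopatch.model import PatchCNNClassifier, ScalingSpec

logger = logging.getLogger(__name__)

#: Validation-accuracy margin (fraction) treated as a tie in select_model.
SELECTION_TIE_MARGIN = 0.0025


@dataclass
class PatchDataset:
    """In-memory patch set: images, labels, and case identity per patch."""

    X: np.ndarray  # (n, H, W, 3)
    y: np.ndarray  # (n,) class labels
    case_ids: np.ndarray  # (n,)
    patch_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.patch_ids is None:
            self.patch_ids = np.asarray([f"patch_{i:06d}" for i in range(len(self.y))])

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class TrainConfig:
    scaling: ScalingSpec = field(default_factory=ScalingSpec)
    learning_rate: float = 3e-3
    batch_size: int = 32
    epochs: int = 30
    patience: int | None = 10
    seed: int = 0


def _check_no_leak(train_set: PatchDataset, val_set: PatchDataset) -> None:
    cases = pd.DataFrame(
        {
            "case_id": np.concatenate([np.unique(train_set.case_ids),
                                       np.unique(val_set.case_ids)]),
            "subset": ["TRAIN"] * len(np.unique(train_set.case_ids))
            + ["VAL"] * len(np.unique(val_set.case_ids)),
        }
    )
    patches = pd.DataFrame(
        {
            "case_id": np.concatenate([train_set.case_ids, val_set.case_ids]),
            "subset": ["TRAIN"] * len(train_set) + ["VAL"] * len(val_set),
        }
    )
    dup = cases[cases["case_id"].duplicated(keep=False)]
    violations = sorted(dup["case_id"].unique())
    if not violations:
        violations = [
            v for v in cohort_mod.assert_single_subset(patches, cases)
        ]
    if violations:
        raise ValueError(f"case leak between train and validation: {violations}")


def train(
    train_set: PatchDataset,
    val_set: PatchDataset,
    config: TrainConfig,
) -> tuple[PatchCNNClassifier, pd.DataFrame, dict]:
    """Fit one family member; returns (estimator, curves, checkpoint info).

    The estimator's weights are restored to the epoch with the highest
    validation accuracy; ``checkpoint`` records that epoch and accuracy.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    _check_no_leak(train_set, val_set)
    est = PatchCNNClassifier(
        scaling=config.scaling,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        patience=config.patience,
        random_state=config.seed,
    )
    est.fit(train_set.X, train_set.y, X_val=val_set.X, y_val=val_set.y)
    checkpoint = {
        "best_epoch": est.best_epoch_,
        "best_val_accuracy": est.best_val_accuracy_,
    }
    return est, est.curves_, checkpoint


def lr_sweep(
    train_set: PatchDataset,
    val_set: PatchDataset,
    scaling: ScalingSpec,
    candidate_lrs,
    screen_epochs: int = 50,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[dict, float]:
    """Screen candidate learning rates for ``screen_epochs`` epochs each.

    Every candidate trains from the same seed (hence identical
    initialization). The chosen rate maximizes the best validation
    accuracy reached during screening; exact ties go to the smaller rate.
    Returns ({lr: curves}, chosen_lr).
    """
    candidate_lrs = list(candidate_lrs)
    if len(candidate_lrs) < 2:
        raise ValueError("need at least 2 candidate learning rates")
    if len(train_set) == 0:
        raise ValueError("empty training set")
    curves_by_lr: dict[float, pd.DataFrame] = {}
    best_by_lr: dict[float, float] = {}
    for lr in candidate_lrs:
        cfg = TrainConfig(
            scaling=scaling, learning_rate=lr, batch_size=batch_size,
            epochs=screen_epochs, patience=None, seed=seed,
        )
        _, curves, ckpt = train(train_set, val_set, cfg)
        curves_by_lr[lr] = curves
        best_by_lr[lr] = ckpt["best_val_accuracy"]
        logger.info("lr sweep: lr=%g best val acc=%.4f", lr, best_by_lr[lr])
    chosen = min(candidate_lrs, key=lambda lr: (-best_by_lr[lr], lr))
    return curves_by_lr, chosen


def choose_lr_from_curves(curves_by_lr: dict[float, pd.DataFrame]) -> float:
    """Chosen rate from recorded screening curves (argmax of best val acc,
    ties to the smaller rate)."""
    best = {lr: c["val_accuracy"].max() for lr, c in curves_by_lr.items()}
    return min(best, key=lambda lr: (-best[lr], lr))


def select_model(
    candidates: list[tuple[ScalingSpec, pd.DataFrame, PatchCNNClassifier]],
    val_set: PatchDataset | None = None,
    class_map: qcagg.ClassMap | None = None,
) -> PatchCNNClassifier:
    """Pick the best family member from trained candidates.

    Primary key: best validation accuracy from the curves. Candidates
    within 0.25 percentage points of the leader are re-compared by
    validation BACC (case-agnostic, patch level, via the QC module) when a
    validation set is given; remaining ties go to the smaller phi.
    """
    if not candidates:
        raise ValueError("no candidates")
    accs = [float(c[1]["val_accuracy"].max()) for c in candidates]
    leader = max(accs)
    tied_idx = [i for i, a in enumerate(accs) if leader - a <= SELECTION_TIE_MARGIN]
    if len(tied_idx) == 1 or val_set is None:
        best = min(tied_idx, key=lambda i: (-accs[i], candidates[i][0].phi))
        return candidates[best][2]
    baccs = {}
    for i in tied_idx:
        est = candidates[i][2]
        records = predict(est, val_set)
        cm = class_map or qcagg.ClassMap.identity(est.classes_)
        result = qcagg.patch_level_eval(records, class_map=cm)
        baccs[i] = result.bacc if result.bacc is not None else -1.0
    best = min(tied_idx, key=lambda i: (-baccs[i], candidates[i][0].phi))
    return candidates[best][2]


def predict(est: PatchCNNClassifier, patches: PatchDataset) -> pd.DataFrame:
    """Per-patch probability table in the shared prediction schema.

    Columns: patch_id, case_id, true_class, and one ``p_<class>`` per
    training class; rows sum to 1.
    """
    probs = est.predict_proba(patches.X)
    out = pd.DataFrame(
        {
            "patch_id": patches.patch_ids,
            "case_id": patches.case_ids,
            "true_class": patches.y,
        }
    )
    for j, c in enumerate(est.classes_):
        out[f"p_{c}"] = probs[:, j]
    return out
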