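"""Two-level quality control, majority voting and balanced accuracy.

Patch-level predictions become case-level diagnoses in four steps:

1. **Class aggregation** — training-class probabilities are mapped onto the
   evaluation vocabulary; by default the three organ-specific reference
   lymph-node classes (lung, colon, pancreas) collapse into one
   "tumor-free reference LN" class by summing their probabilities.
2. **PQC** (patch quality control) — a patch whose maximum aggregated
   probability is *less than* the threshold is discarded.
3. **Majority vote + CQC** (case quality control) — each case takes the
   modal predicted class of its surviving patches; if no patch survives,
   or the winning vote fraction is *less than* the CQC threshold, the case
   is left UNCLASSIFIED and flagged for human review.
4. **Balanced accuracy (BACC)** — the mean of per-class recalls over the
   classified items, robust to class imbalance.

``qc_grid`` sweeps PQC × CQC threshold pairs and reports, per cell, the
BACC (%), the percentage of patches failing PQC, and the percentage of
cases failing CQC (zero-survivor cases count toward the CQC column, as the
PQC column is patch-denominated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

#: Evaluation label for the pooled organ-specific control classes.
TUMOR_FREE = "TUMOR_FREE_LN"

DEFAULT_CLASS_MAP = {
    "SLL_CLL": "SLL_CLL",
    "DLBCL": "DLBCL",
    "LN_LUNG": TUMOR_FREE,
    "LN_COLON": TUMOR_FREE,
    "LN_PANCREAS": TUMOR_FREE,
}

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ClassMap:
    """Total, surjective mapping from training to evaluation classes."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    @property
    def eval_classes(self) -> list[str]:
        seen: list[str] = []
        for v in self.mapping.values():
            if v not in seen:
                seen.append(v)
        return seen

    def require_total(self, train_classes) -> None:
        missing = [c for c in train_classes if c not in self.mapping]
        if missing:
            raise KeyError(f"class map does not cover: {missing}")

    @classmethod
    def identity(cls, classes) -> "ClassMap":
        return cls({c: c for c in classes})


@dataclass(frozen=True)
class QCConfig:
    pqc_threshold: float = 0.0
    cqc_threshold: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pqc_threshold", "cqc_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class CaseDecision:
    case_id: str
    true_eval_class: str
    predicted_eval_class: str  # or UNCLASSIFIED
    vote_fraction: float | None
    n_surviving_patches: int
    n_total_patches: int


def _prob_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("p_")]


def aggregate_probs(records: pd.DataFrame, class_map: ClassMap) -> pd.DataFrame:
    """Map per-patch training-class probabilities to evaluation classes.

    Input columns: identity fields plus one ``p_<train class>`` per
    training class. Output replaces them with one ``p_<eval class>``
    column per evaluation class (probabilities summed within each group)
    and rewrites ``true_class`` through the map. Row sums are preserved.
    """
    prob_cols = _prob_columns(records)
    train_classes = [c[2:] for c in prob_cols]
    class_map.require_total(train_classes)
    id_cols = [c for c in records.columns if not c.startswith("p_")]
    out = records[id_cols].copy()
    if "true_class" in out:
        out["true_class"] = out["true_class"].map(class_map.mapping)
    for ev in class_map.eval_classes:
        members = [f"p_{t}" for t in train_classes if class_map.mapping[t] == ev]
        out[f"p_{ev}"] = records[members].sum(axis=1) if members else 0.0
    return out


def apply_pqc(records: pd.DataFrame, pqc_threshold: float) -> tuple[pd.DataFrame, float]:
    """Filter out low-confidence patches.

    A patch survives iff its maximum class probability is >= the threshold
    (a strictly smaller maximum fails). Returns the surviving records and
    the percentage of all input patches that did not meet the threshold.
    """
    if not (0 <= pqc_threshold <= 1):
        raise ValueError(f"pqc_threshold must lie in [0, 1], got {pqc_threshold}")
    if len(records) == 0:
        return records.copy(), 0.0
    max_prob = records[_prob_columns(records)].to_numpy().max(axis=1)
    keep = max_prob >= pqc_threshold
    pct_not_met = 100.0 * (1.0 - keep.mean())
    return records.loc[keep].copy(), float(pct_not_met)


def _argmax_class(records: pd.DataFrame) -> np.ndarray:
    prob_cols = _prob_columns(records)
    idx = records[prob_cols].to_numpy().argmax(axis=1)
    classes = np.asarray([c[2:] for c in prob_cols])
    return classes[idx]


def vote_case(
    case_records: pd.DataFrame,
    cqc_threshold: float,
    n_total_patches: int | None = None,
    cqc_denominator: str = "survivors",
) -> CaseDecision:
    """Majority-vote one case's surviving patches into a case decision.

    The predicted class is the modal patch-level argmax; ties go to the
    class with the higher summed probability, then to probability-column
    order. The case is UNCLASSIFIED when no patch survived or the vote
    fraction is strictly below ``cqc_threshold``. ``cqc_denominator``
    selects whether the fraction is over PQC survivors (default) or over
    all of the case's patches (``n_total_patches`` must then be given).
    """
    case_ids = case_records["case_id"].unique() if len(case_records) else []
    if len(case_ids) > 1:
        raise ValueError(f"vote_case received mixed case ids: {sorted(case_ids)}")
    n_surv = len(case_records)
    n_total = n_total_patches if n_total_patches is not None else n_surv
    if n_surv == 0:
        return CaseDecision("?", "?", UNCLASSIFIED, None, 0, n_total)
    case_id = case_records["case_id"].iloc[0]
    true_class = case_records["true_class"].iloc[0]
    prob_cols = _prob_columns(case_records)
    classes = [c[2:] for c in prob_cols]
    votes = _argmax_class(case_records)
    counts = {c: int((votes == c).sum()) for c in classes}
    best_n = max(counts.values())
    tied = [c for c in classes if counts[c] == best_n]
    if len(tied) > 1:
        sums = case_records[[f"p_{c}" for c in tied]].sum(axis=0)
        best_sum = sums.max()
        tied = [c for c in tied if sums[f"p_{c}"] == best_sum]
    predicted = tied[0]  # fixed class order breaks any remaining tie
    denom = n_total if cqc_denominator == "all" else n_surv
    vote_fraction = counts[predicted] / denom
    if vote_fraction < cqc_threshold:
        return CaseDecision(case_id, true_class, UNCLASSIFIED, vote_fraction,
                            n_surv, n_total)
    return CaseDecision(case_id, true_class, predicted, vote_fraction,
                        n_surv, n_total)


@dataclass
class ConfusionResult:
    classes: list[str]
    counts: np.ndarray  # (K, K), rows = true
    normalized: np.ndarray  # row-normalized; zero rows stay zero
    bacc: float | None  # None when nothing was classified
    n_excluded: int  # UNCLASSIFIED items left out


def confusion_and_bacc(
    true_labels,
    predicted_labels,
    class_order=None,
) -> ConfusionResult:
    """Confusion matrix and balanced accuracy over classified items.

    UNCLASSIFIED predictions are excluded. BACC is the unweighted mean of
    per-class recall over classes with at least one classified true item;
    classes absent from the (classified) truth are dropped from the mean
    with a warning. Works identically for patch- and case-level input.
    """
    true_labels = np.asarray(list(true_labels), dtype=object)
    predicted_labels = np.asarray(list(predicted_labels), dtype=object)
    keep = predicted_labels != UNCLASSIFIED
    n_excluded = int((~keep).sum())
    t, p = true_labels[keep], predicted_labels[keep]
    if class_order is None:
        class_order = sorted(set(t) | set(p))
    class_order = list(class_order)
    if len(t) == 0:
        logger.warning("confusion_and_bacc: no classified items")
        k = len(class_order)
        return ConfusionResult(class_order, np.zeros((k, k), dtype=int),
                               np.zeros((k, k)), None, n_excluded)
    counts = _sk_confusion(t, p, labels=class_order)
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(
        counts, row_sums, out=np.zeros(counts.shape, dtype=float),
        where=row_sums > 0,
    )
    present = row_sums[:, 0] > 0
    if not present.all():
        absent = [c for c, ok in zip(class_order, present) if not ok]
        logger.warning("classes with no classified true items dropped from BACC: %s",
                       absent)
    recalls = normalized[np.arange(len(class_order)), np.arange(len(class_order))]
    bacc = float(recalls[present].mean())
    return ConfusionResult(class_order, counts, normalized, bacc, n_excluded)


def evaluate_cases(
    records: pd.DataFrame,
    config: QCConfig,
    class_order=None,
    cqc_denominator: str = "survivors",
) -> tuple[list[CaseDecision], ConfusionResult, float, float]:
    """Full patch→case evaluation at one (PQC, CQC) threshold pair.

    ``records`` must already carry evaluation-class probabilities (see
    :func:`aggregate_probs`). Returns (case decisions, case-level
    confusion/BACC, pqc_not_met %, cqc_not_met %); ``cqc_not_met`` counts
    UNCLASSIFIED cases, including those losing all patches to PQC.
    """
    totals = records.groupby("case_id", sort=True).size()
    true_by_case = records.groupby("case_id", sort=True)["true_class"].first()
    surviving, pqc_not_met = apply_pqc(records, config.pqc_threshold)
    decisions: list[CaseDecision] = []
    for case_id in totals.index:
        case_recs = surviving[surviving["case_id"] == case_id]
        dec = vote_case(case_recs, config.cqc_threshold,
                        n_total_patches=int(totals[case_id]),
                        cqc_denominator=cqc_denominator)
        if dec.case_id == "?":
            dec.case_id = case_id
            dec.true_eval_class = true_by_case[case_id]
        decisions.append(dec)
    result = confusion_and_bacc(
        [d.true_eval_class for d in decisions],
        [d.predicted_eval_class for d in decisions],
        class_order=class_order,
    )
    cqc_not_met = 100.0 * np.mean(
        [d.predicted_eval_class == UNCLASSIFIED for d in decisions]
    )
    return decisions, result, pqc_not_met, float(cqc_not_met)


def qc_grid(
    records: pd.DataFrame,
    pqc_thresholds=DEFAULT_THRESHOLDS,
    cqc_thresholds=DEFAULT_THRESHOLDS,
    class_map: ClassMap | None = None,
    cqc_denominator: str = "survivors",
) -> pd.DataFrame:
    """Sweep the (PQC, CQC) threshold grid.

    ``records`` carry training-class probabilities; they are aggregated
    through ``class_map`` (default: pool the reference-LN organs) before
    any thresholding. Returns a tidy DataFrame with one row per threshold
    pair: pqc, cqc, bacc_percent, pqc_not_met_percent, cqc_not_met_percent.
    """
    if len(list(pqc_thresholds)) == 0 or len(list(cqc_thresholds)) == 0:
        raise ValueError("threshold lists must be non-empty")
    if class_map is None:
        class_map = ClassMap()
    agg = aggregate_probs(records, class_map)
    class_order = class_map.eval_classes
    rows = []
    for pqc in pqc_thresholds:
        for cqc in cqc_thresholds:
            _, result, pqc_pct, cqc_pct = evaluate_cases(
                agg, QCConfig(pqc, cqc), class_order=class_order,
                cqc_denominator=cqc_denominator,
            )
            rows.append(
                {
                    "pqc": pqc,
                    "cqc": cqc,
                    "bacc_percent": (
                        100.0 * result.bacc if result.bacc is not None else np.nan
                    ),
                    "pqc_not_met_percent": pqc_pct,
                    "cqc_not_met_percent": cqc_pct,
                }
            )
    return pd.DataFrame(rows)


def grid_to_wide(grid: pd.DataFrame, value: str = "bacc_percent") -> pd.DataFrame:
    """Pivot the tidy grid into the familiar PQC-rows × CQC-columns table."""
    wide = grid.pivot(index="pqc", columns="cqc", values=value)
    return wide.round(2)


def patch_level_eval(
    records: pd.DataFrame,
    class_map: ClassMap | None = None,
    pqc_threshold: float = 0.0,
) -> ConfusionResult:
    """Patch-level confusion matrix + BACC (shares the case-level code path)."""
    if class_map is None:
        class_map = ClassMap()
    agg = aggregate_probs(records, class_map)
    surviving, _ = apply_pqc(agg, pqc_threshold)
    return confusion_and_bacc(
        surviving["true_class"],
        _argmax_class(surviving),
        class_order=class_map.eval_classes,
    )
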