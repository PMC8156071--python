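"""Patient-level subset assignment and cohort summaries.

Cases (patients) are split into training / validation / test subsets at the
patient level — every patch of a case inherits the case's subset, so no
patient's tissue can leak across subsets. The split is reproducible
(seeded, independent of input row order), stratified by class by default,
and apportions non-divisible counts by the largest-remainder rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSETS = ("TRAIN", "VAL", "TEST")


@dataclass(frozen=True)
class SplitConfig:
    """Subset fractions (train, val, test), stratification, seed."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratify_by_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ValueError("each fraction must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1, got {sum(self.fractions)!r}"
            )


def largest_remainder(n: int, fractions) -> list[int]:
    """Apportion ``n`` items to parts by the largest-remainder rule.

    Floors the exact quotas, then hands the leftover items to the parts
    with the largest fractional remainders (ties to the earlier part).
    """
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:leftover]:
        counts[i] += 1
    return counts


def split_cases(cohort: pd.DataFrame, config: SplitConfig) -> pd.DataFrame:
    """Assign every case to exactly one of TRAIN/VAL/TEST.

    ``cohort`` needs columns ``case_id`` and ``class`` (class used only
    when stratifying). Returns a copy with a ``subset`` column. Assignment
    shuffles the sorted case ids with the seed, so it does not depend on
    the input row order.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 cases to form three subsets")
    if cohort["case_id"].duplicated().any():
        raise ValueError("case_id values must be unique")
    rng = np.random.default_rng(config.seed)
    out = cohort.copy()
    out["subset"] = "UNASSIGNED"

    def assign(ids: list[str]) -> dict[str, str]:
        ids = sorted(ids)
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        counts = largest_remainder(len(ids), config.fractions)
        mapping = {}
        pos = 0
        for subset, c in zip(SUBSETS, counts):
            for cid in shuffled[pos : pos + c]:
                mapping[cid] = subset
            pos += c
        return mapping

    if config.stratify_by_class:
        mapping = {}
        for _, grp in out.groupby("class", sort=True):
            mapping.update(assign(grp["case_id"].tolist()))
    else:
        mapping = assign(out["case_id"].tolist())
    out["subset"] = out["case_id"].map(mapping)
    return out


def assert_single_subset(patch_index: pd.DataFrame, cohort: pd.DataFrame) -> list[str]:
    """Leak checkpoint: no case's patches may span more than one subset.

    ``patch_index`` needs ``case_id`` and ``subset`` columns; ``cohort``
    needs ``case_id`` and ``subset``. Returns a list of violation messages
    (empty means the partition is clean). A patch with a case id unknown to
    the cohort is itself a violation.
    """
    violations: list[str] = []
    cohort_subset = dict(zip(cohort["case_id"], cohort["subset"]))
    for case_id, grp in patch_index.groupby("case_id", sort=True):
        subsets = set(grp["subset"])
        if case_id not in cohort_subset:
            violations.append(f"case {case_id}: unknown to cohort table")
            continue
        if len(subsets) > 1:
            violations.append(
                f"case {case_id}: patches span subsets {sorted(subsets)}"
            )
        elif subsets != {cohort_subset[case_id]}:
            violations.append(
                f"case {case_id}: patch subset {sorted(subsets)} != "
                f"cohort subset {cohort_subset[case_id]}"
            )
    return violations


def summarize_subsets(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per (class × subset) statistics of per-case patch counts.

    ``cohort`` needs ``case_id``, ``class``, ``n_patches`` and ``subset``.
    Returns one row per class × subset with case count, patch total,
    min/max/mean/median of per-case counts; empty strata get a zero row
    with ``empty=True``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    classes = sorted(cohort["class"].unique())
    subsets = [s for s in SUBSETS if s in set(cohort["subset"])] or sorted(
        cohort["subset"].unique()
    )
    for subset in subsets:
        for cls in classes:
            grp = cohort[(cohort["class"] == cls) & (cohort["subset"] == subset)]
            if len(grp) == 0:
                logger.warning("empty stratum: class=%s subset=%s", cls, subset)
                rows.append(
                    dict(subset=subset, **{"class": cls}, n_cases=0, n_patches=0,
                         min=0, max=0, mean=0.0, median=0.0, empty=True)
                )
                continue
            counts = grp["n_patches"].to_numpy()
            rows.append(
                dict(
                    subset=subset,
                    **{"class": cls},
                    n_cases=len(grp),
                    n_patches=int(counts.sum()),
                    min=int(counts.min()),
                    max=int(counts.max()),
                    mean=round(float(counts.mean()), 1),
                    median=float(np.median(counts)),
                    empty=False,
                )
            )
    return pd.DataFrame(rows)
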