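"""Independent brute-force oracle for the QC/vote/BACC chain.

Deliberately written with plain Python loops and dicts — no pandas, no
vectorization, no code shared with the package — so it can serve as an
independent cross-check of the qcagg module.
"""

from __future__ import annotations

UNCLASSIFIED = "UNCLASSIFIED"


def oracle_aggregate(prob_row: dict, mapping: dict) -> dict:
    """Sum training-class probabilities into evaluation classes."""
    out: dict = {}
    for train_cls, p in prob_row.items():
        ev = mapping[train_cls]
        out[ev] = out.get(ev, 0.0) + p
    return out


def oracle_eval_cell(
    patches: list[dict],
    mapping: dict,
    eval_classes: list[str],
    pqc: float,
    cqc: float,
):
    """One (PQC, CQC) grid cell, recomputed from scratch.

    ``patches``: list of {"case_id", "true_class", "probs": {train_cls: p}}.
    Returns (bacc_percent, pqc_not_met_percent, cqc_not_met_percent).
    """
    # aggregate and PQC-filter patch by patch
    n_total = len(patches)
    n_rejected = 0
    by_case: dict = {}
    true_of_case: dict = {}
    for patch in patches:
        agg = oracle_aggregate(patch["probs"], mapping)
        case = patch["case_id"]
        true_of_case[case] = mapping[patch["true_class"]]
        by_case.setdefault(case, [])
        max_p = max(agg.values())
        if max_p < pqc:
            n_rejected += 1
            continue
        by_case[case].append(agg)
    pqc_not_met = 100.0 * n_rejected / n_total if n_total else 0.0

    # majority vote per case with the stated tie-breaks
    decisions: dict = {}
    n_unclassified = 0
    for case, survivors in by_case.items():
        if len(survivors) == 0:
            decisions[case] = UNCLASSIFIED
            n_unclassified += 1
            continue
        counts = {c: 0 for c in eval_classes}
        sums = {c: 0.0 for c in eval_classes}
        for agg in survivors:
            best_c, best_p = None, -1.0
            for c in eval_classes:
                if agg[c] > best_p:
                    best_c, best_p = c, agg[c]
            counts[best_c] += 1
            for c in eval_classes:
                sums[c] += agg[c]
        top = max(counts.values())
        tied = [c for c in eval_classes if counts[c] == top]
        if len(tied) > 1:
            best_sum = max(sums[c] for c in tied)
            tied = [c for c in tied if sums[c] == best_sum]
        predicted = tied[0]
        fraction = counts[predicted] / len(survivors)
        if fraction < cqc:
            decisions[case] = UNCLASSIFIED
            n_unclassified += 1
        else:
            decisions[case] = predicted
    cqc_not_met = 100.0 * n_unclassified / len(by_case) if by_case else 0.0

    # balanced accuracy over the classified cases
    per_class_hits: dict = {}
    per_class_total: dict = {}
    for case, predicted in decisions.items():
        if predicted == UNCLASSIFIED:
            continue
        truth = true_of_case[case]
        per_class_total[truth] = per_class_total.get(truth, 0) + 1
        if predicted == truth:
            per_class_hits[truth] = per_class_hits.get(truth, 0) + 1
    if not per_class_total:
        return None, pqc_not_met, cqc_not_met
    recalls = [
        per_class_hits.get(c, 0) / per_class_total[c] for c in sorted(per_class_total)
    ]
    bacc = 100.0 * sum(recalls) / len(recalls)
    return bacc, pqc_not_met, cqc_not_met


def records_frame_to_patches(records) -> list[dict]:
    """Convert the shared prediction-table schema into oracle input."""
    prob_cols = [c for c in records.columns if c.startswith("p_")]
    patches = []
    for row in records.itertuples(index=False):
        row_d = row._asdict()
        patches.append(
            {
                "case_id": row_d["case_id"],
                "true_class": row_d["true_class"],
                "probs": {c[2:]: row_d[c] for c in prob_cols},
            }
        )
    return patches
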