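"""Class aggregation, PQC/CQC filtering, majority voting, balanced accuracy,
and the threshold grid — cross-checked against an independent brute-force
oracle."""

import numpy as np
import pandas as pd
import pytest

from lymphopatch import qcagg, synthdata
from lymphopatch.qcagg import (
    UNCLASSIFIED,
    ClassMap,
    QCConfig,
    aggregate_probs,
    apply_pqc,
    confusion_and_bacc,
    evaluate_cases,
    qc_grid,
    vote_case,
)
from qc_oracle import oracle_eval_cell, records_frame_to_patches


def make_records(rows, classes):
    """rows: list of (patch_id, case_id, true_class, probs)."""
    data = []
    for pid, cid, tc, probs in rows:
        row = {"patch_id": pid, "case_id": cid, "true_class": tc}
        row.update({f"p_{c}": p for c, p in zip(classes, probs)})
        data.append(row)
    return pd.DataFrame(data)


FIVE = list(synthdata.CLASS_LIST)


def fixture_records(seed, n_cases=100, patches=(10, 250), accuracy=0.8, boost=2.0):
    rows = []
    per_class = n_cases // len(FIVE)
    for cls in FIVE:
        for k in range(per_class):
            rows.append({"case_id": f"{cls}_{k:02d}", "class": cls})
    manifest = pd.DataFrame(rows)
    return synthdata.generate_prediction_fixture(
        manifest, patches,
        synthdata.PredictionFixtureConfig(
            patch_accuracy=accuracy, confidence_correct_boost=boost, seed=seed,
        ),
    )


class TestAggregateProbs:
    def test_reference_ln_probabilities_sum(self):
        rec = make_records(
            [("p0", "c0", "LN_LUNG", (0.2, 0.3, 0.2, 0.2, 0.1))], FIVE
        )
        agg = aggregate_probs(rec, ClassMap())
        assert agg.loc[0, "p_SLL_CLL"] == pytest.approx(0.2)
        assert agg.loc[0, "p_DLBCL"] == pytest.approx(0.3)
        assert agg.loc[0, f"p_{qcagg.TUMOR_FREE}"] == pytest.approx(0.5)
        assert agg.loc[0, "true_class"] == qcagg.TUMOR_FREE

    def test_identity_map_is_noop(self):
        rec = make_records([("p0", "c0", "DLBCL", (0.1, 0.5, 0.2, 0.1, 0.1))], FIVE)
        agg = aggregate_probs(rec, ClassMap.identity(FIVE))
        for c, p in zip(FIVE, (0.1, 0.5, 0.2, 0.1, 0.1)):
            assert agg.loc[0, f"p_{c}"] == p

    def test_sums_preserved_on_random_simplex(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(5), size=1000)
        rec = make_records(
            [(f"p{i}", "c0", "DLBCL", probs[i]) for i in range(1000)], FIVE
        )
        agg = aggregate_probs(rec, ClassMap())
        cols = [c for c in agg.columns if c.startswith("p_")]
        assert np.allclose(agg[cols].sum(axis=1), 1.0, atol=1e-9)

    def test_unmapped_class_is_configuration_error(self):
        rec = make_records([("p0", "c0", "DLBCL", (0.5, 0.5))], ["DLBCL", "OTHER"])
        with pytest.raises(KeyError):
            aggregate_probs(rec, ClassMap({"DLBCL": "DLBCL"}))


class TestApplyPqc:
    def test_strict_less_than_fails(self):
        rec = make_records(
            [
                ("p0", "c0", "A", (0.34, 0.33, 0.33)),
                ("p1", "c0", "A", (0.60, 0.20, 0.20)),
                ("p2", "c0", "A", (0.45, 0.30, 0.25)),
            ],
            ["A", "B", "C"],
        )
        surviving, pct = apply_pqc(rec, 0.5)
        assert len(surviving) == 1
        assert pct == pytest.approx(66.67, abs=0.01)

    def test_threshold_zero_keeps_everything(self):
        rec = fixture_records(seed=1, n_cases=10, patches=20)
        surviving, pct = apply_pqc(rec, 0.0)
        assert len(surviving) == len(rec) and pct == 0.0

    def test_exact_threshold_survives(self):
        rec = make_records([("p0", "c0", "A", (0.5, 0.5))], ["A", "B"])
        surviving, _ = apply_pqc(rec, 0.5)
        assert len(surviving) == 1

    def test_threshold_out_of_range_rejected(self):
        rec = make_records([("p0", "c0", "A", (1.0, 0.0))], ["A", "B"])
        with pytest.raises(ValueError):
            apply_pqc(rec, 1.5)

    def test_survivor_count_matches_linear_scan(self):
        rec = fixture_records(seed=7, n_cases=100, patches=100)
        assert len(rec) == 10_000
        surviving, pct = apply_pqc(rec, 0.9)
        cols = [c for c in rec.columns if c.startswith("p_")]
        expected = sum(
            1 for _, row in rec.iterrows() if max(row[c] for c in cols) >= 0.9
        )
        assert len(surviving) == expected
        assert pct == pytest.approx(100.0 * (len(rec) - expected) / len(rec))


class TestVoteCase:
    def _case(self, argmax_classes, cqc):
        rows = []
        for i, cls in enumerate(argmax_classes):
            probs = {c: 0.1 for c in ["A", "B", "C"]}
            probs[cls] = 0.8
            rows.append(("p%d" % i, "c0", "A", tuple(probs[c] for c in "ABC")))
        return vote_case(make_records(rows, ["A", "B", "C"]), cqc)

    def test_majority_classified(self):
        dec = self._case(["A", "A", "B"], cqc=0.5)
        assert dec.predicted_eval_class == "A"
        assert dec.vote_fraction == pytest.approx(2 / 3)

    def test_strict_cqc_comparison_unclassifies(self):
        dec = self._case(["A", "A", "B"], cqc=0.7)
        assert dec.predicted_eval_class == UNCLASSIFIED
        assert dec.vote_fraction == pytest.approx(2 / 3)

    def test_tie_broken_by_summed_probability(self):
        rec = make_records(
            [
                ("p0", "c0", "A", (0.55, 0.45)),
                ("p1", "c0", "A", (0.40, 0.60)),  # B wins this patch
            ],
            ["A", "B"],
        )
        # votes 1:1; summed probs A=0.95, B=1.05 -> B
        dec = vote_case(rec, 0.0)
        assert dec.predicted_eval_class == "B"

    def test_remaining_tie_broken_by_class_order(self):
        rec = make_records(
            [("p0", "c0", "A", (0.6, 0.4)), ("p1", "c0", "A", (0.4, 0.6))],
            ["A", "B"],
        )
        # votes 1:1 and equal summed probs (1.0 each) -> first class order
        dec = vote_case(rec, 0.0)
        assert dec.predicted_eval_class == "A"

    def test_mixed_case_ids_rejected(self):
        rec = make_records(
            [("p0", "c0", "A", (1.0, 0.0)), ("p1", "c1", "A", (1.0, 0.0))],
            ["A", "B"],
        )
        with pytest.raises(ValueError, match="mixed"):
            vote_case(rec, 0.5)

    def test_zero_survivors_unclassified(self):
        rec = make_records([], ["A", "B"]).reindex(
            columns=["patch_id", "case_id", "true_class", "p_A", "p_B"]
        )
        dec = vote_case(rec, 0.5, n_total_patches=7)
        assert dec.predicted_eval_class == UNCLASSIFIED
        assert dec.n_surviving_patches == 0 and dec.n_total_patches == 7


class TestConfusionAndBacc:
    def test_perfect_predictions(self):
        labels = ["A"] * 5 + ["B"] * 2 + ["C"] * 13
        result = confusion_and_bacc(labels, labels)
        assert result.bacc == 1.0

    def test_mean_of_per_class_recalls(self):
        # recalls 1.0, 0.8, 0.9 -> BACC 0.9
        true = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        pred = (
            ["A"] * 10
            + ["B"] * 8 + ["A"] * 2
            + ["C"] * 9 + ["B"]
        )
        result = confusion_and_bacc(true, pred)
        assert result.bacc == pytest.approx(0.9)

    def test_constant_classifier_on_three_classes(self):
        true = ["A", "B", "C"] * 30
        pred = ["B"] * 90
        result = confusion_and_bacc(true, pred)
        assert result.bacc == pytest.approx(1 / 3)

    def test_unclassified_items_excluded(self):
        true = ["A", "A", "B", "B"]
        pred = ["A", UNCLASSIFIED, "B", UNCLASSIFIED]
        result = confusion_and_bacc(true, pred)
        assert result.bacc == 1.0 and result.n_excluded == 2

    def test_zero_classified_items_flagged_not_raised(self):
        result = confusion_and_bacc(["A"], [UNCLASSIFIED], class_order=["A"])
        assert result.bacc is None and result.n_excluded == 1

    def test_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        true = rng.choice(["A", "B", "C"], size=200)
        pred = rng.choice(["A", "B", "C"], size=200)
        result = confusion_and_bacc(true, pred)
        sums = result.normalized.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_matches_per_class_tally_oracle(self):
        rng = np.random.default_rng(11)
        true = rng.choice(["A", "B", "C"], size=500, p=[0.6, 0.3, 0.1])
        pred = rng.choice(["A", "B", "C", UNCLASSIFIED], size=500)
        result = confusion_and_bacc(true, pred)
        recalls = []
        for cls in ("A", "B", "C"):
            sel = [(t, p) for t, p in zip(true, pred) if t == cls and p != UNCLASSIFIED]
            if sel:
                recalls.append(sum(1 for t, p in sel if p == t) / len(sel))
        assert result.bacc == pytest.approx(np.mean(recalls), abs=1e-12)


class TestQcGrid:
    def test_single_case_composition(self):
        rec = make_records(
            [
                ("p0", "c0", "A", (0.8, 0.1, 0.1)),
                ("p1", "c0", "A", (0.7, 0.2, 0.1)),
                ("p2", "c0", "A", (0.2, 0.6, 0.2)),
            ],
            ["A", "B", "C"],
        )
        grid = qc_grid(rec, [0.0], [0.5], class_map=ClassMap.identity(["A", "B", "C"]))
        cell = grid.iloc[0]
        assert cell["bacc_percent"] == 100.0  # majority A is correct
        assert cell["pqc_not_met_percent"] == 0.0
        assert cell["cqc_not_met_percent"] == 0.0

    def test_no_qc_reduces_to_plain_majority_vote(self):
        rec = fixture_records(seed=3, n_cases=20, patches=(10, 30))
        grid = qc_grid(rec, [0.0], [0.0])
        assert grid.iloc[0]["cqc_not_met_percent"] == 0.0
        assert grid.iloc[0]["pqc_not_met_percent"] == 0.0

    @pytest.mark.parametrize("seed", [11, 12])
    def test_every_cell_matches_brute_force_oracle(self, seed):
        """Full 5x5 grid equality against the independent nested-loop
        oracle on a 100-case fixture."""
        rec = fixture_records(seed=seed, n_cases=100, patches=(10, 60))
        grid = qc_grid(rec)
        patches = records_frame_to_patches(rec)
        mapping = dict(qcagg.DEFAULT_CLASS_MAP)
        eval_classes = ClassMap().eval_classes
        for row in grid.itertuples():
            bacc, pqc_pct, cqc_pct = oracle_eval_cell(
                patches, mapping, eval_classes, row.pqc, row.cqc
            )
            assert row.bacc_percent == pytest.approx(bacc, abs=1e-9)
            assert row.pqc_not_met_percent == pytest.approx(pqc_pct, abs=1e-9)
            assert row.cqc_not_met_percent == pytest.approx(cqc_pct, abs=1e-9)

    def test_rejection_percentages_are_monotone(self):
        rec = fixture_records(seed=5, n_cases=50, patches=(10, 40))
        grid = qc_grid(rec)
        for cqc, sub in grid.groupby("cqc"):
            pq = sub.sort_values("pqc")["pqc_not_met_percent"].to_numpy()
            assert (np.diff(pq) >= -1e-12).all()
        for pqc, sub in grid.groupby("pqc"):
            cq = sub.sort_values("cqc")["cqc_not_met_percent"].to_numpy()
            assert (np.diff(cq) >= -1e-12).all()

    def test_cqc_raises_bacc_on_boosted_fixtures(self):
        """With confidence-correct boost > 1, tightening CQC from 0.5 to
        0.9 (at PQC 0.5) does not lower BACC while rejecting more cases
        (5 seeds, at most 1 violation)."""
        violations = 0
        for seed in range(5):
            rec = fixture_records(seed=100 + seed, n_cases=100, patches=(20, 60),
                                  accuracy=0.7, boost=2.0)
            grid = qc_grid(rec, [0.5], [0.5, 0.9]).set_index("cqc")
            ok = (
                grid.loc[0.9, "bacc_percent"] >= grid.loc[0.5, "bacc_percent"]
                and grid.loc[0.9, "cqc_not_met_percent"]
                > grid.loc[0.5, "cqc_not_met_percent"]
            )
            violations += 0 if ok else 1
        assert violations <= 1

    def test_empty_threshold_lists_rejected(self):
        rec = fixture_records(seed=1, n_cases=10, patches=10)
        with pytest.raises(ValueError):
            qc_grid(rec, [], [0.5])

    def test_cqc_denominator_all_option(self):
        rec = make_records(
            [
                ("p0", "c0", "A", (0.95, 0.05)),
                ("p1", "c0", "A", (0.92, 0.08)),
                ("p2", "c0", "A", (0.55, 0.45)),  # fails PQC 0.9
            ],
            ["A", "B"],
        )
        cm = ClassMap.identity(["A", "B"])
        agg = aggregate_probs(rec, cm)
        # survivors-denominated: 2/2 = 1.0 >= 0.9 -> classified
        _, res_surv, _, _ = evaluate_cases(agg, QCConfig(0.9, 0.9))
        assert res_surv.bacc == 1.0
        # all-patches-denominated: 2/3 < 0.9 -> unclassified
        decisions, _, _, cqc_pct = evaluate_cases(
            agg, QCConfig(0.9, 0.9), cqc_denominator="all"
        )
        assert decisions[0].predicted_eval_class == UNCLASSIFIED
        assert cqc_pct == 100.0


def test_case_level_bacc_dominates_patch_level_on_fixtures():
    """With patch accuracy above chance and many conditionally independent
    patches per case, majority voting lifts case-level BACC above
    patch-level BACC (5 seeds, at most 1 violation)."""
    violations = 0
    for seed in range(5):
        rec = fixture_records(seed=200 + seed, n_cases=50, patches=(20, 40),
                              accuracy=0.8, boost=1.0)
        patch_result = qcagg.patch_level_eval(rec)
        grid = qc_grid(rec, [0.0], [0.0])
        case_bacc = grid.iloc[0]["bacc_percent"] / 100.0
        if not case_bacc >= patch_result.bacc:
            violations += 1
    assert violations <= 1
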