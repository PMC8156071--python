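"""Shared fixtures: synthetic cohorts, trained desk-scale models.

The trained models are expensive (~40 s each on one CPU), so they are
built once per session and shared by the trainer, saliency and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from lymphopatch import cohort as cohort_mod
from lymphopatch import synthdata, trainer
from lymphopatch.model import ScalingSpec
from lymphopatch.patchgrid import AnnotatedImage, Annotation, extract_patches

#: Desk-scale study conditions: 3 morphology classes, 30 cases each,
#: 20-40 patches per case, 100 um patches at 32 px.
COHORT3_CLASSES = ("SLL_CLL", "DLBCL", "LN_LUNG")
COHORT3_UM_PER_PX = 100.0 / 32.0
TRAIN_SEEDS = (101, 202, 303)
TRAIN_EPOCHS = 14


def build_cohort3(seed: int = 42, cases_per_class: int = 30):
    """Synthetic 3-class cohort: rendered cases + extracted patch sets."""
    cfg = synthdata.SyntheticCohortConfig(
        cases_per_class=cases_per_class,
        patches_per_case=(20, 40),
        um_per_px=COHORT3_UM_PER_PX,
        class_labels=COHORT3_CLASSES,
        seed=seed,
    )
    cohort = synthdata.generate_cohort(cfg)
    records = []
    for case in cohort.cases:
        img = AnnotatedImage(
            case.image,
            case.um_per_px,
            [Annotation(Polygon(case.polygon_px), case.class_label, case.case_id)],
        )
        recs, _ = extract_patches(img, cfg.patch_size_um)
        records.extend(recs)
    return cohort, records


def records_to_datasets(records, split_seed: int = 1):
    """Patient-level 60/20/20 split of extracted patch records."""
    table = (
        pd.DataFrame(
            [(r.case_id, r.true_class) for r in records],
            columns=["case_id", "class"],
        )
        .groupby(["case_id", "class"])
        .size()
        .rename("n_patches")
        .reset_index()
    )
    split = cohort_mod.split_cases(table, cohort_mod.SplitConfig(seed=split_seed))
    subset_of = dict(zip(split["case_id"], split["subset"]))

    def subset(name):
        sel = [r for r in records if subset_of[r.case_id] == name]
        return trainer.PatchDataset(
            X=np.stack([r.tile for r in sel]),
            y=np.asarray([r.true_class for r in sel]),
            case_ids=np.asarray([r.case_id for r in sel]),
            patch_ids=np.asarray([r.patch_id for r in sel]),
        )

    return subset("TRAIN"), subset("VAL"), subset("TEST"), split


@pytest.fixture(scope="session")
def cohort3():
    cohort, records = build_cohort3()
    train_set, val_set, test_set, split = records_to_datasets(records)
    return {
        "cohort": cohort,
        "records": records,
        "train": train_set,
        "val": val_set,
        "test": test_set,
        "split": split,
    }


@pytest.fixture(scope="session")
def trained_runs(cohort3):
    """One trained desk-scale model per seed, with its curves/checkpoint."""
    runs = []
    for seed in TRAIN_SEEDS:
        cfg = trainer.TrainConfig(
            scaling=ScalingSpec(),
            epochs=TRAIN_EPOCHS,
            patience=None,
            seed=seed,
        )
        est, curves, ckpt = trainer.train(cohort3["train"], cohort3["val"], cfg)
        runs.append({"seed": seed, "est": est, "curves": curves, "ckpt": ckpt})
    return runs


@pytest.fixture(scope="session")
def small_fixture_manifest():
    """100-case manifest over the five training classes."""
    rows = []
    for cls in synthdata.CLASS_LIST:
        for k in range(20):
            rows.append({"case_id": f"{cls}_{k:02d}", "class": cls})
    return pd.DataFrame(rows)
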