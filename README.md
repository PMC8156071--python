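# lymphopatch

Patch-based classification of non-Hodgkin lymphoma on H&E-stained
lymph-node images, with patient-level evaluation and two-level quality
control.

## The problem

Subtyping lymphoma on histology is hard: small lymphocytic lymphoma /
chronic lymphocytic leukemia (SLL/CLL) is a sea of small uniform
lymphocytes, diffuse large B-cell lymphoma (DLBCL) shows large pleomorphic
nuclei, and both must be told apart from tumor-free reactive lymph nodes.
A patch-level CNN can support this decision, but a clinically meaningful
answer is per **patient**, not per patch, and should abstain rather than
guess when the evidence is weak. This package implements that full chain
for anyone building or evaluating such classifiers:

1. **Tiling** — annotated regions (polygons over a scaled image) are cut
   into non-overlapping square patches of fixed physical size (100 µm;
   395 px at 100/395 µm/px), keeping only tiles fully inside both the
   annotation and the image so tissue edges are never over-represented.
2. **Patient-level splits** — cases are assigned 60/20/20 to
   train/validation/test by largest-remainder apportionment, stratified by
   class; all patches inherit their case's subset, and a checkpoint
   (`assert_single_subset`) refuses to train on leaky splits.
3. **A compound-scaled CNN** — one small baseline convolutional network
   whose depth, width and input resolution grow jointly as
   `d·α^φ, w·β^φ, r·γ^φ` (defaults α=1.2, β=1.1, γ=1.15), exposed as a
   scikit-learn estimator (`PatchCNNClassifier`). The protocol around it:
   learning-rate screening from identical initializations, checkpointing
   the best-validation-accuracy epoch, and family-member selection with a
   balanced-accuracy tie-break.
4. **Quality control + aggregation** — the three organ-specific control
   classes (lung/colon/pancreas LN) are pooled into one "tumor-free
   reference LN" evaluation class by summing probabilities; patches whose
   top probability falls below the **PQC** threshold are discarded; each
   case takes the majority vote of its surviving patches and is left
   UNCLASSIFIED when the vote fraction falls below the **CQC** threshold.
   Performance is reported as balanced accuracy (BACC, the mean of
   per-class recalls) over a PQC × CQC threshold grid, together with both
   rejection percentages.
5. **SmoothGrad saliency** — input gradients averaged over Gaussian-
   perturbed copies (noise 0.5 % of the intensity range, 50 samples),
   channel-collapsed by per-pixel maximum and normalized to [0, 1), to
   check the network attends to cells rather than background.

Because clinical tiles cannot be redistributed, the package ships a
synthetic-data module that renders H&E-like lymph-node images with the
morphological contrasts that matter (nucleus size/density/eccentricity,
anthracosis pigment in lung LNs, sinus spaces in colon/pancreas LNs) plus
ground-truth polygon annotations, and — independently — per-patch
probability fixtures with controllable accuracy and confidence–correctness
coupling for testing the evaluation machinery in isolation.

## Worked example

Run the whole chain on a synthetic cohort (30 cases per class, 20–40
patches each, 100 µm patches at 32 px) from Python:

```python
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from lymphopatch import cohort as cohort_mod, qcagg, synthdata, trainer
from lymphopatch.model import ScalingSpec
from lymphopatch.patchgrid import AnnotatedImage, Annotation, extract_patches

# render the cohort and tile every annotated case
cfg = synthdata.SyntheticCohortConfig(
    cases_per_class=30, patches_per_case=(20, 40), um_per_px=100 / 32,
    class_labels=("SLL_CLL", "DLBCL", "LN_LUNG"), seed=42,
)
records = []
for case in synthdata.generate_cohort(cfg).cases:
    img = AnnotatedImage(case.image, case.um_per_px,
                         [Annotation(Polygon(case.polygon_px),
                                     case.class_label, case.case_id)])
    recs, _ = extract_patches(img, cfg.patch_size_um)
    records.extend(recs)

# patient-level 60/20/20 split
table = (pd.DataFrame([(r.case_id, r.true_class) for r in records],
                      columns=["case_id", "class"])
         .groupby(["case_id", "class"]).size().rename("n_patches").reset_index())
split = cohort_mod.split_cases(table, cohort_mod.SplitConfig(seed=1))
subset_of = dict(zip(split["case_id"], split["subset"]))

def dataset(name):
    sel = [r for r in records if subset_of[r.case_id] == name]
    return trainer.PatchDataset(
        X=np.stack([r.tile for r in sel]),
        y=np.asarray([r.true_class for r in sel]),
        case_ids=np.asarray([r.case_id for r in sel]))

train_set, val_set, test_set = dataset("TRAIN"), dataset("VAL"), dataset("TEST")

est, curves, ckpt = trainer.train(
    train_set, val_set,
    trainer.TrainConfig(scaling=ScalingSpec(), epochs=14, patience=None, seed=101),
)
print(ckpt)
preds = trainer.predict(est, test_set)
grid = qcagg.qc_grid(preds, [0.5, 0.9], [0.5, 0.9],
                     class_map=qcagg.ClassMap.identity(est.classes_))
print(qcagg.grid_to_wide(grid))
```

which prints (the checkpoint, then BACC % per PQC row × CQC column):

```
{'best_epoch': 13, 'best_val_accuracy': 0.996415770609319}
cqc    0.5    0.9
pqc
0.5  100.0  100.0
0.9  100.0  100.0
```

A validation patch accuracy of ~0.996 means the φ=0 member separates the
three synthetic morphologies almost perfectly at patch level; after
majority voting every test case is classified correctly at all four
threshold pairs, so the case-level BACC is 100 % and nothing is rejected.
On real tissue the grid is where the interesting trade-off appears:
raising CQC buys accuracy by abstaining on ambiguous patients.

The same run from a shell:

```sh
lymphopatch run --config cfg.yaml            # all stages
lymphopatch run --config cfg.yaml --stages synth --stages extract
```

Each stage writes its outputs plus a `manifest.json` with SHA-256 digests;
deterministic stages reproduce identical digests on re-runs.

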