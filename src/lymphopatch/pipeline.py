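"""End-to-end orchestration: synth → extract → split → train → predict →
qc-grid → saliency, under one YAML-serializable config with per-stage
seeds, structured logging, and a reproducibility manifest of output
digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import re
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from lymphopatch import cohort as cohort_mod
from lymphopatch import patchgrid, qcagg, saliency as saliency_mod, synthdata, trainer
from lymphopatch.model import PatchCNNClassifier, ScalingSpec

logger = logging.getLogger(__name__)

STAGES = ("synth", "extract", "split", "train", "predict", "qc_grid", "saliency")


class DependencyError(RuntimeError):
    """A stage's upstream outputs are missing."""


@dataclass
class PipelineConfig:
    """One config object covering every stage; YAML round-trippable."""

    workdir: str = "lymphopatch_run"
    seed: int = 0
    # synth
    cases_per_class: int = 10
    patches_per_case: tuple[int, int] = (10, 40)
    class_labels: tuple[str, ...] = ("SLL_CLL", "DLBCL", "LN_LUNG")
    um_per_px: float = 100.0 / 32.0
    patch_size_um: float = 100.0
    # split
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratify: bool = True
    # training
    phi: int = 0
    learning_rate: float = 3e-3
    batch_size: int = 32
    epochs: int = 30
    patience: int | None = 10
    # qc
    pqc_thresholds: tuple[float, ...] = qcagg.DEFAULT_THRESHOLDS
    cqc_thresholds: tuple[float, ...] = qcagg.DEFAULT_THRESHOLDS
    # saliency
    saliency_patches: int = 4
    noise_fraction: float = 0.005
    n_samples: int = 50

    def stage_seed(self, stage: str) -> int:
        """Stage seed derived from (global seed, stage name); independent of
        execution order."""
        mix = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(mix.generate_state(1, dtype=np.uint32)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = Path(path).read_text()
        raw = re.sub(
            r"\$\{(\w+)\}", lambda m: os.environ.get(m.group(1), m.group(0)), raw
        )
        data = yaml.safe_load(raw) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("patches_per_case", "class_labels", "fractions",
                    "pqc_thresholds", "cqc_thresholds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Constraint check; returns human-readable violations (no exceptions)."""
    v: list[str] = []
    if abs(sum(config.fractions) - 1.0) > 1e-9:
        v.append(f"split fractions sum to {sum(config.fractions)}, expected 1")
    for name in ("pqc_thresholds", "cqc_thresholds"):
        for t in getattr(config, name):
            if not (0 <= t <= 1):
                v.append(f"{name} entry {t} outside [0, 1]")
    bs = config.batch_size
    if bs < 1 or (bs & (bs - 1)) != 0:
        v.append(f"batch_size {bs} is not a power of two")
    if config.um_per_px <= 0:
        v.append(f"um_per_px must be positive, got {config.um_per_px}")
    if config.patch_size_um <= 0:
        v.append(f"patch_size_um must be positive, got {config.patch_size_um}")
    if config.learning_rate <= 0:
        v.append(f"learning_rate must be positive, got {config.learning_rate}")
    if config.patches_per_case[0] < 1 or config.patches_per_case[0] > config.patches_per_case[1]:
        v.append(f"patches_per_case range invalid: {config.patches_per_case}")
    return v


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_tree(paths: list[Path]) -> dict[str, str]:
    return {p.name: _digest(p) for p in sorted(paths)}


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs output of stage '{stage}' ({path}); "
            f"run that stage first"
        )
    return path


def _resolve(path: str, base: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base / p


def _load_patchset(index: pd.DataFrame, base: Path) -> trainer.PatchDataset:
    X = np.stack([np.asarray(Image.open(_resolve(p, base))) for p in index["path"]])
    return trainer.PatchDataset(
        X=X,
        y=index["true_class"].to_numpy(),
        case_ids=index["case_id"].to_numpy(),
        patch_ids=index["patch_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_synth(cfg: PipelineConfig, wd: Path) -> list[Path]:
    out = wd / "synth"
    cohort = synthdata.generate_cohort(
        synthdata.SyntheticCohortConfig(
            cases_per_class=cfg.cases_per_class,
            patches_per_case=cfg.patches_per_case,
            um_per_px=cfg.um_per_px,
            patch_size_um=cfg.patch_size_um,
            class_labels=cfg.class_labels,
            seed=cfg.stage_seed("synth"),
        )
    )
    synthdata.write_cohort(cohort, out)
    return sorted(out.iterdir())


def _stage_extract(cfg: PipelineConfig, wd: Path) -> list[Path]:
    synth_dir = wd / "synth"
    manifest = pd.read_csv(_require(synth_dir / "manifest.csv", "synth", "extract"))
    out = wd / "patches"
    all_records = []
    for _, row in manifest.iterrows():
        img = patchgrid.load_annotated_image(
            _resolve(row["image_path"], synth_dir),
            _resolve(row["annotation_path"], synth_dir),
            um_per_px=row["um_per_px"],
        )
        records, _report = patchgrid.extract_patches(img, cfg.patch_size_um)
        all_records.extend(records)
    index = patchgrid.write_patches(all_records, out)
    counts = index.groupby("case_id").size().rename("n_patches").reset_index()
    low = counts[counts["n_patches"] < patchgrid.MIN_PATCHES_PER_CASE]
    if len(low):
        logger.warning("cases below the 10-patch minimum: %s",
                       low["case_id"].tolist())
    return [out / "patch_index.csv"]


def _stage_split(cfg: PipelineConfig, wd: Path) -> list[Path]:
    index = pd.read_csv(_require(wd / "patches" / "patch_index.csv", "extract", "split"))
    counts = index.groupby(["case_id", "true_class"]).size().rename("n_patches")
    table = counts.reset_index().rename(columns={"true_class": "class"})
    split = cohort_mod.split_cases(
        table,
        cohort_mod.SplitConfig(
            fractions=cfg.fractions,
            stratify_by_class=cfg.stratify,
            seed=cfg.stage_seed("split"),
        ),
    )
    split.to_csv(wd / "cohort.csv", index=False)
    cohort_mod.summarize_subsets(split).to_csv(wd / "subset_summary.csv", index=False)
    return [wd / "cohort.csv", wd / "subset_summary.csv"]


def _subset_index(wd: Path, subset: str, needed_by: str) -> pd.DataFrame:
    index = pd.read_csv(_require(wd / "patches" / "patch_index.csv", "extract", needed_by))
    split = pd.read_csv(_require(wd / "cohort.csv", "split", needed_by))
    merged = index.merge(split[["case_id", "subset"]], on="case_id", how="left")
    violations = cohort_mod.assert_single_subset(
        merged.assign(subset=merged["subset"]), split
    )
    if violations:
        raise ValueError(f"subset integrity violations: {violations}")
    return merged[merged["subset"] == subset]


def _stage_train(cfg: PipelineConfig, wd: Path) -> list[Path]:
    train_set = _load_patchset(_subset_index(wd, "TRAIN", "train"), wd / "patches")
    val_set = _load_patchset(_subset_index(wd, "VAL", "train"), wd / "patches")
    tcfg = trainer.TrainConfig(
        scaling=ScalingSpec(phi=cfg.phi),
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        patience=cfg.patience,
        seed=cfg.stage_seed("train"),
    )
    est, curves, ckpt = trainer.train(train_set, val_set, tcfg)
    est.save(wd / "model.npz")
    curves.to_csv(wd / "curves.csv", index=False)
    (wd / "checkpoint.json").write_text(json.dumps(ckpt))
    return [wd / "curves.csv", wd / "checkpoint.json"]


def _stage_predict(cfg: PipelineConfig, wd: Path) -> list[Path]:
    _require(wd / "model.npz", "train", "predict")
    est = PatchCNNClassifier.load(wd / "model.npz")
    test_set = _load_patchset(_subset_index(wd, "TEST", "predict"), wd / "patches")
    preds = trainer.predict(est, test_set)
    preds.to_csv(wd / "predictions.csv", index=False)
    return [wd / "predictions.csv"]


def _stage_qc_grid(cfg: PipelineConfig, wd: Path) -> list[Path]:
    preds = pd.read_csv(_require(wd / "predictions.csv", "predict", "qc_grid"))
    train_classes = [c[2:] for c in preds.columns if c.startswith("p_")]
    cmap = qcagg.ClassMap(
        {c: qcagg.DEFAULT_CLASS_MAP.get(c, c) for c in train_classes}
    )
    grid = qcagg.qc_grid(preds, cfg.pqc_thresholds, cfg.cqc_thresholds, cmap)
    grid.to_csv(wd / "qc_grid.csv", index=False)
    qcagg.grid_to_wide(grid).to_csv(wd / "qc_grid_wide.csv")
    return [wd / "qc_grid.csv", wd / "qc_grid_wide.csv"]


def _stage_saliency(cfg: PipelineConfig, wd: Path) -> list[Path]:
    _require(wd / "model.npz", "train", "saliency")
    est = PatchCNNClassifier.load(wd / "model.npz")
    preds = pd.read_csv(_require(wd / "predictions.csv", "predict", "saliency"))
    index = pd.read_csv(wd / "patches" / "patch_index.csv")
    prob_cols = [c for c in preds.columns if c.startswith("p_")]
    argmax = preds[prob_cols].to_numpy().argmax(axis=1)
    pred_class = np.asarray([c[2:] for c in prob_cols])[argmax]
    correct = preds[pred_class == preds["true_class"].to_numpy()]
    chosen = correct.head(cfg.saliency_patches)
    out = wd / "saliency"
    outputs = []
    res = est._scaling().resolution
    class_idx = {c: i for i, c in enumerate(est.classes_)}
    seed = cfg.stage_seed("saliency")
    for _, row in chosen.iterrows():
        path = index.loc[index["patch_id"] == row["patch_id"], "path"].iloc[0]
        patch = np.asarray(Image.open(_resolve(path, wd / "patches")))
        if patch.shape[:2] != (res, res):
            from skimage.transform import resize

            patch = resize(patch, (res, res), order=1, preserve_range=True,
                           anti_aliasing=False)
        scfg = saliency_mod.SaliencyConfig(
            noise_fraction=cfg.noise_fraction,
            n_samples=cfg.n_samples,
            seed=seed,
            target_class=class_idx[row["true_class"]],
        )
        smap = saliency_mod.smoothgrad(est, patch, scfg, patch_id=row["patch_id"])
        saliency_mod.save_saliency(smap, patch, out, stem=row["patch_id"])
        outputs.append(out / f"{row['patch_id']}_provenance.json")
    return outputs


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "extract": _stage_extract,
    "split": _stage_split,
    "train": _stage_train,
    "predict": _stage_predict,
    "qc_grid": _stage_qc_grid,
    "saliency": _stage_saliency,
}


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in canonical order; returns the manifest.

    Each completed stage appends its output digests to
    ``<workdir>/manifest.json``; a failing stage leaves earlier entries in
    place so the run can resume.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest_path = wd / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        from lymphopatch import __version__

        manifest = {
            "config_hash": _config_hash(config),
            "package_version": __version__,
            "stages": {},
        }
    if manifest.get("config_hash") != _config_hash(config):
        logger.warning("config changed since last run; resetting manifest")
        from lymphopatch import __version__

        manifest = {
            "config_hash": _config_hash(config),
            "package_version": __version__,
            "stages": {},
        }
    ordered = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in ordered:
        t0 = time.time()
        logger.info("stage=%s seed=%d starting", stage, config.stage_seed(stage))
        outputs = _STAGE_FUNCS[stage](config, wd)
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage),
            "outputs": _digest_tree(list(outputs)),
            "elapsed_s": round(time.time() - t0, 3),
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        logger.info("stage=%s seed=%d done (%.1fs)", stage,
                    config.stage_seed(stage), time.time() - t0)
    return manifest
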