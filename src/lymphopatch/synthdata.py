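"""Synthetic H&E-like lymph-node images and prediction fixtures.

Real lymphoma tissue tiles are not publicly deposited, so this module
provides two independent synthetic substrates:

1. Rendered tissue images with ground-truth polygon annotations, emulating
   the morphological contrasts the classifier must learn: small uniform
   lymphocytes (SLL/CLL), large pleomorphic nuclei (DLBCL), and mixed
   reactive lymph nodes — the lung variant with dark extracellular
   anthracosis clumps, the colon/pancreas variants with pale sinus spaces.

2. Per-patch class-probability tables with controllable argmax accuracy and
   confidence–correctness coupling, so the quality-control and evaluation
   stages can be tested without any trained model.

All parameter defaults are artifact choices: they produce the class-ordered
morphology (DLBCL nuclei larger than SLL/CLL nuclei) and tunable class
separability that the downstream stages need, not photorealistic histology.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: Physical scale at which a 100 µm patch is exactly 395 px.
DEFAULT_UM_PER_PX = 100.0 / 395.0

#: Ordered training-class vocabulary (5-way).
CLASS_LIST = ("SLL_CLL", "DLBCL", "LN_LUNG", "LN_COLON", "LN_PANCREAS")


@dataclass(frozen=True)
class MorphologyParams:
    """Rendering parameters for one morphology class.

    Densities and rates are per 100×100 µm of tissue; diameters are in µm;
    colors are 8-bit RGB.
    """

    class_label: str
    nucleus_diameter_um: tuple[float, float]  # (mean, std)
    nucleus_density: float  # nuclei per 100x100 um
    eccentricity_range: tuple[float, float]
    pigment_clump_rate: float = 0.0  # anthracosis clumps per 100x100 um
    sinus_rate: float = 0.0  # pale sinus ellipses per 100x100 um
    nucleus_rgb: tuple[int, int, int] = (72, 42, 110)
    background_rgb: tuple[int, int, int] = (232, 205, 225)
    noise_std: float = 8.0  # additive Gaussian noise, 8-bit units

    def __post_init__(self) -> None:
        if self.nucleus_diameter_um[0] <= 0:
            raise ValueError("nucleus diameter mean must be > 0")
        if self.nucleus_density < 0:
            raise ValueError("nucleus density must be >= 0")
        lo, hi = self.eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("eccentricity range must lie in [0, 1)")


def default_morphology(class_label: str) -> MorphologyParams:
    """Default rendering parameters for each of the five training classes.

    The class-discriminative choices: DLBCL nuclei are roughly twice the
    diameter of SLL/CLL nuclei and more eccentric (pleomorphism); the lung
    reference LN carries near-black pigment clumps; colon and pancreas
    reference LNs instead show pale sinus spaces.
    """
    table = {
        "SLL_CLL": MorphologyParams(
            class_label="SLL_CLL",
            nucleus_diameter_um=(7.0, 0.8),
            nucleus_density=55.0,
            eccentricity_range=(0.0, 0.3),
            nucleus_rgb=(60, 35, 105),
            background_rgb=(233, 208, 228),
            noise_std=8.0,
        ),
        "DLBCL": MorphologyParams(
            class_label="DLBCL",
            nucleus_diameter_um=(16.0, 3.0),
            nucleus_density=18.0,
            eccentricity_range=(0.2, 0.7),
            nucleus_rgb=(95, 55, 130),
            background_rgb=(228, 198, 222),
            noise_std=10.0,
        ),
        "LN_LUNG": MorphologyParams(
            class_label="LN_LUNG",
            nucleus_diameter_um=(8.0, 1.8),
            nucleus_density=32.0,
            eccentricity_range=(0.0, 0.5),
            pigment_clump_rate=3.0,
            nucleus_rgb=(75, 45, 115),
            background_rgb=(235, 210, 226),
            noise_std=9.0,
        ),
        "LN_COLON": MorphologyParams(
            class_label="LN_COLON",
            nucleus_diameter_um=(8.0, 1.8),
            nucleus_density=32.0,
            eccentricity_range=(0.0, 0.5),
            sinus_rate=2.0,
            nucleus_rgb=(75, 45, 115),
            background_rgb=(235, 210, 226),
            noise_std=9.0,
        ),
        "LN_PANCREAS": MorphologyParams(
            class_label="LN_PANCREAS",
            nucleus_diameter_um=(8.5, 1.8),
            nucleus_density=28.0,
            eccentricity_range=(0.0, 0.5),
            sinus_rate=3.5,
            nucleus_rgb=(78, 48, 118),
            background_rgb=(236, 212, 228),
            noise_std=9.0,
        ),
    }
    try:
        return table[class_label]
    except KeyError:
        raise ValueError(f"unknown morphology class: {class_label!r}") from None


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Layout of a synthetic multi-case cohort."""

    cases_per_class: int = 10
    patches_per_case: tuple[int, int] = (10, 250)
    um_per_px: float = DEFAULT_UM_PER_PX
    patch_size_um: float = 100.0
    class_labels: tuple[str, ...] = CLASS_LIST
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patches_per_case[0] < 1:
            raise ValueError("patches_per_case lower bound must be >= 1")
        if self.patches_per_case[0] > self.patches_per_case[1]:
            raise ValueError("patches_per_case range inverted")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")


@dataclass(frozen=True)
class PredictionFixtureConfig:
    """Controls for synthetic per-patch probability tables.

    ``patch_accuracy`` is the probability a patch's argmax class equals its
    true class; ``confidence_concentration`` controls how peaked the simplex
    vectors are; ``confidence_correct_boost`` >= 1 makes correct patches
    more confident than incorrect ones.
    """

    patch_accuracy: float = 0.8
    confidence_concentration: float = 4.0
    confidence_correct_boost: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.patch_accuracy <= 1):
            raise ValueError("patch_accuracy must lie in (0, 1]")
        if self.confidence_concentration <= 0:
            raise ValueError("confidence_concentration must be > 0")
        if self.confidence_correct_boost < 1:
            raise ValueError("confidence_correct_boost must be >= 1")


@dataclass
class SyntheticCase:
    """One rendered case: image, its annotation polygon, identity."""

    case_id: str
    class_label: str
    image: np.ndarray  # (H, W, 3) uint8
    polygon_px: list[tuple[float, float]]  # closed ring, pixel coords
    um_per_px: float


@dataclass
class SyntheticCohort:
    cases: list[SyntheticCase]
    config: SyntheticCohortConfig

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"case_id": c.case_id, "class": c.class_label} for c in self.cases]
        )


# ---------------------------------------------------------------------------
# Rendering


def _draw_ellipse(
    img: np.ndarray,
    mask: np.ndarray | None,
    cy: float,
    cx: float,
    r_major: float,
    r_minor: float,
    theta: float,
    rgb: np.ndarray,
) -> None:
    """Paint a filled rotated ellipse; clipped at image bounds."""
    h, w = img.shape[:2]
    r = int(np.ceil(r_major)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / r_major) ** 2 + (v / r_minor) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = rgb
    if mask is not None:
        mask[y0:y1, x0:x1] |= inside


def _poisson_at_least(rng: np.random.Generator, lam: float, floor_if: float) -> int:
    n = int(rng.poisson(lam))
    if lam >= floor_if:
        n = max(n, 1)
    return n


def render_patch(
    params: MorphologyParams,
    size_px: int,
    seed: int,
    um_per_px: float = DEFAULT_UM_PER_PX,
    return_mask: bool = False,
):
    """Render one square tissue patch.

    Parameters
    ----------
    params
        Morphology of the class to emulate.
    size_px
        Side length in pixels (>= 32).
    seed
        Seed; identical seeds give bit-identical images.
    um_per_px
        Physical scale. The default makes a 395 px patch span 100 µm.
    return_mask
        Also return the boolean nucleus mask (used by the separability and
        saliency checks).

    Returns
    -------
    image : (size_px, size_px, 3) uint8 array, or ``(image, nucleus_mask)``
    when ``return_mask`` is true.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    rng = np.random.default_rng(seed)
    img = np.empty((size_px, size_px, 3), dtype=np.float64)
    img[:] = np.asarray(params.background_rgb, dtype=np.float64)
    nucleus_mask = np.zeros((size_px, size_px), dtype=bool)

    area_units = (size_px * um_per_px / 100.0) ** 2  # in 100x100 um units

    # pale sinus spaces first (background structure)
    n_sinus = int(rng.poisson(params.sinus_rate * area_units))
    sinus_rgb = np.minimum(np.asarray(params.background_rgb) + 14.0, 255.0)
    for _ in range(n_sinus):
        cy, cx = rng.uniform(0, size_px, size=2)
        r_maj = rng.uniform(8, 20) / um_per_px / 2
        r_min = r_maj * rng.uniform(0.4, 0.8)
        _draw_ellipse(img, None, cy, cx, r_maj, r_min, rng.uniform(0, np.pi), sinus_rgb)

    # nuclei
    lam = params.nucleus_density * area_units
    n_nuclei = _poisson_at_least(rng, lam, floor_if=1.0)
    mean_d, std_d = params.nucleus_diameter_um
    ecc_lo, ecc_hi = params.eccentricity_range
    nuc_rgb = np.asarray(params.nucleus_rgb, dtype=np.float64)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size_px, size=2)
        d_um = max(mean_d + std_d * rng.standard_normal(), 0.25 * mean_d)
        ecc = rng.uniform(ecc_lo, ecc_hi)
        r_major = d_um / um_per_px / 2.0
        r_minor = r_major * np.sqrt(1.0 - ecc**2)
        shade = nuc_rgb + rng.normal(0, 6, size=3)
        _draw_ellipse(
            img, nucleus_mask, cy, cx, r_major, r_minor,
            rng.uniform(0, np.pi), np.clip(shade, 0, 255),
        )

    # anthracosis pigment clumps (near-black, irregular: a cluster of dots)
    n_clumps = int(rng.poisson(params.pigment_clump_rate * area_units))
    if params.pigment_clump_rate > 0 and lam_clump_floor(params, area_units):
        n_clumps = max(n_clumps, 1)
    for _ in range(n_clumps):
        cy, cx = rng.uniform(0, size_px, size=2)
        for _ in range(rng.integers(3, 7)):
            oy, ox = rng.normal(0, 3.0 / um_per_px / 2, size=2)
            r = rng.uniform(1.5, 4.0) / um_per_px / 2
            _draw_ellipse(
                img, None, cy + oy, cx + ox, r, r * rng.uniform(0.6, 1.0),
                rng.uniform(0, np.pi), np.asarray([28.0, 26.0, 30.0]),
            )

    if params.noise_std > 0:
        img += rng.normal(0, params.noise_std, size=img.shape)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if return_mask:
        return out, nucleus_mask
    return out


def lam_clump_floor(params: MorphologyParams, area_units: float) -> bool:
    """Guarantee at least one clump when the expected count reaches one."""
    return params.pigment_clump_rate * area_units >= 1.0


# ---------------------------------------------------------------------------
# Cohort generation


def _case_polygon(n_tiles: int, side_px: int, margin: int) -> tuple[list, int, int]:
    """Staircase polygon covering exactly ``n_tiles`` grid squares.

    Full rows of ``cols`` tiles plus one partial last row; returns the ring
    (pixel coordinates, origin at (margin, margin)) and the image extent.
    """
    cols = int(np.ceil(np.sqrt(n_tiles)))
    rows = int(np.ceil(n_tiles / cols))
    last = n_tiles - (rows - 1) * cols  # tiles in the last row, 1..cols
    s = side_px
    m = margin
    if last == cols:
        ring = [(m, m), (m + cols * s, m), (m + cols * s, m + rows * s), (m, m + rows * s)]
    else:
        ring = [
            (m, m),
            (m + cols * s, m),
            (m + cols * s, m + (rows - 1) * s),
            (m + last * s, m + (rows - 1) * s),
            (m + last * s, m + rows * s),
            (m, m + rows * s),
        ]
    width = 2 * m + cols * s
    height = 2 * m + rows * s
    return ring, width, height


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Render one image + polygon annotation per case.

    Each case's polygon is a grid-aligned staircase region sized so the
    downstream tiler extracts a patch count drawn uniformly from
    ``config.patches_per_case``.
    """
    if config.cases_per_class == 0:
        logger.warning("generate_cohort: zero cases per class requested; empty cohort")
        return SyntheticCohort(cases=[], config=config)
    rng = np.random.default_rng(config.seed)
    side_px = int(round(config.patch_size_um / config.um_per_px))
    margin = max(4, side_px // 8)
    cases: list[SyntheticCase] = []
    for label in config.class_labels:
        params = default_morphology(label)
        for k in range(config.cases_per_class):
            case_id = f"{label}_{k:03d}"
            lo, hi = config.patches_per_case
            n_tiles = int(rng.integers(lo, hi + 1))
            ring, width, height = _case_polygon(n_tiles, side_px, margin)
            case_seed = int(rng.integers(0, 2**31 - 1))
            tissue = render_patch(
                params,
                size_px=max(width, height, 32),
                seed=case_seed,
                um_per_px=config.um_per_px,
            )
            cases.append(
                SyntheticCase(
                    case_id=case_id,
                    class_label=label,
                    image=tissue[:height, :width],
                    polygon_px=ring,
                    um_per_px=config.um_per_px,
                )
            )
    return SyntheticCohort(cases=cases, config=config)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> pd.DataFrame:
    """Write PNG images, one GeoJSON annotation per case, and the manifest CSV.

    Returns the manifest (case_id, class, image_path, annotation_path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cohort.cases:
        img_path = outdir / f"{case.case_id}.png"
        Image.fromarray(case.image).save(img_path)
        ann_path = outdir / f"{case.case_id}.geojson"
        feature = {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(map(float, p)) for p in case.polygon_px]
                                + [list(map(float, case.polygon_px[0]))]],
            },
            "properties": {"case_id": case.case_id, "class": case.class_label},
        }
        ann_path.write_text(
            json.dumps({"type": "FeatureCollection", "features": [feature]})
        )
        # paths are stored relative to the manifest so the cohort directory
        # is relocatable and its digests are reproducible
        rows.append(
            {
                "case_id": case.case_id,
                "class": case.class_label,
                "image_path": img_path.name,
                "annotation_path": ann_path.name,
                "um_per_px": case.um_per_px,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Prediction fixtures


def generate_prediction_fixture(
    cohort_manifest: pd.DataFrame,
    n_patches_per_case,
    config: PredictionFixtureConfig,
    class_list=CLASS_LIST,
) -> pd.DataFrame:
    """Synthetic per-patch probability vectors for every manifest case.

    Each patch is "correct" with probability ``config.patch_accuracy``; its
    assigned class (the true class if correct, else uniform among the
    others) is guaranteed to be the argmax. Probability vectors are drawn
    from a Dirichlet whose assigned component is concentrated by
    ``confidence_concentration`` (times ``confidence_correct_boost`` for
    correct patches), then the maximum component is swapped into the
    assigned slot.

    Parameters
    ----------
    cohort_manifest
        DataFrame with ``case_id`` and ``class`` columns.
    n_patches_per_case
        Integer, or (lo, hi) range sampled per case.
    class_list
        Ordered probability-column vocabulary; must cover every manifest
        class.

    Returns
    -------
    DataFrame with columns patch_id, case_id, true_class and one
    ``p_<class>`` column per class; rows sum to 1.
    """
    class_list = list(class_list)
    missing = set(cohort_manifest["class"]) - set(class_list)
    if missing:
        raise ValueError(f"manifest classes not in class_list: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    k = len(class_list)
    idx_of = {c: i for i, c in enumerate(class_list)}

    counts = []
    for _ in range(len(cohort_manifest)):
        if np.isscalar(n_patches_per_case):
            counts.append(int(n_patches_per_case))
        else:
            lo, hi = n_patches_per_case
            counts.append(int(rng.integers(lo, hi + 1)))

    n_total = int(np.sum(counts))
    true_idx = np.repeat(
        [idx_of[c] for c in cohort_manifest["class"]], counts
    )
    case_ids = np.repeat(cohort_manifest["case_id"].to_numpy(), counts)

    correct = rng.random(n_total) < config.patch_accuracy
    # assigned class: true if correct, else uniform among the other k-1
    offset = rng.integers(1, k, size=n_total)
    assigned = np.where(correct, true_idx, (true_idx + offset) % k)

    alpha = np.ones((n_total, k))
    conc = config.confidence_concentration
    alpha[np.arange(n_total), assigned] += np.where(
        correct, conc * config.confidence_correct_boost, conc
    )
    gams = rng.gamma(shape=alpha)
    probs = gams / gams.sum(axis=1, keepdims=True)
    # force the assigned component to be the maximum (swap)
    argmax = probs.argmax(axis=1)
    rows = np.arange(n_total)
    pmax = probs[rows, argmax].copy()
    probs[rows, argmax] = probs[rows, assigned]
    probs[rows, assigned] = pmax

    out = pd.DataFrame(
        {
            "patch_id": [f"patch_{i:06d}" for i in range(n_total)],
            "case_id": case_ids,
            "true_class": [class_list[i] for i in true_idx],
        }
    )
    for j, c in enumerate(class_list):
        out[f"p_{c}"] = probs[:, j]
    return out
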