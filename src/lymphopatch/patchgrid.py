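"""Fixed-physical-size tiling of annotated tissue regions.

Annotated regions (polygons in pixel coordinates, one class label and case
identity each) are tiled with non-overlapping square patches of a fixed
physical side (100 µm by default; at 100/395 µm/px that is exactly 395 px).
The grid is anchored at the polygon's bounding-box top-left with stride
equal to the patch side, and a tile is kept only when it lies fully inside
both the polygon and the image — tiles straddling the annotation or image
edge are dropped, so the tissue border is never over-represented.

Coordinate convention: 0-based, x right / y down; a tile occupies the
half-open pixel square [x, x+side) × [y, y+side).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import Point, Polygon, shape
from shapely.prepared import prep

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE_UM = 100.0
MIN_PATCHES_PER_CASE = 10


@dataclass
class Annotation:
    polygon: Polygon  # pixel coordinates
    class_label: str
    case_id: str


@dataclass
class AnnotatedImage:
    """An RGB image with its physical scale and polygon annotations."""

    pixels: np.ndarray  # (H, W, 3)
    um_per_px: float
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.um_per_px is None or self.um_per_px <= 0:
            raise ValueError("um_per_px must be a positive scale")
        h, w = self.pixels.shape[:2]
        bounds = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
        clipped = []
        for ann in self.annotations:
            if not ann.polygon.within(bounds):
                logger.warning(
                    "annotation for case %s extends beyond image bounds; clipping",
                    ann.case_id,
                )
                poly = ann.polygon.intersection(bounds)
                if poly.is_empty or poly.geom_type != "Polygon":
                    logger.warning("annotation for case %s vanished on clip", ann.case_id)
                    continue
                ann = Annotation(poly, ann.class_label, ann.case_id)
            clipped.append(ann)
        self.annotations = clipped


@dataclass
class PatchRecord:
    """One extracted tile: the unit of classification."""

    patch_id: str
    case_id: str
    true_class: str
    tile: np.ndarray  # (side, side, 3)
    origin_px: tuple[int, int]  # (x, y) top-left, 0-based
    side_px: int


def patch_side_px(patch_size_um: float, um_per_px: float) -> int:
    """Patch side in pixels for a physical patch size.

    Rounds half away from zero, so ``patch_side_px(100, 100/395) == 395``.
    """
    if patch_size_um <= 0 or um_per_px <= 0:
        raise ValueError("patch_size_um and um_per_px must be > 0")
    x = patch_size_um / um_per_px
    return int(np.floor(x + 0.5))


def tile_grid(
    polygon: Polygon,
    patch_size_um: float,
    um_per_px: float,
    image_bounds: tuple[int, int] | None = None,
    anchor_offset: tuple[float, float] = (0.0, 0.0),
) -> list[tuple[int, int]]:
    """Origins (x, y) of all kept tiles for one annotation polygon.

    The axis-aligned grid starts at the polygon bounding-box top-left
    (plus ``anchor_offset``), stride = patch side. A tile is kept iff its
    four corners and center are all covered by the polygon (boundary
    inclusive) and the full tile lies inside ``image_bounds`` (W, H) when
    given. Output is row-major (top-to-bottom, left-to-right).
    """
    side = patch_side_px(patch_size_um, um_per_px)
    if polygon.is_empty or polygon.area == 0:
        return []
    minx, miny, maxx, maxy = polygon.bounds
    x0 = minx + anchor_offset[0]
    y0 = miny + anchor_offset[1]
    prepared = prep(polygon)
    origins: list[tuple[int, int]] = []
    ny = int(np.floor((maxy - y0) / side))
    nx = int(np.floor((maxx - x0) / side))
    for iy in range(ny + 1):
        ty = y0 + iy * side
        if ty + side > maxy + 1e-9:
            break
        for ix in range(nx + 1):
            tx = x0 + ix * side
            if tx + side > maxx + 1e-9:
                break
            if image_bounds is not None:
                w, h = image_bounds
                if tx < 0 or ty < 0 or tx + side > w or ty + side > h:
                    continue
            probes = (
                Point(tx, ty),
                Point(tx + side, ty),
                Point(tx, ty + side),
                Point(tx + side, ty + side),
                Point(tx + side / 2.0, ty + side / 2.0),
            )
            if all(prepared.covers(p) for p in probes):
                origins.append((int(round(tx)), int(round(ty))))
    return origins


def extract_patches(
    image: AnnotatedImage,
    patch_size_um: float = DEFAULT_PATCH_SIZE_UM,
) -> tuple[list[PatchRecord], pd.DataFrame]:
    """Cut all kept tiles from every annotation of one image.

    Returns the patch records and a per-case extraction report
    (case_id, class, n_patches, below_minimum). Overlapping annotations are
    tiled independently; a pixel may appear in records of different cases.
    """
    if image.um_per_px is None:
        raise ValueError("image scale (um_per_px) is required for extraction")
    if not image.annotations:
        raise ValueError("image has no annotations")
    side = patch_side_px(patch_size_um, image.um_per_px)
    h, w = image.pixels.shape[:2]
    records: list[PatchRecord] = []
    counts: dict[str, int] = {}
    classes: dict[str, str] = {}
    for ann in image.annotations:
        origins = tile_grid(
            ann.polygon, patch_size_um, image.um_per_px, image_bounds=(w, h)
        )
        classes[ann.case_id] = ann.class_label
        counts.setdefault(ann.case_id, 0)
        for x, y in origins:
            k = counts[ann.case_id]
            records.append(
                PatchRecord(
                    patch_id=f"{ann.case_id}_{ann.class_label}_tile{k}",
                    case_id=ann.case_id,
                    true_class=ann.class_label,
                    tile=image.pixels[y : y + side, x : x + side].copy(),
                    origin_px=(x, y),
                    side_px=side,
                )
            )
            counts[ann.case_id] += 1
    report = pd.DataFrame(
        [
            {
                "case_id": cid,
                "class": classes[cid],
                "n_patches": n,
                "below_minimum": n < MIN_PATCHES_PER_CASE,
            }
            for cid, n in counts.items()
        ]
    )
    return records, report


def flag_low_patch_cases(report: pd.DataFrame, minimum: int = MIN_PATCHES_PER_CASE) -> list[str]:
    """Cases whose extracted patch count falls strictly below ``minimum``."""
    if len(report) == 0:
        raise ValueError("empty extraction report")
    mask = report["n_patches"] < minimum
    return report.loc[mask, "case_id"].tolist()


# ---------------------------------------------------------------------------
# I/O


def load_annotated_image(
    image_path: str | Path,
    geojson_path: str | Path,
    um_per_px: float,
) -> AnnotatedImage:
    """Read a PNG/TIFF image and a GeoJSON FeatureCollection of polygons.

    Each feature must carry ``case_id`` and ``class`` properties (the
    schema exported by common annotation software).
    """
    pixels = np.asarray(Image.open(image_path).convert("RGB"))
    data = json.loads(Path(geojson_path).read_text())
    annotations = []
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        annotations.append(
            Annotation(
                polygon=geom,
                class_label=props.get("class", props.get("classification", "?")),
                case_id=props.get("case_id", props.get("name", "?")),
            )
        )
    return AnnotatedImage(pixels=pixels, um_per_px=um_per_px, annotations=annotations)


def write_patches(records: list[PatchRecord], outdir: str | Path) -> pd.DataFrame:
    """Write tiles as PNG files plus a CSV index; returns the index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        path = outdir / f"{rec.patch_id}.png"
        Image.fromarray(rec.tile).save(path)
        rows.append(
            {
                "patch_id": rec.patch_id,
                "case_id": rec.case_id,
                "true_class": rec.true_class,
                "origin_x": rec.origin_px[0],
                "origin_y": rec.origin_px[1],
                "side_px": rec.side_px,
                "path": path.name,  # relative to the index file
            }
        )
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "patch_index.csv", index=False)
    return index
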