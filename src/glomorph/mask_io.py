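"""Calibrated instance-mask containers and readers/writers.

The measurement engine is mask-driven: its inputs are instance segmentation
masks of TEM images, delivered either as integer label images (PNG/TIFF) or
as COCO-style polygon annotation JSON, together with a physical calibration
(nm per pixel).  This module defines the in-memory containers
(:class:`Calibration`, :class:`LabeledInstance`, :class:`MaskSet`), the two
readers, polygon rasterization, and CSV/JSON report serialization.

Coordinate convention: 0-based ``(row, col)``, pixel centers at integer
coordinates, bounding boxes half-open.  Polygon fill rule: a pixel belongs to
the instance iff its center lies inside the polygon or on its boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon
from skimage.measure import label as _cc_label

logger = logging.getLogger(__name__)

#: Closed vocabulary of ultrastructure classes.
CLASS_LABELS = ("GBM", "FP", "EDD")


class MaskIOError(ValueError):
    """Raised for malformed mask or annotation inputs."""


@dataclass(frozen=True)
class Calibration:
    """Physical scale of one TEM image.

    Parameters
    ----------
    nm_per_pixel : float
        Physical pixel size in nanometres per pixel; must be positive.  There
        is no defensible default: it must always be supplied explicitly.
    image_width, image_height : int
        Image extent in pixels (columns, rows).
    """

    nm_per_pixel: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if not (self.nm_per_pixel > 0):
            raise MaskIOError(f"nm_per_pixel must be > 0, got {self.nm_per_pixel}")
        if self.image_width < 1 or self.image_height < 1:
            raise MaskIOError("image dimensions must be >= 1 pixel")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape as ``(rows, cols)``."""
        return (self.image_height, self.image_width)

    def px_to_nm(self, px: float) -> float:
        return px * self.nm_per_pixel

    def px2_to_nm2(self, px2: float) -> float:
        return px2 * self.nm_per_pixel**2


@dataclass
class LabeledInstance:
    """One segmented instance: a GBM ribbon, a foot process, or a deposit.

    Geometry is either a binary ``pixel_mask`` (full-frame bool array) or a
    closed ``polygon`` (N x 2 array of (row, col) vertices); at least one must
    be present.
    """

    instance_id: int
    class_label: str
    pixel_mask: np.ndarray | None = None
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise MaskIOError(
                f"instance {self.instance_id}: unknown class {self.class_label!r}; "
                f"expected one of {CLASS_LABELS}"
            )
        if self.pixel_mask is None and self.polygon is None:
            raise MaskIOError(f"instance {self.instance_id}: no geometry")
        if self.pixel_mask is not None:
            self.pixel_mask = np.asarray(self.pixel_mask, dtype=bool)
            if not self.pixel_mask.any():
                raise MaskIOError(f"instance {self.instance_id}: empty pixel set")
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise MaskIOError(
                    f"instance {self.instance_id}: polygon needs >= 3 (row, col) vertices"
                )
            # store closed (first vertex repeated at the end is stripped)
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if len(poly) < 3:
                raise MaskIOError(f"instance {self.instance_id}: degenerate polygon")
            self.polygon = poly

    @property
    def has_polygon(self) -> bool:
        return self.polygon is not None

    def area_px(self) -> float:
        """Pixel-count area for mask geometry, shoelace area for polygons."""
        if self.pixel_mask is not None:
            return float(self.pixel_mask.sum())
        return Polygon(self.polygon).area


@dataclass
class MaskSet:
    """All calibrated instances of one TEM image."""

    calibration: Calibration
    instances: list[LabeledInstance] = field(default_factory=list)
    image_id: str = ""

    def __post_init__(self) -> None:
        ids = [i.instance_id for i in self.instances]
        if len(ids) != len(set(ids)):
            raise MaskIOError(f"duplicate instance ids in image {self.image_id!r}")

    def by_class(self, class_label: str) -> list[LabeledInstance]:
        return [i for i in self.instances if i.class_label == class_label]

    def __len__(self) -> int:
        return len(self.instances)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_label_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise MaskIOError(f"{path}: expected a single-channel label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int64)
        else:
            raise MaskIOError(f"{path}: non-integer pixel values in label image")
    return arr.astype(np.int64)


def load_label_mask(
    path: str | Path,
    class_map: Mapping[int, str],
    calibration: Calibration,
    *,
    connectivity: int = 2,
    image_id: str | None = None,
) -> MaskSet:
    """Load an integer label image into a :class:`MaskSet`.

    Each connected component of pixels sharing one non-zero label value
    becomes one :class:`LabeledInstance`; label 0 is background.

    Parameters
    ----------
    class_map : mapping of label value -> class name
        Must cover every non-zero label present in the image.
    connectivity : {1, 2}
        scikit-image connectivity (2 = 8-connectivity, the default, so that
        thin diagonal GBM ribbons do not fragment).
    """
    arr = _read_label_image(path)
    if arr.shape != calibration.shape:
        raise MaskIOError(
            f"{path}: image shape {arr.shape} does not match calibration {calibration.shape}"
        )
    labels = [int(v) for v in np.unique(arr) if v != 0]
    missing = [v for v in labels if v not in class_map]
    if missing:
        raise MaskIOError(f"{path}: labels {missing} missing from class_map")
    instances: list[LabeledInstance] = []
    next_id = 1
    for value in labels:
        comp = _cc_label(arr == value, connectivity=connectivity)
        for k in range(1, comp.max() + 1):
            instances.append(
                LabeledInstance(
                    instance_id=next_id,
                    class_label=class_map[value],
                    pixel_mask=comp == k,
                )
            )
            next_id += 1
    return MaskSet(
        calibration=calibration,
        instances=instances,
        image_id=image_id if image_id is not None else Path(path).stem,
    )


def load_polygon_annotations(
    path: str | Path,
    calibration: Calibration,
    *,
    image_id: str | None = None,
) -> MaskSet:
    """Load COCO-style polygon annotations.

    The JSON layout is a dict with an ``annotations`` list; each annotation
    carries ``id``, ``category`` (one of GBM/FP/EDD, or a ``category_id``
    resolved through a top-level ``categories`` table) and ``segmentation``:
    a flat ``[c0, r0, c1, r1, ...]`` vertex list (x = column, y = row, the
    COCO convention).  Self-intersecting polygons are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    cat_table: dict[int, str] = {}
    for cat in doc.get("categories", []):
        cat_table[int(cat["id"])] = str(cat["name"])
    instances: list[LabeledInstance] = []
    for ann in doc.get("annotations", []):
        if "category" in ann:
            cls = str(ann["category"])
        else:
            cid = int(ann["category_id"])
            if cid not in cat_table:
                raise MaskIOError(f"{path}: unknown category_id {cid}")
            cls = cat_table[cid]
        if cls not in CLASS_LABELS:
            raise MaskIOError(f"{path}: unknown category {cls!r}")
        seg = np.asarray(ann["segmentation"], dtype=float)
        if seg.ndim == 2 and seg.shape[0] == 1:  # COCO wraps in a list
            seg = seg[0]
        verts = seg.reshape(-1, 2)[:, ::-1]  # (x, y) -> (row, col)
        poly = Polygon(verts)
        if not poly.is_valid:
            raise MaskIOError(
                f"{path}: instance {ann.get('id')}: self-intersecting or invalid polygon"
            )
        instances.append(
            LabeledInstance(
                instance_id=int(ann.get("id", len(instances) + 1)),
                class_label=cls,
                polygon=verts,
            )
        )
    return MaskSet(
        calibration=calibration,
        instances=instances,
        image_id=image_id if image_id is not None else str(doc.get("image_id", path.stem)),
    )


def write_polygon_annotations(mask_set: MaskSet, path: str | Path) -> None:
    """Write polygon-geometry instances back to COCO-style JSON."""
    anns = []
    for inst in mask_set.instances:
        if inst.polygon is None:
            raise MaskIOError(
                f"instance {inst.instance_id}: no polygon geometry to serialize"
            )
        flat = np.asarray(inst.polygon)[:, ::-1].ravel().tolist()  # (row,col)->(x,y)
        anns.append(
            {"id": inst.instance_id, "category": inst.class_label, "segmentation": flat}
        )
    doc = {
        "image_id": mask_set.image_id,
        "width": mask_set.calibration.image_width,
        "height": mask_set.calibration.image_height,
        "annotations": anns,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_label_mask(mask_set: MaskSet, path: str | Path) -> dict[int, str]:
    """Write instances as an integer label image; returns the label->class map.

    Each instance gets its own label value (its instance_id), so the
    round-trip through :func:`load_label_mask` recovers the same pixel sets.
    """
    arr = np.zeros(mask_set.calibration.shape, dtype=np.uint16)
    class_map: dict[int, str] = {}
    for inst in mask_set.instances:
        m = inst.pixel_mask
        if m is None:
            m = rasterize(inst, mask_set.calibration)
        arr[m] = inst.instance_id
        class_map[inst.instance_id] = inst.class_label
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)
    return class_map


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(instance: LabeledInstance, calibration: Calibration) -> np.ndarray:
    """Fill a polygon instance into a full-frame boolean mask.

    Fill rule: a pixel is included iff its center (integer (row, col)) lies
    inside the polygon or on its boundary.  Idempotent for instances that
    already carry pixel-set geometry (returned unchanged).
    """
    if instance.pixel_mask is not None:
        return instance.pixel_mask
    verts = instance.polygon
    poly = Polygon(verts)
    out = np.zeros(calibration.shape, dtype=bool)
    if poly.area == 0:
        logger.warning("instance %d: zero-area polygon rasterizes to empty", instance.instance_id)
        return out
    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())), calibration.image_height - 1)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())), calibration.image_width - 1)
    if r1 < r0 or c1 < c0:
        raise MaskIOError(f"instance {instance.instance_id}: polygon outside image bounds")
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    # intersects == inside-or-on-boundary for a point against a polygon
    inside = shapely.intersects_xy(poly, rr.ravel().astype(float), cc.ravel().astype(float))
    out[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    if not out.any():
        raise MaskIOError(f"instance {instance.instance_id}: polygon outside image bounds")
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.format_float_positional(x, precision=sig, unique=False, fractional=False))


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialize a measurement/classification report.

    ``report`` is a mapping with an optional ``"instances"`` key (list of flat
    per-instance dicts -> CSV) and arbitrary scalar/nested summary fields
    (-> JSON).  Reals are written to 6 significant digits so that a
    write/read/write cycle is byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = report.get("instances", [])
    df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(_round_sig)
    df.to_csv(path.with_suffix(".csv"), index=False)

    def _clean(obj):
        if isinstance(obj, Mapping):
            return {k: _clean(v) for k, v in obj.items() if k != "instances"}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            return _round_sig(float(obj))
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.bool_, bool)):
            return bool(obj)
        return obj

    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(_clean(report), fh, indent=1, sort_keys=True)


def read_report(path: str | Path) -> dict:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        doc = json.load(fh)
    csv_path = path.with_suffix(".csv")
    if csv_path.exists():
        df = pd.read_csv(csv_path)
        doc["instances"] = df.to_dict(orient="records")
    return doc
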