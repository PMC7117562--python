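"""Image, ROI and study-layout input/output.

Brightfield section images arrive as 8- or 16-bit TIFF or PNG, grayscale or
RGB.  Nucleus delineations arrive either as polygon ROI files (a small JSON
schema, one polygon per nucleus) or as an integer label-mask raster with a
companion CSV class table.  Every nucleus is tagged ``control`` (lymphocyte,
the internal diploid reference) or ``epithelial`` (the measured population).

Geometry conventions
--------------------
Pixel coordinates are 0-based ``(row, col)``; pixel centers sit at integer
coordinates.  Polygons are closed vertex lists in ``(x=col, y=row)`` order.
A pixel belongs to a polygon iff its *center* lies inside under the even-odd
rule.  With these conventions a polygon and the label mask it rasterizes to
are interchangeable representations of the same nucleus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LineString, Polygon as _ShapelyPolygon

__all__ = [
    "ImagePlane",
    "NucleusROI",
    "StudyLayout",
    "SampleEntry",
    "OverlapReport",
    "ValidationError",
    "CONTROL",
    "EPITHELIAL",
    "load_image",
    "save_image",
    "load_rois",
    "save_rois",
    "check_nonoverlap",
    "rasterize_polygon",
    "load_layout",
    "save_layout",
]

CONTROL = "control"
EPITHELIAL = "epithelial"
_CLASSES = (CONTROL, EPITHELIAL)

# ITU-R BT.601 luminance weights for RGB -> gray reduction
_LUMA = np.array([0.299, 0.587, 0.114])
_CHANNELS = {"red": 0, "green": 1, "blue": 2}


class ValidationError(ValueError):
    """Raised when an input file or geometry violates the format contract."""


@dataclass(frozen=True)
class ImagePlane:
    """A single 2-D intensity raster, the densitometry substrate.

    Attributes
    ----------
    pixels
        2-D array of non-negative integer intensities.
    bit_depth
        8 or 16; pixel values never exceed ``2**bit_depth - 1``.
    white_level
        Reference intensity for full transmission (blank field), in the
        same units as ``pixels``.  Defaults to the bit-depth maximum.
    """

    pixels: np.ndarray
    bit_depth: int
    white_level: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("image must be a non-empty 2-D raster")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"unsupported bit depth {self.bit_depth}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValidationError("pixel values outside bit-depth range")
        if not self.white_level > 0:
            raise ValidationError("white_level must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class NucleusROI:
    """One delineated nucleus: a polygon or a label-mask region, plus class.

    Exactly one of ``polygon`` (N x 2 array of (x, y) vertices) or ``mask``
    (boolean raster) is set.
    """

    id: str
    cell_class: Literal["control", "epithelial"]
    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_class not in _CLASSES:
            raise ValidationError(
                f"ROI {self.id!r}: cell_class must be one of {_CLASSES}, "
                f"got {self.cell_class!r}"
            )
        if (self.polygon is None) == (self.mask is None):
            raise ValidationError(
                f"ROI {self.id!r}: exactly one of polygon or mask required"
            )
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValidationError(
                    f"ROI {self.id!r}: polygon needs >= 3 (x, y) vertices"
                )
            _check_simple(poly, self.id)
            object.__setattr__(self, "polygon", poly)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.ndim != 2 or not m.any():
                raise ValidationError(f"ROI {self.id!r}: empty mask")
            object.__setattr__(self, "mask", m)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this nucleus on a raster of the given shape."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValidationError(
                    f"ROI {self.id!r}: mask shape {self.mask.shape} != {shape}"
                )
            return self.mask
        m = rasterize_polygon(self.polygon, shape)
        if not m.any():
            raise ValidationError(f"ROI {self.id!r}: rasterizes to zero pixels")
        return m


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    condition: str
    image_path: str
    roi_path: str


@dataclass(frozen=True)
class StudyLayout:
    """Maps sample ids to condition groups and their on-disk files."""

    samples: tuple[SampleEntry, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("condition labels must be unique")
        known = set(self.conditions)
        seen: set[str] = set()
        for s in self.samples:
            if s.condition not in known:
                raise ValidationError(
                    f"sample {s.sample_id!r}: unknown condition {s.condition!r}"
                )
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample id {s.sample_id!r}")
            seen.add(s.sample_id)


@dataclass(frozen=True)
class OverlapReport:
    """Result of the non-overlap check: pixels claimed by >= 2 ROIs."""

    ok: bool
    # (row, col) -> tuple of ROI ids claiming that pixel
    violations: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return len(self.violations)

    def involved_rois(self) -> set[str]:
        out: set[str] = set()
        for ids in self.violations.values():
            out.update(ids)
        return out


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def load_image(
    path: str | Path,
    channel_policy: str = "luminance",
    white_level: float | None = None,
) -> ImagePlane:
    """Read an 8/16-bit grayscale or RGB TIFF/PNG as one intensity plane.

    RGB images are reduced to a single plane according to ``channel_policy``:
    ``"luminance"`` (ITU-R 601 weights, rounded back to integers) or a named
    channel (``"red" | "green" | "blue"``).  ``white_level`` defaults to the
    bit-depth maximum.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap reader-specific errors
        raise ValidationError(f"unreadable image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"empty image {path}")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValidationError(
            f"unsupported pixel type {arr.dtype} in {path}; need uint8/uint16"
        )

    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValidationError(f"unsupported channel count {arr.shape[2]}")
        rgb = arr[:, :, :3].astype(np.float64)
        if channel_policy == "luminance":
            plane = np.rint(rgb @ _LUMA).astype(arr.dtype)
        elif channel_policy in _CHANNELS:
            plane = arr[:, :, _CHANNELS[channel_policy]]
        else:
            raise ValidationError(f"unknown channel_policy {channel_policy!r}")
    elif arr.ndim == 2:
        plane = arr
    else:
        raise ValidationError(f"unsupported image dimensionality {arr.ndim}")

    if white_level is None:
        white_level = float(2**bit_depth - 1)
    return ImagePlane(pixels=plane, bit_depth=bit_depth, white_level=white_level)


def save_image(path: str | Path, plane: ImagePlane) -> None:
    """Write an ImagePlane to TIFF or PNG, preserving bit depth exactly."""
    path = Path(path)
    dtype = np.uint8 if plane.bit_depth == 8 else np.uint16
    data = plane.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


# ---------------------------------------------------------------------------
# Polygon geometry
# ---------------------------------------------------------------------------

def _check_simple(poly: np.ndarray, roi_id: str) -> None:
    """Reject self-intersecting (non-simple) polygons."""
    ring = np.vstack([poly, poly[:1]])
    if not LineString(ring).is_simple:
        raise ValidationError(f"ROI {roi_id!r}: polygon is self-intersecting")
    if _ShapelyPolygon(poly).area <= 0:
        raise ValidationError(f"ROI {roi_id!r}: polygon has zero area")


def rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd pixel-center rasterization of a closed polygon.

    A pixel (row r, col c) is inside iff the point (x=c, y=r) is inside the
    polygon by ray casting with the standard half-open edge rule, which keeps
    the result deterministic for centers lying exactly on an edge.
    """
    poly = np.asarray(poly, dtype=float)
    h, w = shape
    c0 = max(int(np.floor(poly[:, 0].min())), 0)
    c1 = min(int(np.ceil(poly[:, 0].max())), w - 1)
    r0 = max(int(np.floor(poly[:, 1].min())), 0)
    r1 = min(int(np.ceil(poly[:, 1].max())), h - 1)
    out = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return out
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    px = cols.ravel().astype(float)
    py = rows.ravel().astype(float)

    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for xa, ya, xb, yb in zip(x1, y1, x2, y2):
        if ya == yb:
            continue  # horizontal edges never cross a horizontal ray
        crosses = (ya > py) != (yb > py)
        if not crosses.any():
            continue
        xint = xa + (py - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (px < xint)
    out[py.astype(int)[inside], px.astype(int)[inside]] = True
    return out


# ---------------------------------------------------------------------------
# ROI files
# ---------------------------------------------------------------------------

def load_rois(
    path: str | Path,
    class_table: str | Path | None = None,
    raster_shape: tuple[int, int] | None = None,
    on_overlap: str = "error",
) -> list[NucleusROI]:
    """Read nucleus ROIs from a polygon JSON file or an integer label mask.

    Parameters
    ----------
    path
        Either a ``.json`` polygon file with schema
        ``{"rois": [{"id", "cell_class", "polygon": [[x, y], ...]}, ...]}``
        or an integer-label TIFF; the latter requires ``class_table``, a CSV
        with columns ``label,cell_class``.
    raster_shape
        If given, overlap between ROIs is checked on that raster.
    on_overlap
        ``"error"`` (default) raises on overlapping ROIs; ``"warn"`` emits a
        warning and keeps going; ``"ignore"`` skips the check.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rois = _load_polygon_json(path)
    else:
        rois = _load_label_mask(path, class_table)
    if raster_shape is not None and on_overlap != "ignore":
        report = check_nonoverlap(rois, raster_shape)
        if not report.ok:
            msg = (
                f"{report.n_pixels} pixel(s) shared by ROIs "
                f"{sorted(report.involved_rois())}"
            )
            if on_overlap == "error":
                raise ValidationError(f"overlapping ROIs in {path}: {msg}")
            import warnings

            warnings.warn(f"overlapping ROIs in {path}: {msg}", stacklevel=2)
    return rois


def _load_polygon_json(path: Path) -> list[NucleusROI]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed ROI JSON {path}: {exc}") from exc
    if not isinstance(doc, dict) or "rois" not in doc:
        raise ValidationError(f"{path}: expected a top-level 'rois' list")
    rois: list[NucleusROI] = []
    seen: set[str] = set()
    for rec in doc["rois"]:
        missing = {"id", "cell_class", "polygon"} - rec.keys()
        if missing:
            raise ValidationError(f"{path}: ROI record missing {sorted(missing)}")
        rid = str(rec["id"])
        if rid in seen:
            raise ValidationError(f"{path}: duplicate ROI id {rid!r}")
        seen.add(rid)
        rois.append(
            NucleusROI(id=rid, cell_class=rec["cell_class"],
                       polygon=np.asarray(rec["polygon"], dtype=float))
        )
    return rois


def _load_label_mask(path: Path, class_table: str | Path | None) -> list[NucleusROI]:
    if class_table is None:
        raise ValidationError("label-mask ROIs need a class_table CSV")
    labels = tifffile.imread(path)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValidationError(f"{path}: label mask must be an integer raster")
    table = pd.read_csv(class_table)
    if not {"label", "cell_class"} <= set(table.columns):
        raise ValidationError(f"{class_table}: need columns label,cell_class")
    classes = dict(zip(table["label"].astype(int), table["cell_class"]))
    rois: list[NucleusROI] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        lab = int(lab)
        if lab not in classes:
            raise ValidationError(f"label {lab} has no cell_class entry")
        rois.append(
            NucleusROI(id=str(lab), cell_class=str(classes[lab]),
                       mask=labels == lab)
        )
    return rois


def save_rois(path: str | Path, rois: Iterable[NucleusROI]) -> None:
    """Write polygon ROIs to the JSON schema (masks are not serialized)."""
    recs = []
    for roi in rois:
        if roi.polygon is None:
            raise ValidationError(
                f"ROI {roi.id!r} is mask-based; convert to polygon first"
            )
        recs.append(
            {
                "id": roi.id,
                "cell_class": roi.cell_class,
                "polygon": [[float(x), float(y)] for x, y in roi.polygon],
            }
        )
    Path(path).write_text(json.dumps({"rois": recs}, indent=1))


def check_nonoverlap(
    rois: Sequence[NucleusROI], raster_shape: tuple[int, int]
) -> OverlapReport:
    """Report every pixel claimed by two or more ROIs.

    Delineated nuclei must be non-overlapping for densitometry: a shared
    pixel would contribute its optical density to two different cells.
    """
    count = np.zeros(raster_shape, dtype=np.int32)
    masks: list[tuple[str, np.ndarray]] = []
    for roi in rois:
        m = roi.rasterize(raster_shape)
        masks.append((roi.id, m))
        count += m
    bad = np.argwhere(count >= 2)
    if bad.size == 0:
        return OverlapReport(ok=True)
    violations: dict[tuple[int, int], tuple[str, ...]] = {}
    for r, c in map(tuple, bad):
        owners = tuple(rid for rid, m in masks if m[r, c])
        violations[(int(r), int(c))] = owners
    return OverlapReport(ok=False, violations=violations)


# ---------------------------------------------------------------------------
# Study layout
# ---------------------------------------------------------------------------

_LAYOUT_COLS = ["sample_id", "condition", "image_path", "roi_path"]


def load_layout(path: str | Path, conditions: Sequence[str] | None = None) -> StudyLayout:
    """Read a study layout CSV (columns sample_id,condition,image_path,roi_path).

    Condition order defaults to first appearance in the file.
    """
    df = pd.read_csv(path, comment="#")
    if not set(_LAYOUT_COLS) <= set(df.columns):
        raise ValidationError(f"{path}: layout needs columns {_LAYOUT_COLS}")
    if len(df) == 0:
        raise ValidationError(f"{path}: layout is empty")
    samples = tuple(
        SampleEntry(str(r.sample_id), str(r.condition), str(r.image_path), str(r.roi_path))
        for r in df.itertuples()
    )
    if conditions is None:
        conditions = tuple(dict.fromkeys(s.condition for s in samples))
    return StudyLayout(samples=samples, conditions=tuple(conditions))


def save_layout(path: str | Path, layout: StudyLayout) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.condition, s.image_path, s.roi_path) for s in layout.samples],
        columns=_LAYOUT_COLS,
    )
    df.to_csv(path, index=False)
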