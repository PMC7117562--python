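"""Feulgen densitometry: optical density maps and per-nucleus IOD.

The Feulgen reaction stains DNA stoichiometrically, so under Beer-Lambert
absorption the optical density of a pixel,

    OD(p) = -10 * log10(p / white_level),

is proportional to the local chromophore (hence DNA) amount, and the
*integrated* optical density of a nucleus,

    IOD = sum over nucleus pixels of OD(p),

is proportional to the cell's total DNA content.  The factor 10 is the
conventional densitometry scale; any constant factor cancels later in the
DNA index, which is a ratio of IODs.

``white_level`` is the blank (full-transmission) intensity.  It defaults to
the bit-depth maximum, or can be estimated from the modal background
intensity of the slide, or given as a number.  Dark pixels are clamped at
``epsilon * white_level`` to keep OD finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .roi_io import CONTROL, EPITHELIAL, ImagePlane, NucleusROI, check_nonoverlap

__all__ = [
    "ODMap",
    "NucleusMeasurement",
    "MeasurementWarning",
    "DEFAULT_EPSILON",
    "DEFAULT_MIN_AREA",
    "resolve_white_level",
    "to_optical_density",
    "integrated_optical_density",
    "measure_sample",
]

DEFAULT_EPSILON = 1e-4
DEFAULT_MIN_AREA = 10

# operator-workload guidance from the measurement protocol
EXPECTED_CONTROLS = 30
EXPECTED_EPITHELIAL = (150, 200)


class MeasurementWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ODMap:
    """Per-pixel optical density (x10 scale) with its white reference."""

    od: np.ndarray
    white_level: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape


@dataclass(frozen=True)
class NucleusMeasurement:
    """Per-nucleus integrated optical density and derived quantities."""

    roi_id: str
    cell_class: str
    area_px: int
    iod: float
    mean_od: float


def resolve_white_level(image: ImagePlane, policy: str | float = "max") -> float:
    """Turn a white-level policy into a number.

    ``"max"``    -> the bit-depth maximum (2**bit_depth - 1).
    ``"background"`` -> the modal pixel intensity of the image (slides are
    mostly clear background, so the histogram mode is the blank level).
    A number is used as-is.
    """
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        wl = float(policy)
    elif policy == "max":
        wl = float(2**image.bit_depth - 1)
    elif policy == "background":
        counts = np.bincount(image.pixels.ravel().astype(np.int64),
                             minlength=2**image.bit_depth)
        wl = float(np.argmax(counts))
    else:
        raise ValueError(f"unknown white_level policy {policy!r}")
    if wl <= 0:
        raise ValueError("white_level must be positive")
    return wl


def to_optical_density(
    image: ImagePlane,
    white_level: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> ODMap:
    """Convert an intensity raster to a map of -10*log10(p / white_level).

    Pixels at ``white_level`` map to OD 0; OD decreases strictly with
    increasing intensity.  Pixels below ``epsilon * white_level`` (including
    zeros) are clamped there, capping OD at ``-10*log10(epsilon)``.
    """
    wl = float(white_level) if white_level is not None else image.white_level
    if wl <= 0:
        raise ValueError("white_level must be positive")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    trans = np.maximum(image.pixels.astype(np.float64), epsilon * wl) / wl
    od = -10.0 * np.log10(trans)
    return ODMap(od=od, white_level=wl)


def integrated_optical_density(
    od_map: ODMap,
    roi: NucleusROI,
    min_area: int = DEFAULT_MIN_AREA,
) -> NucleusMeasurement:
    """Sum the OD map over exactly the ROI's pixel set.

    Additive over disjoint pixel subsets and blind to every pixel outside
    the ROI.  Rejects degenerate delineations below ``min_area`` pixels.
    """
    mask = roi.rasterize(od_map.shape)
    if roi.polygon is not None:
        poly = roi.polygon
        h, w = od_map.shape
        if (poly[:, 0].min() < -0.5 or poly[:, 0].max() > w - 0.5
                or poly[:, 1].min() < -0.5 or poly[:, 1].max() > h - 0.5):
            raise ValueError(f"ROI {roi.id!r} extends outside the image")
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"ROI {roi.id!r} rasterizes to zero pixels")
    if area < min_area:
        raise ValueError(
            f"ROI {roi.id!r}: area {area} px below minimum {min_area}"
        )
    iod = float(od_map.od[mask].sum())
    return NucleusMeasurement(
        roi_id=roi.id,
        cell_class=roi.cell_class,
        area_px=area,
        iod=iod,
        mean_od=iod / area,
    )


def measure_sample(
    image: ImagePlane,
    rois: Sequence[NucleusROI],
    white_level: str | float = "max",
    epsilon: float = DEFAULT_EPSILON,
    min_area: int = DEFAULT_MIN_AREA,
    on_overlap: str = "error",
) -> list[NucleusMeasurement]:
    """Measure IOD for every nucleus ROI on one slide image.

    Warns when the delineation falls short of the measurement protocol
    (fewer than 30 lymphocyte controls, or an epithelial count outside
    150-200).  Zero control ROIs is an error: without the internal diploid
    reference no DNA index can be formed downstream.
    """
    if on_overlap != "ignore":
        report = check_nonoverlap(rois, image.shape)
        if not report.ok:
            msg = (
                f"{report.n_pixels} pixel(s) shared by ROIs "
                f"{sorted(report.involved_rois())}"
            )
            if on_overlap == "error":
                raise ValueError(f"overlapping ROIs: {msg}")
            warnings.warn(msg, MeasurementWarning, stacklevel=2)

    n_ctrl = sum(1 for r in rois if r.cell_class == CONTROL)
    n_epi = sum(1 for r in rois if r.cell_class == EPITHELIAL)
    if n_ctrl == 0:
        raise ValueError("no control ROIs: DI normalization impossible")
    if n_ctrl < EXPECTED_CONTROLS:
        warnings.warn(
            f"only {n_ctrl} control nuclei (protocol expects "
            f"{EXPECTED_CONTROLS}); modal IOD may be unstable",
            MeasurementWarning, stacklevel=2,
        )
    lo, hi = EXPECTED_EPITHELIAL
    if not lo <= n_epi <= hi:
        warnings.warn(
            f"{n_epi} epithelial nuclei outside the protocol range {lo}-{hi}",
            MeasurementWarning, stacklevel=2,
        )

    od_map = to_optical_density(
        image, white_level=resolve_white_level(image, white_level), epsilon=epsilon
    )
    return [integrated_optical_density(od_map, roi, min_area=min_area) for roi in rois]
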