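"""Vessel-lumen segmentation and region measurements on stem sections.

A stained transverse section shows vessel lumens as dark, roughly
elliptical holes in a lighter xylem matrix.  Segmentation is classical:
optional Gaussian smoothing, a global threshold (Otsu by default) below
which pixels count as lumen, connected-component labelling, and a
minimum-lumen-area filter to reject tracheid-scale noise.  Physical
units are attached at measurement time: lumen area VA in square
micrometres is pixel count times ``pixel_size**2`` and the vessel
diameter is that of the circle of equal area, ``d = 2 sqrt(VA / pi)``.

Sections are partitioned into two lateral (L1, L2) and two dorso-ventral
(DV1, DV2) sectors, each holding several pure-xylem areas (Xy) delimited
by parenchymatic bands, phloem and pith; a vessel belongs to the Xy that
owns its centroid pixel in the label map.

Necrosis on graft-union sections is the dark-pixel fraction of a region
of interest; the default ROI rule is a horizontal band of width equal to
a quarter of the sample diameter, centred on the graft line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, segmentation

from .errors import InvalidInputError

__all__ = [
    "VesselRecord",
    "XylemRegion",
    "NecrosisMeasurement",
    "SegmentationParams",
    "equivalent_diameter",
    "segment_vessel_lumens",
    "assign_sectors",
    "regions_from_label_map",
    "quarter_diameter_roi",
    "measure_necrosis_fraction",
]


@dataclass(frozen=True)
class VesselRecord:
    """One segmented vessel lumen."""

    vessel_id: int
    centroid_rc: tuple[float, float]  # (row, col), 0-indexed pixels
    lumen_area_um2: float
    diameter_um: float
    sector: str | None = None  # L1, L2, DV1, DV2
    xy_id: int | None = None

    def __post_init__(self) -> None:
        if self.lumen_area_um2 <= 0:
            raise InvalidInputError("lumen area must be > 0")


@dataclass(frozen=True)
class XylemRegion:
    """One pure-xylem (Xy) area of a section."""

    xy_id: int
    sector: str
    area_um2: float
    vessel_ids: tuple[int, ...] = ()
    frame_area_um2: float | None = None

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise InvalidInputError("Xy area must be > 0")


@dataclass(frozen=True)
class NecrosisMeasurement:
    roi_area_um2: float
    necrotic_area_um2: float
    threshold: float

    @property
    def percent_necrosis(self) -> float:
        return 100.0 * self.necrotic_area_um2 / self.roi_area_um2


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the lumen segmentation.

    threshold : intensity below which a pixel is lumen; None = lowest
        cut of a 3-class multi-Otsu (lumens are the darkest of several
        tissue classes, so plain 2-class Otsu would merge tissue with
        lumens).
    min_lumen_area_um2 : objects below this physical area are discarded
        (default 20 um^2, tracheid-scale).
    smooth_sigma : Gaussian pre-smoothing in pixels (0 disables).
    clear_border : drop lumens touching the image border.
    """

    threshold: float | None = None
    min_lumen_area_um2: float = 20.0
    smooth_sigma: float = 1.0
    clear_border: bool = True


def equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the given area: ``2 sqrt(A / pi)``."""
    if not (area_um2 > 0) or not math.isfinite(area_um2):
        raise InvalidInputError(f"area must be finite and > 0, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def segment_vessel_lumens(
    image: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> list[VesselRecord]:
    """Segment dark vessel lumens in a single-channel section image.

    Returns one :class:`VesselRecord` per detected lumen (sector and
    xy_id unassigned).  An empty or flat image yields an empty list.
    """
    if pixel_size_um <= 0:
        raise InvalidInputError(f"pixel size must be > 0, got {pixel_size_um}")
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=-1)  # RGB -> luminance
    if img.ndim != 2:
        raise InvalidInputError("image must be 2-D (or RGB with trailing channel)")
    params = params or SegmentationParams()

    img = img.astype(float)
    if img.size == 0 or np.ptp(img) == 0:
        return []
    if params.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.smooth_sigma)
    if params.threshold is not None:
        thr = params.threshold
    else:
        try:
            thr = filters.threshold_multiotsu(img, classes=3)[0]
        except ValueError:  # fewer than 3 distinct grey levels
            thr = filters.threshold_otsu(img)
    mask = img < thr
    if not mask.any():
        return []
    if params.clear_border:
        mask = segmentation.clear_border(mask)
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    min_px = params.min_lumen_area_um2 / px_area
    records = []
    vid = 0
    for prop in measure.regionprops(labels):
        if prop.area < min_px:
            continue
        vid += 1
        area_um2 = float(prop.area) * px_area
        records.append(
            VesselRecord(
                vessel_id=vid,
                centroid_rc=(float(prop.centroid[0]), float(prop.centroid[1])),
                lumen_area_um2=area_um2,
                diameter_um=equivalent_diameter(area_um2),
            )
        )
    return records


def assign_sectors(
    records: Sequence[VesselRecord],
    label_map: np.ndarray,
    sector_of_label: dict[int, str],
    image_shape: tuple[int, int] | None = None,
) -> list[VesselRecord]:
    """Fill sector and xy_id from the Xy label map.

    ``label_map`` holds 0 for non-xylem pixels and positive Xy ids
    elsewhere; ``sector_of_label`` maps each Xy id to its sector name.
    The label map is authoritative: a centroid exactly on a boundary
    belongs to whatever region owns that pixel.  Vessels whose centroid
    falls outside every Xy stay unassigned (sector None) and are excluded
    from per-Xy statistics downstream.
    """
    label_map = np.asarray(label_map)
    if label_map.ndim != 2:
        raise InvalidInputError("label map must be 2-D")
    if image_shape is not None and tuple(image_shape) != label_map.shape:
        raise InvalidInputError(
            f"label map shape {label_map.shape} does not match image shape {tuple(image_shape)}"
        )
    out = []
    nr, nc = label_map.shape
    for rec in records:
        r = int(round(rec.centroid_rc[0]))
        c = int(round(rec.centroid_rc[1]))
        if not (0 <= r < nr and 0 <= c < nc):
            out.append(replace(rec, sector=None, xy_id=None))
            continue
        lab = int(label_map[r, c])
        if lab > 0 and lab in sector_of_label:
            out.append(replace(rec, sector=sector_of_label[lab], xy_id=lab))
        else:
            out.append(replace(rec, sector=None, xy_id=None))
    return out


def regions_from_label_map(
    label_map: np.ndarray,
    sector_of_label: dict[int, str],
    pixel_size_um: float,
    records: Sequence[VesselRecord] = (),
) -> list[XylemRegion]:
    """Build :class:`XylemRegion` objects (areas in um^2) from a label map."""
    if pixel_size_um <= 0:
        raise InvalidInputError("pixel size must be > 0")
    label_map = np.asarray(label_map)
    px_area = pixel_size_um**2
    frame = float(label_map.size) * px_area
    vessels_by_xy: dict[int, list[int]] = {}
    for rec in records:
        if rec.xy_id is not None:
            vessels_by_xy.setdefault(rec.xy_id, []).append(rec.vessel_id)
    regions = []
    labels, counts = np.unique(label_map[label_map > 0], return_counts=True)
    for lab, cnt in zip(labels, counts):
        lab = int(lab)
        if lab not in sector_of_label:
            raise InvalidInputError(f"label {lab} missing from sector table")
        regions.append(
            XylemRegion(
                xy_id=lab,
                sector=sector_of_label[lab],
                area_um2=float(cnt) * px_area,
                vessel_ids=tuple(vessels_by_xy.get(lab, ())),
                frame_area_um2=frame,
            )
        )
    return regions


def quarter_diameter_roi(
    image_shape: tuple[int, int],
    sample_mask: np.ndarray | None = None,
    graft_line_row: float | None = None,
) -> np.ndarray:
    """ROI for necrosis: a horizontal band of height = sample diameter / 4,
    centred on the graft line (default: the image mid-row), intersected
    with the sample mask when one is given."""
    nr, nc = image_shape
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, dtype=bool)
        if sample_mask.shape != (nr, nc):
            raise InvalidInputError("sample mask shape mismatch")
        rows = np.where(sample_mask.any(axis=1))[0]
        if rows.size == 0:
            raise InvalidInputError("empty sample mask")
        diameter = rows[-1] - rows[0] + 1
    else:
        diameter = nr
    centre = (nr - 1) / 2.0 if graft_line_row is None else float(graft_line_row)
    half = diameter / 8.0  # band height is diameter/4
    roi = np.zeros((nr, nc), dtype=bool)
    lo = max(0, int(round(centre - half)))
    hi = min(nr, int(round(centre + half)))
    roi[lo:hi, :] = True
    if sample_mask is not None:
        roi &= sample_mask
    return roi


def measure_necrosis_fraction(
    image: np.ndarray,
    roi: np.ndarray,
    pixel_size_um: float = 1.0,
    intensity_threshold: float | None = None,
) -> NecrosisMeasurement:
    """Dark-pixel fraction of the ROI.

    Necrotic tissue is darker than healthy tissue; pixels strictly below
    the threshold count as necrotic.  With ``intensity_threshold=None``
    the threshold is Otsu's on the ROI histogram — appropriate when both
    phases are present; pass a fixed threshold for reproducible batch
    measurements or single-phase ROIs.
    """
    if pixel_size_um <= 0:
        raise InvalidInputError("pixel size must be > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise InvalidInputError("ROI shape does not match image")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise InvalidInputError("empty ROI")
    vals = img[roi]
    if intensity_threshold is None:
        if np.ptp(vals) == 0:
            # single-phase ROI: nothing darker than the rest
            thr = float(vals[0])
        else:
            thr = float(filters.threshold_otsu(vals))
    else:
        thr = float(intensity_threshold)
    dark = int(np.count_nonzero(vals < thr))
    px_area = pixel_size_um**2
    return NecrosisMeasurement(
        roi_area_um2=n_roi * px_area,
        necrotic_area_um2=dark * px_area,
        threshold=thr,
    )
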