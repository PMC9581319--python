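"""Seeded generators for every input of the analysis pipeline.

The study's raw inputs (stained cross-section micrographs, biweekly
height series, graft-union sections) are not deposited, so each is
emulated with known ground truth:

* :func:`render_xylem_section` draws a stem cross-section — pith,
  xylem annulus crossed by radial parenchymatic bands, phloem ring —
  with non-overlapping elliptical vessel lumens, and returns the image
  together with the vessel records, a vessel label map and the Xy
  (pure-xylem area) label map split into two lateral (L) and two
  dorso-ventral (DV) sectors.
* :func:`simulate_growth_series` draws replicate logistic growth curves
  with additive Gaussian measurement noise.
* :func:`render_graft_union_image` draws a graft section whose dark
  necrotic blob covers an exactly known fraction of the quarter-diameter
  ROI.
* :func:`generate_study_dataset` draws a balanced two-factor replicate
  table from per-cell true means and SDs.

Every generator is a pure function of its spec (the seed lives in the
spec), so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, PlacementError, UnsupportedDesignError
from .growth import GrowthSeries, LogisticParams, logistic_value
from .morphometry import VesselRecord, equivalent_diameter

__all__ = [
    "VesselPopulationSpec",
    "SectionImageSpec",
    "SectionGroundTruth",
    "GrowthSimSpec",
    "GraftUnionImageSpec",
    "StudyDesignSpec",
    "draw_vessel_diameters",
    "render_xylem_section",
    "simulate_growth_series",
    "render_graft_union_image",
    "generate_study_dataset",
    "preset_section_spec",
    "SECTION_PRESETS",
]

# 8-bit intensity palette of the rendered section
_I_BACKGROUND = 230
_I_PITH = 180
_I_PHLOEM = 160
_I_BAND = 200
_I_XYLEM = 150
_I_LUMEN = 40

_SECTORS = ("DV1", "L1", "DV2", "L2")  # quadrants starting at 45 deg
_WALL_MARGIN_PX = 2  # minimum wall distance between lumens
_MAX_RETRIES = 10_000


@dataclass(frozen=True)
class VesselPopulationSpec:
    """Diameter distribution and density of a vessel population.

    ``location_um`` is the distribution median (lognormal), Weibull scale,
    or the small-mode median of a two-mode lognormal mixture; ``scale``
    the log-SD (lognormal/mixture) or Weibull shape.  ``scale == 0``
    degenerates to a point mass at ``location_um``.
    """

    family: str = "lognormal"  # lognormal | weibull | mixture
    location_um: float = 26.0
    scale: float = 0.12
    location2_um: float | None = None  # large mode of the mixture
    scale2: float | None = None
    mix_weight: float = 0.5  # probability of the large mode
    target_density_mm2: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "weibull", "mixture"):
            raise InvalidInputError(f"unknown distribution family {self.family!r}")
        if self.target_density_mm2 <= 0:
            raise InvalidInputError("target density must be > 0")
        if self.location_um <= 0 or self.scale < 0:
            raise InvalidInputError("location must be > 0 and scale >= 0")
        if self.family == "mixture":
            if self.location2_um is None or self.scale2 is None:
                raise InvalidInputError("mixture needs location2_um and scale2")
            if not 0 <= self.mix_weight <= 1:
                raise InvalidInputError("mix_weight must be in [0, 1]")


def _draw(spec: VesselPopulationSpec, count: int, rng: np.random.Generator) -> np.ndarray:
    if count == 0:
        return np.empty(0)
    if spec.family == "lognormal":
        if spec.scale == 0:
            return np.full(count, spec.location_um)
        return spec.location_um * np.exp(spec.scale * rng.standard_normal(count))
    if spec.family == "weibull":
        if spec.scale == 0:
            return np.full(count, spec.location_um)
        return spec.location_um * rng.weibull(spec.scale, count)
    # mixture of two lognormal modes
    large = rng.random(count) < spec.mix_weight
    d = np.where(
        large,
        (spec.location2_um or 1.0) * np.exp((spec.scale2 or 0.0) * rng.standard_normal(count)),
        spec.location_um * np.exp(spec.scale * rng.standard_normal(count)),
    )
    return d


def draw_vessel_diameters(
    spec: VesselPopulationSpec, xylem_area_mm2: float
) -> np.ndarray:
    """Draw ``round(target_density * area)`` vessel diameters (um)."""
    if xylem_area_mm2 <= 0:
        raise InvalidInputError(f"xylem area must be > 0, got {xylem_area_mm2}")
    count = int(round(spec.target_density_mm2 * xylem_area_mm2))
    rng = np.random.default_rng(spec.seed)
    d = _draw(spec, count, rng)
    if d.size and (np.any(~np.isfinite(d)) or np.any(d <= 0)):
        raise InvalidInputError("drawn diameters must be positive and finite")
    return d


@dataclass(frozen=True)
class SectionImageSpec:
    """Geometry, vessel population and noise of a rendered cross-section."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 1.0
    pith_radius_um: float = 100.0
    phloem_width_um: float = 60.0
    xy_per_quadrant: int = 5  # parenchymatic bands per quadrant (4-6 Xy areas)
    band_width_um: float = 20.0
    vessels: VesselPopulationSpec = field(default_factory=VesselPopulationSpec)
    noise_sigma: float = 0.0  # additive Gaussian, 8-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise InvalidInputError("pixel size must be > 0")
        if not 4 <= self.xy_per_quadrant <= 6:
            raise InvalidInputError("each quadrant must hold 4-6 xylem areas")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")
        if min(self.width_px, self.height_px) < 128:
            raise InvalidInputError("image too small to render a section")


@dataclass(frozen=True)
class SectionGroundTruth:
    """Rendered section with full annotations."""

    image: np.ndarray            # uint8 grayscale
    records: tuple[VesselRecord, ...]
    vessel_label_map: np.ndarray  # uint16, 0 background
    xy_label_map: np.ndarray      # uint16, 0 non-xylem
    sector_of_label: dict[int, str]
    spec: SectionImageSpec

    @property
    def xylem_area_um2(self) -> float:
        return float(np.count_nonzero(self.xy_label_map)) * self.spec.pixel_size_um**2


def _section_geometry(spec: SectionImageSpec):
    """Polar scaffold: xy label map, sector table and tissue masks."""
    h, w = spec.height_px, spec.width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)  # px
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0

    px = spec.pixel_size_um
    stem_r = 0.95 * min(h, w) / 2.0
    phloem_w = spec.phloem_width_um / px
    pith_r = spec.pith_radius_um / px
    xyl_outer = stem_r - phloem_w
    if xyl_outer <= pith_r + 20:
        raise InvalidInputError("geometry leaves no xylem annulus")

    stem = r < stem_r
    pith = r < pith_r
    phloem = stem & (r >= xyl_outer)
    annulus = (r >= pith_r) & (r < xyl_outer)

    n_xy = 4 * spec.xy_per_quadrant
    spacing = 360.0 / n_xy
    rel = (theta - 45.0) % 360.0
    wedge = np.floor(rel / spacing).astype(int)  # 0 .. n_xy-1
    phase = rel % spacing
    ang_dist = np.minimum(phase, spacing - phase)  # deg to nearest band ray
    lin_dist = r * np.radians(ang_dist)
    band = annulus & (lin_dist < (spec.band_width_um / px) / 2.0)

    xy_map = np.zeros((h, w), dtype=np.uint16)
    xy_map[annulus & ~band] = wedge[annulus & ~band] + 1

    sector_of_label = {}
    for i in range(n_xy):
        centre_angle = (45.0 + (i + 0.5) * spacing) % 360.0
        quadrant = int(((centre_angle - 45.0) % 360.0) // 90.0)
        sector_of_label[i + 1] = _SECTORS[quadrant]

    masks = {"stem": stem, "pith": pith, "phloem": phloem, "band": band,
             "annulus": annulus}
    return xy_map, sector_of_label, masks


def _ellipse_offsets(a: float, b: float, angle: float, margin: float = 0.0):
    """Integer pixel offsets covered by an ellipse (+margin) at the origin."""
    rmax = int(math.ceil(max(a, b) + margin)) + 1
    dy, dx = np.mgrid[-rmax : rmax + 1, -rmax : rmax + 1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / (a + margin)) ** 2 + (v / (b + margin)) ** 2 <= 1.0
    return dy[inside], dx[inside]


def render_xylem_section(spec: SectionImageSpec) -> SectionGroundTruth:
    """Render a section image with ground-truth vessel annotations.

    Vessel count is ``round(target_density * Xy area)``; lumens are
    placed by rejection sampling with a 2 px minimum wall distance and
    never overlap.  Raises :class:`PlacementError` when the requested
    density cannot be placed within the retry bound.
    """
    rng = np.random.default_rng(spec.seed)
    xy_map, sector_of_label, masks = _section_geometry(spec)
    h, w = xy_map.shape
    px = spec.pixel_size_um
    px_area = px * px

    image = np.full((h, w), _I_BACKGROUND, dtype=float)
    image[masks["stem"]] = _I_XYLEM
    image[masks["phloem"]] = _I_PHLOEM
    image[masks["band"]] = _I_BAND
    image[masks["pith"]] = _I_PITH

    xy_area_mm2 = np.count_nonzero(xy_map) * px_area * 1e-6
    pop = replace(spec.vessels, seed=int(rng.integers(2**31)))
    diameters = draw_vessel_diameters(pop, xy_area_mm2)

    # lumens may abut parenchymatic bands (as real vessels abut rays) but
    # stay inside the xylem annulus and never overlap each other; centres
    # are sampled inside Xy areas so every vessel gets a sector label
    free = masks["annulus"].copy()
    xy_rows, xy_cols = np.nonzero(xy_map > 0)
    vessel_labels = np.zeros((h, w), dtype=np.uint16)
    records: list[VesselRecord] = []
    retries = 0
    # place big vessels first: they are the hardest to fit
    order = np.argsort(diameters)[::-1]
    for vid_idx, di in enumerate(order, start=1):
        d_px = diameters[di] / px
        aspect = rng.uniform(0.85, 1.0)
        a = math.sqrt((d_px / 2.0) ** 2 / aspect)
        b = aspect * a
        angle = rng.uniform(0, math.pi)
        oy, ox = _ellipse_offsets(a, b, angle)
        my, mx = _ellipse_offsets(a, b, angle, margin=_WALL_MARGIN_PX)
        placed = False
        while retries < _MAX_RETRIES:
            idx = rng.integers(len(xy_rows))
            cy, cx = int(xy_rows[idx]), int(xy_cols[idx])
            ry, rx = my + cy, mx + cx
            if (
                ry.min() < 0 or ry.max() >= h or rx.min() < 0 or rx.max() >= w
                or not free[ry, rx].all()
            ):
                retries += 1
                continue
            # commit: lumen pixels + wall margin become unavailable
            ly, lx = oy + cy, ox + cx
            vessel_labels[ly, lx] = vid_idx
            image[ly, lx] = _I_LUMEN
            free[ry, rx] = False
            area_um2 = float(ly.size) * px_area
            lab = int(xy_map[int(round(ly.mean())), int(round(lx.mean()))])
            records.append(
                VesselRecord(
                    vessel_id=vid_idx,
                    centroid_rc=(float(ly.mean()), float(lx.mean())),
                    lumen_area_um2=area_um2,
                    diameter_um=equivalent_diameter(area_um2),
                    sector=sector_of_label.get(lab),
                    xy_id=lab if lab > 0 else None,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place vessel {vid_idx}/{diameters.size} "
                f"(d={diameters[di]:.1f} um) within {_MAX_RETRIES} retries"
            )

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    records.sort(key=lambda rec: rec.vessel_id)
    return SectionGroundTruth(
        image=image,
        records=tuple(records),
        vessel_label_map=vessel_labels,
        xy_label_map=xy_map,
        sector_of_label=sector_of_label,
        spec=spec,
    )


#: presets emulating the study's measured ranges.  ``glera_like`` targets
#: the published vessel density (~120 mm^-2) and Dh (~27 um) envelopes;
#: ``high_vaf`` targets the published vessel-area fraction (~22%) instead
#: (larger, sparser vessels) — the three envelopes are geometrically
#: incompatible for circular lumens, see docs/methods.md.
SECTION_PRESETS: dict[str, VesselPopulationSpec] = {
    "glera_like": VesselPopulationSpec(
        family="lognormal", location_um=26.0, scale=0.12, target_density_mm2=120.0
    ),
    "cabernet_like": VesselPopulationSpec(
        family="lognormal", location_um=27.5, scale=0.12, target_density_mm2=98.0
    ),
    "teroldego_like": VesselPopulationSpec(
        family="lognormal", location_um=25.5, scale=0.12, target_density_mm2=121.0
    ),
    "high_vaf": VesselPopulationSpec(
        family="lognormal", location_um=56.0, scale=0.12, target_density_mm2=85.0
    ),
}


def preset_section_spec(
    preset: str = "glera_like", seed: int = 0, noise_sigma: float = 0.0
) -> SectionImageSpec:
    """A :class:`SectionImageSpec` using one of the documented presets."""
    if preset not in SECTION_PRESETS:
        raise InvalidInputError(
            f"unknown preset {preset!r}; choose from {sorted(SECTION_PRESETS)}"
        )
    return SectionImageSpec(
        vessels=replace(SECTION_PRESETS[preset], seed=seed), seed=seed,
        noise_sigma=noise_sigma,
    )


# ---------------------------------------------------------------------------
# growth series

@dataclass(frozen=True)
class GrowthSimSpec:
    """Replicated logistic growth series with Gaussian measurement noise.

    Default sampling is the study's biweekly schedule, day-of-year 182 to
    281 (eight dates), with 15 replicates.
    """

    true_params: LogisticParams = field(
        default_factory=lambda: LogisticParams(k=100.0, y0=1.0, r=0.12)
    )
    sampling_days: tuple[float, ...] = (182, 196, 210, 224, 238, 252, 266, 280)
    noise_sigma: float = 2.0  # cm (height) or count (internodes)
    n_replicates: int = 15
    trait: str = "height"
    clip_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_days, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("sampling days must be strictly increasing")
        if self.n_replicates < 1:
            raise InvalidInputError("need n >= 1 replicates")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")


def simulate_growth_series(spec: GrowthSimSpec) -> list[GrowthSeries]:
    """Simulate replicate growth series; time origin is the first
    sampling day, so the noise-free value on that day is ``y0``."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_days, dtype=float)
    clean = logistic_value(t - t[0], spec.true_params)
    out = []
    for rep in range(spec.n_replicates):
        y = clean + rng.normal(0.0, spec.noise_sigma, size=t.size) if spec.noise_sigma else clean.copy()
        if spec.clip_at_zero:
            y = np.maximum(y, 0.0)
        out.append(
            GrowthSeries(times=t, values=y, plant_id=f"plant{rep + 1:03d}", trait=spec.trait)
        )
    return out


# ---------------------------------------------------------------------------
# graft-union images

@dataclass(frozen=True)
class GraftUnionImageSpec:
    """Graft-union section with a necrotic blob of exact known fraction.

    The ROI is a horizontal band of height = sample diameter / 4 centred
    on the graft line; the necrotic mask covers
    ``round(necrotic_fraction_true * |ROI|)`` pixels, carved from a
    smoothed random field so it forms contiguous dark blobs.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 1.0
    necrotic_fraction_true: float = 0.3
    contrast: float = 1.0   # 0 = invisible, 1 = full dark
    blob_scale_px: float = 15.0  # smoothing length of the blob field
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.necrotic_fraction_true <= 1.0:
            raise InvalidInputError("necrotic fraction must be in [0, 1]")
        if not 0.0 <= self.contrast <= 1.0:
            raise InvalidInputError("contrast must be in [0, 1]")
        if self.pixel_size_um <= 0:
            raise InvalidInputError("pixel size must be > 0")


def render_graft_union_image(
    spec: GraftUnionImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (image, necrosis_mask, roi_mask).

    The mask's pixel count equals ``round(f * |ROI|)`` exactly, so the
    ground-truth fraction agrees with ``necrotic_fraction_true`` to
    within one pixel-quantization unit.
    """
    from scipy import ndimage

    from .morphometry import quarter_diameter_roi

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    sample = np.hypot(yy - cy, xx - cx) < 0.95 * min(h, w) / 2.0
    roi = quarter_diameter_roi((h, w), sample_mask=sample)

    k = int(round(spec.necrotic_fraction_true * roi.sum()))
    necrosis = np.zeros((h, w), dtype=bool)
    if k > 0:
        field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.blob_scale_px)
        vals = field_[roi]
        order = np.argsort(vals, kind="stable")[:k]
        rr, cc = np.nonzero(roi)
        necrosis[rr[order], cc[order]] = True

    healthy, dark = 170.0, 170.0 - spec.contrast * (170.0 - 40.0)
    image = np.full((h, w), float(_I_BACKGROUND))
    image[sample] = healthy
    image[necrosis] = dark
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, necrosis, roi


# ---------------------------------------------------------------------------
# factorial study datasets

@dataclass(frozen=True)
class StudyDesignSpec:
    """Balanced two-factor design with per-cell true means and SDs."""

    levels_a: tuple[str, ...]
    levels_b: tuple[str, ...]
    cell_means: tuple[tuple[float, ...], ...]  # shape (a, b)
    cell_sds: tuple[tuple[float, ...], ...]    # shape (a, b)
    n_per_cell: int = 5
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = len(self.levels_a), len(self.levels_b)
        m = np.asarray(self.cell_means, dtype=float)
        s = np.asarray(self.cell_sds, dtype=float)
        if m.shape != (a, b) or s.shape != (a, b):
            raise UnsupportedDesignError(
                f"cell means/SDs must be {a}x{b} grids matching the factor levels"
            )
        if np.any(s < 0):
            raise InvalidInputError("cell SDs must be >= 0")
        if self.n_per_cell < 1:
            raise UnsupportedDesignError("need n >= 1 per cell (balanced)")


def generate_study_dataset(spec: StudyDesignSpec) -> pd.DataFrame:
    """Draw a balanced replicate table (long format: factorA, factorB,
    replicate, value) from the design's cell means and SDs."""
    rng = np.random.default_rng(spec.seed)
    m = np.asarray(spec.cell_means, dtype=float)
    s = np.asarray(spec.cell_sds, dtype=float)
    rows = []
    for i, la in enumerate(spec.levels_a):
        for j, lb in enumerate(spec.levels_b):
            vals = m[i, j] + s[i, j] * rng.standard_normal(spec.n_per_cell)
            for rep, v in enumerate(vals, start=1):
                rows.append(
                    {"factorA": la, "factorB": lb, "replicate": rep,
                     "trait": spec.trait, "value": float(v)}
                )
    return pd.DataFrame(rows)
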