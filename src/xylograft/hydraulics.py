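"""Xylem morphology and hydraulic traits from vessel records.

Per stem cross-section the traits of interest are:

* ``Vd``  — vessel density, vessels per mm^2 of xylem area,
* ``VAf`` — total vessel lumen area as a percent of xylem area,
* ``Dh``  — hydraulically weighted vessel diameter, ``sum(d^5)/sum(d^4)``
  (micrometres), which weights conduits by their contribution to laminar
  flow (proportional to d^4),
* ``Kst`` — theoretical specific hydraulic conductivity from the
  Hagen-Poiseuille law for ideal capillaries,
  ``Kst = (pi * rho / (C * eta * Ai)) * sum(d^4)`` in
  kg MPa^-1 s^-1 m^-1, with diameters in metres and ``Ai`` the analyzed
  xylem area in m^2.

The default Poiseuille coefficient ``C`` is 1.28; the classical constant
128 is selectable (see :class:`HydraulicConstants`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "HydraulicConstants",
    "HydraulicProfile",
    "vessel_density",
    "vessel_area_fraction",
    "hydraulically_weighted_diameter",
    "theoretical_specific_conductivity",
    "profile_section",
]

#: mm^2 per m^2
_MM2_PER_M2 = 1e6
#: metres per micrometre
_M_PER_UM = 1e-6


@dataclass(frozen=True)
class HydraulicConstants:
    """Physical constants of the conductivity formula (water at 20 degC).

    Parameters
    ----------
    rho : float
        Water density, kg m^-3.
    eta : float
        Water dynamic viscosity expressed in MPa s (1.002e-3 Pa s
        == 1.002e-9 MPa s).
    coefficient : float
        Dimensionless Poiseuille coefficient; 1.28 by default, the
        classical Hagen-Poiseuille value 128 is selectable.
    """

    rho: float = 998.2
    eta: float = 1.002e-9
    coefficient: float = 1.28

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eta <= 0 or self.coefficient <= 0:
            raise InvalidInputError("all hydraulic constants must be > 0")


@dataclass(frozen=True)
class HydraulicProfile:
    """Aggregate traits of one section (or one sector of a section)."""

    n_vessels: int
    xylem_area_mm2: float
    vd: float            # vessels mm^-2
    vaf_percent: float   # %
    dh_um: float | None  # hydraulically weighted diameter, um; None if no vessels
    kst: float           # kg MPa^-1 s^-1 m^-1
    constants: HydraulicConstants = field(default_factory=HydraulicConstants)


def vessel_density(n_vessels: int, xylem_area_mm2: float) -> float:
    """Vessels per mm^2 of xylem area."""
    if xylem_area_mm2 <= 0:
        raise InvalidInputError(f"xylem area must be > 0, got {xylem_area_mm2}")
    if n_vessels < 0:
        raise InvalidInputError("vessel count must be >= 0")
    return n_vessels / xylem_area_mm2


def vessel_area_fraction(vessel_areas_um2: Iterable[float], xylem_area_um2: float) -> float:
    """Total lumen area as a percent of xylem area.

    A result above 100% is physically impossible under area conservation
    and triggers a warning (the value is still returned, unclipped, so the
    inconsistency is visible to the caller).
    """
    if xylem_area_um2 <= 0:
        raise InvalidInputError(f"xylem area must be > 0, got {xylem_area_um2}")
    areas = np.asarray(list(vessel_areas_um2), dtype=float)
    if areas.size and np.any(areas < 0):
        raise InvalidInputError("vessel areas must be >= 0")
    vaf = 100.0 * areas.sum() / xylem_area_um2
    if vaf > 100.0:
        warnings.warn(
            f"vessel area fraction {vaf:.1f}% exceeds 100%: vessel areas are "
            "not contained in the stated xylem area",
            stacklevel=2,
        )
    return float(vaf)


def hydraulically_weighted_diameter(diameters_um: Sequence[float]) -> float:
    """``sum(d^5) / sum(d^4)`` over vessel diameters, in micrometres.

    Bounded by ``[min(d), max(d)]``; equals ``d`` for a homogeneous
    population.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise UndefinedStatisticError("Dh is undefined for an empty vessel list")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise InvalidInputError("all diameters must be finite and > 0")
    # normalise by max(d) before taking powers to avoid overflow on long lists
    dmax = d.max()
    x = d / dmax
    return float(dmax * np.sum(x**5) / np.sum(x**4))


def theoretical_specific_conductivity(
    diameters_um: Sequence[float],
    ai_m2: float,
    constants: HydraulicConstants | None = None,
) -> float:
    """Hagen-Poiseuille theoretical conductivity, kg MPa^-1 s^-1 m^-1.

    ``Kst = (pi * rho / (C * eta * Ai)) * sum(d^4)`` with diameters
    converted to metres.  Zero for an empty vessel list.
    """
    constants = constants or HydraulicConstants()
    if ai_m2 <= 0:
        raise InvalidInputError(f"analyzed area Ai must be > 0 m^2, got {ai_m2}")
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        return 0.0
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise InvalidInputError("all diameters must be finite and > 0")
    d_m = d * _M_PER_UM
    prefactor = np.pi * constants.rho / (constants.coefficient * constants.eta * ai_m2)
    return float(prefactor * np.sum(d_m**4))


def profile_section(
    records,
    regions,
    constants: HydraulicConstants | None = None,
    ai: str = "xylem",
) -> dict:
    """Aggregate vessel records and xylem regions into hydraulic profiles.

    Parameters
    ----------
    records : sequence of VesselRecord
        Segmented vessels (see :mod:`xylograft.morphometry`).  Vessels
        without a sector assignment are excluded, mirroring the rule that
        traits are measured on pure-xylem areas only.
    regions : sequence of XylemRegion
        The xylem (Xy) areas of the section.
    ai : {"xylem", "image"}
        Definition of the analyzed area used for Vd and Kst: the sum of
        Xy areas (default) or, if every region carries a
        ``frame_area_um2`` attribute, the whole image frame.

    Returns
    -------
    dict
        ``{"section": HydraulicProfile, "sectors": {label: HydraulicProfile}}``.
    """
    constants = constants or HydraulicConstants()
    regions = list(regions)
    if not regions:
        raise InvalidInputError("profile_section requires at least one xylem region")
    if ai not in ("xylem", "image"):
        raise InvalidInputError("ai must be 'xylem' or 'image'")

    sector_of_region = {r.xy_id: r.sector for r in regions}
    area_by_sector: dict[str, float] = {}
    for r in regions:
        area_by_sector[r.sector] = area_by_sector.get(r.sector, 0.0) + r.area_um2
    total_area_um2 = sum(area_by_sector.values())
    if ai == "image":
        frame = getattr(regions[0], "frame_area_um2", None)
        if frame is None:
            raise InvalidInputError("ai='image' requires regions with frame_area_um2")
        total_area_um2_ai = float(frame)
    else:
        total_area_um2_ai = total_area_um2

    assigned = [v for v in records if v.sector is not None and v.xy_id in sector_of_region]

    def _profile(vessels, xy_area_um2: float, ai_area_um2: float) -> HydraulicProfile:
        areas = [v.lumen_area_um2 for v in vessels]
        diam = [v.diameter_um for v in vessels]
        area_mm2 = ai_area_um2 * 1e-6  # um^2 -> mm^2
        return HydraulicProfile(
            n_vessels=len(vessels),
            xylem_area_mm2=area_mm2,
            vd=vessel_density(len(vessels), area_mm2),
            vaf_percent=vessel_area_fraction(areas, xy_area_um2) if xy_area_um2 > 0 else 0.0,
            dh_um=hydraulically_weighted_diameter(diam) if vessels else None,
            kst=theoretical_specific_conductivity(diam, ai_area_um2 * 1e-12, constants),
            constants=constants,
        )

    out = {"section": _profile(assigned, total_area_um2, total_area_um2_ai), "sectors": {}}
    for sector, area in sorted(area_by_sector.items()):
        vs = [v for v in assigned if sector_of_region[v.xy_id] == sector]
        out["sectors"][sector] = _profile(vs, area, area)
    return out
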