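"""Vessel density, area fraction, Dh and Hagen-Poiseuille conductivity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from xylograft.errors import InvalidInputError, UndefinedStatisticError
from xylograft.hydraulics import (
    HydraulicConstants,
    hydraulically_weighted_diameter,
    profile_section,
    theoretical_specific_conductivity,
    vessel_area_fraction,
    vessel_density,
)


@pytest.mark.parametrize(
    "n, area, expected",
    [(120, 1.0, 120.0), (0, 1.0, 0.0), (12, 0.1, 120.0)],
)
def test_vessel_density_ratio(n, area, expected):
    assert vessel_density(n, area) == pytest.approx(expected)


def test_vessel_density_rejects_nonpositive_area():
    with pytest.raises(InvalidInputError):
        vessel_density(10, 0.0)


def test_vessel_area_fraction_basic():
    assert vessel_area_fraction([20_000.0], 100_000.0) == pytest.approx(20.0)
    assert vessel_area_fraction([], 100_000.0) == 0.0
    with pytest.raises(InvalidInputError):
        vessel_area_fraction([-1.0], 100.0)


def test_vessel_area_fraction_above_100_warns():
    with pytest.warns(UserWarning, match="exceeds 100%"):
        vessel_area_fraction([2e5], 1e5)


class TestDh:
    def test_homogeneous_population_identity(self):
        assert hydraulically_weighted_diameter([30.0] * 7) == pytest.approx(30.0)

    def test_two_vessel_hand_oracle(self):
        # sum d^5 = 1e5 + 3.2e6 = 3.3e6 ; sum d^4 = 1e4 + 1.6e5 = 1.7e5
        assert hydraulically_weighted_diameter([10.0, 20.0]) == pytest.approx(
            3_300_000 / 170_000
        )

    def test_empty_and_invalid(self):
        with pytest.raises(UndefinedStatisticError):
            hydraulically_weighted_diameter([])
        with pytest.raises(InvalidInputError):
            hydraulically_weighted_diameter([10.0, -1.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        hst.lists(hst.floats(min_value=1.0, max_value=200.0), min_size=1, max_size=40)
    )
    def test_bounds_and_loop_oracle(self, diameters):
        """Dh lies in [min d, max d] and the vectorized path agrees with
        direct loop summation to 1e-12 relative."""
        dh = hydraulically_weighted_diameter(diameters)
        assert min(diameters) - 1e-9 <= dh <= max(diameters) + 1e-9
        num = sum(d**5 for d in diameters)
        den = sum(d**4 for d in diameters)
        assert dh == pytest.approx(num / den, rel=1e-12)

    def test_appending_larger_vessel_increases_dh(self, rng):
        for _ in range(50):
            d = list(rng.uniform(5, 60, size=rng.integers(1, 20)))
            dh0 = hydraulically_weighted_diameter(d)
            dh1 = hydraulically_weighted_diameter(d + [max(d) * 1.3])
            assert dh1 > dh0

    def test_adding_small_vessels_never_raises_dh(self, rng):
        """Raising density with only small vessels drives Dh down —
        the negative density-diameter association regime."""
        for _ in range(20):
            d = list(rng.uniform(25, 45, size=10))
            dh0 = hydraulically_weighted_diameter(d)
            dh1 = hydraulically_weighted_diameter(d + list(rng.uniform(5, 10, 5)))
            assert dh1 <= dh0


class TestKst:
    def test_empty_list_is_zero(self):
        assert theoretical_specific_conductivity([], 1e-6) == 0.0

    def test_single_vessel_hand_value(self):
        # (pi*998.2 / (1.28 * 1.002e-9 * 1e-6)) * (30e-6)^4
        expected = (
            math.pi * 998.2 / (1.28 * 1.002e-9 * 1e-6) * (30e-6) ** 4
        )
        got = theoretical_specific_conductivity([30.0], 1e-6)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.9805, rel=1e-3)

    def test_linearity_and_area_scaling(self, rng):
        d = list(rng.uniform(10, 40, size=12))
        k1 = theoretical_specific_conductivity(d, 1e-6)
        assert theoretical_specific_conductivity(d, 2e-6) == pytest.approx(k1 / 2)
        assert theoretical_specific_conductivity(d + d, 1e-6) == pytest.approx(2 * k1)

    def test_classical_coefficient_selectable(self):
        c128 = HydraulicConstants(coefficient=128.0)
        assert theoretical_specific_conductivity(
            [30.0], 1e-6, c128
        ) == pytest.approx(theoretical_specific_conductivity([30.0], 1e-6) / 100.0)

    def test_rejects_bad_area(self):
        with pytest.raises(InvalidInputError):
            theoretical_specific_conductivity([30.0], 0.0)


class TestProfileSection:
    def test_composition_matches_direct_formulas(self):
        from xylograft.morphometry import VesselRecord, XylemRegion

        recs = [
            VesselRecord(1, (5.0, 5.0), 500.0, 2 * math.sqrt(500 / math.pi), "L1", 1),
            VesselRecord(2, (9.0, 9.0), 700.0, 2 * math.sqrt(700 / math.pi), "L1", 1),
        ]
        regions = [XylemRegion(1, "L1", 1e5)]
        prof = profile_section(recs, regions)["section"]
        assert prof.vd == pytest.approx(2 / 0.1)  # 1e5 um^2 = 0.1 mm^2
        assert prof.vaf_percent == pytest.approx(100 * 1200 / 1e5)
        d = [r.diameter_um for r in recs]
        assert prof.dh_um == pytest.approx(hydraulically_weighted_diameter(d))
        assert prof.kst == pytest.approx(
            theoretical_specific_conductivity(d, 1e5 * 1e-12)
        )

    def test_requires_regions(self):
        with pytest.raises(InvalidInputError):
            profile_section([], [])

    def test_preset_section_in_envelope(self, clean_section):
        """End-to-end on the generator preset: Vd and Dh inside the
        published envelopes (Vd 85-140 mm^-2, Dh 24-33 um)."""
        from xylograft.morphometry import regions_from_label_map

        gt = clean_section
        regions = regions_from_label_map(
            gt.xy_label_map, gt.sector_of_label, gt.spec.pixel_size_um, gt.records
        )
        prof = profile_section(gt.records, regions)["section"]
        assert 85 <= prof.vd <= 140
        assert 24 <= prof.dh_um <= 33
        # unit-audit guard: diameters left in um would inflate Kst by 1e24
        assert 1.0 <= prof.kst <= 1e4

    def test_two_sections_pool_by_area(self, clean_section):
        """Concatenating two sections gives the area-weighted density."""
        from xylograft import synthetic_data as sd
        from xylograft.morphometry import regions_from_label_map

        gt2 = sd.render_xylem_section(
            sd.preset_section_spec("cabernet_like", seed=12)
        )
        profs = []
        for gt in (clean_section, gt2):
            regions = regions_from_label_map(
                gt.xy_label_map, gt.sector_of_label, gt.spec.pixel_size_um, gt.records
            )
            profs.append(profile_section(gt.records, regions)["section"])
        n = profs[0].n_vessels + profs[1].n_vessels
        area = profs[0].xylem_area_mm2 + profs[1].xylem_area_mm2
        pooled_vd = n / area
        w = np.array([p.xylem_area_mm2 for p in profs])
        assert pooled_vd == pytest.approx(
            float(np.average([p.vd for p in profs], weights=w))
        )
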