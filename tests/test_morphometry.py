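"""Volumes, the envelope, counting statistics and interleaved sampling."""

import numpy as np
import pytest
from scipy import ndimage

from olfrecon.morphometry import (
    CountEstimate,
    LinearDensity,
    ThicknessEstimate,
    VoxelGeometry,
    abercrombie_correct,
    delta_ratio_sem,
    disk_closing,
    envelope_section,
    epithelium_surface_area,
    fieller_ratio_ci,
    interleaved_error,
    interpolated_areas,
    olfactory_envelope,
    ratio_report,
    sphere_glomerulus_count,
    structure_volume,
    total_osn,
    volumetric_density,
)

GEOM = VoxelGeometry()  # 1.097 x 1.097 x 10 um


class TestStructureVolume:
    def test_single_section_voxel_arithmetic(self):
        """1000 positive px in one section: 1000 * 1.097^2 * 10 um^3."""
        mask = np.zeros((1, 40, 40), bool)
        mask[0].flat[:1000] = True
        v = structure_volume(mask, np.array([True]), GEOM)
        assert v * 1e9 == pytest.approx(1000 * 1.097**2 * 10, rel=1e-12)
        assert v * 1e9 == pytest.approx(1.2034e4, rel=1e-3)

    def test_missing_section_midpoint_interpolation(self):
        areas = np.array([100.0, 0.0, 200.0])
        filled = interpolated_areas(areas, np.array([True, False, True]))
        assert filled[1] == 150.0

    def test_no_missing_sections_equals_plain_count(self, rng):
        masks = rng.random((4, 10, 10)) > 0.5
        inc = np.ones(4, bool)
        v = structure_volume(masks, inc, GEOM)
        assert v == pytest.approx(masks.sum() * GEOM.voxel_volume_um3 * 1e-9)

    def test_boundary_gaps_use_nearest_neighbour(self):
        areas = np.array([0.0, 50.0, 60.0, 0.0])
        inc = np.array([False, True, True, False])
        assert interpolated_areas(areas, inc).tolist() == [50.0, 50.0, 60.0, 60.0]

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            structure_volume(np.zeros((2, 4, 4), bool), np.zeros(2, bool), GEOM)

    def test_exact_for_linear_area_profile(self):
        """Linear ramps survive any interleave rate away from the boundary."""
        n = 33
        areas = 10.0 + 3.0 * np.arange(n)
        inc = np.zeros(n, bool)
        inc[::4] = True
        inc[-1] = True  # keep the posterior boundary section
        filled = interpolated_areas(areas, inc)
        assert np.allclose(filled, areas)


class TestEnvelope:
    @staticmethod
    def band_with_gap(gap_px: int):
        """An epithelium band whose OSN support has one central gap."""
        epi = np.zeros((80, 300), bool)
        epi[10:60] = True
        osn = epi.copy()
        if gap_px:
            mid = 150
            osn[:, mid - gap_px // 2 : mid + (gap_px + 1) // 2] = False
        return epi, osn

    def test_gapless_band_closing_is_identity(self):
        epi, osn = self.band_with_gap(0)
        env = envelope_section(epi, osn, disk_radius_px=36)
        assert np.array_equal(env, epi)

    def test_sub_element_gap_is_closed(self):
        gap = int(round(20 / GEOM.pixel_size))  # a 20 um interruption
        epi, osn = self.band_with_gap(gap)
        env = envelope_section(epi, osn, disk_radius_px=36)
        assert env[30].all()  # continuous along the band mid-line

    def test_super_element_gap_is_preserved_and_matches_oracle(self):
        gap = int(round(200 / GEOM.pixel_size))  # a 200 um interruption
        epi, osn = self.band_with_gap(gap)
        env = envelope_section(epi, osn, disk_radius_px=36)
        assert not env[30, 140:160].any()
        # oracle: direct dilation followed by erosion with the same disk
        from skimage.morphology import disk
        fp = disk(36)
        pad = 40
        expanded = osn  # the band already spans the full thickness
        big = np.pad(expanded, pad)
        dil = ndimage.binary_dilation(big, structure=fp)
        ero = ndimage.binary_erosion(dil, structure=fp, border_value=1)
        oracle = ero[pad:-pad, pad:-pad]
        assert np.array_equal(disk_closing(expanded, 36), oracle)

    def test_envelope_contains_osn_epithelium_intersection(self, small_series):
        inc = small_series.included_flags()
        env = olfactory_envelope(
            small_series.mask_stack("nasal_epithelium"),
            small_series.mask_stack("osn"), inc, GEOM,
        )
        core = small_series.mask_stack("osn") & small_series.mask_stack(
            "nasal_epithelium"
        )
        assert (env.masks | ~core).all()  # core subset of envelope
        core_vol = structure_volume(core, inc, GEOM)
        assert env.volume_mm3 >= core_vol

    def test_closing_is_idempotent(self, rng):
        m = ndimage.gaussian_filter(rng.normal(size=(90, 90)), 5) > 0.2
        once = disk_closing(m, 10)
        assert np.array_equal(disk_closing(once, 10), once)

    def test_sub_pixel_element_rejected(self, small_series):
        with pytest.raises(ValueError):
            olfactory_envelope(
                small_series.mask_stack("nasal_epithelium"),
                small_series.mask_stack("osn"),
                small_series.included_flags(), GEOM, disk_diameter_um=0.5,
            )


class TestAbercrombie:
    @pytest.mark.parametrize("raw,T,D,expected", [
        (100, 10, 0, 100),   # no correction without nuclear extent
        (100, 10, 10, 50),   # factor 1/2
        (120, 10, 5, 80),    # factor 2/3
    ])
    def test_classical_factor(self, raw, T, D, expected):
        assert abercrombie_correct(raw, T, D) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            abercrombie_correct(-1, 10, 5)
        with pytest.raises(ValueError):
            abercrombie_correct(10, 10, -5)


class TestDensityAndTotals:
    def test_round_number_density(self):
        d = volumetric_density(LinearDensity(100.0, 0.0),
                               ThicknessEstimate(100.0, 0.0), 10.0)
        assert d.mean == pytest.approx(100_000.0)

    def test_zero_input_sems_give_zero_sem(self):
        d = volumetric_density(LinearDensity(80.0, 0.0),
                               ThicknessEstimate(60.0, 0.0), 10.0)
        assert d.sem == pytest.approx(0.0, abs=1e-9)

    def test_fieller_and_delta_agree_at_small_input_sems(self):
        """First-order agreement: at 0.1 % input SEMs the two SEMs coincide."""
        a, b = 78.31, 67.23
        fl = fieller_ratio_ci(a, a * 1e-3, b, b * 1e-3)
        sem_f = (fl[1] - fl[0]) / (2 * 1.645)
        sem_d = delta_ratio_sem(a, a * 1e-3, b, b * 1e-3)
        assert sem_f == pytest.approx(sem_d, rel=1e-4)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            volumetric_density(LinearDensity(80.0, 1.0),
                               ThicknessEstimate(0.0, 0.0), 10.0)

    def test_total_scales_density_by_volume(self):
        d = CountEstimate(1000.0, 100.0, (835.5, 1164.5))
        t = total_osn(d, 2.0)
        assert (t.mean, t.sem) == (2000.0, 200.0)
        assert t.ci90 == pytest.approx((2000 - 1.645 * 200, 2000 + 1.645 * 200))

    def test_zero_density_degenerate_interval(self):
        t = total_osn(CountEstimate(0.0, 0.0, (0.0, 0.0)), 5.0)
        assert t.mean == 0.0 and t.ci90 == (0.0, 0.0)

    def test_surface_area_unit_case(self):
        a = epithelium_surface_area(1.0, ThicknessEstimate(1000.0, 0.0))
        assert a.mean == pytest.approx(1.0)
        assert a.sem == 0.0


class TestSphereModel:
    def test_volume_of_exactly_one_sphere_counts_one(self):
        d = 60.0
        v = (4 / 3) * np.pi * (d / 2) ** 3 * 1e-9
        assert sphere_glomerulus_count(v, d).count == 1

    def test_count_strictly_decreasing_in_diameter(self):
        counts = [sphere_glomerulus_count(1.55, d).count_float
                  for d in np.linspace(40, 80, 9)]
        assert all(b < a for a, b in zip(counts, counts[1:]))

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_glomerulus_count(1.0, 0.0)


class TestRatios:
    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            ratio_report(100.0, 0, 389)
        with pytest.raises(ValueError):
            ratio_report(100.0, 10, 0)

    def test_rounding_convenience_values(self):
        r = ratio_report(1000.0, 3, 7)
        assert r["osns_per_glomerulus_rounded"] == 333
        assert r["osns_per_gene_rounded"] == 143


class TestInterleavedSampling:
    def test_constant_area_profile_has_zero_error(self):
        masks = np.zeros((64, 20, 20), bool)
        masks[:, 5:15, 5:15] = True
        inc = np.ones(64, bool)
        err = interleaved_error(masks, inc, GEOM, rates=(4, 16, 32))
        assert all(e == pytest.approx(0.0, abs=1e-12) for e in err.values())

    def test_rate_one_reproduces_complete_dataset(self):
        masks = np.random.default_rng(0).random((8, 10, 10)) > 0.5
        inc = np.ones(8, bool)
        err = interleaved_error(masks, inc, GEOM, rates=(1,))
        assert err[1] == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_error_matches_closed_form(self):
        """Interior interpolation is exact; only boundary extrapolation errs.

        With areas a_i = i for i = 0..n-1 and every 4th section kept, the
        final kept section is i = 4*floor((n-1)/4); the sections after it are
        filled with its value, so the deficit is the triangular shortfall."""
        n = 30
        masks = np.zeros((n, 40, 40), bool)
        for i in range(n):
            masks[i].flat[: (i + 1)] = True  # area i+1 px
        inc = np.ones(n, bool)
        err = interleaved_error(masks, inc, GEOM, rates=(4,))
        areas = np.arange(1, n + 1, dtype=float)
        kept = np.zeros(n, bool)
        kept[::4] = True
        filled = np.interp(np.arange(n), np.flatnonzero(kept), areas[kept])
        expected = abs(filled.sum() - areas.sum()) / areas.sum() * 100
        assert err[4] == pytest.approx(expected, rel=1e-12)

    def test_too_few_surviving_sections_rejected(self):
        masks = np.ones((4, 5, 5), bool)
        with pytest.raises(ValueError):
            interleaved_error(masks, np.ones(4, bool), GEOM, rates=(4,))
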