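"""Blocks, DSC-driven selections, displacement fields, pair registration."""

import numpy as np
import pytest
from scipy import ndimage

from olfrecon.phantom import PhantomConfig, make_series
from olfrecon.registration import (
    apply_field,
    combined_mask,
    compose_fields,
    interblock_interpolate,
    partition_blocks,
    register_block,
    register_pair_intensity,
    register_pair_mask,
    register_series,
    section_combined_mask,
    select_interblock_pair,
    select_intrablock_reference,
    zero_field,
)
from olfrecon.segmentation import dsc


def mean_adjacent_dsc(series):
    inc = series.included
    return np.mean([
        dsc(section_combined_mask(a), section_combined_mask(b))
        for a, b in zip(inc, inc[1:])
    ])


class TestCombinedMask:
    def test_boolean_or(self):
        v = np.array([[1, 0]], bool)
        e = np.array([[0, 1]], bool)
        assert combined_mask(v, e).tolist() == [[True, True]]

    def test_idempotent_on_equal_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert np.array_equal(combined_mask(m, m), m)

    def test_empty_inputs_stay_empty(self):
        z = np.zeros((4, 4), bool)
        assert not combined_mask(z, z).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combined_mask(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestBlockPartition:
    def test_complete_dataset_of_1234_sections_gives_247_blocks(self):
        blocks = partition_blocks(range(1, 1235), block_size=5)
        assert len(blocks) == 247
        sizes = [len(b.section_indices) for b in blocks]
        assert sizes[:-1] == [5] * 246
        assert sizes[-1] == 4

    @pytest.mark.parametrize("n,expected", [(10, [5, 5]), (3, [3]), (7, [5, 2])])
    def test_remainder_block_keeps_leftover(self, n, expected):
        blocks = partition_blocks(range(n))
        assert [len(b.section_indices) for b in blocks] == expected

    def test_empty_and_unsorted_rejected(self):
        with pytest.raises(ValueError):
            partition_blocks([])
        with pytest.raises(ValueError):
            partition_blocks([3, 1, 2])


class TestReferenceSelection:
    def test_agreeing_pair_beats_outlier(self):
        a = np.zeros((6, 6), bool)
        a[1:4, 1:4] = True
        c = np.zeros((6, 6), bool)
        c[4:, 4:] = True
        assert select_intrablock_reference([a, a.copy(), c]) == 0

    def test_all_identical_ties_to_lowest_index(self):
        m = np.ones((4, 4), bool)
        assert select_intrablock_reference([m] * 5) == 0

    def test_matches_exhaustive_sum_dsc_oracle(self, rng):
        masks = [rng.random((16, 16)) > 0.5 for _ in range(5)]
        sums = [sum(dsc(masks[i], masks[j]) for j in range(5)) for i in range(5)]
        assert select_intrablock_reference(masks) == int(np.argmax(sums))


class TestInterfaceSelection:
    def test_identical_cross_pair_wins(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        other = np.zeros((6, 6), bool)
        other[0, 0] = True
        third = np.zeros((6, 6), bool)
        third[5, 5] = True
        assert select_interblock_pair([other, m], [m.copy(), third]) == (1, 0)

    def test_all_equal_ties_to_lexicographically_smallest(self):
        m = np.ones((3, 3), bool)
        assert select_interblock_pair([m] * 3, [m] * 3) == (0, 0)

    def test_matches_brute_force_over_25_pairs(self, rng):
        a = [rng.random((12, 12)) > 0.5 for _ in range(5)]
        b = [rng.random((12, 12)) > 0.5 for _ in range(5)]
        table = [(dsc(a[i], b[j]), (-i, -j)) for i in range(5) for j in range(5)]
        best = max(table)
        assert select_interblock_pair(a, b) == (-best[1][0], -best[1][1])


class TestFields:
    def test_zero_field_is_identity(self, rng):
        img = rng.random((20, 20))
        assert np.allclose(apply_field(img, zero_field((20, 20)), "linear"), img)

    def test_constant_integer_field_shifts_exactly(self):
        img = np.zeros((10, 10), dtype=np.float32)
        img[4, 4] = 1.0
        f = zero_field((10, 10))
        f[0] = 2.0  # sample at row+2 -> content moves up 2 rows
        out = apply_field(img, f, "linear")
        assert out[2, 4] == 1.0 and out[4, 4] == 0.0

    def test_nearest_mode_keeps_masks_binary(self, rng):
        mask = rng.random((16, 16)) > 0.5
        f = rng.normal(0, 1.5, (2, 16, 16)).astype(np.float32)
        out = apply_field(mask, f, "nearest")
        assert out.dtype == bool

    def test_field_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_field(np.zeros((5, 5)), zero_field((6, 6)))

    def test_interpolation_scales_exactly_as_fraction(self, rng):
        phi = rng.normal(0, 3, (2, 8, 8)).astype(np.float32)
        n = 5
        parts = interblock_interpolate(phi, n)
        assert len(parts) == n
        for i, part in enumerate(parts, start=1):
            assert np.array_equal(part, ((i - 1) / n) * phi)

    def test_first_interpolated_field_is_zero(self):
        assert not interblock_interpolate(np.ones((2, 4, 4)), 3)[0].any()

    def test_constant_field_three_quarters(self):
        phi = np.zeros((2, 4, 4), np.float32)
        phi[0] = 8.0
        assert np.allclose(interblock_interpolate(phi, 4)[3][0], 6.0)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            interblock_interpolate(np.zeros((2, 4, 4)), 0)

    def test_composition_of_constant_fields_adds(self):
        a, b = zero_field((12, 12)), zero_field((12, 12))
        a[1], b[1] = 2.0, 3.0
        assert np.allclose(compose_fields(a, b)[1], 5.0)


class TestPairRegistration:
    def test_self_registration_recovers_near_identity(self, small_series, fast_reg):
        s = small_series.sections[0]
        f = register_pair_intensity(s.channels, s.channels, fast_reg)
        assert np.mean(np.abs(f)) < 0.1

    def test_known_translation_recovered(self, small_series, fast_reg):
        s = small_series.sections[0]
        moved = np.stack([ndimage.shift(c, (5, 3), order=1) for c in s.channels])
        f = register_pair_intensity(s.channels, moved, fast_reg)
        assert np.median(f[0]) == pytest.approx(5.0, abs=0.5)
        assert np.median(f[1]) == pytest.approx(3.0, abs=0.5)

    def test_programmed_warp_improves_mask_dsc(self, jittered_series, fast_reg):
        a, b = jittered_series.sections[0], jittered_series.sections[1]
        f = register_pair_intensity(a.channels, b.channels, fast_reg)
        ma, mb = section_combined_mask(a), section_combined_mask(b)
        warped = apply_field(mb, f, "nearest")
        assert dsc(warped, ma) >= dsc(mb, ma)

    def test_non_finite_input_rejected(self, fast_reg):
        bad = np.full((4, 32, 32), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            register_pair_intensity(bad, bad, fast_reg)


class TestMaskRefinement:
    def test_aligned_masks_left_unchanged(self, small_series, fast_reg):
        m = section_combined_mask(small_series.sections[0])
        before = dsc(m, m)
        f = register_pair_mask(m, m, zero_field(m.shape), fast_reg)
        after = dsc(apply_field(m, f, "nearest"), m)
        assert abs(after - before) < 1e-6

    def test_residual_shift_refined_upward(self, small_series, fast_reg):
        m = section_combined_mask(small_series.sections[0])
        moved = ndimage.shift(m.astype(float), (2, 1), order=0) > 0.5
        pre = dsc(moved, m)
        f = register_pair_mask(m, moved, zero_field(m.shape), fast_reg)
        post = dsc(apply_field(moved, f, "nearest"), m)
        assert post >= pre

    def test_empty_fixed_mask_returns_init_field_with_warning(self, fast_reg):
        init = np.full((2, 16, 16), 1.5, dtype=np.float32)
        with pytest.warns(UserWarning):
            out = register_pair_mask(
                np.zeros((16, 16), bool), np.ones((16, 16), bool), init, fast_reg
            )
        assert np.array_equal(out, init)


class TestBlockRegistration:
    def test_identical_sections_yield_near_zero_fields(self, small_series, fast_reg):
        s = small_series.sections[0]
        clones = [
            type(s)(index=i + 1, channels=s.channels.copy(),
                    masks=s.masks.copy(), included=True)
            for i in range(3)
        ]
        _, _, fields = register_block(clones, fast_reg)
        for f in fields.values():
            assert np.mean(np.abs(f)) < 0.1

    def test_block_registration_is_deterministic(self, jittered_series, fast_reg):
        secs = jittered_series.sections[:3]
        _, _, f1 = register_block(secs, fast_reg)
        _, _, f2 = register_block(secs, fast_reg)
        assert all(np.array_equal(f1[k], f2[k]) for k in f1)

    def test_block_improves_mean_pairwise_dsc(self, jittered_series, fast_reg):
        secs = jittered_series.sections[:5]

        def pairwise(ms):
            return np.mean([
                dsc(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))
            ])

        before = pairwise([section_combined_mask(s) for s in secs])
        _, warped, _ = register_block(secs, fast_reg)
        after = pairwise([section_combined_mask(s) for s in warped])
        assert after >= before


class TestSeriesRegistration:
    def test_jittered_stack_alignment_improves(self, jittered_series, fast_reg):
        pre = mean_adjacent_dsc(jittered_series)
        registered, fields = register_series(jittered_series, fast_reg)
        post = mean_adjacent_dsc(registered)
        assert post >= pre
        assert set(fields) == set(jittered_series.included_indices)

    def test_single_block_series_matches_register_block(self, fast_reg):
        cfg = PhantomConfig(grid_shape=(4, 128, 128), dropout_rate=0.0,
                            deform_amplitude=1.5, banana_curvature=0.0, seed=13)
        series = make_series(cfg)
        registered, fields = register_series(series, fast_reg, block_size=5)
        _, warped, bfields = register_block(series.sections, fast_reg)
        for got, want in zip(registered.sections, warped):
            assert np.array_equal(got.masks, want.masks)
        assert all(np.array_equal(fields[k], bfields[k]) for k in fields)

    def test_too_few_sections_rejected(self, small_series, fast_reg):
        lone = type(small_series)(
            sections=[small_series.sections[0]], n_cut=1,
        )
        with pytest.raises(ValueError):
            register_series(lone, fast_reg)
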