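import numpy as np
import pytest

from conftest import diff_map_from_values, fom_from_lists
from fibremap.compare import (
    EXCLUDE_COUNT,
    EXCLUDE_EMPTY,
    EXCLUDE_NONE,
    RigidTransform,
    apply_transform,
    full_comparison,
    histogram_stats,
    match_and_diff,
    upscale_fom,
)


class TestUpscale:
    def test_identity_when_pixel_sizes_match(self):
        fom = fom_from_lists([[[10.0], [20.0]], [[30.0], []]])
        out = upscale_fom(fom, 2.37, 2.37)
        assert np.array_equal(
            out.orientations, fom.orientations, equal_nan=True
        )

    def test_double_resolution_blocks(self):
        fom = fom_from_lists([[[10.0], [20.0]], [[30.0], [40.0]]])
        out = upscale_fom(fom, 2.0, 1.0)
        assert out.shape == (4, 4)
        assert np.all(out.orientations[:2, :2, 0] == 10.0)
        assert np.all(out.orientations[:2, 2:, 0] == 20.0)
        assert np.all(out.orientations[2:, :2, 0] == 30.0)
        assert np.all(out.orientations[2:, 2:, 0] == 40.0)

    def test_instrument_pixel_ratio(self):
        fom = fom_from_lists([[[45.0]] * 24] * 24)
        out = upscale_fom(fom, 2.87, 2.37)
        assert out.shape == (29, 29)  # 24 · 2.87/2.37 ≈ 29.06
        assert np.all(out.orientations[..., 0] == 45.0)

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError):
            upscale_fom(fom_from_lists([[[0.0]]]), 0.0, 1.0)


class TestApplyTransform:
    def test_identity(self):
        fom = fom_from_lists([[[10.0], [110.0]], [[55.0], []]])
        out = apply_transform(fom, RigidTransform())
        assert np.array_equal(
            out.orientations, fom.orientations, equal_nan=True
        )

    def test_rotation_co_rotates_values(self):
        # a uniform map under 90° rotation keeps its grid but every
        # orientation advances by the rotation angle
        fom = fom_from_lists([[[10.0]] * 5] * 5)
        out = apply_transform(fom, RigidTransform(rotation_deg=90.0))
        assert np.all(out.orientations[..., 0] == 100.0)

    def test_rotation_moves_pixels(self):
        grid = [[[] for _ in range(5)] for _ in range(5)]
        grid[2][4] = [0.0]  # east of centre
        fom = fom_from_lists(grid)
        out = apply_transform(fom, RigidTransform(rotation_deg=90.0))
        # anticlockwise (y up): east → north, i.e. up in row terms
        assert out.n_orientations()[0, 2] == 1
        assert out.orientations[0, 2, 0] == 90.0
        assert out.n_orientations().sum() == 1

    def test_translation_y_up(self):
        grid = [[[] for _ in range(5)] for _ in range(5)]
        grid[2][2] = [30.0]
        fom = fom_from_lists(grid)
        out = apply_transform(fom, RigidTransform(translation=(1.0, 2.0)))
        assert out.n_orientations()[0, 3] == 1  # +x is right, +y is up
        assert out.orientations[0, 3, 0] == 30.0

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(0)
        grid = [
            [[float(rng.uniform(0, 180))] for _ in range(7)] for _ in range(7)
        ]
        fom = fom_from_lists(grid)
        t = RigidTransform(rotation_deg=90.0, translation=(1.0, -2.0))
        back = apply_transform(apply_transform(fom, t), t.inverse())
        inside = ~np.isnan(back.orientations[..., 0])
        assert inside.sum() >= 25
        assert np.allclose(
            back.orientations[inside],
            fom.orientations[inside],
            atol=1e-9,
            equal_nan=True,
        )


class TestMatchAndDiff:
    def test_seam_wrapped_difference(self):
        a = fom_from_lists([[[10.0]]])
        b = fom_from_lists([[[170.0]]])
        d = match_and_diff(a, b)
        assert d.differences[0, 0, 0] == pytest.approx(20.0)

    def test_multi_orientation_slotwise(self):
        a = fom_from_lists([[[30.0, 120.0]]])
        b = fom_from_lists([[[118.0, 35.0]]])
        d = match_and_diff(a, b)
        assert d.differences[0, 0, 0] == pytest.approx(-5.0)
        assert d.differences[0, 0, 1] == pytest.approx(2.0)

    def test_exclusion_codes(self):
        a = fom_from_lists([[[10.0], [10.0, 40.0], []]])
        b = fom_from_lists([[[12.0], [20.0], [50.0]]])
        d = match_and_diff(a, b)
        assert d.exclusion[0, 0] == EXCLUDE_NONE
        assert d.exclusion[0, 1] == EXCLUDE_COUNT
        assert d.exclusion[0, 2] == EXCLUDE_EMPTY
        assert d.n_compared == 1 and d.n_excluded == 2

    def test_antisymmetry(self, rng):
        grid_a, grid_b = [], []
        for _ in range(6):
            row_a, row_b = [], []
            for _ in range(6):
                n = int(rng.integers(0, 3))
                row_a.append([float(rng.uniform(0, 179.9)) for _ in range(n)])
                row_b.append([float(rng.uniform(0, 179.9)) for _ in range(n)])
            grid_a.append(row_a)
            grid_b.append(row_b)
        a, b = fom_from_lists(grid_a), fom_from_lists(grid_b)
        dab = match_and_diff(a, b)
        dba = match_and_diff(b, a)
        assert np.array_equal(dab.exclusion, dba.exclusion)
        va, vb = dab.differences, dba.differences
        ok = ~np.isnan(va)
        # antisymmetric except exactly on the +90° boundary
        boundary = np.isclose(np.abs(va), 90.0)
        assert np.allclose(va[ok & ~boundary], -vb[ok & ~boundary])

    def test_exclusion_conservation(self):
        a = fom_from_lists([[[10.0], [], [5.0, 95.0]], [[1.0], [2.0], []]])
        b = fom_from_lists([[[12.0], [30.0], [7.0]], [[], [3.0], []]])
        d = match_and_diff(a, b)
        assert d.n_compared + d.n_excluded == 6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_and_diff(fom_from_lists([[[0.0]]]), fom_from_lists([[[0.0], [0.0]]]))


class TestHistogramStats:
    def test_delta_at_zero(self):
        stats = histogram_stats(diff_map_from_values(np.zeros(100)))
        assert stats.mode_deg == 0.0
        assert stats.fwhm_deg == 1.0  # floored at the bin width
        assert stats.n_compared == 100

    def test_gaussian_fwhm(self, rng):
        vals = rng.normal(0.0, 10.0, size=100_000)
        vals = 90.0 - np.mod(90.0 - vals, 180.0)  # wrap to (−90, 90]
        stats = histogram_stats(diff_map_from_values(vals))
        assert abs(stats.mode_deg) <= 1.0
        assert stats.fwhm_deg == pytest.approx(2.3548 * 10.0, abs=0.8)

    def test_mode_tie_resolved_towards_zero(self):
        vals = np.array([-50.0] * 7 + [40.0] * 7 + [80.0])
        stats = histogram_stats(diff_map_from_values(vals))
        assert stats.mode_deg == 40.0

    def test_shifted_mode(self):
        stats = histogram_stats(diff_map_from_values(np.full(50, 12.3)))
        assert stats.mode_deg == 12.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_stats(diff_map_from_values(np.full(3, np.nan)))

    def test_counts_sum(self):
        vals = np.array([-10.0, 0.0, 0.0, 45.0])
        stats = histogram_stats(diff_map_from_values(vals))
        assert stats.counts.sum() == 4


class TestFullComparison:
    def test_identical_maps(self):
        grid = [[[float((7 * (r + c)) % 180)] for c in range(10)] for r in range(10)]
        fom = fom_from_lists(grid)
        stats, diff = full_comparison(fom, fom)
        assert stats.mode_deg == 0.0
        assert diff.n_compared == 100
        assert np.allclose(diff.values(), 0.0)

    def test_declared_rotation_recovered(self):
        rng = np.random.default_rng(4)
        grid = [
            [[float(rng.uniform(0, 179.9))] for _ in range(12)] for _ in range(12)
        ]
        fom = fom_from_lists(grid)
        t = RigidTransform(rotation_deg=90.0)
        rotated = apply_transform(fom, t)
        # pSHG map rotated relative to ComSLI: declaring the transform
        # brings the difference mode back to zero
        stats, _ = full_comparison(fom, rotated, transform=t)
        assert stats.mode_deg == 0.0
        assert stats.n_compared > 100

    def test_pixel_size_mismatch_handled(self):
        grid = [[[42.0] for _ in range(12)] for _ in range(12)]
        comsli = fom_from_lists(grid)
        pshg = fom_from_lists([[[42.0] for _ in range(14)] for _ in range(14)])
        stats, diff = full_comparison(
            comsli, pshg, comsli_pixel_size=2.87, pshg_pixel_size=2.37
        )
        assert stats.mode_deg == 0.0
        assert diff.n_compared == 14 * 14

    def test_unknown_direction_rejected(self):
        fom = fom_from_lists([[[0.0]]])
        with pytest.raises(ValueError):
            full_comparison(fom, fom, direction="sideways")
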