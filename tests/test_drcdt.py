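"""DRCDT transform: projections, quantile embedding, covariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculoscreen import (
    AngleGrid,
    PointSet,
    binocular_feature,
    drcdt_transform,
    quantile_resample,
    radon_project,
)


def brute_force_feature(points: np.ndarray, angles: np.ndarray, M: int) -> np.ndarray:
    """Independent oracle: dot products, sort, midpoint-quantile lookup."""
    rows = []
    for theta in angles:
        w = np.array([np.cos(theta), np.sin(theta)])
        proj = np.sort([p @ w for p in points])
        n = len(proj)
        levels = (np.arange(1, M + 1) - 0.5) / M
        pos = (np.arange(1, n + 1) - 0.5) / n
        rows.append(np.interp(levels, pos, proj))
    return np.concatenate(rows)


class TestRadonProject:
    @pytest.mark.parametrize("theta", [0.0, np.pi / 2])
    def test_axis_projections_of_unit_points(self, theta):
        ps = PointSet([[1.0, 0.0], [0.0, 1.0]])
        sp = radon_project(ps, theta)
        np.testing.assert_allclose(sp.values, [0.0, 1.0], atol=1e-12)

    def test_oblique_projection_hand_computed(self):
        ps = PointSet([[3.0, 4.0], [-1.0, 2.0], [0.0, 0.0]])
        sp = radon_project(ps, np.pi / 4)
        expected = np.sort([7 / np.sqrt(2), 1 / np.sqrt(2), 0.0])
        np.testing.assert_allclose(sp.values, expected, atol=1e-12)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            radon_project(PointSet.empty(), 0.0)


class TestQuantileResample:
    def test_two_point_set_returns_order_statistics(self):
        sp = radon_project(PointSet([[0.0, 0.0], [1.0, 0.0]]), 0.0)
        np.testing.assert_allclose(quantile_resample(sp, 2), [0.0, 1.0])

    def test_single_point_gives_constant_vector(self):
        sp = radon_project(PointSet([[2.5, 0.0]]), 0.0)
        np.testing.assert_allclose(quantile_resample(sp, 4), [2.5] * 4)

    def test_uniform_sample_approximates_quantile_function(self):
        rng = np.random.default_rng(42)
        ps = PointSet(np.column_stack([rng.uniform(0, 1, 1000), np.zeros(1000)]))
        q = quantile_resample(radon_project(ps, 0.0), 10)
        levels = (np.arange(1, 11) - 0.5) / 10
        assert np.max(np.abs(q - levels)) < 0.05

    def test_matches_order_statistics_when_divisible(self):
        # n = c*M with c odd: levels coincide with plotting positions
        rng = np.random.default_rng(3)
        M, c = 8, 3
        vals = np.sort(rng.normal(size=M * c))
        ps = PointSet(np.column_stack([vals, np.zeros(M * c)]))
        q = quantile_resample(radon_project(ps, 0.0), M)
        direct = vals[[c * i + (c - 1) // 2 for i in range(M)]]
        np.testing.assert_allclose(q, direct, atol=1e-12)


class TestDrcdtTransform:
    def test_point_mass_rows_are_projections(self):
        grid = AngleGrid.uniform(8)
        feat = drcdt_transform(PointSet([[3.0, -2.0]]), grid, 16)
        for j, theta in enumerate(grid.angles):
            expected = 3.0 * np.cos(theta) - 2.0 * np.sin(theta)
            np.testing.assert_allclose(feat.matrix[j], expected, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(37, 2)) * 50
        grid = AngleGrid.uniform(8)
        feat = drcdt_transform(PointSet(pts), grid, 64)
        oracle = brute_force_feature(pts, grid.angles, 64)
        np.testing.assert_allclose(feat.vector, oracle, atol=1e-10)

    def test_translation_covariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 2))
        t = np.array([13.0, -7.0])
        grid = AngleGrid.uniform(8)
        base = drcdt_transform(PointSet(pts), grid, 32)
        shifted = drcdt_transform(PointSet(pts).translate(t), grid, 32)
        for j, theta in enumerate(grid.angles):
            shift = t @ [np.cos(theta), np.sin(theta)]
            np.testing.assert_allclose(shifted.matrix[j], base.matrix[j] + shift,
                                       atol=1e-10)

    def test_positive_scale_covariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(25, 2))
        grid = AngleGrid.uniform(8)
        base = drcdt_transform(PointSet(pts), grid, 32)
        scaled = drcdt_transform(PointSet(pts).scale(2.5), grid, 32)
        np.testing.assert_allclose(scaled.vector, 2.5 * base.vector, atol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_permutation_invariance_and_sortedness(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(2, 40), 2))
        grid = AngleGrid.uniform(4)
        feat = drcdt_transform(PointSet(pts), grid, 16)
        shuffled = drcdt_transform(PointSet(rng.permutation(pts)), grid, 16)
        np.testing.assert_array_equal(feat.vector, shuffled.vector)
        assert (np.diff(feat.matrix, axis=1) >= 0).all()


class TestBinocularFeature:
    def test_shape_independent_of_sample_counts(self):
        rng = np.random.default_rng(0)
        grid = AngleGrid.uniform(8)
        left = PointSet(rng.normal(size=(100, 2)))
        right = PointSet(rng.normal(size=(80, 2)))
        disp = PointSet(rng.normal(size=(80, 2)))
        f = binocular_feature(left, right, disp, grid, 64)
        assert f.shape == (3 * 8 * 64,)

    def test_identical_eyes_give_equal_blocks_and_zero_disparity(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(30, 2))
        grid = AngleGrid.uniform(8)
        L = 8 * 16
        f = binocular_feature(PointSet(pts), PointSet(pts),
                              PointSet(np.zeros((30, 2))), grid, 16)
        np.testing.assert_allclose(f[:L], f[L:2 * L])
        np.testing.assert_allclose(f[2 * L:], 0.0, atol=1e-12)

    def test_swapping_eyes_swaps_blocks_and_negates_disparity(self):
        rng = np.random.default_rng(5)
        lpts, rpts = rng.normal(size=(20, 2)), rng.normal(size=(20, 2))
        grid = AngleGrid.uniform(4)
        M, L = 16, 4 * 16
        disp = PointSet(lpts - rpts)
        disp_swapped = PointSet(rpts - lpts)
        f1 = binocular_feature(PointSet(lpts), PointSet(rpts), disp, grid, M)
        f2 = binocular_feature(PointSet(rpts), PointSet(lpts), disp_swapped, grid, M)
        np.testing.assert_allclose(f1[:L], f2[L:2 * L], atol=1e-12)
        np.testing.assert_allclose(f1[L:2 * L], f2[:L], atol=1e-12)
        # negated disparity: the sorted projections mirror-reverse
        oracle = brute_force_feature(rpts - lpts, grid.angles, M)
        np.testing.assert_allclose(f2[2 * L:], oracle, atol=1e-12)

    def test_missing_eye_duplicates_present_block(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(15, 2))
        grid = AngleGrid.uniform(4)
        L = 4 * 8
        f = binocular_feature(PointSet(pts), PointSet.empty(), PointSet.empty(),
                              grid, 8)
        np.testing.assert_array_equal(f[:L], f[L:2 * L])
        np.testing.assert_array_equal(f[2 * L:], 0.0)

    def test_both_eyes_empty_errors(self):
        grid = AngleGrid.uniform(4)
        with pytest.raises(ValueError):
            binocular_feature(PointSet.empty(), PointSet.empty(),
                              PointSet.empty(), grid, 8)


class TestFeatureExport:
    def test_matrix_round_trips_with_sidecar(self, tmp_path):
        from oculoscreen.drcdt import load_feature_matrix, save_feature_matrix

        rng = np.random.default_rng(0)
        grid = AngleGrid.uniform(4)
        F = rng.normal(size=(5, 3 * 4 * 8))
        path = tmp_path / "features.csv"
        save_feature_matrix(path, F, grid, 8)
        back, meta = load_feature_matrix(path)
        np.testing.assert_allclose(back, F, atol=1e-10)
        assert meta["blocks"] == ["left", "right", "disparity"]
        np.testing.assert_allclose(meta["angles"], grid.angles)


class TestAngleGrid:
    def test_uniform_grid_unit_directions(self):
        grid = AngleGrid.uniform(8)
        np.testing.assert_allclose(grid.angles, np.arange(8) * np.pi / 8)
        np.testing.assert_allclose(np.linalg.norm(grid.directions, axis=1), 1.0,
                                   atol=1e-12)

    def test_rejects_out_of_range_angles(self):
        with pytest.raises(ValueError):
            AngleGrid([0.0, np.pi])
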