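"""Feature extraction: derivatives, curvature, variance, labelling, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cowseg.exceptions import (
    EmptyInputError,
    IncompletePatchError,
    InvalidParameterError,
    InvalidPolygonError,
)
from cowseg.features import (
    FeatureTable,
    PolygonLabel,
    extract_features,
    gradient_hessian,
    label_by_polygons,
    local_variance,
    mean_curvature,
    minmax_apply,
    minmax_fit,
    split_holdout,
)
from cowseg.scene_sim import BODY_PARTS, DepthScene, preset_pose, render_depth
from tests.conftest import make_table


def quadratic_patch(a, b, c, d, e, g, x0=0.0, y0=0.0):
    """Sample f(x,y) = a x^2/2 + b y^2/2 + c xy + d x + e y + g on the 3x3
    grid centred at (x0, y0); x is the column direction."""
    xs = np.array([x0 - 1, x0, x0 + 1])
    ys = np.array([y0 - 1, y0, y0 + 1])
    X, Y = np.meshgrid(xs, ys)
    return a * X**2 / 2 + b * Y**2 / 2 + c * X * Y + d * X + e * Y + g


class TestGradientHessian:
    def test_flat_patch(self):
        g, H = gradient_hessian(np.full((3, 3), 900.0))
        assert np.array_equal(g, [0, 0]) and not H.any()

    def test_paraboloid_offset_centre(self):
        # f = (x^2 + y^2)/2 sampled around (1, 0): grad (1, 0), Hessian I
        patch = quadratic_patch(1, 1, 0, 0, 0, 10, x0=1.0, y0=0.0)
        g, H = gradient_hessian(patch)
        assert np.allclose(g, [1.0, 0.0])
        assert np.allclose(H, np.eye(2))

    def test_saddle_cross_term(self):
        patch = quadratic_patch(0, 0, 1, 0, 0, 5)  # f = xy
        _, H = gradient_hessian(patch)
        assert H[0, 1] == pytest.approx(1.0)
        assert H[1, 0] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-3, max_value=3, allow_nan=False), min_size=6,
            max_size=6,
        )
    )
    def test_exact_on_any_quadratic(self, coeffs):
        """Central differences recover any degree-2 surface exactly."""
        a, b, c, d, e, g0 = coeffs
        patch = quadratic_patch(a, b, c, d, e, g0 + 100.0)
        if np.any(patch <= 0):
            return
        g, H = gradient_hessian(patch)
        assert np.allclose(g, [d, e], atol=1e-9)
        assert np.allclose(H, [[a, c], [c, b]], atol=1e-9)

    def test_background_in_patch_rejected(self):
        patch = np.full((3, 3), 800.0)
        patch[0, 2] = 0.0
        with pytest.raises(IncompletePatchError):
            gradient_hessian(patch)


class TestMeanCurvature:
    def test_zero_gradient_convention(self):
        assert mean_curvature([0, 0], [[5, 1], [1, -2]]) == 0.0

    def test_unit_gradient_identity_hessian(self):
        assert mean_curvature([1, 0], np.eye(2)) == pytest.approx(-0.5)

    def test_diagonal_gradient_saddle(self):
        val = mean_curvature([1, 1], [[0, 1], [1, 0]])
        assert val == pytest.approx(2.0 / (2.0 * 2.0**1.5))


class TestLocalVariance:
    def test_constant_patch(self):
        assert local_variance(np.full((3, 3), 644.0)) == 0.0

    def test_seven_two_split(self):
        patch = np.full(9, 672.0)
        patch[:2] += 1.0
        assert local_variance(patch.reshape(3, 3)) == pytest.approx(126 / 648)

    def test_eight_one_split(self):
        patch = np.full(9, 685.0)
        patch[4] += 1.0
        assert local_variance(patch.reshape(3, 3)) == pytest.approx(72 / 648)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            patch = rng.uniform(500, 4000, (3, 3))
            mean = patch.sum() / 9.0
            oracle = ((patch - mean) ** 2).sum() / 8.0
            assert local_variance(patch) == pytest.approx(oracle, rel=1e-9)


class TestLabelByPolygons:
    def test_square_interior(self):
        square = PolygonLabel(((2, 2), (2, 6), (6, 6), (6, 2)), "He")
        mask = label_by_polygons(10, 10, [square])
        assert mask[4, 4] == BODY_PARTS.index("He") + 1
        assert mask[0, 0] == 0

    def test_empty_polygon_list(self):
        assert not label_by_polygons(8, 8, []).any()

    @pytest.mark.parametrize("w,h", [(4, 4), (5, 9), (2, 3)])
    def test_strict_interior_count_on_rectangles(self, w, h):
        poly = PolygonLabel(((1, 1), (1, 1 + w), (1 + h, 1 + w), (1 + h, 1)), "Ru")
        mask = label_by_polygons(h + 4, w + 4, [poly])
        # enumeration oracle: integer points strictly inside the rectangle
        count = sum(
            1
            for r in range(h + 4)
            for c in range(w + 4)
            if 1 < r < 1 + h and 1 < c < 1 + w
        )
        assert (mask > 0).sum() == count == (w - 1) * (h - 1)

    def test_overlap_later_polygon_wins(self):
        a = PolygonLabel(((0, 0), (0, 8), (8, 8), (8, 0)), "He")
        b = PolygonLabel(((2, 2), (2, 6), (6, 6), (6, 2)), "Ba")
        mask = label_by_polygons(10, 10, [a, b])
        assert mask[4, 4] == BODY_PARTS.index("Ba") + 1
        assert mask[1, 1] == BODY_PARTS.index("He") + 1

    def test_too_few_vertices_rejected(self):
        with pytest.raises(InvalidPolygonError):
            PolygonLabel(((0, 0), (1, 1)), "He")


class TestExtractFeatures:
    def test_isolated_pixel_yields_empty_table(self):
        depth = np.zeros((9, 9), dtype=int)
        labels = np.zeros((9, 9), dtype=np.uint8)
        depth[4, 4], labels[4, 4] = 900, 1
        assert len(extract_features(DepthScene(depth, labels))) == 0

    def test_constant_block_rows_and_values(self):
        depth = np.zeros((9, 9), dtype=int)
        labels = np.zeros((9, 9), dtype=np.uint8)
        depth[2:7, 2:7] = 900
        labels[2:7, 2:7] = BODY_PARTS.index("Ru") + 1
        table = extract_features(DepthScene(depth, labels))
        assert len(table) == 9  # interior 3x3 of the 5x5 block
        assert (table.df["m_curv"] == 0).all()
        assert (table.df["var"] == 0).all()
        assert (table.df["Ru"] == 1).all()

    def test_row_count_matches_eligibility_enumeration(self, cow):
        from cowseg.scene_sim import CameraIntrinsics

        scene = render_depth(
            cow,
            intrinsics=CameraIntrinsics(image_width=64, image_height=64),
            pose=preset_pose("N"),
            noise_sigma=2.0,
            seed=3,
        )
        table = extract_features(scene)
        count = 0
        H, W = scene.depth.shape
        for r in range(H):
            for c in range(W):
                if scene.labels[r, c] == 0 or not (0 < r < H - 1 and 0 < c < W - 1):
                    continue
                if (scene.depth[r - 1 : r + 2, c - 1 : c + 2] > 0).all():
                    count += 1
        assert len(table) == count

    def test_matches_patch_functions_at_sampled_pixels(self, scene_s):
        table = extract_features(scene_s)
        sample = table.df.sample(100, random_state=0)
        for _, row in sample.iterrows():
            r, c = int(row["row"]), int(row["col"])
            patch = scene_s.depth[r - 1 : r + 2, c - 1 : c + 2].astype(float)
            g, H = gradient_hessian(patch)
            assert row["m_curv"] == pytest.approx(mean_curvature(g, H), abs=1e-9)
            assert row["var"] == pytest.approx(local_variance(patch), abs=1e-6)

    def test_upper_position_excludes_udder(self, scene_u):
        table = extract_features(scene_u)
        assert table.camera_position == "U"
        assert table.n_classes == 7
        assert not table.df["Ud"].any()
        assert len(table) > 0

    def test_max_rows_subsampling_deterministic(self, scene_s):
        a = extract_features(scene_s, max_rows=500, seed=1)
        b = extract_features(scene_s, max_rows=500, seed=1)
        assert len(a) == 500
        pd.testing.assert_frame_equal(a.df, b.df)


class TestSphereCurvature:
    """On a radially symmetric depth surface the curvature score has a
    closed form: exactly -1/(2p) at pixel distance p from the cap,
    independent of the sphere radius (it is a level-set curvature, so it
    measures the ring radius, not the surface bending)."""

    @staticmethod
    def _analytic_sphere(radius_mm, zc_mm, rows, cols):
        from cowseg.scene_sim import CameraIntrinsics

        intr = CameraIntrinsics()
        f = intr.focal_length
        cx, cy = intr.principal_point
        a = (cols - cx) / f
        b = (rows - cy) / f
        A = a * a + b * b + 1.0
        disc = zc_mm**2 - A * (zc_mm**2 - radius_mm**2)
        return (zc_mm - np.sqrt(disc)) / A

    @pytest.mark.parametrize("radius_mm", [150.0, 300.0])
    def test_level_set_closed_form_and_sign(self, radius_mm):
        from cowseg.scene_sim import CameraIntrinsics

        cx, cy = CameraIntrinsics().principal_point
        rows, cols = np.meshgrid(
            np.arange(205, 276), np.arange(285, 356), indexing="ij"
        )
        z = self._analytic_sphere(radius_mm, 1500.0, rows.astype(float),
                                  cols.astype(float))
        checked = 0
        for i in range(1, z.shape[0] - 1, 2):
            for j in range(1, z.shape[1] - 1, 2):
                p = np.hypot(rows[i, j] - cy, cols[i, j] - cx)
                if not 8.0 < p < 30.0:
                    continue
                g, H = gradient_hessian(z[i - 1 : i + 2, j - 1 : j + 2])
                mc = mean_curvature(g, H)
                assert mc < 0  # uniform sign across the visible cap
                assert mc == pytest.approx(-1.0 / (2.0 * p), rel=0.005)
                checked += 1
        assert checked > 100


class TestMinMax:
    def test_affine_map(self):
        table = make_table(np.array([[2.0], [4.0], [6.0]]), np.zeros(3, int))
        scaled = minmax_apply(table, minmax_fit(table))
        assert np.allclose(sorted(scaled.X[:, 0]), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        table = make_table(np.full((3, 5), 5.0), np.zeros(3, int))
        scaled = minmax_apply(table, minmax_fit(table))
        assert not scaled.X.any()

    def test_extrapolation_not_clipped(self):
        fit_on = make_table(np.arange(11, dtype=float)[:, None], np.zeros(11, int))
        params = minmax_fit(fit_on)
        out = minmax_apply(make_table([[12.0]], [0]), params)
        assert out.X[0, 0] == pytest.approx(1.2)

    def test_fit_then_apply_lands_in_unit_interval(self, scene_s):
        table = extract_features(scene_s, max_rows=2000, seed=0)
        scaled = minmax_apply(table, minmax_fit(table))
        assert scaled.X.min() >= 0.0 and scaled.X.max() <= 1.0

    def test_empty_fit_rejected(self):
        empty = make_table(np.empty((0, 5)), np.empty(0, int))
        with pytest.raises(EmptyInputError):
            minmax_fit(empty)

    def test_params_json_round_trip(self, tmp_path):
        table = make_table(np.arange(10, dtype=float)[:, None], np.zeros(10, int))
        params = minmax_fit(table)
        params.to_json(tmp_path / "scaler.json")
        from cowseg.features import ScalerParams

        back = ScalerParams.from_json(tmp_path / "scaler.json")
        assert np.array_equal(back.minimum, params.minimum)
        assert np.array_equal(back.maximum, params.maximum)


class TestSplitHoldout:
    def test_sizes(self):
        table = make_table(np.random.default_rng(0).normal(size=(100, 5)),
                           np.zeros(100, int))
        train, hold = split_holdout(table, 0.3, seed=0, stratified=False)
        assert len(train) == 70 and len(hold) == 30

    def test_stratified_proportions(self):
        y = np.array([0] * 90 + [1] * 10)
        table = make_table(np.random.default_rng(1).normal(size=(100, 5)), y)
        _, hold = split_holdout(table, 0.3, seed=0, stratified=True)
        counts = hold.df[["He", "Ru"]].sum()
        assert counts["He"] == 27 and counts["Ru"] == 3

    def test_disjoint_and_exhaustive(self, scene_s):
        table = extract_features(scene_s, max_rows=1000, seed=0)
        train, hold = split_holdout(table, 0.3, seed=5)
        assert len(train) + len(hold) == len(table)
        key = ["row", "col"]
        merged = train.df[key].merge(hold.df[key], on=key)
        assert merged.empty

    def test_deterministic_per_seed(self):
        table = make_table(np.random.default_rng(2).normal(size=(50, 5)),
                           np.zeros(50, int))
        a1, b1 = split_holdout(table, 0.3, seed=9)
        a2, b2 = split_holdout(table, 0.3, seed=9)
        pd.testing.assert_frame_equal(a1.df, a2.df)
        pd.testing.assert_frame_equal(b1.df, b2.df)

    def test_invalid_fraction_rejected(self):
        table = make_table(np.zeros((10, 5)), np.zeros(10, int))
        with pytest.raises(InvalidParameterError):
            split_holdout(table, 1.5, seed=0)


class TestCsvRoundTrip:
    def test_header_and_print_convention(self, scene_s, tmp_path):
        table = extract_features(scene_s, max_rows=200, seed=0)
        path = tmp_path / "features.csv"
        table.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "No,row,col,depth,m_curv,var," + ",".join(BODY_PARTS)
        back = FeatureTable.from_csv(path, camera_position="S")
        assert len(back) == len(table)
        assert np.array_equal(back.y_onehot, table.y_onehot)
        # m_curv/var survive at their printed precision
        assert np.allclose(back.df["m_curv"], table.df["m_curv"], atol=0.005 + 1e-12)
        assert np.allclose(back.df["var"], table.df["var"], atol=5e-5 + 1e-12)
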