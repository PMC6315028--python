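import numpy as np
import pandas as pd
import pytest

from scenerecall import attention, inventory as inv, maps


class TestPatchGrid:
    def test_center_count_matches_enumeration(self):
        grid = attention.build_patch_grid((512, 384), 64, 32)
        # explicit enumeration oracle
        xs = [x for x in np.arange(0, 512 + 1e-9, 32)]
        ys = [y for y in np.arange(0, 384 + 1e-9, 32)]
        assert len(grid.centers) == len(xs) * len(ys)

    def test_every_pixel_covered(self):
        for cfg in (attention.SMALL_PATCH, attention.LARGE_PATCH):
            grid = attention.build_patch_grid((128, 112), cfg["diameter"],
                                              cfg["spacing"])
            px, py = np.meshgrid(np.arange(128) + 0.5, np.arange(112) + 0.5)
            pts = np.column_stack([px.ravel(), py.ravel()])
            d2 = ((pts[:, None, :] - grid.centers[None, :, :]) ** 2).sum(-1)
            assert (d2.min(axis=1) <= (cfg["diameter"] / 2) ** 2).all()

    def test_deterministic_and_row_major(self):
        a = attention.build_patch_grid((100, 80), 30, 20)
        b = attention.build_patch_grid((100, 80), 30, 20)
        np.testing.assert_array_equal(a.centers, b.centers)
        # row-major: y constant within a row, x increasing
        first_row = a.centers[a.centers[:, 1] == 0]
        assert np.all(np.diff(first_row[:, 0]) > 0)

    def test_oversized_diameter_raises(self):
        with pytest.raises(ValueError):
            attention.build_patch_grid((100, 80), 90, 10)


class TestTPS:
    def test_interpolant_passes_through_control_points(self, rng):
        centers = rng.uniform(0, 100, size=(40, 2))
        values = rng.normal(size=40)
        out = attention.tps_interpolate(centers, values, centers, smoothing=0.0)
        np.testing.assert_allclose(out, values, atol=1e-8)

    def test_permutation_invariant_to_patch_order(self, rng):
        centers = rng.uniform(0, 50, size=(25, 2))
        values = rng.normal(size=25)
        query = rng.uniform(0, 50, size=(10, 2))
        perm = rng.permutation(25)
        a = attention.tps_interpolate(centers, values, query)
        b = attention.tps_interpolate(centers[perm], values[perm], query)
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestMeaningMap:
    def _ratings(self, grids, value_fn, n_raters=3):
        rows = []
        for g in grids.values():
            for cx, cy in g.centers:
                for k in range(n_raters):
                    rows.append({"scale": g.scale, "cx": cx, "cy": cy,
                                 "worker_id": f"w{k}",
                                 "rating": value_fn(cx, cy)})
        return pd.DataFrame(rows)

    def test_constant_ratings_degenerate_map(self):
        dims = (64, 48)
        grids = {
            "small": attention.build_patch_grid(dims, 20, 14, scale="small"),
            "large": attention.build_patch_grid(dims, 40, 28, scale="large"),
        }
        ratings = self._ratings(grids, lambda x, y: 4)
        m = attention.build_meaning_map(ratings, grids, dims,
                                        center_bias_sigma=None, eval_stride=2)
        assert not m.values.any()

    def test_nondegenerate_map_spans_unit_interval(self):
        dims = (64, 48)
        grids = {
            "small": attention.build_patch_grid(dims, 20, 14, scale="small"),
            "large": attention.build_patch_grid(dims, 40, 28, scale="large"),
        }
        ratings = self._ratings(grids, lambda x, y: 1 + 5 * x / 64)
        m = attention.build_meaning_map(ratings, grids, dims,
                                        center_bias_sigma=None, eval_stride=2)
        assert m.values.min() == 0.0 and m.values.max() == 1.0

    def test_missing_scale_raises(self):
        dims = (64, 48)
        grids = {"small": attention.build_patch_grid(dims, 20, 14, scale="small")}
        with pytest.raises(ValueError, match="large"):
            attention.build_meaning_map(pd.DataFrame(
                {"scale": ["small"], "cx": [0.0], "cy": [0.0],
                 "worker_id": ["w"], "rating": [3]}), grids, dims)

    def test_reconstructs_latent_field(self):
        # noisy two-scale ratings of a smooth field: reconstruction correlates
        from scenerecall import synth

        dims = (256, 192)
        sc = synth.generate_scene(4, seed=23, image_dims=dims)
        grids = {
            "small": attention.build_patch_grid(dims, 24, 12, scale="small"),
            "large": attention.build_patch_grid(dims, 48, 24, scale="large"),
        }
        ratings = pd.concat([
            synth.simulate_patch_ratings(sc.meaning, g, rater_sd=0.5, seed=3)
            for g in grids.values()])
        m = attention.build_meaning_map(ratings, grids, dims,
                                        center_bias_sigma=None, eval_stride=2)
        r = np.corrcoef(m.values.ravel(), sc.meaning.ravel())[0, 1]
        assert r > 0.9


class TestSaliency:
    def test_linear_rescale(self):
        arr = np.array([[2.0, 6.0], [10.0, 4.0]])
        m = attention.load_saliency_map(arr, (2, 2))
        np.testing.assert_allclose(m.values, (arr - 2) / 8)

    def test_constant_input_zero_map(self):
        m = attention.load_saliency_map(np.full((4, 4), 3.0), (4, 4))
        assert not m.values.any()

    def test_non_finite_raises(self):
        arr = np.array([[1.0, np.nan], [0.0, 2.0]])
        with pytest.raises(ValueError):
            attention.load_saliency_map(arr, (2, 2))

    def test_csv_roundtrip(self, tmp_path, rng):
        arr = rng.random((8, 6))
        np.savetxt(tmp_path / "s.csv", arr, delimiter=",")
        m = attention.load_saliency_map(str(tmp_path / "s.csv"), (6, 8))
        np.testing.assert_allclose(
            m.values, (arr - arr.min()) / (arr.max() - arr.min()), rtol=1e-10)


class TestObjectScores:
    def _scene(self):
        image = inv.SceneImage("img", "c", 4, 4)
        o = inv.SceneObject("o", "x", [(0, 0), (2, 0), (2, 2), (0, 2)])
        inv.object_geometry(o, (4, 4))
        s = inv.SceneInventory(image, [o], filtered_object_ids=["o"])
        return s

    def test_uniform_map_mean_equals_peak(self):
        s = self._scene()
        m = maps.ObjectMap("img", np.full((4, 4), 0.7), "saliency")
        mean = attention.object_model_scores(m, s, "mean").loc[0, "score"]
        peak = attention.object_model_scores(m, s, "peak").loc[0, "score"]
        assert mean == peak == pytest.approx(0.7)

    def test_gradient_mean_below_peak(self):
        s = self._scene()
        vals = np.arange(16, dtype=float).reshape(4, 4)
        m = maps.ObjectMap("img", vals, "saliency")
        mean = attention.object_model_scores(m, s, "mean").loc[0, "score"]
        peak = attention.object_model_scores(m, s, "peak").loc[0, "score"]
        assert mean < peak

    def test_hand_computed_mean(self):
        s = self._scene()
        vals = np.zeros((4, 4))
        vals[0, 0], vals[0, 1], vals[1, 0], vals[1, 1] = 1, 2, 3, 6
        m = maps.ObjectMap("img", vals, "saliency")
        out = attention.object_model_scores(m, s, "mean")
        assert out.loc[0, "score"] == pytest.approx(3.0)

    def test_bad_mode_raises(self):
        with pytest.raises(ValueError):
            attention.object_model_scores(
                maps.ObjectMap("x", np.ones((4, 4)), "saliency"),
                self._scene(), "median")


class TestRecallModelCorrelation:
    def test_monotone_relation_gives_rho_one(self):
        x = np.array([0.1, 0.3, 0.5, 0.8, 0.9])
        res = attention.recall_model_correlation(x**2, x)
        assert res.rho == pytest.approx(1.0)

    def test_constant_control_falls_back_to_simple(self, rng):
        x = rng.random(30)
        y = 0.5 * x + rng.normal(0, 0.2, 30)
        simple = attention.recall_model_correlation(y, x)
        semi = attention.recall_model_correlation(y, x, np.full(30, 2.0),
                                                  method="semi_partial")
        assert semi.rho == pytest.approx(simple.rho)
        assert semi.method == "simple"

    def test_semi_partial_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.random(60)
        z = rng.random(60)
        y = 0.5 * x + 0.5 * z + rng.normal(0, 0.3, 60)
        res = attention.recall_model_correlation(y, x, z, method="semi_partial",
                                                 residualize="predictor")
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", x_covar="z",
                                    method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_partial_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.random(50)
        z = rng.random(50)
        y = 0.4 * x + 0.6 * z + rng.normal(0, 0.3, 50)
        res = attention.recall_model_correlation(y, x, z, method="partial")
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_planted_semi_partial_structure_recovered(self, rng):
        # y depends on x only through z: semi-partial of x beyond z is ~0
        n = 400
        z = rng.normal(size=n)
        x = z + rng.normal(0, 0.5, n)
        y = z + rng.normal(0, 0.5, n)
        semi = attention.recall_model_correlation(y, x, z, method="semi_partial")
        assert abs(semi.rho) < 0.12
        simple = attention.recall_model_correlation(y, x)
        assert simple.rho > 0.4

    def test_small_n_flagged(self):
        res = attention.recall_model_correlation([1, 2], [2, 1])
        assert np.isnan(res.rho) and "n<3" in res.flags

    def test_rank_invariance_under_monotone_map_transform(self, rng):
        x = rng.random(40)
        y = 0.6 * x + rng.normal(0, 0.2, 40)
        a = attention.recall_model_correlation(y, x)
        b = attention.recall_model_correlation(y, np.exp(3 * x))
        assert a.rho == pytest.approx(b.rho)
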