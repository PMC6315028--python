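import numpy as np
import pandas as pd
import pytest

from scenerecall import attention, crowd, synth


class TestGenerateScene:
    def test_object_count_and_size_guarantee(self):
        sc = synth.generate_scene(5, seed=7)
        assert len(sc.inventory.objects) == 5
        assert all(o.equivalent_diameter >= 50 for o in sc.inventory.objects)

    def test_same_seed_identical(self):
        a = synth.generate_scene(8, seed=42)
        b = synth.generate_scene(8, seed=42)
        for oa, ob in zip(a.inventory.objects, b.inventory.objects):
            np.testing.assert_array_equal(oa.polygon, ob.polygon)
        np.testing.assert_array_equal(a.saliency, b.saliency)
        np.testing.assert_array_equal(a.meaning, b.meaning)

    def test_space_defining_surface_filtered_out(self):
        sc = synth.generate_scene(4, seed=1, n_space_defining=1)
        names = {o.name for o in sc.inventory.objects}
        assert "wall" in names
        filtered_names = {o.name for o in sc.inventory.filtered_objects}
        assert "wall" not in filtered_names

    def test_latent_fields_unit_interval(self):
        sc = synth.generate_scene(5, seed=2)
        for f in (sc.saliency, sc.meaning):
            assert f.min() >= 0 and f.max() <= 1
            assert f.shape == (384, 512)

    def test_bad_k_raises(self):
        with pytest.raises(ValueError):
            synth.generate_scene(0, seed=0)

    def test_object_count_distribution(self):
        scenes, manifest = synth.generate_study_scenes(seed=9, n_categories=25)
        ks = manifest["n_objects"].to_numpy()
        assert ks.min() >= 6 and ks.max() <= 50
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        # clipping at 6/50 pulls the mean slightly below 21.1
        assert abs(ks.mean() - 21.1) < 3 * se + 1.0


@pytest.fixture(scope="module")
def mini_world():
    scenes, manifest = synth.generate_study_scenes(seed=13, n_categories=4)
    return scenes, manifest


class TestSimulateStudy:
    def test_noiseless_limit_draws_everything_exactly(self, mini_world):
        scenes, manifest = mini_world
        params = synth.ConditionParams(
            condition="image_drawing", image_recall_prob=1.0,
            mean_object_recall_prob=1.0, mean_abs_dx=0.0, mean_abs_dy=0.0,
            size_bias_w=0.0, size_bias_h=0.0, size_noise_sd=0.0,
            extra_object_rate=0.0)
        contents = synth.simulate_study(scenes, manifest, params, 2, seed=3)
        assert len(contents) == 2 * 4  # every participant drew every image
        for c in contents:
            invf = scenes[c.image_id].inventory
            assert {d[0] for d in c.drawn_objects} == set(invf.filtered_object_ids)
            for oid, (cx, cy), w, h in c.drawn_objects:
                ex, ey, ew, eh = invf.object_by_id(oid).bounding_ellipse
                assert (cx, cy) == pytest.approx((ex, ey))
                assert (w, h) == pytest.approx((ew, eh))
            assert c.extra_objects == []

    def test_mean_absolute_displacement_half_normal_identity(self, mini_world):
        # E|N(0, s)| = s*sqrt(2/pi), so recovered mean |dx| equals the target
        scenes, manifest = mini_world
        params = synth.ConditionParams(
            condition="delayed_recall", image_recall_prob=1.0,
            mean_object_recall_prob=1.0, mean_abs_dx=0.065, mean_abs_dy=0.099,
            size_noise_sd=0.0, size_bias_w=0.0, size_bias_h=0.0)
        contents = synth.simulate_study(scenes, manifest, params, 120, seed=8)
        dxs, dys = [], []
        for c in contents:
            invf = scenes[c.image_id].inventory
            for oid, (cx, cy), _, _ in c.drawn_objects:
                ex, ey, _, _ = invf.object_by_id(oid).bounding_ellipse
                dxs.append(abs(cx - ex))
                dys.append(abs(cy - ey))
        dxs, dys = np.array(dxs), np.array(dys)
        assert len(dxs) >= 10_000
        for arr, target in ((dxs, 0.065), (dys, 0.099)):
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            # centroid clipping to [0,1] shrinks a handful of extreme draws
            assert abs(arr.mean() - target) < 3 * se + 1e-3

    def test_extra_objects_poisson_mean(self, mini_world):
        scenes, manifest = mini_world
        params = synth.ConditionParams(
            condition="image_drawing", image_recall_prob=1.0,
            mean_object_recall_prob=0.3, extra_object_rate=1.83 / 30)
        contents = synth.simulate_study(scenes, manifest, params, 200, seed=21)
        per_part = {}
        for c in contents:
            per_part.setdefault(c.participant_id, 0)
            per_part[c.participant_id] += len(c.extra_objects)
        totals = np.array(list(per_part.values()))
        target = 1.83 / 30 * 4  # 4 drawings per participant here
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - target) < 3 * se

    def test_object_recall_targets_mean_probability(self, mini_world):
        scenes, manifest = mini_world
        params = synth.DEFAULT_CONDITIONS["delayed_recall"]
        probs = synth.object_recall_probabilities(scenes, params)
        assert probs["p_drawn"].mean() == pytest.approx(0.374, abs=1e-6)


class TestSimulateCrowd:
    def _contents(self, mini_world, **over):
        scenes, manifest = mini_world
        params = synth.ConditionParams(
            condition="delayed_recall", image_recall_prob=1.0,
            mean_object_recall_prob=0.5, extra_object_rate=0.5, **over)
        return scenes, synth.simulate_study(scenes, manifest, params, 3, seed=5)

    def test_noiseless_crowd_reproduces_ground_truth(self, mini_world):
        scenes, contents = self._contents(mini_world, mean_abs_dx=0.0,
                                          mean_abs_dy=0.0, size_bias_w=0.0,
                                          size_bias_h=0.0, size_noise_sd=0.0)
        tables = synth.simulate_crowd(contents, scenes, synth.NOISELESS, seed=6)
        ms = crowd.score_matching(tables["match_trials"])
        assert (ms["proportion_correct"] == 1.0).all()

        for c in contents:
            inv = scenes[c.image_id].inventory
            pres = crowd.aggregate_presence(
                tables["presence_votes"][
                    tables["presence_votes"]["drawing_id"] == c.drawing_id], inv)
            assert set(pres.loc[0, "present_object_ids"]) == {
                d[0] for d in c.drawn_objects}

        agg = crowd.aggregate_ellipses(tables["ellipses"])
        truth = {
            (c.drawing_id, d[0]): d for c in contents for d in c.drawn_objects}
        for rec in agg.itertuples(index=False):
            _, (cx, cy), w, h = truth[(rec.drawing_id, rec.object_id)]
            assert (rec.cx, rec.cy) == pytest.approx((cx, cy), abs=1e-9)
            assert (rec.w, rec.h) == pytest.approx((w, h), abs=1e-9)

        extras = crowd.count_extra_objects(tables["extra_reports"])
        for c in contents:
            got = extras.loc[extras["drawing_id"] == c.drawing_id,
                             "n_extras"].iloc[0]
            want = len({crowd.normalize_name(n) for n in c.extra_objects})
            assert got == want

    def test_worker_counts_validated(self, mini_world):
        scenes, contents = self._contents(mini_world)
        with pytest.raises(ValueError):
            synth.simulate_crowd(contents, scenes, synth.NOISELESS, seed=0,
                                 worker_counts={"match": 0})

    def test_deterministic_under_seed(self, mini_world):
        scenes, contents = self._contents(mini_world)
        t1 = synth.simulate_crowd(contents, scenes, synth.WorkerNoise(), seed=9)
        t2 = synth.simulate_crowd(contents, scenes, synth.WorkerNoise(), seed=9)
        for key in t1:
            pd.testing.assert_frame_equal(t1[key], t2[key])


class TestPatchRatings:
    def test_zero_noise_constant_field(self):
        field = np.full((96, 128), 0.6, dtype=np.float32)
        grid = attention.build_patch_grid((128, 96), 30, 20, scale="small")
        out = synth.simulate_patch_ratings(field, grid, rater_sd=0.0, seed=1)
        assert (out["rating"] == 4).all()  # 1 + 5*0.6 = 4

    def test_ratings_bounded(self):
        rng = np.random.default_rng(3)
        field = rng.random((96, 128)).astype(np.float32)
        grid = attention.build_patch_grid((128, 96), 30, 20, scale="small")
        out = synth.simulate_patch_ratings(field, grid, rater_sd=3.0, seed=2)
        assert out["rating"].between(1, 6).all()

    def test_many_raters_converge_to_latent(self):
        field = np.full((64, 64), 0.5, dtype=np.float32)
        grid = attention.build_patch_grid((64, 64), 30, 30, scale="small")
        out = synth.simulate_patch_ratings(field, grid, rater_sd=0.8,
                                           n_raters=200, seed=4)
        m = out.groupby(["cx", "cy"])["rating"].mean()
        assert np.allclose(m, 3.5, atol=0.25)  # latent 1 + 5*0.5


class TestRecognition:
    def test_extreme_ability_limits(self):
        scenes, manifest = synth.generate_study_scenes(seed=17, n_categories=3)
        trials = synth.simulate_recognition(manifest, 4, seed=1, ability=50.0,
                                            fa_rate=0.0)
        targets = trials[trials["is_target"]]
        foils = trials[~trials["is_target"]]
        assert (targets["response"] == "old").all()
        assert (foils["response"] == "new").all()

    def test_no_memorability_effect_under_null(self):
        scenes, manifest = synth.generate_study_scenes(seed=17, n_categories=6)
        trials = synth.simulate_recognition(manifest, 120, seed=2,
                                            memorability_effect=0.0)
        t = trials[trials["is_target"]].assign(
            hit=lambda d: d["response"].eq("old"))
        rates = t.groupby("memorability_half")["hit"].mean()
        assert abs(rates["high"] - rates["low"]) < 0.05

    def test_positive_effect_recovered(self):
        scenes, manifest = synth.generate_study_scenes(seed=17, n_categories=6)
        trials = synth.simulate_recognition(manifest, 120, seed=3,
                                            memorability_effect=3.0)
        t = trials[trials["is_target"]].assign(
            hit=lambda d: d["response"].eq("old"))
        rates = t.groupby("memorability_half")["hit"].mean()
        assert rates["high"] > rates["low"]

    def test_missing_foils_raise(self):
        scenes, manifest = synth.generate_study_scenes(seed=17, n_categories=3)
        with pytest.raises(ValueError):
            synth.simulate_recognition(
                manifest[manifest["role"] != "medium_foil"], 2, seed=0)
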