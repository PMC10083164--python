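"""ENL / CNR / NSS-score metrics, summaries and checkpoint selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from octpt import quality as q
from octpt.phantom import BScanImage, MACULAR_CUBE, simulate_bscan


@pytest.fixture(scope="module")
def speckle_image():
    rng = np.random.default_rng(0)
    return rng.exponential(1.0, (120, 120))


class TestENL:
    def test_unit_exponential_background(self, speckle_image):
        # mean^2/var of a unit-mean exponential is 1
        val = q.enl(speckle_image / speckle_image.max(), (0, 0, 100, 100))
        se = 3 * np.sqrt(1.0 / 1e4) * 4  # generous sampling-error band
        assert abs(val - 1.0) < se

    def test_scale_invariance(self, speckle_image):
        a = q.enl(speckle_image, (0, 0, 50, 50))
        b = q.enl(speckle_image * 0.37, (0, 0, 50, 50))
        assert a == pytest.approx(b, rel=1e-9)

    def test_constant_region_error(self):
        with pytest.raises(q.UndefinedMetricError):
            q.enl(np.full((20, 20), 0.5), (0, 0, 10, 10))

    def test_recovers_look_count_on_phantom_background(self):
        vals = []
        refl = np.full((64, 64), 0.3)
        for looks, preset in ((9, MACULAR_CUBE),):
            for rep in range(20):
                img = simulate_bscan(refl, preset, seed=rep,
                                     log_compress=False)
                vals.append(q.enl(img, (0, 0, 64, 64)))
        assert np.mean(vals) == pytest.approx(9.0, rel=0.1)


class TestCNR:
    def test_zero_when_means_equal(self):
        rng = np.random.default_rng(1)
        img = rng.normal(1.0, 0.1, (40, 40))
        img[:10, :10] = img[20:30, 20:30]
        assert q.cnr(img, (0, 0, 10, 10), (20, 20, 10, 10)) == pytest.approx(
            0.0, abs=1e-12)

    def test_direct_substitution(self):
        img = np.zeros((20, 20))
        img[:5, :5] = 20.0
        rng = np.random.default_rng(2)
        img[10:, 10:] = rng.normal(10.0, 2.0, (10, 10))
        bg = img[10:, 10:]
        expected = (20.0 - bg.mean()) / bg.std(ddof=1)
        assert q.cnr(img, (0, 0, 5, 5), (10, 10, 10, 10)) == pytest.approx(
            expected)

    @given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    def test_scale_and_offset_invariance(self, scale, offset):
        rng = np.random.default_rng(3)
        img = rng.uniform(0.2, 1.0, (30, 30))
        base = q.cnr(img, (0, 0, 10, 10), (15, 15, 10, 10))
        scaled = q.cnr(img * scale + offset, (0, 0, 10, 10), (15, 15, 10, 10))
        assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_constant_background_error(self):
        img = np.zeros((20, 20))
        img[:5, :5] = 1.0
        with pytest.raises(q.UndefinedMetricError):
            q.cnr(img, (0, 0, 5, 5), (10, 10, 5, 5))


class TestROIAnnotation:
    def test_overlap_rejected(self):
        ann = q.ROIAnnotation((0, 0, 10, 10), (5, 5, 10, 10))
        with pytest.raises(ValueError, match="overlap"):
            ann.validate((64, 64))

    def test_outside_image_rejected(self):
        ann = q.ROIAnnotation((0, 0, 10, 10), (60, 60, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            ann.validate((64, 64))


class TestNSSFeatures:
    def test_feature_vector_length_36(self, speckle_image):
        feats = q.brisque_features(speckle_image / speckle_image.max())
        assert feats.shape == (36,)
        assert np.all(np.isfinite(feats))

    def test_deterministic(self, speckle_image):
        img = speckle_image / speckle_image.max()
        np.testing.assert_array_equal(q.brisque_features(img),
                                      q.brisque_features(img))

    def test_constant_image_error(self):
        with pytest.raises(q.UndefinedMetricError):
            q.brisque_features(np.full((64, 64), 0.5))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            q.brisque_features(np.zeros((16, 16)))

    def test_missing_scorer_error(self, speckle_image):
        with pytest.raises(q.ConfigurationError):
            q.brisque_score(speckle_image / speckle_image.max(), None)

    def test_synthetic_scorer_ranks_speckle(self):
        """Heavier look averaging (higher quality) must score lower."""
        scorer = q.train_synthetic_scorer(seed=0, n_per_level=6,
                                          looks_levels=(1, 4, 9, 25))
        rng = np.random.default_rng(5)
        from octpt.phantom import (sample_phantom_spec, make_reflectivity_map,
                                   PresetProfile)
        means = []
        for looks in (1, 25):
            scores = []
            preset = PresetProfile(f"l{looks}", looks, 1, (1, 1))
            for i in range(6):
                spec = sample_phantom_spec(rng, 64, 64)
                img = simulate_bscan(make_reflectivity_map(spec), preset,
                                     seed=300 + i)
                scores.append(q.brisque_score(img, scorer))
            means.append(np.mean(scores))
        assert means[0] > means[1]  # 1-look noisier -> worse (higher) score


class TestSummaries:
    def test_constant_sample(self):
        mean, sd, skw = q.summarize_scores([1.0, 1.0, 1.0, 1.0])
        assert (mean, sd, skw) == (1.0, 0.0, 0.0)

    def test_symmetric_sample(self):
        _, _, skw = q.summarize_scores([-1.0, 0.0, 1.0])
        assert skw == pytest.approx(0.0, abs=1e-12)

    def test_matches_moment_formula(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(1.0, 500)
        mean, sd, skw = q.summarize_scores(x)
        n = len(x)
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        g1 = m3 / m2 ** 1.5
        adj = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        assert mean == pytest.approx(x.mean())
        assert sd == pytest.approx(x.std(ddof=1))
        assert skw == pytest.approx(adj, rel=1e-9)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            q.summarize_scores([1.0])


class FakeCkpt:
    def __init__(self, epoch):
        self.epoch = epoch


class TestCheckpointSelection:
    def test_mean_of_two_images(self):
        imgs = ["a", "b"]
        scores = {"a": 1.0, "b": 3.0}
        table = q.evaluate_checkpoints([FakeCkpt(20)], imgs,
                                       score_fn=lambda s: scores[s],
                                       convert=lambda c, s: s)
        assert len(table) == 1
        assert table.loc[0, "mean"] == pytest.approx(2.0)

    def test_one_row_per_checkpoint_and_permutation_invariance(self):
        imgs = list("abcd")
        scores = dict(zip(imgs, [4.0, 1.0, 3.0, 2.0]))
        kwargs = dict(score_fn=lambda s: scores[s], convert=lambda c, s: s)
        t1 = q.evaluate_checkpoints([FakeCkpt(20), FakeCkpt(40)], imgs, **kwargs)
        t2 = q.evaluate_checkpoints([FakeCkpt(20), FakeCkpt(40)], imgs[::-1],
                                    **kwargs)
        assert len(t1) == 2
        np.testing.assert_allclose(t1["mean"], t2["mean"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            q.evaluate_checkpoints([], ["a"], lambda s: 0, lambda c, s: s)

    def test_lowest_highest_and_ties(self):
        table = pd.DataFrame({"epoch": [20, 40, 60],
                              "mean": [3.0, 1.0, 2.0]})
        assert q.select_checkpoint(table, "lowest") == 40
        assert q.select_checkpoint(table, "highest") == 20
        tie = pd.DataFrame({"epoch": [40, 20], "mean": [1.0, 1.0]})
        assert q.select_checkpoint(tie, "lowest") == 20  # earliest epoch wins

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            q.select_checkpoint(pd.DataFrame(columns=["epoch", "mean"]),
                                "lowest")


class TestQualityReport:
    def test_summary_recomputable(self, tmp_path):
        rep = q.QualityReport()
        for i, v in enumerate([1.0, 2.0, 3.0]):
            rep.add(f"img{i}", "enl", v)
        summary = rep.summary()
        row = summary[summary.metric == "enl"].iloc[0]
        assert row["count"] == 3
        assert row["mean"] == pytest.approx(2.0)
        rep.to_csv(tmp_path / "scores.csv")
        back = pd.read_csv(tmp_path / "scores.csv")
        assert len(back) == 3

    def test_histogram_export(self, tmp_path):
        q.plot_score_histograms({"set_a": [1, 2, 3], "set_b": [2, 3, 4]},
                                tmp_path / "hist.png")
        assert (tmp_path / "hist.png").stat().st_size > 0
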