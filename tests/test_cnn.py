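import numpy as np
import pytest

import dcrisk as d
from dcrisk.cnn_classifier import CNN, ConfigurationError, ModelConfig

from .oracles import pair_count_auc


def _zeroed_model(**kw):
    m = d.build_model(ModelConfig(input_normalization="none", **kw))
    for p in m.net.params:
        p[...] = 0.0
    return m


class TestArchitecture:
    def test_shape_chain(self):
        """1536 -> (6,16,16) -> 768 flattened -> 192 hidden -> 2 out."""
        trace = dict(d.build_model().shape_trace())
        assert trace["input"] == (1, 6, 16, 16)
        assert trace["Flatten"] == (768,)
        assert trace["Linear"] == (2,)  # last Linear wins in the dict
        names = [n for n, _ in d.build_model().shape_trace()]
        shapes = [s for _, s in d.build_model().shape_trace()]
        assert shapes[names.index("Linear")] == (192,)

    def test_pooling_halves_spatial_grid(self):
        trace = d.build_model().shape_trace()
        pool_shapes = [s for n, s in trace if n == "AvgPool1x2x2"]
        assert pool_shapes == [(4, 6, 8, 8), (8, 6, 4, 4)]

    def test_bad_channel_plan_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(channels=(1, 4, 4))

    def test_accepts_vectors_and_tensors(self, rng):
        m = _zeroed_model()
        v = rng.random((3, 1536))
        t = v.reshape(3, 6, 16, 16)
        np.testing.assert_array_equal(m.predict_proba(v),
                                      m.predict_proba(t))


class TestSoftmax:
    def test_zero_weights_give_half_half(self, rng):
        m = _zeroed_model()
        proba = m.predict_proba(rng.random((4, 6, 16, 16)))
        np.testing.assert_allclose(proba, 0.5)

    def test_probabilities_sum_to_one(self, rng):
        m = d.build_model(ModelConfig(input_normalization="none"))
        proba = m.predict_proba(rng.random((10, 6, 16, 16)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_tie_resolves_to_low_risk(self, rng):
        m = _zeroed_model()
        assert (m.predict(rng.random((5, 6, 16, 16))) == 0).all()


class TestBalanceDownsample:
    def test_majority_reduced(self, rng):
        X = rng.random((140, 4))
        y = np.array([1] * 100 + [0] * 40)
        Xb, yb, idx = d.balance_downsample(X, y, seed=0)
        assert (yb == 1).sum() == 40 and (yb == 0).sum() == 40

    def test_balanced_is_identity(self, rng):
        X = rng.random((8, 4))
        y = np.array([0, 1] * 4)
        Xb, yb, idx = d.balance_downsample(X, y, seed=3)
        np.testing.assert_array_equal(idx, np.arange(8))
        np.testing.assert_array_equal(Xb, X)

    def test_seed_reproducible(self, rng):
        X = rng.random((50, 4))
        y = np.array([1] * 35 + [0] * 15)
        _, _, i1 = d.balance_downsample(X, y, seed=11)
        _, _, i2 = d.balance_downsample(X, y, seed=11)
        np.testing.assert_array_equal(i1, i2)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            d.balance_downsample(rng.random((5, 2)), np.ones(5), seed=0)


class _ScoreStub:
    """Stands in for a trained model: fixed scores for evaluate()."""

    def __init__(self, p1):
        self.p1 = np.asarray(p1, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.p1, self.p1])

    def predict(self, X):
        return (self.p1 > 0.5).astype(int)


class TestEvaluate:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        rep = d.evaluate(_ScoreStub([.1, .2, .3, .7, .8, .9]), np.zeros(6), y)
        assert rep.auc == 1.0
        np.testing.assert_array_equal(rep.confusion, [[3, 0], [0, 3]])

    def test_reversed_ranking(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        rep = d.evaluate(_ScoreStub([.9, .8, .7, .3, .2, .1]), np.zeros(6), y)
        assert rep.auc == 0.0

    def test_matches_pair_count_oracle_with_tie(self):
        scores = [.2, .4, .4, .3, .6, .9]
        y = np.array([0, 0, 0, 1, 1, 1])
        rep = d.evaluate(_ScoreStub(scores), np.zeros(6), y)
        expected = pair_count_auc(scores[3:], scores[:3])
        assert rep.auc == pytest.approx(expected)

    def test_single_class_auc_undefined(self):
        rep = d.evaluate(_ScoreStub([.2, .6]), np.zeros(2),
                         np.array([1, 1]))
        assert rep.auc is None and rep.confusion.sum() == 2


class TestTraining:
    def _separable_data(self):
        X = np.zeros((40, 6, 16, 16))
        X[:20, :, :, :8] = 1.0   # pattern A
        X[20:, :, :, 8:] = 1.0   # pattern B
        y = np.array([1] * 20 + [0] * 20)
        return X, y

    def test_separable_patterns_reach_full_accuracy(self):
        X, y = self._separable_data()
        cfg = ModelConfig(seed=0, epochs=30, input_normalization="none")
        m = d.build_model(cfg)
        d.train(m, X, y, cfg)
        assert (m.predict(X) == y).all()

    def test_loss_decreases(self):
        X, y = self._separable_data()
        cfg = ModelConfig(seed=0, epochs=15, input_normalization="none")
        m = d.build_model(cfg)
        hist = d.train(m, X, y, cfg)
        assert np.mean(hist[-1]) < np.mean(hist[0])
        assert len(hist) == 15  # one loss list per epoch

    def test_seeded_training_reproducible(self):
        X, y = self._separable_data()
        histories = []
        for _ in range(2):
            cfg = ModelConfig(seed=5, epochs=5, input_normalization="none")
            m = d.build_model(cfg)
            histories.append(d.train(m, X, y, cfg))
        assert histories[0] == histories[1]


class TestCrossValidation:
    def test_every_sample_in_exactly_one_validation_fold(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0, 1] * 25)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(50, dtype=int)
        for _, va in skf.split(np.zeros((50, 1)), y):
            seen[va] += 1
        assert (seen == 1).all()

    def test_fit_with_cv_reports_fold_aucs(self, small_training_data):
        X, y, _ = small_training_data
        cfg = ModelConfig(seed=7, epochs=5, folds=5)
        res = d.DCRClassifier(X, y, cfg).fit(cross_validate=True)
        assert len(res.cv_reports) == 5
        assert all(0 <= a <= 1 for a in res.cv_aucs)


class TestFcLayerPca:
    def test_identical_activations_not_significant(self):
        m = _zeroed_model()
        X = np.ones((12, 6, 16, 16))
        y = np.array([0, 1] * 6)
        out = d.fc_layer_pca_test(m, X, y, seed=0)
        assert out["pca1"]["p_paired"] == pytest.approx(1.0)

    def test_group_offset_loads_on_first_component(self, rng):
        cfg = ModelConfig(seed=1, input_normalization="none")
        m = d.build_model(cfg)
        noise = rng.normal(0, 0.01, size=(40, 6, 16, 16))
        X = noise.copy()
        X[:20] += 1.0  # constant offset for the high-risk group
        y = np.array([1] * 20 + [0] * 20)
        out = d.fc_layer_pca_test(m, X, y, seed=0)
        assert out["pca1"]["p_paired"] < 0.05
        assert out["pca2"]["p_paired"] > 0.05

    def test_components_uncorrelated(self, rng):
        m = d.build_model(ModelConfig(seed=2, input_normalization="none"))
        X = rng.random((30, 6, 16, 16))
        y = np.array([0, 1] * 15)
        out = d.fc_layer_pca_test(m, X, y, seed=0)
        c = out["coordinates"]
        cov = np.cov(c.T)[0, 1]
        assert abs(cov) < 1e-8 * max(1.0, np.cov(c.T)[0, 0])

    def test_small_group_errors(self):
        m = _zeroed_model()
        with pytest.raises(ValueError):
            d.fc_layer_pca_test(m, np.ones((4, 6, 16, 16)),
                                np.array([0, 0, 1, 1]))


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(seed=3)
        m = d.build_model(cfg)
        X = rng.random((30, 6, 16, 16))
        y = np.array([0, 1] * 15)
        d.train(m, X, y, ModelConfig(seed=3, epochs=2))
        m.save(tmp_path / "model")
        loaded = CNN.load(tmp_path / "model")
        np.testing.assert_array_equal(m.predict_proba(X),
                                      loaded.predict_proba(X))
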