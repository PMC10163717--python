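"""mCNN architecture, training behavior, grid search, meta-ML comparison."""

import numpy as np
import pytest

from qsarstack import meta
from qsarstack.evaluation import evaluate
from qsarstack.zoo import PFMatrix


def _toy_pf(n=60, d=12, seed=0, signal=True):
    """PF matrix where column 0 equals the label (perfectly separable)."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.uniform(0.2, 0.8, size=(n, d))
    if signal:
        X[:, 0] = y * 0.98 + 0.01
    cols = [f"BM{i}" for i in range(d)]
    return PFMatrix([f"c{i}" for i in range(n)], cols, X), y


class TestArchitecture:
    def test_default_filter_budget(self):
        model = meta.build_mcnn()
        assert model.total_filters == 300
        assert model.input_length == 156

    def test_default_pooling_gives_6d_penultimate(self):
        assert meta.build_mcnn().penultimate_dim == 6

    def test_alternative_pooling_also_6d_via_dense(self):
        cfg = meta.MetaModelConfig(pooling="filter-max-dense")
        model = meta.build_mcnn(cfg)
        assert model.penultimate_dim == 6
        assert model.W_mid.shape == (300, 6)

    def test_region_size_exceeding_input_rejected(self):
        with pytest.raises(ValueError, match="region size"):
            meta.MCnn(meta.MetaModelConfig(region_sizes=(3, 200)), input_length=156)

    def test_nonpositive_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            meta.MetaModelConfig(learning_rate=0.0)

    @pytest.mark.parametrize("pooling", meta.POOLING_SCHEMES)
    def test_softmax_outputs_normalized(self, pooling):
        pf, y = _toy_pf()
        cfg = meta.MetaModelConfig(epochs=3, pooling=pooling, seed=1)
        model = meta.MCnn(cfg, input_length=12).fit(pf, y)
        probs = model.predict_proba(pf)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestTraining:
    def test_learns_separable_pf_signal(self):
        # the 6-D pooled bottleneck needs a hot learning rate on tiny data
        pf, y = _toy_pf()
        cfg = meta.MetaModelConfig(epochs=150, learning_rate=1e-2, seed=0)
        model = meta.MCnn(cfg, input_length=12).fit(pf, y)
        assert evaluate(y, model.predict_scores(pf)).MCC == pytest.approx(1.0)

    def test_fit_is_deterministic(self):
        pf, y = _toy_pf()
        cfg = meta.MetaModelConfig(epochs=10, seed=5)
        p1 = meta.MCnn(cfg, input_length=12).fit(pf, y).predict_scores(pf)
        p2 = meta.MCnn(cfg, input_length=12).fit(pf, y).predict_scores(pf)
        np.testing.assert_array_equal(p1, p2)

    def test_permuted_labels_give_null_mcc(self):
        """Label-permutation null: CV MCC centered at zero."""
        pf, y = _toy_pf(n=80)
        rng = np.random.default_rng(9)
        mccs = []
        for trial in range(10):
            yp = rng.permutation(y)
            idx = rng.permutation(len(y))
            train, test = idx[:60], idx[60:]
            model = meta.MCnn(meta.MetaModelConfig(epochs=15, seed=trial), input_length=12)
            model.fit(pf.values[train], yp[train])
            rep = evaluate(yp[test], model.predict_scores(pf.values[test]))
            mccs.append(rep.MCC)
        assert abs(np.mean(mccs)) < 0.1


class TestPrediction:
    def test_tie_at_half_is_classed_active(self):
        pred = meta.MetaPrediction.from_probability("c", 0.5)
        assert pred.label == "active"
        assert pred.p_active + pred.p_inactive == pytest.approx(1.0)

    def test_column_manifest_mismatch_rejected(self):
        pf, y = _toy_pf()
        model = meta.MCnn(meta.MetaModelConfig(epochs=2, seed=0), input_length=12).fit(pf, y)
        shuffled = PFMatrix(pf.compound_ids, list(reversed(pf.columns)), pf.values)
        with pytest.raises(ValueError, match="manifest"):
            model.predict_proba(shuffled)

    def test_wrong_width_rejected(self):
        model = meta.build_mcnn()
        with pytest.raises(ValueError, match="156"):
            model.predict_proba(np.zeros((3, 100)))

    def test_predict_returns_one_row_per_compound(self):
        pf, y = _toy_pf()
        model = meta.MCnn(meta.MetaModelConfig(epochs=5, seed=0), input_length=12).fit(pf, y)
        preds = meta.predict(model, pf)
        assert [p.compound_id for p in preds] == pf.compound_ids
        for p in preds:
            assert (p.label == "active") == (p.p_active >= 0.5)


class TestGridSearch:
    def test_enumerates_16_configurations(self):
        pf, y = _toy_pf(n=40)
        _cfg, _model, log = meta.grid_search_mcnn(
            pf, y, cv_folds=4, seed=0,
            epoch_grid=(5, 10, 20, 40), lr_grid=(1e-4, 1e-3, 1e-2, 1e-1),
        )
        assert len(log["evaluated"]) == 16

    def test_finds_perfect_mcc_on_separable_pfs(self):
        pf, y = _toy_pf(n=40)
        _cfg, model, log = meta.grid_search_mcnn(
            pf, y, cv_folds=4, seed=0, epoch_grid=(50, 150), lr_grid=(1e-2, 3e-2),
        )
        assert max(e["cv_mcc"] for e in log["evaluated"]) == pytest.approx(1.0)

    def test_repeat_run_selects_same_config(self):
        pf, y = _toy_pf(n=40, seed=2)
        kw = dict(cv_folds=4, seed=3, epoch_grid=(5, 10), lr_grid=(1e-3, 1e-2))
        cfg1, _m1, _ = meta.grid_search_mcnn(pf, y, **kw)
        cfg2, _m2, _ = meta.grid_search_mcnn(pf, y, **kw)
        assert cfg1 == cfg2


class TestMetaML:
    def test_thirteen_meta_models_plus_mcnn(self):
        pf, y = _toy_pf(n=40)
        from qsarstack.zoo import ALGORITHM_ORDER

        rows = {}
        for alg in ALGORITHM_ORDER:
            m = meta.train_meta_ml(pf, y, alg, seed=0)
            rows[f"m{alg}"] = evaluate(y, m.predict_scores(pf))
        rows["mCNN"] = evaluate(
            y, meta.MCnn(meta.MetaModelConfig(epochs=30, seed=0), input_length=12)
            .fit(pf, y).predict_scores(pf)
        )
        assert len(rows) == 14

    def test_constant_pf_matrix_gives_chance_mcc(self):
        n = 40
        y = np.array([0, 1] * (n // 2))
        pf = PFMatrix([f"c{i}" for i in range(n)], [f"b{j}" for j in range(8)],
                      np.full((n, 8), 0.5))
        m = meta.train_meta_ml(pf, y, "DT", seed=0)
        assert abs(evaluate(y, m.predict_scores(pf)).MCC) == pytest.approx(0.0, abs=1e-9)

    def test_meta_ml_checks_column_manifest(self):
        pf, y = _toy_pf()
        m = meta.train_meta_ml(pf, y, "LR", seed=0)
        shuffled = PFMatrix(pf.compound_ids, list(reversed(pf.columns)), pf.values)
        with pytest.raises(ValueError, match="manifest"):
            m.predict_scores(shuffled)


def test_stacking_does_not_underperform_median_baseline(reduced_pipeline, splits):
    """Held-out mCNN MCC >= the median baseline's CV MCC on synthetic data."""
    z = reduced_pipeline["zoo"]
    model = reduced_pipeline["model"]
    rep = evaluate(splits.test.labels(), model.predict_scores(reduced_pipeline["pf_test"]))
    median_baseline = float(np.median([s.cv_mcc for s in z.specs]))
    assert rep.MCC >= median_baseline
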