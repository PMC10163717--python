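"""Attribution: local accuracy, symmetry, surrogate substructure tables."""

import numpy as np
import pandas as pd
import pytest

from qsarstack import fingerprints as fps
from qsarstack import interpretation as itp
from qsarstack.zoo import PFMatrix


def _pf(values, prefix="BM"):
    values = np.asarray(values, dtype=float)
    return PFMatrix(
        [f"c{i}" for i in range(values.shape[0])],
        [f"{prefix}{j}" for j in range(values.shape[1])],
        values,
    )


class _Linear:
    """Toy scoring model: w . x + b (clipped to [0, 1])."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b
        self.columns = None

    def predict_scores(self, X):
        X = X.values if isinstance(X, PFMatrix) else np.asarray(X, dtype=float)
        return np.clip(X @ self.w + self.b, 0.0, 1.0)


class TestPermutationShap:
    def test_constant_model_attributes_nothing(self):
        rng = np.random.default_rng(0)
        pf, bg = _pf(rng.random((5, 8))), _pf(rng.random((20, 8)))
        report = itp.explain_meta(_Linear(np.zeros(8), b=0.4), pf, bg, seed=1)
        np.testing.assert_allclose(report.shap_values, 0.0, atol=1e-12)

    def test_single_passthrough_column_takes_all_credit(self):
        rng = np.random.default_rng(1)
        w = np.zeros(8)
        w[3] = 1.0
        pf, bg = _pf(rng.random((6, 8)) * 0.5), _pf(rng.random((30, 8)) * 0.5)
        report = itp.explain_meta(_Linear(w), pf, bg, seed=2)
        share = report.mean_abs_shap[3] / report.mean_abs_shap.sum()
        assert share == pytest.approx(1.0, abs=1e-9)

    def test_additivity_is_exact_for_any_sample_count(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=8) * 0.1
        pf, bg = _pf(rng.random((10, 8))), _pf(rng.random((25, 8)))
        for n_perm in (1, 3, 7):
            report = itp.explain_meta(_Linear(w, b=0.3), pf, bg,
                                      n_permutations=n_perm, seed=3)
            assert report.additivity_residuals().max() < 1e-10

    def test_duplicate_columns_share_attribution(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 6))
        X[:, 5] = X[:, 4]  # exact duplicate
        w = np.zeros(6)
        w[4] = w[5] = 0.5
        report = itp.explain_meta(_Linear(w), _pf(X), _pf(X), n_permutations=200, seed=5)
        a, b = report.mean_abs_shap[4], report.mean_abs_shap[5]
        assert a == pytest.approx(b, rel=0.15)  # sampling tolerance

    def test_column_mismatch_rejected(self):
        pf = _pf(np.zeros((2, 4)))
        bg = _pf(np.zeros((2, 4)), prefix="OTHER")
        with pytest.raises(itp.ExplanationError):
            itp.explain_meta(_Linear(np.zeros(4)), pf, bg)

    def test_empty_background_rejected(self):
        with pytest.raises(itp.ExplanationError):
            itp.permutation_shap(lambda X: X[:, 0], np.zeros((2, 4)), np.zeros((0, 4)))

    def test_ranking_is_sorted_by_mean_abs_shap(self):
        rng = np.random.default_rng(6)
        w = np.array([0.5, 0.01, 0.2, 0.0])
        report = itp.explain_meta(
            _Linear(w), _pf(rng.random((8, 4))), _pf(rng.random((10, 4))), seed=7
        )
        ranked_mass = [dict(zip(report.feature_names, report.mean_abs_shap))[f]
                       for f in report.ranking]
        assert ranked_mass == sorted(ranked_mass, reverse=True)


class TestMetaModelExplanation:
    def test_mcnn_additivity(self, reduced_pipeline):
        oof = reduced_pipeline["oof"]
        model = reduced_pipeline["model"]
        bg = PFMatrix(oof.pf.compound_ids[:50], oof.pf.columns, oof.pf.values[:50])
        ex = PFMatrix(oof.pf.compound_ids[50:70], oof.pf.columns, oof.pf.values[50:70])
        report = itp.explain_meta(model, ex, bg, n_permutations=6, seed=0)
        assert report.additivity_residuals().max() < 1e-3


@pytest.fixture(scope="module")
def surrogate_setup(splits):
    feats = fps.featurize(splits.train, "PubChem")
    model = itp.fit_surrogate(feats, splits.train.labels(), seed=0)
    return feats, model


class TestSurrogate:
    def test_tree_shap_reproduces_model_margin(self, surrogate_setup):
        feats, model = surrogate_setup
        sv, base = itp.tree_shap(model, feats.values[:20])
        margin = model.predict(feats.values[:20], raw_score=True)
        np.testing.assert_allclose(base + sv.sum(axis=1), margin, atol=1e-6)

    def test_top_k_table_layout(self, surrogate_setup):
        feats, model = surrogate_setup
        _report, table = itp.explain_surrogate(model, feats, top_k=20)
        assert list(table.columns) == [
            "feature", "smarts", "description", "mean_abs_shap", "sign_tendency",
        ]
        assert len(table) == 20
        assert table["mean_abs_shap"].is_monotonic_decreasing

    def test_hashed_family_rejected(self, splits):
        feats = fps.featurize(splits.train, "Circle")
        model = itp.fit_surrogate(feats, splits.train.labels(), seed=0)
        with pytest.raises(itp.ExplanationError, match="keyed"):
            itp.explain_surrogate(model, feats)

    def test_absent_feature_has_zero_value_in_waterfall(self, surrogate_setup):
        feats, model = surrogate_setup
        report, _ = itp.explain_surrogate(model, feats, compounds=feats.compound_ids[:1])
        wf = itp.waterfall_export(report, feats.compound_ids[0])
        absent = wf[wf["feature_value"] == 0.0]
        assert len(absent) > 0  # sparse fingerprints always miss features


class TestWaterfall:
    def test_cumulative_sum_ends_at_model_output(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=6) * 0.1
        pf, bg = _pf(rng.random((4, 6))), _pf(rng.random((15, 6)))
        report = itp.explain_meta(_Linear(w, b=0.5), pf, bg, seed=9)
        for cid, out in zip(report.compound_ids, report.model_output):
            wf = itp.waterfall_export(report, cid)
            assert wf["cumulative"].iloc[-1] == pytest.approx(out, abs=1e-9)
            assert (wf["contribution"].abs().diff().dropna() <= 1e-12).all()

    def test_unknown_compound_rejected(self):
        report = itp.ShapReport(["a"], ["f0"], np.zeros((1, 1)), np.zeros((1, 1)), 0.0, np.zeros(1))
        with pytest.raises(itp.ExplanationError):
            itp.waterfall_export(report, "nope")

    def test_one_feature_model_single_row(self):
        report = itp.ShapReport(["a"], ["f0"], np.array([[0.2]]), np.array([[1.0]]), 0.3, np.array([0.5]))
        wf = itp.waterfall_export(report, "a")
        assert len(wf) == 1 and wf["cumulative"].iloc[0] == pytest.approx(0.5)

    def test_export_for_top_ranked_screening_compounds(self):
        rng = np.random.default_rng(10)
        w = rng.normal(size=5) * 0.1
        pf = _pf(rng.random((10, 5)))
        report = itp.explain_meta(_Linear(w, b=0.4), pf, _pf(rng.random((12, 5))), seed=11)
        tables = [itp.waterfall_export(report, cid) for cid in report.compound_ids]
        assert len(tables) == 10
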