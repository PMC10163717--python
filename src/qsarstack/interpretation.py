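"""Feature attribution for the stacked framework.

Two attribution routes are provided:

* a model-agnostic **permutation Shapley explainer** for the CNN meta-model
  (and any scoring callable). Each sampled permutation telescopes from a
  background row to the explained compound, so the per-compound attributions
  sum *exactly* to ``model output - base value`` (local accuracy holds by
  construction, to floating-point precision, for any sample count);
* the **native TreeSHAP** (``pred_contrib``) of LightGBM/XGBoost for
  interpretable substructure surrogates, where per-feature SMARTS patterns
  turn the ranking into a substructure table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fingerprints as fps
from .fingerprints import FeatureMatrix
from .zoo import PFMatrix


class ExplanationError(ValueError):
    pass


@dataclass
class ShapReport:
    """Signed per-feature attributions for a set of explained compounds."""

    compound_ids: list[str]
    feature_names: list[str]
    shap_values: np.ndarray  # (n_explained, n_features), signed
    feature_values: np.ndarray  # the explained compounds' inputs
    base_value: float
    model_output: np.ndarray  # (n_explained,)

    def __post_init__(self) -> None:
        self.shap_values = np.asarray(self.shap_values, dtype=float)
        self.feature_values = np.asarray(self.feature_values, dtype=float)
        self.model_output = np.asarray(self.model_output, dtype=float)

    @property
    def mean_abs_shap(self) -> np.ndarray:
        return np.abs(self.shap_values).mean(axis=0)

    @property
    def ranking(self) -> list[str]:
        """Feature names ordered by non-increasing mean |SHAP|."""
        order = np.argsort(-self.mean_abs_shap, kind="stable")
        return [self.feature_names[i] for i in order]

    def additivity_residuals(self) -> np.ndarray:
        return np.abs(self.base_value + self.shap_values.sum(axis=1) - self.model_output)

    def sign_tendency(self) -> np.ndarray:
        """Mean signed SHAP per feature (+ pushes toward active)."""
        return self.shap_values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.mean_abs_shap, kind="stable")
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in order],
                "mean_abs_shap": self.mean_abs_shap[order],
                "sign_tendency": self.sign_tendency()[order],
            }
        )


def permutation_shap(
    score_fn,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Sampled-permutation Shapley values of ``score_fn`` for rows of X.

    For each of ``n_permutations`` draws, a random feature order and a random
    background row are sampled (shared across explained compounds); features
    are switched one at a time from the background value to the compound's
    value and the score deltas are credited to the switched feature. Returns
    (shap_values, base_value, model_output).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[1] != X.shape[1]:
        raise ExplanationError("background and explained matrices disagree in width")
    if len(background) == 0:
        raise ExplanationError("background set must be non-empty")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(d) for _ in range(n_permutations)]
    bg_rows = rng.integers(0, len(background), size=n_permutations)

    shap_values = np.zeros((n, d))
    base_acc = 0.0
    for perm, bg_idx in zip(perms, bg_rows):
        b = background[bg_idx]
        base_acc += float(np.mean(score_fn(b[None, :])))
        for i in range(n):
            # path of d+1 inputs from the background row to compound i
            path = np.tile(b, (d + 1, 1))
            mask = np.zeros(d, dtype=bool)
            for step, j in enumerate(perm, start=1):
                mask[j] = True
                path[step, mask] = X[i, mask]
            scores = np.asarray(score_fn(path), dtype=float)
            shap_values[i, perm] += np.diff(scores)
    shap_values /= n_permutations
    base_value = base_acc / n_permutations
    model_output = np.asarray(score_fn(X), dtype=float)
    return shap_values, base_value, model_output


def explain_meta(
    meta_model,
    pf: PFMatrix,
    background: PFMatrix,
    n_permutations: int = 10,
    seed: int = 0,
) -> ShapReport:
    """Permutation-Shapley explanation of the meta-model's p(active)."""
    if list(pf.columns) != list(background.columns):
        raise ExplanationError("PF and background column orders differ")
    trained_cols = getattr(meta_model, "columns", None)
    if trained_cols is not None and list(pf.columns) != list(trained_cols):
        raise ExplanationError("PF columns disagree with the model's training manifest")

    def score_fn(X):
        return meta_model.predict_scores(np.asarray(X, dtype=float))

    sv, base, out = permutation_shap(
        score_fn, pf.values, background.values, n_permutations=n_permutations, seed=seed
    )
    return ShapReport(
        compound_ids=list(pf.compound_ids),
        feature_names=list(pf.columns),
        shap_values=sv,
        feature_values=pf.values,
        base_value=base,
        model_output=out,
    )


def tree_shap(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-feature contributions from a fitted LightGBM/XGBoost model.

    Returns (contributions in log-odds space, expected value). Contributions
    plus the expected value reproduce the model margin exactly.
    """
    X = np.asarray(X, dtype=float)
    if hasattr(model, "predict") and model.__class__.__module__.startswith("lightgbm"):
        contrib = model.predict(X, pred_contrib=True, raw_score=True)
    elif model.__class__.__module__.startswith("xgboost"):
        import xgboost as xgb

        booster = model.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)
    else:
        raise ExplanationError(
            f"{type(model).__name__} has no native tree-path attribution"
        )
    contrib = np.asarray(contrib)
    return contrib[:, :-1], float(contrib[0, -1])


def fit_surrogate(features: FeatureMatrix, labels, seed: int = 42, **params):
    """Gradient-boosting surrogate over an interpretable fingerprint family."""
    from lightgbm import LGBMClassifier

    model = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                           n_estimators=params.pop("n_estimators", 200), **params)
    model.fit(features.values, np.asarray(labels, dtype=int))
    return model


def explain_surrogate(
    substructure_model,
    features: FeatureMatrix,
    compounds: list[str] | None = None,
    top_k: int = 20,
) -> tuple[ShapReport, pd.DataFrame]:
    """Substructure attribution via the surrogate's native TreeSHAP.

    The fingerprint family must carry a pattern dictionary (SMARTS per
    feature); hashed families are rejected. Returns the report plus a
    top-k table (feature, SMARTS pattern, substructure description).
    """
    family = features.spec.name
    if family not in fps.INTERPRETABLE_FAMILIES:
        raise ExplanationError(
            f"family {family!r} has no pattern dictionary; use a keyed family"
        )
    ids = list(features.compound_ids)
    if compounds is not None:
        index = {cid: k for k, cid in enumerate(ids)}
        missing = [c for c in compounds if c not in index]
        if missing:
            raise ExplanationError(f"compounds not in feature matrix: {missing[:5]}")
        rows = [index[c] for c in compounds]
    else:
        rows = list(range(len(ids)))
    X = features.values[rows]
    sv, base = tree_shap(substructure_model, X)
    margin = base + sv.sum(axis=1)
    report = ShapReport(
        compound_ids=[ids[r] for r in rows],
        feature_names=list(features.feature_names),
        shap_values=sv,
        feature_values=X,
        base_value=base,
        model_output=margin,
    )
    table = substructure_table(report, family, top_k=top_k)
    return report, table


def substructure_table(report: ShapReport, family: str, top_k: int = 20) -> pd.DataFrame:
    """Top-k features with their SMARTS patterns and descriptions."""
    definitions = fps.feature_definitions(family)
    descriptions = fps.feature_descriptions(family)
    ranked = report.ranking[:top_k]
    mean_abs = dict(zip(report.feature_names, report.mean_abs_shap))
    tendency = dict(zip(report.feature_names, report.sign_tendency()))
    return pd.DataFrame(
        {
            "feature": ranked,
            "smarts": [definitions.get(f, "") for f in ranked],
            "description": [descriptions.get(f, "") for f in ranked],
            "mean_abs_shap": [mean_abs[f] for f in ranked],
            "sign_tendency": [tendency[f] for f in ranked],
        }
    )


def waterfall_export(report: ShapReport, compound_id: str) -> pd.DataFrame:
    """Ordered signed contributions for one compound.

    Rows are sorted by |contribution| (largest first); the cumulative column
    starts at the base value and ends at the model output for the compound.
    """
    try:
        row = report.compound_ids.index(compound_id)
    except ValueError:
        raise ExplanationError(f"compound {compound_id!r} was not explained") from None
    sv = report.shap_values[row]
    order = np.argsort(-np.abs(sv), kind="stable")
    cumulative = report.base_value + np.cumsum(sv[order])
    return pd.DataFrame(
        {
            "feature": [report.feature_names[i] for i in order],
            "feature_value": report.feature_values[row][order],
            "contribution": sv[order],
            "cumulative": cumulative,
        }
    )
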