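"""Phase 1: the baseline-classifier zoo and probabilistic-feature generation.

Every (algorithm, descriptor) pair yields one baseline model; with the full
13-algorithm and 12-family defaults that is 156 baselines. Each baseline's
predicted probability of activity for a compound is one probabilistic
feature (PF); stacking the PFs of all baselines, algorithm-major then
descriptor, gives the canonical feature vector

    FV(C) = { PF_BM(1,1), PF_BM(1,2), ..., PF_BM(1,12), PF_BM(2,1), ...,
              PF_BM(13,12) }

consumed by the Phase-2 meta-model.

Training-set PFs are out-of-fold cross-validation predictions (standard
stacking: the model that scores a compound never saw it during fitting),
while test/screening PFs come from baselines refit on the full training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .evaluation import ConfusionCounts, metrics, stratified_folds
from .fingerprints import FAMILY_ORDER, FeatureMatrix

ALGORITHM_ORDER = [
    "RF", "ADA", "LGBM", "PLS", "MLP", "NB", "DT",
    "ET", "XGB", "KNN", "LR", "SVMLN", "SVMRBF",
]


class _LogisticLink(BaseEstimator, ClassifierMixin):
    """Probability via a logistic link on a continuous decision value.

    Used for estimators without native probability output (PLS regression
    scores, linear-SVM decision values): the inner model is fitted first,
    then a one-dimensional logistic regression maps its decision values to
    [0, 1] on the same training fold.
    """

    def __init__(self, inner=None):
        self.inner = inner

    def _decision(self, X) -> np.ndarray:
        if hasattr(self.inner_, "decision_function"):
            return np.asarray(self.inner_.decision_function(X)).ravel()
        return np.asarray(self.inner_.predict(X)).ravel()

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.inner_ = clone(self.inner)
        self.inner_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        d = self._decision(X).reshape(-1, 1)
        self.link_ = LogisticRegression(max_iter=1000)
        self.link_.fit(d, y)
        return self

    def predict_proba(self, X):
        d = self._decision(np.asarray(X, dtype=float)).reshape(-1, 1)
        return self.link_.predict_proba(d)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_estimator(algorithm_id: str, params: dict, seed: int):
    """Fresh unfitted estimator for one algorithm id with given parameters."""
    p = dict(params)
    if algorithm_id == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if algorithm_id == "ADA":
        return AdaBoostClassifier(random_state=seed, **p)
    if algorithm_id == "LGBM":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **p)
    if algorithm_id == "PLS":
        return _LogisticLink(PLSRegression(scale=False, **p))
    if algorithm_id == "MLP":
        return MLPClassifier(random_state=seed, max_iter=300, **p)
    if algorithm_id == "NB":
        return BernoulliNB(**p)
    if algorithm_id == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if algorithm_id == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **p)
    if algorithm_id == "XGB":
        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist",
            eval_metric="logloss", **p,
        )
    if algorithm_id == "KNN":
        return KNeighborsClassifier(n_jobs=1, **p)
    if algorithm_id == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **p)
    if algorithm_id == "SVMLN":
        return _LogisticLink(LinearSVC(random_state=seed, dual="auto", **p))
    if algorithm_id == "SVMRBF":
        return SVC(kernel="rbf", probability=True, random_state=seed, **p)
    raise ValueError(f"unknown algorithm id {algorithm_id!r}")


#: compact, config-overridable hyperparameter grids (declared order is the
#: grid-search tie-break order: the first point at equal CV MCC wins)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100, 500], "max_depth": [None, 8]},
    "ADA": {"n_estimators": [100, 500]},
    "LGBM": {"n_estimators": [100, 500], "max_depth": [-1, 8]},
    "PLS": {"n_components": [2, 5, 10]},
    "MLP": {"hidden_layer_sizes": [(100,)], "alpha": [1e-4, 1e-2]},
    "NB": {"alpha": [0.1, 1.0]},
    "DT": {"max_depth": [None, 8]},
    "ET": {"n_estimators": [100, 500], "max_depth": [None, 8]},
    "XGB": {"n_estimators": [100, 500], "max_depth": [6, 8]},
    "KNN": {"n_neighbors": [3, 5, 7]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "SVMLN": {"C": [0.1, 1.0, 10.0]},
    "SVMRBF": {"C": [0.1, 1.0, 10.0]},
}

#: minimal grids for quick runs (one point per algorithm)
FAST_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100]},
    "ADA": {"n_estimators": [100]},
    "LGBM": {"n_estimators": [100]},
    "PLS": {"n_components": [2]},
    "MLP": {"hidden_layer_sizes": [(100,)]},
    "NB": {"alpha": [1.0]},
    "DT": {"max_depth": [8]},
    "ET": {"n_estimators": [100]},
    "XGB": {"n_estimators": [100]},
    "KNN": {"n_neighbors": [5]},
    "LR": {"C": [1.0]},
    "SVMLN": {"C": [1.0]},
    "SVMRBF": {"C": [1.0]},
}


def _build(algorithm_id: str, params: dict, seed: int):
    if algorithm_id in ("PLS", "SVMLN"):
        # parameters address the wrapped inner estimator
        est = make_estimator(algorithm_id, {}, seed)
        for key, value in params.items():
            setattr(est.inner, key.removeprefix("inner__"), value)
        return est
    return make_estimator(algorithm_id, params, seed)


@dataclass
class BaselineModelSpec:
    algorithm_id: str
    descriptor_id: str
    hyperparameter_grid: dict[str, list]
    tuned_params: dict = field(default_factory=dict)
    cv_mcc: float = float("nan")

    @property
    def name(self) -> str:
        return f"{self.algorithm_id}-{self.descriptor_id}"


@dataclass
class PFMatrix:
    """n x (|algorithms| * |descriptors|) probability matrix, canonical order."""

    compound_ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.compound_ids), len(self.columns)):
            raise ValueError("PF matrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probabilistic features must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.columns)

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "compound_id", frame.index)
        frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PFMatrix":
        df = pd.read_csv(path, dtype={"compound_id": str}).set_index("compound_id")
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class Zoo:
    """Fitted baseline models plus their tuning records.

    ``models`` maps column name (``ALG-FAMILY``) to the estimator refit on
    the full training set; ``specs`` holds the tuning record per baseline in
    canonical order.
    """

    specs: list[BaselineModelSpec]
    models: dict[str, object]
    algorithms: list[str]
    descriptors: list[str]
    seed: int
    cv_folds: int

    @property
    def column_order(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def best_baseline(self) -> BaselineModelSpec:
        return max(self.specs, key=lambda s: s.cv_mcc)

    def manifest(self) -> dict:
        return {
            "algorithms": self.algorithms,
            "descriptors": self.descriptors,
            "seed": self.seed,
            "cv_folds": self.cv_folds,
            "baselines": [
                {
                    "name": s.name,
                    "tuned_params": {k: repr(v) for k, v in s.tuned_params.items()},
                    "cv_mcc": s.cv_mcc,
                }
                for s in self.specs
            ],
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def default_zoo_specs(
    algorithms: list[str] | None = None,
    descriptors: list[str] | None = None,
    grids: dict[str, dict] | None = None,
) -> list[BaselineModelSpec]:
    """The canonical (algorithm-major) enumeration of baseline specs."""
    algorithms = algorithms or ALGORITHM_ORDER
    descriptors = descriptors or FAMILY_ORDER
    grids = grids or DEFAULT_GRIDS
    return [
        BaselineModelSpec(a, d, grids.get(a, {}))
        for a in algorithms
        for d in descriptors
    ]


def _canonical_features(
    features: dict[str, FeatureMatrix | np.ndarray], descriptors: list[str]
) -> dict[str, np.ndarray]:
    missing = [d for d in descriptors if d not in features]
    if missing:
        raise ValueError(f"feature matrices missing for descriptor families: {missing}")
    out = {}
    for d in descriptors:
        m = features[d]
        out[d] = m.values if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)
    return out


def _proba(model, X: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = model.predict_proba(X)
    return np.clip(np.asarray(p)[:, 1], 0.0, 1.0)


def _cv_mcc(algorithm_id, params, X, y, folds, seed) -> float:
    """Pooled (micro) MCC over shared stratified folds."""
    y = np.asarray(y, dtype=int)
    all_idx = np.arange(len(y))
    pred = np.zeros(len(y), dtype=int)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        est = _build(algorithm_id, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train_idx], y[train_idx])
        pred[test_idx] = (_proba(est, X[test_idx]) >= 0.5).astype(int)
    return metrics(ConfusionCounts.from_predictions(y, pred)).MCC


def train_zoo(
    train_features: dict[str, FeatureMatrix | np.ndarray],
    labels,
    cv_folds: int = 10,
    seed: int = 42,
    algorithms: list[str] | None = None,
    descriptors: list[str] | None = None,
    grids: dict[str, dict] | None = None,
) -> Zoo:
    """Tune and fit one baseline per (algorithm, descriptor) pair.

    Hyperparameters maximize pooled CV MCC over seeded stratified folds
    shared by every baseline; ties go to the earlier grid point. The
    returned models are refit on the full training set with the tuned
    parameters (these produce test/screening PFs).
    """
    algorithms = algorithms or ALGORITHM_ORDER
    descriptors = descriptors or [d for d in FAMILY_ORDER if d in train_features]
    grids = grids or DEFAULT_GRIDS
    y = np.asarray(labels, dtype=int)
    X_by_family = _canonical_features(train_features, descriptors)
    folds = stratified_folds(y, cv_folds, seed)

    specs: list[BaselineModelSpec] = []
    models: dict[str, object] = {}
    for alg in algorithms:
        grid = grids.get(alg, {})
        for fam in descriptors:
            X = X_by_family[fam]
            best_params, best_mcc = None, -np.inf
            for params in ParameterGrid(grid) if grid else [{}]:
                score = _cv_mcc(alg, params, X, y, folds, seed)
                if score > best_mcc:
                    best_params, best_mcc = dict(params), score
            spec = BaselineModelSpec(alg, fam, grid, best_params, float(best_mcc))
            est = _build(alg, best_params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X, y)
            specs.append(spec)
            models[spec.name] = est
    return Zoo(specs, models, list(algorithms), list(descriptors), seed, cv_folds)


@dataclass
class OOFResult:
    """Training PF matrix plus fold provenance for leakage auditing.

    ``fold_of_row[r]`` is the fold whose held-out half contains row r;
    ``fit_rows[f]`` are the row indices each fold-f model was fitted on.
    """

    pf: PFMatrix
    fold_of_row: np.ndarray
    fit_rows: list[np.ndarray]


def oof_pf(
    zoo: Zoo,
    train_features: dict[str, FeatureMatrix | np.ndarray],
    labels,
    cv_folds: int | None = None,
    seed: int | None = None,
    compound_ids: list[str] | None = None,
) -> OOFResult:
    """Out-of-fold training PFs: row r is scored by a model fit without r.

    Fold assignment is identical across all baselines (same seeded
    stratified folds used for tuning when folds/seed are left at the zoo's).
    """
    cv_folds = cv_folds or zoo.cv_folds
    seed = zoo.seed if seed is None else seed
    y = np.asarray(labels, dtype=int)
    X_by_family = _canonical_features(train_features, zoo.descriptors)
    n = len(y)
    folds = stratified_folds(y, cv_folds, seed)
    all_idx = np.arange(n)
    fold_of_row = np.full(n, -1, dtype=int)
    fit_rows = []
    for f, test_idx in enumerate(folds):
        fold_of_row[test_idx] = f
        fit_rows.append(np.setdiff1d(all_idx, test_idx))

    values = np.zeros((n, len(zoo.specs)))
    for col, spec in enumerate(zoo.specs):
        X = X_by_family[spec.descriptor_id]
        for f, test_idx in enumerate(folds):
            est = _build(spec.algorithm_id, spec.tuned_params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[fit_rows[f]], y[fit_rows[f]])
            values[test_idx, col] = _proba(est, X[test_idx])

    ids = compound_ids or [str(i) for i in range(n)]
    pf = PFMatrix(list(ids), zoo.column_order, values)
    return OOFResult(pf=pf, fold_of_row=fold_of_row, fit_rows=fit_rows)


def apply_pf(
    zoo: Zoo,
    new_features: dict[str, FeatureMatrix | np.ndarray],
    compound_ids: list[str] | None = None,
) -> PFMatrix:
    """PF matrix for unseen compounds from the fully-refit baselines."""
    X_by_family = _canonical_features(new_features, zoo.descriptors)
    n = next(iter(X_by_family.values())).shape[0]
    values = np.zeros((n, len(zoo.specs)))
    for col, spec in enumerate(zoo.specs):
        values[:, col] = _proba(zoo.models[spec.name], X_by_family[spec.descriptor_id])
    if compound_ids is None:
        first = next(iter(new_features.values()))
        compound_ids = (
            list(first.compound_ids) if isinstance(first, FeatureMatrix) else [str(i) for i in range(n)]
        )
    return PFMatrix(list(compound_ids), zoo.column_order, values)
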