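"""Phase 2: the 1D-CNN meta-classifier (mCNN) over the PF vector.

The 156 probabilistic features are treated as a fixed-order one-dimensional
sequence with a single channel. A single convolutional layer applies filters
of three region sizes (3, 4, 5; 100 filters each, 300 in total, "same"
zero padding) followed by ReLU. Each region size is pooled globally — max
and average over positions and filters — yielding two scalars per region
size, a 6-D penultimate vector, which feeds a softmax layer over
{active, inactive}. An alternative pooling scheme (global max per filter ->
300-D -> dense 6) is selectable.

Training is mini-batch Adam on the cross-entropy loss, implemented directly
in NumPy; all randomness (initialization, shuffling) is governed by the
config seed. Alternative stacked meta-learners reuse the Phase-1 algorithm
registry on the identical PF matrix for comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import ConfusionCounts, metrics, stratified_folds
from .zoo import PFMatrix, _build, _proba

POOLING_SCHEMES = ("region-maxavg", "filter-max-dense")

EPOCH_GRID = (20, 50, 100, 200)
LEARNING_RATE_GRID = (1e-5, 1e-4, 1e-3, 1e-2)


@dataclass(frozen=True)
class MetaModelConfig:
    region_sizes: tuple[int, ...] = (3, 4, 5)
    filters_per_region: int = 100
    pooling: str = "region-maxavg"
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.pooling not in POOLING_SCHEMES:
            raise ValueError(f"pooling must be one of {POOLING_SCHEMES}")

    @property
    def total_filters(self) -> int:
        return len(self.region_sizes) * self.filters_per_region

    @property
    def penultimate_dim(self) -> int:
        return 2 * len(self.region_sizes) if self.pooling == "region-maxavg" else 6


@dataclass
class MetaPrediction:
    compound_id: str
    p_active: float
    p_inactive: float
    label: str

    @classmethod
    def from_probability(cls, compound_id: str, p_active: float) -> "MetaPrediction":
        # ties at 0.5 are classed active
        return cls(
            compound_id=compound_id,
            p_active=float(p_active),
            p_inactive=float(1.0 - p_active),
            label="active" if p_active >= 0.5 else "inactive",
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _windows(X: np.ndarray, k: int) -> np.ndarray:
    """(n, L, k) sliding windows of the zero-padded input ("same" conv)."""
    left, right = (k - 1) // 2, k // 2
    Xp = np.pad(X, ((0, 0), (left, right)))
    return np.lib.stride_tricks.sliding_window_view(Xp, k, axis=1)


class MCnn:
    """Single-layer 1D-CNN meta-classifier on a fixed-length PF sequence."""

    def __init__(self, config: MetaModelConfig, input_length: int = 156):
        if max(config.region_sizes) > input_length:
            raise ValueError(
                f"region size {max(config.region_sizes)} exceeds input length {input_length}"
            )
        self.config = config
        self.input_length = input_length
        self.columns: list[str] | None = None  # training column manifest
        self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.kernels = [
            rng.normal(0.0, np.sqrt(2.0 / (k * 1)), size=(k, cfg.filters_per_region))
            for k in cfg.region_sizes
        ]
        self.biases = [np.zeros(cfg.filters_per_region) for _ in cfg.region_sizes]
        if cfg.pooling == "filter-max-dense":
            self.W_mid = rng.normal(0.0, np.sqrt(2.0 / cfg.total_filters), size=(cfg.total_filters, 6))
            self.b_mid = np.zeros(6)
        else:
            self.W_mid, self.b_mid = None, None
        d = self.penultimate_dim
        self.W_out = rng.normal(0.0, np.sqrt(1.0 / d), size=(d, 2))
        self.b_out = np.zeros(2)
        self._rng = rng

    @property
    def total_filters(self) -> int:
        return self.config.total_filters

    @property
    def penultimate_dim(self) -> int:
        return self.config.penultimate_dim

    def _params(self) -> list[np.ndarray]:
        ps = [*self.kernels, *self.biases, self.W_out, self.b_out]
        if self.W_mid is not None:
            ps += [self.W_mid, self.b_mid]
        return ps

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, keep: bool = False):
        cfg = self.config
        acts, wins = [], []
        pooled_parts = []
        for r, k in enumerate(cfg.region_sizes):
            W = _windows(X, k)
            Z = W @ self.kernels[r] + self.biases[r]
            A = np.maximum(Z, 0.0)
            if cfg.pooling == "region-maxavg":
                pooled_parts.append(A.reshape(len(X), -1))
            else:
                pooled_parts.append(A.max(axis=1))  # per-filter max over positions
            if keep:
                acts.append(A)
                wins.append(W)
        if cfg.pooling == "region-maxavg":
            h = np.empty((len(X), self.penultimate_dim))
            for r, flat in enumerate(pooled_parts):
                h[:, 2 * r] = flat.max(axis=1)
                h[:, 2 * r + 1] = flat.mean(axis=1)
            mid = None
        else:
            pooled = np.concatenate(pooled_parts, axis=1)  # (n, total_filters)
            mid_z = pooled @ self.W_mid + self.b_mid
            h = np.maximum(mid_z, 0.0)
            mid = (pooled, mid_z)
        probs = _softmax(h @ self.W_out + self.b_out)
        if keep:
            return probs, h, acts, wins, mid
        return probs

    # -- training -----------------------------------------------------------

    def fit(self, pf, y, epochs: int | None = None, callback=None) -> "MCnn":
        """Train with Adam on cross-entropy.

        ``callback(epoch, model)`` (if given) runs after each epoch, which
        lets a grid search over epoch counts evaluate checkpoints of a
        single trajectory instead of retraining per epoch budget.
        """
        X, self.columns = _pf_to_array(pf, self.input_length)
        y = np.asarray(y, dtype=int)
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        self._init_params()
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(X)
        for epoch in range(1, epochs + 1):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                grads = self._gradients(X[idx], y[idx])
                if any(not np.isfinite(g).all() for g in grads):
                    raise FloatingPointError("non-finite gradient during mCNN training")
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if callback is not None:
                callback(epoch, self)
        return self

    def _gradients(self, X: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        cfg = self.config
        B = len(X)
        probs, h, acts, wins, mid = self._forward(X, keep=True)
        onehot = np.zeros((B, 2))
        onehot[np.arange(B), y] = 1.0
        dlogits = (probs - onehot) / B
        dW_out = h.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dh = dlogits @ self.W_out.T

        dK = [np.zeros_like(k) for k in self.kernels]
        db = [np.zeros_like(b) for b in self.biases]
        if cfg.pooling == "region-maxavg":
            for r, A in enumerate(acts):
                flat = A.reshape(B, -1)
                dA_flat = np.zeros_like(flat)
                amax = flat.argmax(axis=1)
                dA_flat[np.arange(B), amax] += dh[:, 2 * r]
                dA_flat += dh[:, 2 * r + 1][:, None] / flat.shape[1]
                dZ = dA_flat.reshape(A.shape) * (A > 0)
                dK[r] = np.einsum("blk,blf->kf", wins[r], dZ)
                db[r] = dZ.sum(axis=(0, 1))
            dW_mid_list: list[np.ndarray] = []
        else:
            pooled, mid_z = mid
            dh_mid = dh * (mid_z > 0)
            dW_mid = pooled.T @ dh_mid
            db_mid = dh_mid.sum(axis=0)
            dpooled = dh_mid @ self.W_mid.T
            off = 0
            for r, A in enumerate(acts):
                F = cfg.filters_per_region
                dslice = dpooled[:, off:off + F]
                off += F
                dA = np.zeros_like(A)
                amax = A.argmax(axis=1)  # (B, F) position of max per filter
                bi = np.arange(B)[:, None]
                fi = np.arange(F)[None, :]
                dA[bi, amax, fi] = dslice
                dZ = dA * (A > 0)
                dK[r] = np.einsum("blk,blf->kf", wins[r], dZ)
                db[r] = dZ.sum(axis=(0, 1))
            dW_mid_list = [dW_mid, db_mid]
        return [*dK, *db, dW_out, db_out, *dW_mid_list]

    # -- inference ----------------------------------------------------------

    def predict_proba(self, pf) -> np.ndarray:
        X, cols = _pf_to_array(pf, self.input_length)
        if self.columns is not None and cols is not None and cols != self.columns:
            raise ValueError("PF column order disagrees with the training manifest")
        return self._forward(X)

    def predict_scores(self, pf) -> np.ndarray:
        return self.predict_proba(pf)[:, 1]


def _pf_to_array(pf, expected_length: int):
    if isinstance(pf, PFMatrix):
        X, cols = pf.values, list(pf.columns)
    else:
        X, cols = np.asarray(pf, dtype=float), None
    if X.ndim != 2 or X.shape[1] != expected_length:
        raise ValueError(f"expected {expected_length}-D PF vectors, got shape {X.shape}")
    return X, cols


def build_mcnn(config: MetaModelConfig | None = None, input_length: int = 156) -> MCnn:
    return MCnn(config or MetaModelConfig(), input_length=input_length)


def grid_search_mcnn(
    pf_train: PFMatrix,
    labels,
    cv_folds: int = 10,
    seed: int = 42,
    epoch_grid: tuple[int, ...] = EPOCH_GRID,
    lr_grid: tuple[float, ...] = LEARNING_RATE_GRID,
    base_config: MetaModelConfig | None = None,
) -> tuple[MetaModelConfig, MCnn, dict]:
    """Tune epochs x learning rate by k-fold CV MCC; refit the winner.

    For each learning rate, one training trajectory per fold is checkpointed
    at every epoch budget in the grid (identical to independent runs because
    initialization and shuffling depend only on the config seed). A grid
    point whose training diverges is scored MCC -1 and logged. Ties go to
    the earlier grid point (epoch-major within each learning rate, learning
    rates in declared order).
    """
    y = np.asarray(labels, dtype=int)
    base = base_config or MetaModelConfig()
    folds = stratified_folds(y, cv_folds, seed)
    all_idx = np.arange(len(y))
    X = pf_train.values
    input_length = X.shape[1]
    epoch_set = sorted(set(epoch_grid))
    max_epochs = epoch_set[-1]

    scores: dict[tuple[int, float], float] = {}
    failures: list[tuple[int, float]] = []
    oof = {(e, lr): np.zeros(len(y), dtype=int) for e in epoch_set for lr in lr_grid}
    for lr in lr_grid:
        diverged = False
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = MCnn(replace(base, learning_rate=lr, epochs=max_epochs, seed=seed),
                         input_length=input_length)

            def checkpoint(epoch, mdl, test_idx=test_idx):
                if epoch in epoch_set:
                    p = mdl._forward(X[test_idx])[:, 1]
                    oof[(epoch, lr)][test_idx] = (p >= 0.5).astype(int)

            try:
                model.fit(X[train_idx], y[train_idx], callback=checkpoint)
            except FloatingPointError:
                diverged = True
                break
        if diverged:
            for e in epoch_set:
                scores[(e, lr)] = -1.0
                failures.append((e, lr))
            continue
        for e in epoch_set:
            scores[(e, lr)] = metrics(
                ConfusionCounts.from_predictions(y, oof[(e, lr)])
            ).MCC

    best_key, best_mcc = None, -np.inf
    for lr in lr_grid:  # declared order is the tie-break order
        for e in epoch_grid:
            if scores[(e, lr)] > best_mcc:
                best_key, best_mcc = (e, lr), scores[(e, lr)]
    best_config = replace(base, epochs=best_key[0], learning_rate=best_key[1], seed=seed)
    final = MCnn(best_config, input_length=input_length).fit(pf_train, y)
    search_log = {
        "evaluated": [
            {"epochs": e, "learning_rate": lr, "cv_mcc": scores[(e, lr)]}
            for lr in lr_grid for e in epoch_grid
        ],
        "diverged": [{"epochs": e, "learning_rate": lr} for e, lr in failures],
        "best_cv_mcc": float(best_mcc),
    }
    return best_config, final, search_log


class MetaML:
    """A conventional ML meta-learner over the PF matrix (comparison rows)."""

    def __init__(self, algorithm_id: str, seed: int = 42, params: dict | None = None):
        self.algorithm_id = algorithm_id
        self.seed = seed
        self.params = params or {}
        self.columns: list[str] | None = None

    def fit(self, pf, y) -> "MetaML":
        X, self.columns = _pf_to_array(pf, _pf_width(pf))
        self.model_ = _build(self.algorithm_id, self.params, self.seed)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(X, np.asarray(y, dtype=int))
        return self

    def predict_scores(self, pf) -> np.ndarray:
        X, cols = _pf_to_array(pf, self.model_.n_features_in_ if hasattr(self.model_, "n_features_in_") else _pf_width(pf))
        if self.columns is not None and cols is not None and cols != self.columns:
            raise ValueError("PF column order disagrees with the training manifest")
        return _proba(self.model_, X)


def _pf_width(pf) -> int:
    return pf.values.shape[1] if isinstance(pf, PFMatrix) else np.asarray(pf).shape[1]


def train_meta_ml(pf_train: PFMatrix, labels, algorithm_id: str, seed: int = 42,
                  params: dict | None = None) -> MetaML:
    """One stacked meta-model per requested algorithm on the identical PFs."""
    return MetaML(algorithm_id, seed=seed, params=params).fit(pf_train, labels)


def predict(model, pf: PFMatrix) -> list[MetaPrediction]:
    """MetaPredictions for every PF row (threshold 0.5, ties active)."""
    scores = model.predict_scores(pf)
    return [
        MetaPrediction.from_probability(cid, p)
        for cid, p in zip(pf.compound_ids, scores)
    ]
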