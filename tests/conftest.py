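"""Shared fixtures: the synthetic benchmark and a reduced fitted pipeline.

The expensive session fixtures (default synthetic dataset, reduced zoo with
out-of-fold PFs and a fitted meta-model) are computed once and shared by the
unit and acceptance suites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qsarstack import curation, fingerprints, meta, synthetic, zoo

REDUCED_ALGORITHMS = ["RF", "LGBM", "LR", "NB"]
REDUCED_FAMILIES = ["MACCS", "EState", "Circle"]


@pytest.fixture(scope="session")
def synthetic_default() -> synthetic.SyntheticDataset:
    """The benchmark at generator defaults (433 active / 409 inactive)."""
    return synthetic.generate(synthetic.SyntheticConfig())


@pytest.fixture(scope="session")
def splits(synthetic_default) -> curation.SplitDataset:
    return curation.split(synthetic_default.dataset, train_fraction=0.8, seed=42)


@pytest.fixture(scope="session")
def reduced_features(splits) -> dict:
    return {
        "train": {f: fingerprints.featurize(splits.train, f) for f in REDUCED_FAMILIES},
        "test": {f: fingerprints.featurize(splits.test, f) for f in REDUCED_FAMILIES},
    }


@pytest.fixture(scope="session")
def reduced_pipeline(splits, reduced_features) -> dict:
    """Reduced zoo (4 algorithms x 3 families) + OOF PFs + fitted mCNN."""
    y_train = splits.train.labels()
    z = zoo.train_zoo(
        reduced_features["train"],
        y_train,
        cv_folds=5,
        seed=42,
        algorithms=REDUCED_ALGORITHMS,
        descriptors=REDUCED_FAMILIES,
        grids=zoo.FAST_GRIDS,
    )
    oof = zoo.oof_pf(z, reduced_features["train"], y_train, compound_ids=splits.train.ids())
    pf_test = zoo.apply_pf(z, reduced_features["test"], compound_ids=splits.test.ids())
    cfg = meta.MetaModelConfig(epochs=100, learning_rate=1e-3, seed=42)
    model = meta.MCnn(cfg, input_length=oof.pf.shape[1]).fit(oof.pf, y_train)
    return {"zoo": z, "oof": oof, "pf_test": pf_test, "model": model}


@pytest.fixture()
def tiny_table() -> pd.DataFrame:
    """A small raw bioactivity table exercising every curation filter."""
    return pd.DataFrame(
        {
            "compound_id": ["A", "B", "C", "D", "E", "F", "G", "G", "H", "H"],
            "smiles": [
                "c1ccccc1C#N", "CCO", "CCN", "c1ccc(Cl)cc1", None, "CCOC",
                "CC(=O)O", "CC(=O)O", "CCCO", "CCCO",
            ],
            "standard_relation": ["=", "=", "=", "<", "=", "=", "=", "=", "=", "="],
            "standard_value": [0.5, 10.0, 5.0, 0.5, 1.0, 2.0, 100.0, 400.0, 1.0, 90000.0],
            "standard_units": ["uM", "uM", "uM", "uM", "uM", "furlongs", "nM", "nM", "nM", "nM"],
        }
    )


@pytest.fixture(scope="session")
def toy_binary_features() -> tuple[dict, np.ndarray]:
    """Perfectly separable toy features: the label equals the first bit."""
    rng = np.random.default_rng(7)
    n = 40
    y = np.array([0, 1] * (n // 2))
    mats = {}
    for fam in ("MACCS", "EState"):
        d = 12
        X = rng.integers(0, 2, size=(n, d)).astype(float)
        X[:, 0] = y
        mats[fam] = X
    return mats, y
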