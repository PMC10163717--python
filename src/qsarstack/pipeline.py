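"""End-to-end orchestration: one config object, staged artifacts, manifests.

Stages mirror the framework flow — dataset preparation (curate/split,
chemical space), optimization and construction (fingerprints, baseline zoo,
OOF probabilistic features, meta-model), evaluation and interpretation
(metric tables, SHAP reports), and screening. Each stage writes artifacts
into the workdir and a manifest recording the config hash and seeds, so a
run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import curation, evaluation, fingerprints, interpretation, meta, screening, synthetic, zoo


@dataclass
class RunConfig:
    """Everything a run needs; defaults give the reduced benchmark profile."""

    input_csv: str = ""
    workdir: str = "qsarstack_run"
    seed: int = 42
    train_fraction: float = 0.8
    cv_folds: int = 5
    active_threshold_nM: float = curation.ACTIVE_THRESHOLD_NM
    inactive_threshold_nM: float = curation.INACTIVE_THRESHOLD_NM
    descriptors: list = field(default_factory=lambda: ["MACCS", "EState", "Circle"])
    algorithms: list = field(default_factory=lambda: ["RF", "LGBM", "LR", "NB"])
    grids: str = "default"  # "default" | "fast"
    meta_grid_search: bool = False
    meta_epochs: int = 100
    meta_learning_rate: float = 1e-3
    surrogate_family: str = "PubChem"
    top_k: int = 10
    synth_seed: int = 0
    synth_n_active: int = 433
    synth_n_inactive: int = 409

    @classmethod
    def full(cls, **overrides) -> "RunConfig":
        """The full-scale profile: 13 algorithms x 12 descriptors, 10 folds."""
        cfg = cls(
            descriptors=list(fingerprints.FAMILY_ORDER),
            algorithms=list(zoo.ALGORITHM_ORDER),
            cv_folds=10,
            meta_grid_search=True,
        )
        return dataclasses.replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"{path.name} not found in workdir; run the '{producer}' stage first"
        )
    return path


class Pipeline:
    """Stage runner bound to one config and workdir."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.workdir = Path(config.workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)

    # -- paths --------------------------------------------------------------

    def path(self, name: str) -> Path:
        return self.workdir / name

    def _write_manifest(self, stage: str, extra: dict | None = None) -> None:
        manifest_path = self.path("manifest.json")
        manifest = {}
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
        manifest.setdefault("config", self.config.to_dict())
        manifest["config_digest"] = self.config.digest()
        manifest["python"] = platform.python_version()
        manifest.setdefault("stages", {})
        manifest["stages"][stage] = {"seed": self.config.seed, **(extra or {})}
        manifest_path.write_text(json.dumps(manifest, indent=1))

    # -- stages -------------------------------------------------------------

    def synth(self) -> synthetic.SyntheticDataset:
        ds = synthetic.generate(
            synthetic.SyntheticConfig(
                n_active=self.config.synth_n_active,
                n_inactive=self.config.synth_n_inactive,
                seed=self.config.synth_seed,
            )
        )
        ds.write(self.path("synthetic.csv"), self.path("synthetic_truth.json"))
        self.config.input_csv = str(self.path("synthetic.csv"))
        self._write_manifest("synth", {"n": len(ds.records)})
        return ds

    def curate(self) -> curation.SplitDataset:
        if not self.config.input_csv:
            synth_csv = self.path("synthetic.csv")
            if synth_csv.exists():
                self.config.input_csv = str(synth_csv)
            else:
                raise MissingArtifactError(
                    "no input CSV configured; run 'synth' or set input_csv"
                )
        raw = curation.read_bioactivity_csv(self.config.input_csv)
        ds = curation.curate(
            raw,
            active_threshold_nM=self.config.active_threshold_nM,
            inactive_threshold_nM=self.config.inactive_threshold_nM,
        )
        curation.write_curated_csv(ds, self.path("curated.csv"))
        curation.write_filter_log(ds, self.path("filter_log.tsv"))
        report = curation.chem_space(ds)
        self.path("chemspace.json").write_text(json.dumps(report.to_json_dict(), indent=1))
        splits = curation.split(ds, self.config.train_fraction, self.config.seed)
        curation.write_curated_csv(splits.train, self.path("train.csv"))
        curation.write_curated_csv(splits.test, self.path("test.csv"))
        self._write_manifest("curate", {"n_train": splits.train.n, "n_test": splits.test.n})
        return splits

    def _load_split(self) -> tuple[curation.CuratedDataset, curation.CuratedDataset]:
        out = []
        for name in ("train.csv", "test.csv"):
            df = pd.read_csv(_require(self.path(name), "curate"), dtype={"compound_id": str})
            out.append(
                curation.CuratedDataset(
                    records=[
                        curation.CompoundRecord(r.compound_id, r.smiles, "=", r.value_nM, r.label)
                        for r in df.itertuples()
                    ]
                )
            )
        return out[0], out[1]

    def featurize(self) -> dict:
        train, test = self._load_split()
        features = {}
        for part, ds in (("train", train), ("test", test)):
            features[part] = {
                fam: fingerprints.featurize(ds, fam) for fam in self.config.descriptors
            }
        joblib.dump(features, self.path("features.joblib"))
        self._write_manifest("featurize", {"families": self.config.descriptors})
        return features

    def _load_features(self) -> dict:
        return joblib.load(_require(self.path("features.joblib"), "featurize"))

    def train_baselines(self) -> zoo.Zoo:
        train, _ = self._load_split()
        features = self._load_features()
        grids = zoo.FAST_GRIDS if self.config.grids == "fast" else zoo.DEFAULT_GRIDS
        z = zoo.train_zoo(
            features["train"],
            train.labels(),
            cv_folds=self.config.cv_folds,
            seed=self.config.seed,
            algorithms=self.config.algorithms,
            descriptors=self.config.descriptors,
            grids=grids,
        )
        joblib.dump(z, self.path("zoo.joblib"))
        z.write_manifest(self.path("zoo_manifest.json"))
        self._write_manifest("train-baselines", {"n_baselines": len(z.specs)})
        return z

    def gen_pf(self) -> tuple[zoo.OOFResult, zoo.PFMatrix]:
        train, test = self._load_split()
        features = self._load_features()
        z: zoo.Zoo = joblib.load(_require(self.path("zoo.joblib"), "train-baselines"))
        oof = zoo.oof_pf(z, features["train"], train.labels(), compound_ids=train.ids())
        pf_test = zoo.apply_pf(z, features["test"], compound_ids=test.ids())
        oof.pf.write_csv(self.path("pf_train.csv"))
        pf_test.write_csv(self.path("pf_test.csv"))
        joblib.dump(oof, self.path("oof.joblib"))
        self._write_manifest("gen-pf", {"pf_dim": oof.pf.shape[1]})
        return oof, pf_test

    def train_meta(self):
        train, _ = self._load_split()
        pf_train = zoo.PFMatrix.read_csv(_require(self.path("pf_train.csv"), "gen-pf"))
        y = train.labels()
        width = pf_train.shape[1]
        if self.config.meta_grid_search:
            cfg, model, log = meta.grid_search_mcnn(
                pf_train, y, cv_folds=self.config.cv_folds, seed=self.config.seed
            )
            self.path("meta_search.json").write_text(json.dumps(log, indent=1))
        else:
            cfg = meta.MetaModelConfig(
                epochs=self.config.meta_epochs,
                learning_rate=self.config.meta_learning_rate,
                seed=self.config.seed,
            )
            model = meta.MCnn(cfg, input_length=width).fit(pf_train, y)
        self.path("meta_config.json").write_text(json.dumps(dataclasses.asdict(cfg), indent=1))
        joblib.dump(model, self.path("meta.joblib"))
        self._write_manifest("train-meta", {"total_filters": model.total_filters})
        return model

    def evaluate(self) -> dict:
        train, test = self._load_split()
        pf_train = zoo.PFMatrix.read_csv(_require(self.path("pf_train.csv"), "gen-pf"))
        pf_test = zoo.PFMatrix.read_csv(_require(self.path("pf_test.csv"), "gen-pf"))
        model = joblib.load(_require(self.path("meta.joblib"), "train-meta"))
        reports = {}
        reports["mCNN-train-oof"] = evaluation.evaluate(train.labels(), model.predict_scores(pf_train))
        reports["mCNN-test"] = evaluation.evaluate(test.labels(), model.predict_scores(pf_test))
        for alg in self.config.algorithms:
            m = meta.train_meta_ml(pf_train, train.labels(), alg, seed=self.config.seed)
            reports[f"m{alg}-test"] = evaluation.evaluate(test.labels(), m.predict_scores(pf_test))
        table = evaluation.comparison_table(reports)
        table.to_csv(self.path("comparison.csv"))
        metrics_json = {name: rep.to_dict() for name, rep in reports.items()}
        self.path("metrics.json").write_text(json.dumps(metrics_json, indent=1, sort_keys=True))
        preds = meta.predict(model, pf_test)
        pd.DataFrame(
            {
                "compound_id": [p.compound_id for p in preds],
                "p_active": [p.p_active for p in preds],
                "label": [p.label for p in preds],
            }
        ).to_csv(self.path("predictions.csv"), index=False)
        self._write_manifest("evaluate", {"test_mcc": reports["mCNN-test"].MCC})
        return metrics_json

    def explain(self, n_explained: int = 50, n_background: int = 100):
        train, _ = self._load_split()
        pf_train = zoo.PFMatrix.read_csv(_require(self.path("pf_train.csv"), "gen-pf"))
        model = joblib.load(_require(self.path("meta.joblib"), "train-meta"))
        rng = np.random.default_rng(self.config.seed)
        n = pf_train.shape[0]
        bg_idx = rng.choice(n, size=min(n_background, n), replace=False)
        ex_idx = rng.choice(n, size=min(n_explained, n), replace=False)
        background = zoo.PFMatrix(
            [pf_train.compound_ids[i] for i in bg_idx], pf_train.columns, pf_train.values[bg_idx]
        )
        explained = zoo.PFMatrix(
            [pf_train.compound_ids[i] for i in ex_idx], pf_train.columns, pf_train.values[ex_idx]
        )
        report = interpretation.explain_meta(model, explained, background, seed=self.config.seed)
        report.to_frame().to_csv(self.path("shap_meta.csv"), index=False)

        # interpretable surrogate over a keyed substructure family
        fam = self.config.surrogate_family
        feats = fingerprints.featurize(train, fam)
        surrogate = interpretation.fit_surrogate(feats, train.labels(), seed=self.config.seed)
        surr_report, table = interpretation.explain_surrogate(surrogate, feats, top_k=20)
        table.to_csv(self.path("shap_substructures.csv"), index=False)
        self._write_manifest("explain", {"surrogate_family": fam})
        return report, surr_report, table

    def screen(self, library=None) -> screening.ScreeningResult:
        train, test = self._load_split()
        z = joblib.load(_require(self.path("zoo.joblib"), "train-baselines"))
        model = joblib.load(_require(self.path("meta.joblib"), "train-meta"))
        if library is None:
            lib_path = _require(Path(self.config.input_csv), "synth")
            library = pd.read_csv(lib_path).rename(columns=str.lower)
        result = screening.screen(
            library, z, model, top_k=self.config.top_k, known_datasets=[train, test]
        )
        screening.write_ranking(result, self.path("screening.csv"))
        self._write_manifest("screen", {"n_ranked": len(result.ranking)})
        return result

    def run_all(self, include_screen: bool = False) -> dict:
        if not self.config.input_csv:
            self.synth()
        self.curate()
        self.featurize()
        self.train_baselines()
        self.gen_pf()
        self.train_meta()
        metrics_json = self.evaluate()
        self.explain()
        if include_screen:
            self.screen()
        return metrics_json
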