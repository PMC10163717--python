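"""Bioactivity table curation, activity labeling and dataset splitting.

The curation pipeline mirrors standard ChEMBL-export hygiene for IC50-based
QSAR work: keep only exact measurements (standard relation ``=``), drop rows
with missing structure or value, convert everything to nM, collapse replicate
measurements per compound, and assign binary activity labels from potency
thresholds (active: IC50 <= 1 uM; inactive: IC50 >= 10 uM; the open interval
in between is left undetermined and excluded from modeling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from scipy.stats import mannwhitneyu

RDLogger.DisableLog("rdApp.*")

ACTIVE_THRESHOLD_NM = 1000.0
INACTIVE_THRESHOLD_NM = 10000.0

#: supported unit -> factor converting to nM
_UNIT_TO_NM = {"nM": 1.0, "uM": 1000.0, "μM": 1000.0, "µM": 1000.0}

ACTIVE = "active"
INACTIVE = "inactive"
UNDETERMINED = "undetermined"


class CurationError(ValueError):
    """Raised when curation cannot produce a usable dataset."""


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule with its bioactivity measurement and class label."""

    compound_id: str
    smiles: str
    relation: str | None = "="
    value_nM: float | None = None
    label: str = UNDETERMINED

    def __post_init__(self) -> None:
        if self.value_nM is not None and self.value_nM < 0:
            raise ValueError(f"negative IC50 for {self.compound_id}")
        if self.label != UNDETERMINED and self.relation != "=":
            raise ValueError("only exact ('=') measurements may carry a label")


def assign_label(value_nM: float) -> str:
    """Potency label from an IC50 in nM.

    active iff IC50 <= 1000 nM, inactive iff IC50 >= 10000 nM; values in the
    open interval between the thresholds are undetermined.
    """
    if value_nM <= ACTIVE_THRESHOLD_NM:
        return ACTIVE
    if value_nM >= INACTIVE_THRESHOLD_NM:
        return INACTIVE
    return UNDETERMINED


@dataclass
class CuratedDataset:
    """Labeled records plus an auditable filter log.

    ``filter_log`` rows are (filter name, records removed, records remaining),
    in application order, so that remaining after step k equals remaining
    before minus removed.
    """

    records: list[CompoundRecord] = field(default_factory=list)
    filter_log: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([1 if r.label == ACTIVE else 0 for r in self.records])

    def class_counts(self) -> tuple[int, int]:
        y = self.labels()
        return int(y.sum()), int((1 - y).sum())

    def subset(self, indices: list[int]) -> "CuratedDataset":
        return CuratedDataset(records=[self.records[i] for i in indices])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "value_nM": [r.value_nM for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


@dataclass
class SplitDataset:
    train: CuratedDataset
    test: CuratedDataset
    seed: int
    train_fraction: float


def standardize_smiles(smiles: str, canonical_tautomer: bool = True) -> str | None:
    """Canonical SMILES of the largest organic fragment, tautomer-normalized.

    Returns None for unparseable input. Salt stripping keeps the largest
    covalent fragment (standard pre-processing before fingerprinting).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        mol = rdMolStandardize.FragmentParent(mol)
        if canonical_tautomer:
            mol = _tautomer_enumerator().Canonicalize(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


_TAUTOMER_ENUMERATOR = None


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER_ENUMERATOR


def curate(
    raw_table: pd.DataFrame,
    active_threshold_nM: float = ACTIVE_THRESHOLD_NM,
    inactive_threshold_nM: float = INACTIVE_THRESHOLD_NM,
    replicate_pic50_sd_max: float = 2.0,
    standardize: bool = True,
) -> CuratedDataset:
    """Apply the full curation pipeline to a raw bioactivity table.

    Parameters
    ----------
    raw_table
        DataFrame with columns ``compound_id, smiles, standard_relation,
        standard_value, standard_units`` (units nM or uM).
    replicate_pic50_sd_max
        Compounds whose replicate '=' measurements have a pIC50 standard
        deviation above this bound are considered irreproducible and dropped.
        Replicates within the bound are aggregated by the geometric mean of
        IC50 (arithmetic mean in pIC50 space).
    standardize
        Strip salts and canonicalize tautomers before storing SMILES.
    """
    required = {"compound_id", "smiles", "standard_relation", "standard_value", "standard_units"}
    missing = required - set(raw_table.columns)
    if missing:
        raise CurationError(f"raw table lacks required columns: {sorted(missing)}")

    df = raw_table.copy()
    log: list[tuple[str, int, int]] = []
    n = len(df)

    def _log(name: str, kept: pd.DataFrame) -> pd.DataFrame:
        nonlocal n
        log.append((name, n - len(kept), len(kept)))
        n = len(kept)
        return kept

    df = _log("relation_equals", df[df["standard_relation"].astype(str).str.strip() == "="])
    df = _log(
        "missing_smiles_or_value",
        df[df["smiles"].notna() & (df["smiles"].astype(str).str.len() > 0) & df["standard_value"].notna()],
    )

    units = df["standard_units"].astype(str).str.strip()
    known = units.isin(_UNIT_TO_NM)
    df = _log("unknown_units", df[known])
    factors = units[known].map(_UNIT_TO_NM)
    df = df.assign(value_nM=pd.to_numeric(df["standard_value"], errors="coerce") * factors)
    df = _log("non_numeric_or_negative_value", df[df["value_nM"].notna() & (df["value_nM"] >= 0)])

    if standardize:
        std = {s: standardize_smiles(s) for s in df["smiles"].unique()}
        df = df.assign(canonical_smiles=df["smiles"].map(std))
        df = _log("unparseable_smiles", df[df["canonical_smiles"].notna()])
    else:
        df = df.assign(canonical_smiles=df["smiles"])

    # replicate handling: geometric-mean aggregation, irreproducible drop
    records: list[CompoundRecord] = []
    n_irreproducible = 0
    for cid, grp in df.groupby("compound_id", sort=False):
        values = grp["value_nM"].to_numpy(dtype=float)
        values = np.clip(values, 1e-6, None)  # pIC50 needs strictly positive molar values
        pic50 = 9.0 - np.log10(values)
        if len(values) > 1 and float(np.std(pic50, ddof=0)) > replicate_pic50_sd_max:
            n_irreproducible += 1
            continue
        value = float(10 ** (9.0 - float(np.mean(pic50))))  # geometric mean in nM
        records.append(
            CompoundRecord(
                compound_id=str(cid),
                smiles=str(grp["canonical_smiles"].iloc[0]),
                relation="=",
                value_nM=value,
                label=UNDETERMINED,
            )
        )
    log.append(("irreproducible_replicates", n_irreproducible, len(records)))

    labeled = []
    n_undetermined = 0
    for rec in records:
        if rec.value_nM <= active_threshold_nM:
            label = ACTIVE
        elif rec.value_nM >= inactive_threshold_nM:
            label = INACTIVE
        else:
            label = UNDETERMINED
        if label == UNDETERMINED:
            n_undetermined += 1
            continue
        labeled.append(replace(rec, label=label))
    log.append(("undetermined_potency", n_undetermined, len(labeled)))

    if not labeled:
        raise CurationError("curation removed every record; no labeled compounds remain")
    return CuratedDataset(records=labeled, filter_log=log)


def split(dataset: CuratedDataset, train_fraction: float = 0.8, seed: int = 42) -> SplitDataset:
    """Stratified random train/test split.

    Per-class train size is round(train_fraction * class size); membership is
    deterministic for a fixed seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1); got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    y = dataset.labels()
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError("need at least 2 records per class to split")
        n_train = int(round(train_fraction * len(idx)))
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return SplitDataset(
        train=dataset.subset(sorted(train_idx)),
        test=dataset.subset(sorted(test_idx)),
        seed=seed,
        train_fraction=train_fraction,
    )


# ---------------------------------------------------------------------------
# chemical space analysis

#: descriptor name -> (callable on Mol, unit)
_DESCRIPTORS = {
    "MW": (Descriptors.MolWt, "Da"),
    "ALogP": (Crippen.MolLogP, ""),
    "nHAcc": (Lipinski.NumHAcceptors, "count"),
    "nHDon": (Lipinski.NumHDonors, "count"),
    "ARR": (None, "ratio"),  # aromatic bond ratio, computed inline
    "nCIC": (rdMolDescriptors.CalcNumRings, "count"),
    "RBN": (Lipinski.NumRotatableBonds, "count"),
    "nBnz": (None, "count"),  # benzene-like rings, computed inline
}

RO5_THRESHOLDS = {"MW": 500.0, "ALogP": 5.0, "nHAcc": 10.0, "nHDon": 5.0}


def _aromatic_ratio(mol: Chem.Mol) -> float:
    bonds = mol.GetBonds()
    if not bonds:
        return 0.0
    return sum(b.GetIsAromatic() for b in bonds) / len(bonds)


def _n_benzene_rings(mol: Chem.Mol) -> int:
    count = 0
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) == 6 and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() and mol.GetAtomWithIdx(i).GetAtomicNum() == 6
            for i in ring
        ):
            count += 1
    return count


def compute_descriptors(smiles: str) -> dict[str, float] | None:
    """The eight chemical-space descriptors for one molecule, or None."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return {
        "MW": float(Descriptors.MolWt(mol)),
        "ALogP": float(Crippen.MolLogP(mol)),
        "nHAcc": float(Lipinski.NumHAcceptors(mol)),
        "nHDon": float(Lipinski.NumHDonors(mol)),
        "ARR": _aromatic_ratio(mol),
        "nCIC": float(rdMolDescriptors.CalcNumRings(mol)),
        "RBN": float(Lipinski.NumRotatableBonds(mol)),
        "nBnz": float(_n_benzene_rings(mol)),
    }


def ro5_pass(desc: dict[str, float]) -> bool:
    """Lipinski rule-of-five compliance from the descriptor dict."""
    return all(desc[k] < v for k, v in RO5_THRESHOLDS.items())


@dataclass
class ChemSpaceReport:
    """Class-wise descriptor summaries, Ro5 flags and Mann-Whitney p-values."""

    summaries: pd.DataFrame  # index (descriptor, class), columns min/max/median/mean/sd
    p_values: dict[str, float]
    ro5_flags: dict[str, bool]
    failed_ids: list[str]

    def to_json_dict(self) -> dict:
        out = {"p_values": self.p_values, "ro5_pass_fraction": float(np.mean(list(self.ro5_flags.values())))}
        out["summaries"] = {
            f"{d}|{c}": row.to_dict() for (d, c), row in self.summaries.iterrows()
        }
        return out


def chem_space(dataset: CuratedDataset) -> ChemSpaceReport:
    """Descriptor summaries per class plus two-sided Mann-Whitney tests.

    Unparseable SMILES are recorded and excluded from the summaries rather
    than failing the whole report.
    """
    rows, failed, flags = [], [], {}
    for rec in dataset.records:
        desc = compute_descriptors(rec.smiles)
        if desc is None:
            failed.append(rec.compound_id)
            continue
        flags[rec.compound_id] = ro5_pass(desc)
        rows.append({"compound_id": rec.compound_id, "label": rec.label, **desc})
    if not rows:
        raise CurationError("no parseable compounds for chemical-space analysis")
    df = pd.DataFrame(rows)

    summaries = []
    p_values: dict[str, float] = {}
    for name in _DESCRIPTORS:
        for cls in (ACTIVE, INACTIVE):
            x = df.loc[df["label"] == cls, name]
            if len(x) == 0:
                continue
            summaries.append(
                pd.Series(
                    {"min": x.min(), "max": x.max(), "median": x.median(), "mean": x.mean(), "sd": x.std(ddof=1)},
                    name=(name, cls),
                )
            )
        a = df.loc[df["label"] == ACTIVE, name].to_numpy()
        b = df.loc[df["label"] == INACTIVE, name].to_numpy()
        if len(a) and len(b):
            p_values[name] = mann_whitney_p(a, b)
    return ChemSpaceReport(
        summaries=pd.DataFrame(summaries),
        p_values=p_values,
        ro5_flags=flags,
        failed_ids=failed,
    )


def mann_whitney_p(a, b) -> float:
    """Two-sided Mann-Whitney p-value; 1.0 for identical constant samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def read_bioactivity_csv(path) -> pd.DataFrame:
    """Read the canonical bioactivity CSV dialect."""
    return pd.read_csv(path, dtype={"compound_id": str})


def write_curated_csv(dataset: CuratedDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def write_filter_log(dataset: CuratedDataset, path) -> None:
    pd.DataFrame(dataset.filter_log, columns=["filter", "removed", "remaining"]).to_csv(
        path, sep="\t", index=False
    )
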