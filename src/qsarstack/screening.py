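"""Virtual screening: rank an external library by predicted p(active).

The full fitted framework (fingerprints -> baseline PFs -> meta-model) is
applied to a SMILES library; compounds already present in the training or
test sets (matched by canonical SMILES, since identifiers are unreliable
across sources) are flagged and excluded before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import CuratedDataset
from .fingerprints import featurize
from .zoo import Zoo, apply_pf


class ScreeningError(ValueError):
    pass


@dataclass
class ScreeningResult:
    ranking: pd.DataFrame  # rank, compound_id, smiles, p_active
    overlap_ids: list[str] = field(default_factory=list)
    skipped_ids: list[str] = field(default_factory=list)

    def top(self, k: int) -> pd.DataFrame:
        return self.ranking.head(k).reset_index(drop=True)


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def screen(
    library: pd.DataFrame | list,
    zoo: Zoo,
    meta_model,
    top_k: int | None = None,
    known_datasets: list[CuratedDataset] | None = None,
    check_overlap: bool = True,
) -> ScreeningResult:
    """Rank library compounds by the meta-model's probability of activity.

    ``library`` is a DataFrame with compound_id/smiles columns, or a list of
    SMILES strings (ids are generated), or a list of (id, smiles) pairs.
    Unparseable SMILES are skipped and logged; ties in probability are
    broken by input order (stable sort). Probabilities are reported to five
    decimal places in the output table.
    """
    rows = _library_rows(library)
    parsed, skipped = [], []
    for cid, smi in rows:
        canon = _canonical(smi)
        if canon is None:
            skipped.append(cid)
        else:
            parsed.append((cid, smi, canon))

    overlap_ids: list[str] = []
    if check_overlap and known_datasets:
        known = set()
        for ds in known_datasets:
            for rec in ds.records:
                canon = _canonical(rec.smiles)
                if canon:
                    known.add(canon)
        kept = []
        for cid, smi, canon in parsed:
            if canon in known:
                overlap_ids.append(cid)
            else:
                kept.append((cid, smi, canon))
        parsed = kept

    if not parsed:
        raise ScreeningError("no screenable compounds remain after filtering")

    id_smiles = [(cid, canon) for cid, _smi, canon in parsed]
    features = {fam: featurize(id_smiles, fam) for fam in zoo.descriptors}
    pf = apply_pf(zoo, features, compound_ids=[cid for cid, _ in id_smiles])
    scores = meta_model.predict_scores(pf)

    frame = pd.DataFrame(
        {
            "compound_id": [cid for cid, _s, _c in parsed],
            "smiles": [smi for _c2, smi, _c in parsed],
            "p_active": np.round(scores, 5),
        }
    )
    # stable sort: equal probabilities keep input order
    frame = frame.sort_values("p_active", ascending=False, kind="stable").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    if top_k is not None:
        frame = frame.head(top_k)
    return ScreeningResult(ranking=frame, overlap_ids=overlap_ids, skipped_ids=skipped)


def _library_rows(library) -> list[tuple[str, str]]:
    if isinstance(library, pd.DataFrame):
        if "smiles" not in library.columns:
            raise ScreeningError("library DataFrame needs a 'smiles' column")
        ids = (
            library["compound_id"].astype(str)
            if "compound_id" in library.columns
            else [f"LIB{i:06d}" for i in range(len(library))]
        )
        return list(zip(ids, library["smiles"]))
    rows = []
    for i, item in enumerate(library):
        if isinstance(item, str):
            rows.append((f"LIB{i:06d}", item))
        else:
            cid, smi = item
            rows.append((str(cid), smi))
    return rows


def read_smiles_file(path) -> pd.DataFrame:
    """One-column SMILES file or (id, smiles) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        df.columns = ["smiles"]
    return df


def write_ranking(result: ScreeningResult, path) -> None:
    result.ranking.to_csv(path, index=False, float_format="%.5f")
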