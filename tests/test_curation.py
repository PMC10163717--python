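"""Curation filters, potency labeling, stratified splitting, chemical space."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qsarstack import curation


def _row(value, unit="uM", relation="=", cid="X", smiles="CCO"):
    return pd.DataFrame(
        {
            "compound_id": [cid],
            "smiles": [smiles],
            "standard_relation": [relation],
            "standard_value": [value],
            "standard_units": [unit],
        }
    )


class TestLabeling:
    @pytest.mark.parametrize(
        "value_uM, expected",
        [(0.5, "active"), (1.0, "active"), (10.0, "inactive"), (50.0, "inactive")],
    )
    def test_threshold_labels(self, value_uM, expected):
        ds = curation.curate(_row(value_uM))
        assert [r.label for r in ds.records] == [expected]

    def test_intermediate_potency_is_excluded_but_logged(self):
        table = pd.concat([_row(5.0, cid="mid"), _row(0.5, cid="act")])
        ds = curation.curate(table)
        assert ds.ids() == ["act"]
        removed = dict((name, rem) for name, rem, _ in ds.filter_log)
        assert removed["undetermined_potency"] == 1

    def test_label_gap_never_labeled(self):
        # the open interval (1 uM, 10 uM) yields no labeled record
        for v in (1.001, 2.0, 5.0, 9.999):
            assert curation.assign_label(v * 1000) == curation.UNDETERMINED
        assert curation.assign_label(1000.0) == "active"
        assert curation.assign_label(10000.0) == "inactive"

    def test_inexact_relation_removed(self):
        table = pd.concat([_row(0.5, relation="<", cid="lt"), _row(0.5, cid="eq")])
        ds = curation.curate(table)
        assert ds.ids() == ["eq"]

    def test_unknown_unit_rejected_with_reason(self, tiny_table):
        ds = curation.curate(tiny_table)
        log = {name: rem for name, rem, _ in ds.filter_log}
        assert log["unknown_units"] == 1
        assert "F" not in ds.ids()

    def test_labeled_record_requires_exact_relation(self):
        with pytest.raises(ValueError):
            curation.CompoundRecord("x", "CCO", relation="<", value_nM=5.0, label="active")

    def test_empty_result_raises(self):
        with pytest.raises(curation.CurationError):
            curation.curate(_row(0.5, relation="<"))


class TestReplicates:
    def test_geometric_mean_aggregation(self):
        table = pd.concat([_row(100.0, unit="nM", cid="G"), _row(400.0, unit="nM", cid="G")])
        ds = curation.curate(table)
        assert len(ds.records) == 1
        assert ds.records[0].value_nM == pytest.approx(200.0)  # sqrt(100*400)

    def test_irreproducible_replicates_dropped(self, tiny_table):
        # compound H spans 1 nM to 90 uM: pIC50 SD ~ 2.45 > 2
        ds = curation.curate(tiny_table)
        assert "H" not in ds.ids()
        log = {name: rem for name, rem, _ in ds.filter_log}
        assert log["irreproducible_replicates"] == 1

    def test_filter_log_reconciles(self, tiny_table):
        ds = curation.curate(tiny_table)
        n = len(tiny_table)
        for _name, removed, remaining in ds.filter_log[:5]:
            assert remaining == n - removed
            n = remaining
        assert ds.filter_log[-1][2] == len(ds.records)

    def test_micromolar_converted_to_nanomolar(self):
        ds = curation.curate(_row(0.5, unit="uM"))
        assert ds.records[0].value_nM == pytest.approx(500.0)


class TestSplit:
    def test_published_class_partition(self, synthetic_default):
        # 433 + 409 compounds at fraction 0.8 -> 346/327 train, 87/82 test
        s = curation.split(synthetic_default.dataset, 0.8, seed=42)
        assert s.train.class_counts() == (346, 327)
        assert s.test.class_counts() == (87, 82)

    def test_split_is_disjoint_and_deterministic(self, synthetic_default):
        s1 = curation.split(synthetic_default.dataset, 0.8, seed=11)
        s2 = curation.split(synthetic_default.dataset, 0.8, seed=11)
        assert set(s1.train.ids()).isdisjoint(s1.test.ids())
        assert s1.train.ids() == s2.train.ids()
        s3 = curation.split(synthetic_default.dataset, 0.8, seed=12)
        assert s1.train.ids() != s3.train.ids()

    def test_small_balanced_split(self):
        recs = [
            curation.CompoundRecord(f"a{i}", "CCO", "=", 10.0, "active") for i in range(10)
        ] + [
            curation.CompoundRecord(f"i{i}", "CCO", "=", 20000.0, "inactive") for i in range(10)
        ]
        s = curation.split(curation.CuratedDataset(records=recs), 0.5, seed=0)
        assert s.train.class_counts() == (5, 5)

    def test_bad_fraction_rejected(self, synthetic_default):
        with pytest.raises(ValueError):
            curation.split(synthetic_default.dataset, 1.2, seed=0)


def _exact_mann_whitney(a, b) -> float:
    """Enumeration oracle: exact two-sided p over all label assignments."""
    a, b = list(a), list(b)
    combined = a + b
    n, m = len(a), len(b)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_stat(a, b)
    center = n * m / 2.0
    total = more_extreme = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n + m) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= abs(u_obs - center) - 1e-12:
            more_extreme += 1
    return more_extreme / total


class TestChemSpace:
    @pytest.mark.parametrize(
        "a, b",
        [
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
            ([1.0, 5.0, 2.0, 8.0], [3.0, 4.0, 9.0]),
            ([0.3, 0.1], [0.2, 0.4, 0.6, 0.5]),
            ([10.0, 20.0, 30.0, 40.0, 50.0, 60.0], [15.0, 25.0, 35.0]),
            ([1.0], [2.0, 3.0, 4.0, 5.0, 6.0]),
        ],
    )
    def test_mann_whitney_matches_enumeration(self, a, b):
        """Tie-free two-sample inputs: exact p equals brute-force enumeration."""
        assert curation.mann_whitney_p(a, b) == pytest.approx(_exact_mann_whitney(a, b), abs=1e-9)

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert curation.mann_whitney_p(x, x) >= 0.99

    def test_separated_normals_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        assert curation.mann_whitney_p(a, b) < 1e-3

    def test_report_structure_and_ro5(self, synthetic_default):
        report = curation.chem_space(synthetic_default.dataset)
        assert set(report.p_values) == {"MW", "ALogP", "nHAcc", "nHDon", "ARR", "nCIC", "RBN", "nBnz"}
        assert all(0.0 <= p <= 1.0 for p in report.p_values.values())
        for (_d, _c), row in report.summaries.iterrows():
            assert row["min"] <= row["median"] <= row["max"]

    def test_ro5_thresholds(self):
        # drug-like molecule passes; a huge greasy one fails on MW
        assert curation.ro5_pass(curation.compute_descriptors("CC(=O)Nc1ccc(O)cc1"))
        big = curation.compute_descriptors("C" * 50)
        assert big["MW"] > 500 and not curation.ro5_pass(big)

    def test_unparseable_smiles_excluded_not_fatal(self):
        recs = [
            curation.CompoundRecord("ok", "CCO", "=", 10.0, "active"),
            curation.CompoundRecord("ok2", "CCCO", "=", 20000.0, "inactive"),
        ]
        ds = curation.CuratedDataset(records=recs)
        ds.records.append(
            curation.CompoundRecord.__new__(curation.CompoundRecord)
        )
        object.__setattr__(ds.records[-1], "compound_id", "bad")
        object.__setattr__(ds.records[-1], "smiles", "not_a_smiles(((")
        object.__setattr__(ds.records[-1], "label", "active")
        object.__setattr__(ds.records[-1], "value_nM", 1.0)
        object.__setattr__(ds.records[-1], "relation", "=")
        report = curation.chem_space(ds)
        assert report.failed_ids == ["bad"]


class TestStandardization:
    def test_salt_stripping_keeps_largest_fragment(self):
        assert curation.standardize_smiles("CCO.[Na+].[Cl-]") == "CCO"

    def test_invalid_smiles_returns_none(self):
        assert curation.standardize_smiles("xyz((") is None

    def test_canonicalization_is_idempotent(self):
        s1 = curation.standardize_smiles("Oc1ccccc1C#N")
        assert curation.standardize_smiles(s1) == s1
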