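"""Dataset labelling, filtering and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixcpi import corpus
from helixcpi.corpus import (InteractionRecord, SplitSpec, deduplicate,
                             filter_class_a, filter_ligand_bias,
                             label_interaction, make_splits, summarize)

from conftest import rec


class TestLabeling:
    @pytest.mark.parametrize("molar,expected", [
        (1e-6, "positive"),    # pAff = 6.0, threshold inclusive
        (1e-5, "negative"),    # pAff = 5.0
        (3.2e-8, "positive"),  # pAff ~ 7.49
        (9.99e-7, "positive"),
        (1.01e-6, "negative"),
    ])
    def test_threshold(self, molar, expected):
        assert label_interaction(molar) == expected

    @pytest.mark.parametrize("bad", [0.0, -1e-6, float("nan"), float("inf"), None])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            label_interaction(bad)


class TestTableLoading:
    def test_units_and_type_filter(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text(
            "accession\tsmiles\taffinity_type\taffinity_value\tunit\n"
            "P1\tCC\tIC50\t100\tnM\n"     # 1e-7 M -> positive
            "P1\tCCO\tEC50\t10\tuM\n"     # 1e-5 M -> negative
            "P1\tCCN\tKi\t1\tnM\n"        # wrong affinity type -> dropped
            "P1\tCCS\tIC50\t-5\tnM\n"     # non-positive -> dropped
            "P1\tCCF\tIC50\t1\tfurlongs\n")  # unknown unit -> dropped
        records = corpus.load_interactions(path)
        assert [(r.smiles, r.label) for r in records] == [
            ("CC", "positive"), ("CCO", "negative")]
        assert records[0].affinity_molar == pytest.approx(1e-7)

    def test_default_unit_when_column_missing(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text("accession\tsmiles\taffinity_type\taffinity_value\n"
                        "P1\tCC\tIC50\t100\n")
        records = corpus.load_interactions(path, default_unit="nM")
        assert records[0].label == "positive"


class TestDeduplicate:
    def test_agreeing_duplicates_collapse(self):
        records = [rec("P1", "CC", 1e-7), rec("P1", "CC", 1e-8)]
        assert len(deduplicate(records)) == 1

    def test_contradictory_duplicates_dropped(self):
        records = [rec("P1", "CC", 1e-7), rec("P1", "CC", 1e-4)]
        assert deduplicate(records) == []


class TestLigandBiasFilter:
    def test_single_interaction_compound_removed(self):
        out = filter_ligand_bias([rec("P1", "CC", 1e-7)])
        assert out == []

    def test_single_class_compound_removed(self):
        records = [rec(f"P{i}", "CC", 1e-7) for i in range(3)]  # all positive
        assert filter_ligand_bias(records) == []

    def test_both_class_compound_kept(self):
        records = [rec("P1", "CC", 1e-7), rec("P2", "CC", 1e-4)]
        assert len(filter_ligand_bias(records)) == 2

    def test_cascade_reaches_fixed_point(self):
        # removing CC's records leaves CCO with one record, which must then go
        records = [rec("P1", "CC", 1e-7),                 # CC: single class
                   rec("P2", "CC", 1e-8),
                   rec("P1", "CCO", 1e-7), rec("P2", "CCO", 1e-4)]
        out = filter_ligand_bias(records)
        assert len(out) == 2  # CCO survives; CC removed
        records2 = records[:3]  # now CCO loses its negative partner record
        assert filter_ligand_bias(records2) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 4),
                              st.booleans()), max_size=30))
    def test_idempotent_and_valid(self, raw):
        records = [rec(f"P{p}", f"{'C' * (c + 1)}", 1e-7 if pos else 1e-4)
                   for p, c, pos in raw]
        once = filter_ligand_bias(records)
        assert filter_ligand_bias(once) == once
        by_smiles = {}
        for r in once:
            by_smiles.setdefault(r.smiles, []).append(r.label)
        for labels in by_smiles.values():
            assert len(labels) >= 2 and len(set(labels)) == 2


class TestClassAFilter:
    def test_membership_subset(self):
        records = [rec("P42866", "CC", 1e-7), rec("Q99999", "CC", 1e-7)]
        out = filter_class_a(records, {"P42866"})
        assert [r.accession for r in out] == ["P42866"]

    def test_superset_is_identity(self):
        records = [rec("P1", "CC", 1e-7)]
        assert filter_class_a(records, {"P1", "P2"}) == records

    def test_empty_records(self):
        assert filter_class_a([], {"P1"}) == []

    def test_empty_membership_is_error(self):
        with pytest.raises(ValueError):
            filter_class_a([rec("P1", "CC", 1e-7)], set())


def _many_records(n, n_prot=10, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        smiles = "C" * (i % 17 + 1) + "N" * (i % 3)  # unique-ish per record
        out.append(rec(f"P{i % n_prot}", smiles,
                       1e-7 if rng.random() < 0.5 else 1e-4))
    # drop duplicate (accession, smiles) pairs so records are unambiguous
    seen, uniq = set(), []
    for r in out:
        key = (r.accession, r.smiles)
        if key not in seen:
            seen.add(key)
            uniq.append(r)
    return uniq


class TestSplits:
    def test_sizes_8_2_then_8_2(self):
        records = [rec(f"P{i}", "C" * (i % 9 + 1), 1e-7) for i in range(100)]
        train, val, test = make_splits(records, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (64, 16, 20)

    def test_partition_exhaustive_and_disjoint(self):
        records = [rec(f"P{i}", "C" * (i % 9 + 1), 1e-7) for i in range(100)]
        train, val, test = make_splits(records, SplitSpec(seed=1))
        ids = lambda rs: {(r.accession, r.smiles) for r in rs}
        assert ids(train) | ids(val) | ids(test) == ids(records)
        assert not (ids(train) & ids(test)) and not (ids(val) & ids(test))

    def test_deterministic_and_order_independent(self):
        records = _many_records(80)
        a = make_splits(records, SplitSpec(seed=3))
        b = make_splits(list(reversed(records)), SplitSpec(seed=3))
        assert a == b

    def test_protein_disjoint(self):
        records = _many_records(200, n_prot=10)
        spec = SplitSpec(seed=0, mode="protein_disjoint")
        train, val, test = make_splits(records, spec)
        trainval = {r.accession for r in train} | {r.accession for r in val}
        assert trainval.isdisjoint({r.accession for r in test})

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            make_splits([rec("P1", "C", 1e-7), rec("P2", "C", 1e-4)],
                        SplitSpec(seed=0))

    def test_labels_conserved(self):
        records = _many_records(50)
        train, val, test = make_splits(records, SplitSpec(seed=0))
        original = {(r.accession, r.smiles): r.label for r in records}
        for r in train + val + test:
            assert r.label == original[(r.accession, r.smiles)]


class TestSummarize:
    def test_counts(self):
        records = [rec("P1", "CC", 1e-7), rec("P1", "CCO", 1e-7),
                   rec("P2", "CC", 1e-4)]
        s = summarize(records)
        assert (s.n_proteins, s.n_compounds, s.n_interactions,
                s.n_positive, s.n_negative) == (2, 2, 3, 2, 1)

    def test_empty(self):
        s = summarize([])
        assert (s.n_proteins, s.n_compounds, s.n_interactions,
                s.n_positive, s.n_negative) == (0, 0, 0, 0, 0)

    def test_dedup_then_count_matches_bruteforce(self):
        # 10-row fixture with duplicates; oracle recount over unique pairs
        rows = [("P1", "CC", 1e-7), ("P1", "CC", 1e-8),   # agreeing dup
                ("P1", "CCO", 1e-4), ("P2", "CC", 1e-7),
                ("P2", "CCO", 1e-7), ("P2", "CCO", 1e-4),  # contradictory dup
                ("P3", "CCN", 1e-4), ("P3", "CCN", 1e-4),
                ("P3", "CC", 1e-7), ("P1", "CCN", 1e-5)]
        records = [rec(a, s, m) for a, s, m in rows]
        deduped = deduplicate(records)
        # brute-force oracle: unique (acc, smiles) pairs with consistent labels
        labels = {}
        for a, s, m in rows:
            labels.setdefault((a, s), set()).add(label_interaction(m))
        expected_pairs = {k for k, v in labels.items() if len(v) == 1}
        assert {(r.accession, r.smiles) for r in deduped} == expected_pairs
        assert summarize(deduped).n_interactions == len(expected_pairs)
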