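import json

import pytest

from bbbp.data_io import (
    CurationReport,
    MoleculeRecord,
    apply_patches,
    canonical_smiles,
    curate_free_form,
    deduplicate,
    read_bbbp_csv,
    read_patch_csv,
    write_bbbp_csv,
)
from bbbp.errors import InvalidSmilesError, SchemaError
from conftest import make_records

TOY_CSV = """num,name,p_np,smiles
1,ethanol,1,CCO
2,"acid, acetic",0,CC(=O)O
3,benzene,1,c1ccccc1
4,propane,0,CCC
"""


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


class TestReadWrite:
    def test_reads_rows_in_order_with_coerced_labels(self, toy_csv):
        records = read_bbbp_csv(toy_csv)
        assert [r.num for r in records] == ["1", "2", "3", "4"]
        assert [r.p_np for r in records] == [1, 0, 1, 0]
        assert records[1].name == "acid, acetic"  # quoted comma survives

    def test_header_is_order_insensitive(self, tmp_path):
        path = tmp_path / "shuffled.csv"
        path.write_text("smiles,p_np,num,name\nCCO,1,9,ethanol\n")
        (rec,) = read_bbbp_csv(path)
        assert (rec.num, rec.p_np, rec.smiles) == ("9", 1, "CCO")

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("num,name,smiles\n1,x,CCO\n")
        with pytest.raises(SchemaError, match="p_np"):
            read_bbbp_csv(path)

    def test_bad_label_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("num,name,p_np,smiles\n7,x,maybe,CCO\n")
        with pytest.raises(SchemaError, match="'7'"):
            read_bbbp_csv(path)

    def test_round_trip_preserves_fields(self, toy_csv, tmp_path):
        records = read_bbbp_csv(toy_csv)
        out = tmp_path / "out.csv"
        write_bbbp_csv(records, out)
        assert read_bbbp_csv(out) == records


class TestCanonicalSmiles:
    def test_same_molecule_same_canonical_form(self):
        assert canonical_smiles("OCC") == canonical_smiles("CCO")

    def test_idempotent(self):
        c = canonical_smiles("c1ccccc1")
        assert canonical_smiles(c) == c

    def test_invalid_smiles_raises_with_offender(self):
        with pytest.raises(InvalidSmilesError, match="not_a_smiles"):
            canonical_smiles("not_a_smiles")


class TestDeduplicate:
    def test_three_identical_same_label_keeps_smallest_num(self):
        records = make_records(
            [(5, "a", 1, "CCO"), (2, "b", 1, "OCC"), (9, "c", 1, "CCO")]
        )
        kept, report = deduplicate(records)
        assert [r.num for r in kept] == ["2"]
        assert sorted(report.removed_duplicates) == [("5", "2"), ("9", "2")]
        assert report.n_out == report.n_in - 2

    def test_inconsistent_pair_removed_entirely(self):
        records = make_records([(1, "a", 1, "CCO"), (2, "b", 0, "OCC")])
        kept, report = deduplicate(records)
        assert kept == []
        assert report.removed_inconsistent == [["1", "2"]]

    def test_all_unique_empty_report(self):
        records = make_records(
            [(i, f"m{i}", i % 2, s)
             for i, s in enumerate(["CCO", "CCC", "c1ccccc1", "CCN", "CCCl"], 1)]
        )
        kept, report = deduplicate(records)
        assert kept == records
        assert not report.removed_duplicates and not report.removed_inconsistent

    def test_kept_set_invariant_under_permutation(self):
        records = make_records(
            [(3, "a", 1, "CCO"), (1, "b", 1, "OCC"), (4, "c", 0, "CCC"),
             (2, "d", 0, "CCCl"), (8, "e", 0, "ClCCC")]
        )
        kept_fwd, rep_fwd = deduplicate(records)
        kept_rev, rep_rev = deduplicate(records[::-1])
        assert {r.num for r in kept_fwd} == {r.num for r in kept_rev}
        assert rep_fwd.n_out == rep_rev.n_out

    def test_report_json_round_trip(self):
        records = make_records([(1, "a", 1, "CCO"), (2, "b", 1, "OCC")])
        _, report = deduplicate(records)
        again = CurationReport.from_json(report.to_json())
        assert again == report


class TestCuration:
    def test_salts_of_same_parent_collide(self):
        # same amine as free base and as hydrochloride: one kept
        records = make_records([(1, "free", 1, "CCN"), (2, "salt", 1, "CCN.Cl")])
        kept, report = curate_free_form(records)
        assert [r.num for r in kept] == ["1"]
        assert report.removed_duplicates == [("2", "1")]

    def test_patch_replaces_smiles_and_is_logged(self, tmp_path):
        patch = tmp_path / "patch.csv"
        patch.write_text("num,smiles\n2,CCO\n")
        records = make_records([(1, "a", 1, "CCC"), (2, "b", 1, "bad(((smiles")])
        patched = apply_patches(records, read_patch_csv(patch))
        assert patched[1].smiles == "CCO"
        kept, report = curate_free_form(records, read_patch_csv(patch))
        assert ("2", "patched") in report.corrected
        assert len(kept) == 2

    def test_unparseable_smiles_passes_through_flagged(self):
        records = make_records([(1, "a", 1, "CCO"), (2, "b", 1, "bad(((smiles")])
        kept, report = curate_free_form(records)
        assert kept[1].smiles == "bad(((smiles"
        assert ("2", "unparseable-smiles: left as-is") in report.corrected

    def test_table4_style_ledger(self):
        """Two-identical sets, a three-identical set and an inconsistent pair
        are each handled per the published removal ledger semantics."""
        records = make_records(
            [
                (3, "dup2-kept", 1, "CCO"), (415, "dup2-gone", 1, "OCC"),
                (83, "dup3-kept", 0, "CCC"), (269, "dup3-gone", 0, "CCC"),
                (569, "dup3-gone", 0, "CCC"),
                (1, "inc", 1, "CCN"), (380, "inc", 0, "NCC"),
                (50, "unique", 1, "c1ccccc1"),
            ]
        )
        kept, report = deduplicate(records)
        assert {r.num for r in kept} == {"3", "83", "50"}
        assert sorted(report.removed_duplicates) == [
            ("269", "83"), ("415", "3"), ("569", "83")
        ]
        assert report.removed_inconsistent == [["1", "380"]]
        assert report.removed_nums == {"415", "269", "569", "1", "380"}
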