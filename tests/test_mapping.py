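"""Column maps, binding-site projection, conservation classification."""

import pytest
from hypothesis import given, settings, strategies as st

from msaligmap.alignment import MSA
from msaligmap.contacts import (
    HYDROGEN_BOND,
    NON_BONDED,
    BindingSite,
    InteractionRecord,
)
from msaligmap.errors import ContractError, LookupError_
from msaligmap.mapping import (
    IDENTICAL,
    SUBSTITUTED,
    build_column_map,
    project_all,
    project_binding_site,
    project_track,
)
from msaligmap.secondary_structure import SecondaryStructureTrack
from msaligmap.structure_io import ResidueNumberMap


def _record(num, cls=HYDROGEN_BOND, icode="", comp="SER"):
    return InteractionRecord(
        comp_id=comp, author_number=num, insertion_code=icode, chain_id="A",
        partner_id="LIG", interaction_class=cls, min_distance=3.0,
    )


def _site(nums, cls=HYDROGEN_BOND, structure_id="1abc:A"):
    site = BindingSite(structure_id=structure_id, partner_label="LIG")
    site.records = [_record(n, cls) for n in nums]
    return site


def _num_map(seq, start=1):
    return ResidueNumberMap(
        entries=[(i, start + i, "", c) for i, c in enumerate(seq)]
    )


class TestBuildColumnMap:
    def test_gapped_row(self):
        msa = MSA(records=[("x", "AC-DE")])
        cm = build_column_map(msa, "x")
        assert cm.seq_to_col == [0, 1, 3, 4]
        assert cm.col_to_seq == [0, 1, None, 2, 3]

    def test_gap_free_identity(self):
        msa = MSA(records=[("x", "ACDE")])
        cm = build_column_map(msa, "x")
        assert cm.seq_to_col == [0, 1, 2, 3]

    def test_unknown_id(self):
        with pytest.raises(LookupError_):
            build_column_map(MSA(records=[("x", "AC")]), "y")

    @given(st.text(alphabet="ACDEFG-", min_size=1, max_size=40))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_round_trip_property(self, row):
        if row.replace("-", "") == "":
            row += "A"
        cm = build_column_map(MSA(records=[("x", row)]), "x")
        for i, col in enumerate(cm.seq_to_col):
            assert cm.col_to_seq[col] == i
        assert len(cm.seq_to_col) == len(row) - row.count("-")


class TestProjectBindingSite:
    def test_hand_walked_gap_in_target(self):
        msa = MSA(records=[("1ABC:A", "ACDE"), ("t1", "AC-E")])
        site = _site([3])  # author 3 -> seq index 2 -> 'D'
        mapped, unmap = project_binding_site(
            site, _num_map("ACDE"), build_column_map(msa, "1ABC:A"), msa)
        assert not unmap
        assert len(mapped) == 1
        m = mapped[0]
        assert m.column == 2
        assert m.per_record["t1"] == ("-", None)
        assert m.status == SUBSTITUTED

    def test_first_column_gap_free(self):
        msa = MSA(records=[("1ABC:A", "ACDE"), ("t1", "ACDE")])
        mapped, _ = project_binding_site(
            _site([1]), _num_map("ACDE"), build_column_map(msa, "1ABC:A"), msa)
        assert mapped[0].column == 0
        assert mapped[0].per_record == {"1ABC:A": ("A", 0), "t1": ("A", 0)}

    def test_unmappable_reported_not_dropped(self):
        msa = MSA(records=[("1ABC:A", "ACDE"), ("t1", "ACDE")])
        site = _site([3, 99])  # 99 not present in coordinates
        mapped, unmap = project_binding_site(
            site, _num_map("ACDE"), build_column_map(msa, "1ABC:A"), msa)
        assert len(mapped) == 1
        assert len(unmap) == 1
        assert unmap[0][1].author_number == 99
        # conservation of records
        assert len(mapped) + len(unmap) == len(site.records)

    def test_insertion_code_resolution(self):
        msa = MSA(records=[("1ABC:A", "ACD"), ("t1", "ACD")])
        nmap = ResidueNumberMap(entries=[(0, 52, "", "A"), (1, 52, "A", "C"),
                                         (2, 53, "", "D")])
        site = BindingSite(structure_id="1abc:A", partner_label="LIG")
        site.records = [_record(52, icode="A")]
        mapped, unmap = project_binding_site(
            site, nmap, build_column_map(msa, "1ABC:A"), msa)
        assert mapped[0].column == 1


class TestClassifyConservation:
    def test_all_same_identical(self):
        msa = MSA(records=[("s", "SSSSS")] + [(f"t{i}", "SSSSS") for i in range(4)])
        report = project_all(msa, [(_site([3]), _num_map("SSSSS"), "s")])
        assert report.sites[0].status == IDENTICAL

    @pytest.mark.parametrize("rows,expected", [
        ([("s", "S"), ("a", "S"), ("b", "T")], SUBSTITUTED),
        ([("s", "S"), ("a", "S"), ("b", "-")], SUBSTITUTED),
        ([("s", "S"), ("a", "S"), ("b", "S")], IDENTICAL),
    ])
    def test_definition_cases(self, rows, expected):
        msa = MSA(records=rows)
        report = project_all(msa, [(_site([1]), _num_map("S"), "s")])
        assert report.sites[0].status == expected

    def test_summary_recomputable_from_sites(self):
        msa = MSA(records=[("s", "ACDEF"), ("t", "ACDKF")])
        site = BindingSite(structure_id="1abc:A", partner_label="LIG")
        site.records = [_record(1), _record(4), _record(2, NON_BONDED)]
        report = project_all(msa, [(site, _num_map("ACDEF"), "s")])
        summary = report.summary()
        hb_sites = report.sites_of_class(HYDROGEN_BOND)
        assert summary[HYDROGEN_BOND]["n_sites"] == len({s.column for s in hb_sites})
        assert summary[HYDROGEN_BOND]["n_identical"] == sum(
            1 for s in hb_sites if s.status == IDENTICAL)
        assert summary[NON_BONDED]["n_sites"] == 1

    def test_row_order_invariance(self):
        rows = [("s", "ACDEF"), ("t1", "ACDKF"), ("t2", "AC-EF")]
        site = _site([2, 4])
        r1 = project_all(MSA(records=rows), [(site, _num_map("ACDEF"), "s")])
        r2 = project_all(MSA(records=[rows[0], rows[2], rows[1]]),
                         [(site, _num_map("ACDEF"), "s")])
        assert [(s.column, s.status) for s in r1.sites] == \
               [(s.column, s.status) for s in r2.sites]

    def test_self_copies_all_identical(self):
        seq = "MKTAYIAKQR"
        rows = [("s", seq)] + [(f"c{i}", seq) for i in range(3)]
        site = _site(list(range(1, len(seq) + 1)))
        report = project_all(MSA(records=rows), [(site, _num_map(seq), "s")])
        assert all(s.status == IDENTICAL for s in report.sites)
        assert report.summary()[HYDROGEN_BOND]["n_substituted"] == 0

    def test_pooled_structures_deduplicate_by_column(self):
        """Two structures' equivalent residues occupy one column and are
        counted once in the pooled summary."""
        msa = MSA(records=[("s1", "ACDEF"), ("s2", "ACDEF"), ("t", "ACDEF")])
        report = project_all(msa, [
            (_site([3], structure_id="1abc:A"), _num_map("ACDEF"), "s1"),
            (_site([3], structure_id="2xyz:A"), _num_map("ACDEF"), "s2"),
        ])
        assert len(report.sites) == 2  # one per structure
        assert report.summary()[HYDROGEN_BOND]["n_sites"] == 1  # pooled by column


class TestProjectTrack:
    def test_hand_walked(self):
        track = SecondaryStructureTrack(structure_id="x:A", codes=["H", "H", "T"])
        msa = MSA(records=[("x", "A-BC")])
        assert project_track(track, build_column_map(msa, "x")) == "H-HT"

    def test_gap_free_unchanged(self):
        track = SecondaryStructureTrack(structure_id="x:A", codes=list("HHT "))
        msa = MSA(records=[("x", "ABCD")])
        assert project_track(track, build_column_map(msa, "x")) == "HHT "

    def test_trailing_gap_padding(self):
        track = SecondaryStructureTrack(structure_id="x:A", codes=["H", "H"])
        msa = MSA(records=[("x", "AB--")])
        assert project_track(track, build_column_map(msa, "x")) == "HH--"

    def test_length_mismatch(self):
        track = SecondaryStructureTrack(structure_id="x:A", codes=["H"])
        msa = MSA(records=[("x", "AB")])
        with pytest.raises(ContractError):
            project_track(track, build_column_map(msa, "x"))
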