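"""PDB parsing, entity classification, sequence extraction, fetching."""

import pytest

from msaligmap.errors import (
    AvailabilityError,
    EntityTypeError,
    LookupError_,
    ParseError,
    ValidationError,
)
from msaligmap.fixtures import ToySpec, make_toy_complex
from msaligmap.structure_io import (
    ResidueNumberMap,
    extract_chain_sequence,
    fetch_structure,
    parse_structure,
)

from conftest import MINIMAL_ALA_PDB


def _atom_line(serial, name, comp, chain, num, xyz, icode=" ", het=False, occ=1.0,
               alt=" "):
    rec = "HETATM" if het else "ATOM  "
    return (f"{rec}{serial:>5}  {name:<3}{alt}{comp:>3} {chain}{num:>4}{icode}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00"
            f"          {name[0]:>2}")


class TestParseStructure:
    def test_minimal_peptide(self, minimal_structure):
        st = minimal_structure
        assert len(st.chains) == 1
        chain = st.chains[0]
        assert chain.entity_kind == "protein"
        assert len(chain.residues) == 3
        assert [r.comp_id for r in chain.residues] == ["ALA"] * 3

    def test_no_atoms_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_structure("HEADER    EMPTY\nEND\n")

    def test_malformed_coordinates_name_line(self):
        bad = MINIMAL_ALA_PDB.replace("1.458", "x.458")
        with pytest.raises(ParseError, match="line 2"):
            parse_structure(bad)

    def test_first_model_only(self):
        lines = ["MODEL        1",
                 _atom_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0)),
                 _atom_line(2, "CA", "ALA", "A", 1, (1.5, 0.0, 0.0)),
                 "ENDMDL",
                 "MODEL        2",
                 _atom_line(1, "N", "ALA", "A", 1, (9.0, 9.0, 9.0)),
                 _atom_line(2, "CA", "ALA", "A", 1, (10.5, 9.0, 9.0)),
                 "ENDMDL", "END"]
        st = parse_structure("\n".join(lines))
        res = st.chains[0].residues[0]
        # coordinates must come from MODEL 1 (manual extraction of its lines)
        assert res.get_atom("N").coords == (0.0, 0.0, 0.0)
        assert res.get_atom("CA").coords == (1.5, 0.0, 0.0)

    def test_altloc_highest_occupancy_wins(self):
        lines = [
            _atom_line(1, "N", "SER", "A", 1, (0.0, 0.0, 0.0)),
            _atom_line(2, "CA", "SER", "A", 1, (1.0, 0.0, 0.0), alt="A", occ=0.4),
            _atom_line(3, "CA", "SER", "A", 1, (2.0, 0.0, 0.0), alt="B", occ=0.6),
            "END",
        ]
        st = parse_structure("\n".join(lines))
        ca = st.chains[0].residues[0].get_atom("CA")
        assert ca.coords[0] == 2.0
        assert ca.alt_loc == "B"

    def test_altloc_tie_keeps_first_in_file(self):
        lines = [
            _atom_line(1, "CA", "SER", "A", 1, (1.0, 0.0, 0.0), alt="A", occ=0.5),
            _atom_line(2, "CA", "SER", "A", 1, (2.0, 0.0, 0.0), alt="B", occ=0.5),
            "END",
        ]
        st = parse_structure("\n".join(lines))
        assert st.chains[0].residues[0].get_atom("CA").coords[0] == 1.0

    def test_entity_classification(self):
        lines = [
            _atom_line(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0)),
            _atom_line(2, "P", "DA", "B", 1, (9.0, 0.0, 0.0)),
            _atom_line(3, "P", "DT", "B", 2, (12.0, 0.0, 0.0)),
            _atom_line(4, "O", "HOH", "W", 1, (20.0, 0.0, 0.0), het=True),
            _atom_line(5, "N1", "NDP", "L", 1, (30.0, 0.0, 0.0), het=True),
            "END",
        ]
        st = parse_structure("\n".join(lines))
        kinds = {c.chain_id: c.entity_kind for c in st.chains}
        assert kinds == {"A": "protein", "B": "dna", "W": "water", "L": "ligand"}

    def test_parse_is_deterministic(self, helix_complex):
        _, pdb_text, _, _ = helix_complex
        a = parse_structure(pdb_text, "1tst")
        b = parse_structure(pdb_text, "1tst")
        assert a == b


class TestExtractChainSequence:
    def test_modres_mapping(self):
        lines = [
            "MODRES 1ABC MSE A   12  MET  SELENOMETHIONINE",
            _atom_line(1, "CA", "ALA", "A", 10, (0.0, 0.0, 0.0)),
            _atom_line(2, "CA", "GLY", "A", 11, (4.0, 0.0, 0.0)),
            _atom_line(3, "CA", "MSE", "A", 12, (8.0, 0.0, 0.0), het=True),
            "END",
        ]
        seq, nmap = extract_chain_sequence(parse_structure("\n".join(lines)), "A")
        assert seq == "AGM"
        assert nmap.entries == [(0, 10, "", "A"), (1, 11, "", "G"), (2, 12, "", "M")]

    def test_numbering_gap_not_filled(self):
        lines = [_atom_line(i + 1, "CA", "ALA", "A", num, (4.0 * i, 0.0, 0.0))
                 for i, num in enumerate((5, 6, 9, 10))] + ["END"]
        seq, nmap = extract_chain_sequence(parse_structure("\n".join(lines)), "A")
        assert len(seq) == 4
        assert nmap.index_of(9) == 2
        assert nmap.author_of(2) == (9, "")
        assert nmap.index_of(7) is None

    def test_insertion_codes_distinct(self):
        lines = [
            _atom_line(1, "CA", "ALA", "A", 52, (0.0, 0.0, 0.0)),
            _atom_line(2, "CA", "GLY", "A", 52, (4.0, 0.0, 0.0), icode="A"),
            _atom_line(3, "CA", "SER", "A", 53, (8.0, 0.0, 0.0)),
            "END",
        ]
        seq, nmap = extract_chain_sequence(parse_structure("\n".join(lines)), "A")
        assert seq == "AGS"
        assert nmap.index_of(52, "") == 0
        assert nmap.index_of(52, "A") == 1
        assert nmap.index_of(52, "A") != nmap.index_of(52, "")

    def test_unknown_residue_becomes_x(self):
        lines = [
            _atom_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
            _atom_line(2, "CA", "ZZZ", "A", 2, (4.0, 0.0, 0.0)),
            "END",
        ]
        seq, _ = extract_chain_sequence(parse_structure("\n".join(lines)), "A")
        assert seq == "AX"

    def test_errors(self, minimal_structure):
        with pytest.raises(LookupError_):
            extract_chain_sequence(minimal_structure, "Z")

    def test_non_protein_chain_rejected(self):
        lines = [_atom_line(1, "P", "DA", "B", 1, (0.0, 0.0, 0.0)), "END"]
        with pytest.raises(EntityTypeError):
            extract_chain_sequence(parse_structure("\n".join(lines)), "B")


class TestResidueNumberMap:
    @pytest.mark.parametrize("geometry,insertion_at", [
        ("ideal_helix", None), ("ideal_helix", 3), ("extended", None),
        ("hairpin", 4),
    ])
    def test_bijection_on_fixtures(self, geometry, insertion_at):
        """Sequence index <-> (author number, icode) must invert both ways."""
        spec = ToySpec(n_residues=12, geometry=geometry, start_number=100,
                       insertion_at=insertion_at)
        pdb_text, _, _ = make_toy_complex(spec)
        st = parse_structure(pdb_text)
        seq, nmap = extract_chain_sequence(st, "A")
        n_amino = sum(1 for c in st.chains if c.chain_id == "A"
                      for _ in c.residues)
        assert len(seq) == len(nmap) == 12
        for idx, num, icode, letter in nmap.entries:
            assert nmap.index_of(num, icode) == idx
            assert nmap.author_of(idx) == (num, icode)
        assert nmap.sequence == seq

    def test_insertion_numbering(self):
        spec = ToySpec(n_residues=5, start_number=100, insertion_at=3)
        pdb_text, _, _ = make_toy_complex(spec)
        _, nmap = extract_chain_sequence(parse_structure(pdb_text), "A")
        assert [(n, i) for _, n, i, _ in nmap.entries] == [
            (100, ""), (101, ""), (102, ""), (102, "A"), (103, "")]

    def test_duplicate_key_rejected(self):
        with pytest.raises(ParseError):
            ResidueNumberMap(entries=[(0, 5, "", "A"), (1, 5, "", "G")])


class TestFetchStructure:
    def test_warm_cache_no_network(self, tmp_path):
        (tmp_path / "3wxb.pdb").write_text("HEADER    CACHED 3WXB\n")
        text = fetch_structure("3wxb", cache_dir=tmp_path, offline=True)
        assert "3WXB" in text

    def test_code_case_insensitive_cache(self, tmp_path):
        (tmp_path / "3wxb.pdb").write_text("HEADER    X\n")
        assert fetch_structure("3WXB", cache_dir=tmp_path, offline=True)

    @pytest.mark.parametrize("bad", ["XYZ", "12345", "WXYZ", "3wx!"])
    def test_malformed_code_rejected(self, bad, tmp_path):
        with pytest.raises(ValidationError):
            fetch_structure(bad, cache_dir=tmp_path, offline=True)

    def test_offline_cold_cache_unavailable(self, tmp_path):
        with pytest.raises(AvailabilityError):
            fetch_structure("1abc", cache_dir=tmp_path, offline=True)
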