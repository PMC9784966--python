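import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from msaligmap.contacts import ContactCriteria
from msaligmap.fixtures import LigandAtom, ToySpec, make_toy_complex
from msaligmap.structure_io import parse_structure


MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       6.042   1.591   0.000  1.00  0.00           O
ATOM      9  N   ALA A   3       6.191   3.828   0.000  1.00  0.00           N
ATOM     10  CA  ALA A   3       7.648   3.847   0.000  1.00  0.00           C
ATOM     11  C   ALA A   3       8.204   5.263   0.000  1.00  0.00           C
ATOM     12  O   ALA A   3       7.446   6.233   0.000  1.00  0.00           O
TER      13      ALA A   3
END
"""


@pytest.fixture
def minimal_structure():
    return parse_structure(MINIMAL_ALA_PDB, "1min")


@pytest.fixture
def helix_complex():
    """12-residue ideal helix with three ligand atoms at exact offsets."""
    spec = ToySpec(
        n_residues=12,
        geometry="ideal_helix",
        sequence="ADKLSTRWYEQN",
        ligand_atoms=[
            LigandAtom("O", 5, "N", (2.6, 1.2, 0.6)),
            LigandAtom("N", 8, "O", (1.8, 1.8, 1.2)),
            LigandAtom("C", 2, "CB", (2.8, 2.0, 0.0)),
        ],
    )
    pdb_text, expected_site, expected_track = make_toy_complex(spec)
    return spec, pdb_text, expected_site, expected_track


@pytest.fixture
def default_criteria():
    return ContactCriteria()
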