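"""Chemical lookup tables shared across modules.

Three-letter/one-letter amino-acid codes, a small built-in table of common
modified residues (supplementing MODRES records), hydrogen-bond donor /
acceptor typing for standard-residue heavy atoms, and the ClustalX residue
colour classes used by the HTML report.
"""

from __future__ import annotations

# 20 standard amino acids, 3-letter -> 1-letter
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Frequently deposited modified residues and their canonical parents.
# Applied after any MODRES records in the file; unknowns become 'X'.
MODIFIED_TO_CANONICAL: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (rendered as C to keep a 20+X alphabet)
    "PYL": "LYS",
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",  # S-hydroxycysteine
    "CME": "CYS",
    "CSD": "CYS",
    "OCS": "CYS",
    "KCX": "LYS",
    "LLP": "LYS",
    "MLY": "LYS",
    "M3L": "LYS",
    "HYP": "PRO",  # hydroxyproline
    "PCA": "GLU",  # pyroglutamate
    "FME": "MET",
    "AIB": "ALA",
    "SAR": "GLY",
}

STANDARD_AA = set(THREE_TO_ONE)

# Deoxyribonucleotide component codes; legacy single-letter codes were used
# in pre-remediation PDB entries for DNA as well.
DNA_COMPONENTS = {"DA", "DC", "DG", "DT", "DU", "DI"}
RNA_COMPONENTS = {"A", "C", "G", "U", "I"}
LEGACY_DNA_COMPONENTS = {"T"}  # thymine only occurs in DNA
WATER_COMPONENTS = {"HOH", "DOD", "WAT"}

# Hydrogen-bond donor/acceptor typing for standard-residue heavy atoms.
# Backbone: N is a donor (except proline), O (and terminal OXT) acceptors.
# Sidechain entries follow textbook residue chemistry; hydroxyls and
# histidine ring nitrogens can act as either.
_D, _A, _B = "donor", "acceptor", "both"

BACKBONE_POLAR = {"N": _D, "O": _A, "OXT": _A}

SIDECHAIN_POLAR: dict[str, dict[str, str]] = {
    "ARG": {"NE": _D, "NH1": _D, "NH2": _D},
    "ASN": {"OD1": _A, "ND2": _D},
    "ASP": {"OD1": _A, "OD2": _A},
    "CYS": {"SG": _D},
    "GLN": {"OE1": _A, "NE2": _D},
    "GLU": {"OE1": _A, "OE2": _A},
    "HIS": {"ND1": _B, "NE2": _B},
    "LYS": {"NZ": _D},
    "MET": {},
    "SER": {"OG": _B},
    "THR": {"OG1": _B},
    "TRP": {"NE1": _D},
    "TYR": {"OH": _B},
}


def protein_atom_polarity(comp_id: str, atom_name: str) -> str:
    """Return donor/acceptor/both/neither for a protein heavy atom."""
    if atom_name in BACKBONE_POLAR:
        if atom_name == "N" and comp_id == "PRO":
            return "neither"  # proline nitrogen has no amide hydrogen
        return BACKBONE_POLAR[atom_name]
    return SIDECHAIN_POLAR.get(comp_id, {}).get(atom_name, "neither")


def partner_atom_polarity(element: str) -> str:
    """Element-based typing for arbitrary partner chemistry.

    O and N atoms are treated as simultaneously donor and acceptor -- the
    safe superset when protonation states of a ligand are unknown.
    """
    return "both" if element.upper() in {"O", "N"} else "neither"


# ClustalX physicochemical colour classes (canonical scheme, simplified to
# residue-letter -> class; the context-dependent ClustalX rules collapse to
# the residue-type palette the alignment viewers display by default).
CLUSTALX_CLASS: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AILMFWV"},
    "K": "positive", "R": "positive",
    "E": "negative", "D": "negative",
    **{aa: "polar" for aa in "NQST"},
    "C": "cysteine",
    "G": "glycine",
    "P": "proline",
    "H": "aromatic", "Y": "aromatic",
    "X": "unconserved",
}

CLUSTALX_COLORS: dict[str, str] = {
    "hydrophobic": "#80a0f0",  # blue
    "positive": "#f01505",     # red
    "negative": "#c048c0",     # magenta
    "polar": "#15c015",        # green
    "cysteine": "#f08080",     # pink
    "glycine": "#f09048",      # orange
    "proline": "#c0c000",      # yellow
    "aromatic": "#15a4a4",     # cyan
    "unconserved": "#ffffff",  # white
}
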