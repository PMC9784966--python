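"""Per-residue secondary-structure codes for structure chains.

Two routes produce a :class:`SecondaryStructureTrack` aligned 1:1 with the
extracted chain sequence:

* :func:`parse_dssp` reads a classic DSSP file (the primary path when the
  user supplies one), and
* :func:`assign_secondary_structure` computes a simplified Kabsch–Sander
  assignment from the coordinates when no DSSP file is available.

The code alphabet is {H, E, G, I, S, B, T, ' '} with ' ' for coil/loop.
Codes introduced by newer DSSP versions (e.g. 'P' for polyproline II) are
mapped to coil so the alphabet stays closed.

The built-in assignment reconstructs amide hydrogens from the preceding
peptide unit (N–H parallel to the previous C=O, 1.0 Å), evaluates the
Kabsch–Sander electrostatic hydrogen-bond energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and accepts a bond when E < -0.5 kcal/mol.  n-turns (n = 3, 4, 5) yield
G/H/I helices when two consecutive turns stack, bridges/ladders yield B/E,
isolated turns T, and CA-trace bends S.  Assembly priority: H > E/B > G >
I > T > S.  It is a simplified assignment, not a bit-exact DSSP clone;
corner rules (helix termination, ladder bulges) may differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import LookupError_, ParseError
from .structure_io import Structure, amino_residues

logger = logging.getLogger(__name__)

SS_ALPHABET = {"H", "E", "G", "I", "S", "B", "T", " "}

# Kabsch-Sander constants
_KS_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom (charge product * factor)
_HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_NH_LENGTH = 1.0  # Angstrom
_MIN_SEQ_SEP = 2  # exclude peptide-bond neighbours from H-bond search
_CA_SEARCH_CUTOFF = 9.0  # Angstrom, CA-CA prefilter as in DSSP
_BEND_ANGLE = 70.0  # degrees


@dataclass
class SecondaryStructureTrack:
    structure_id: str
    codes: list[str]

    def __post_init__(self) -> None:
        bad = set(self.codes) - SS_ALPHABET
        if bad:
            raise ValueError(f"codes outside alphabet: {bad}")

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return "".join(self.codes)


def parse_dssp(dssp_text: str, chain_id: str, structure_id: str = "") -> SecondaryStructureTrack:
    """Read per-residue summary codes for one chain from classic DSSP text.

    Chain-break '!' lines contribute no code; out-of-alphabet codes map to
    coil (' ').
    """
    lines = dssp_text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ParseError("not a classic DSSP file: residue table header not found")
    codes: list[str] = []
    seen_chains = set()
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) < 17:
            raise ParseError(f"line {lineno}: truncated DSSP residue line")
        aa = line[13]
        if aa == "!":  # chain break / chain terminator
            continue
        ch = line[11]
        seen_chains.add(ch)
        if ch != chain_id:
            continue
        code = line[16]
        codes.append(code if code in SS_ALPHABET else " ")
    if not codes:
        raise LookupError_(
            f"chain {chain_id!r} absent from DSSP file (chains present: "
            f"{', '.join(sorted(seen_chains)) or 'none'})"
        )
    return SecondaryStructureTrack(structure_id=structure_id or f"?:{chain_id}", codes=codes)


def _backbone_arrays(residues) -> tuple[np.ndarray, np.ndarray]:
    """(n,4,3) array of N, CA, C, O coordinates and a validity mask."""
    n = len(residues)
    coords = np.full((n, 4, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, res in enumerate(residues):
        atoms = {}
        for name in ("N", "CA", "C", "O"):
            a = res.get_atom(name)
            if a is not None:
                atoms[name] = a.coords
        if len(atoms) == 4:
            coords[i, 0] = atoms["N"]
            coords[i, 1] = atoms["CA"]
            coords[i, 2] = atoms["C"]
            coords[i, 3] = atoms["O"]
            ok[i] = True
    return coords, ok


def kabsch_sander_hbonds(
    coords: np.ndarray, ok: np.ndarray, is_proline: np.ndarray
) -> np.ndarray:
    """Boolean matrix hb[a, d]: CO of residue a accepts the NH of residue d.

    Amide H of residue d is reconstructed from residue d-1's C=O; the first
    residue and prolines have no amide hydrogen and never donate.
    """
    n = len(ok)
    hb = np.zeros((n, n), dtype=bool)
    h_pos = np.full((n, 3), np.nan)
    for d in range(1, n):
        if ok[d] and ok[d - 1] and not is_proline[d]:
            co = coords[d - 1, 2] - coords[d - 1, 3]  # C - O of previous residue
            norm = np.linalg.norm(co)
            if norm > 0:
                h_pos[d] = coords[d, 0] + _NH_LENGTH * co / norm
    for a in range(n):
        if not ok[a]:
            continue
        c_a, o_a = coords[a, 2], coords[a, 3]
        for d in range(n):
            if d == a or abs(d - a) < _MIN_SEQ_SEP or not ok[d]:
                continue
            if np.isnan(h_pos[d]).any():
                continue
            if np.linalg.norm(coords[a, 1] - coords[d, 1]) > _CA_SEARCH_CUTOFF:
                continue
            n_d, h_d = coords[d, 0], h_pos[d]
            r_on = np.linalg.norm(o_a - n_d)
            r_ch = np.linalg.norm(c_a - h_d)
            r_oh = np.linalg.norm(o_a - h_d)
            r_cn = np.linalg.norm(c_a - n_d)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # degenerate geometry
            energy = _KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HBOND_ENERGY_CUTOFF:
                hb[a, d] = True
    return hb


def _helix_codes(hb: np.ndarray, n: int) -> dict[str, np.ndarray]:
    """Turn and helix flags from the H-bond matrix."""
    turns = {}
    for span in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - span):
            if hb[i, i + span]:
                t[i] = True
        turns[span] = t
    helices = {}
    for span, code in ((4, "H"), (3, "G"), (5, "I")):
        h = np.zeros(n, dtype=bool)
        t = turns[span]
        for i in range(n - span - 1):
            if t[i] and t[i + 1]:
                h[i + 1 : i + 1 + span] = True
        helices[code] = h
    turn_flag = np.zeros(n, dtype=bool)
    for span in (3, 4, 5):
        t = turns[span]
        for i in range(n - span):
            if t[i]:
                turn_flag[i + 1 : i + span] = True
    return {"H": helices["H"], "G": helices["G"], "I": helices["I"], "T": turn_flag}


def _bridge_codes(hb: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(strand E, isolated bridge B) flags from ladder detection."""
    pairs = set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                pairs.add((i, j))
    strand = np.zeros(n, dtype=bool)
    bridge = np.zeros(n, dtype=bool)
    for i, j in pairs:
        in_ladder = any(
            p in pairs
            for p in ((i + 1, j + 1), (i + 1, j - 1), (i - 1, j - 1), (i - 1, j + 1))
        )
        if in_ladder:
            strand[i] = strand[j] = True
        else:
            bridge[i] = bridge[j] = True
    return strand, bridge


def _bend_codes(coords: np.ndarray, ok: np.ndarray) -> np.ndarray:
    n = len(ok)
    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if not (ok[i - 2] and ok[i] and ok[i + 2]):
            continue
        u = coords[i, 1] - coords[i - 2, 1]
        v = coords[i + 2, 1] - coords[i, 1]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            continue
        cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        if math.degrees(math.acos(cosang)) > _BEND_ANGLE:
            bend[i] = True
    return bend


def assign_secondary_structure(
    structure: Structure, chain_id: str
) -> SecondaryStructureTrack:
    """Compute a simplified Kabsch–Sander assignment for a protein chain.

    Residues lacking any of the four backbone atoms are coded coil and
    logged; they also never participate in hydrogen bonds.
    """
    residues = amino_residues(structure, chain_id)
    coords, ok = _backbone_arrays(residues)
    n = len(residues)
    missing = [r for r, flag in zip(residues, ok) if not flag]
    if missing:
        logger.warning(
            "%s:%s: %d residue(s) missing backbone atoms, coded as coil",
            structure.pdb_code, chain_id, len(missing),
        )
    is_pro = np.array([r.comp_id == "PRO" for r in residues])
    hb = kabsch_sander_hbonds(coords, ok, is_pro)
    flags = _helix_codes(hb, n)
    strand, bridge = _bridge_codes(hb, n)
    bend = _bend_codes(coords, ok)

    codes = [" "] * n
    # priority: H > E/B > G > I > T > S
    for i in range(n):
        if flags["H"][i]:
            codes[i] = "H"
        elif strand[i]:
            codes[i] = "E"
        elif bridge[i]:
            codes[i] = "B"
        elif flags["G"][i]:
            codes[i] = "G"
        elif flags["I"][i]:
            codes[i] = "I"
        elif flags["T"][i]:
            codes[i] = "T"
        elif bend[i]:
            codes[i] = "S"
    return SecondaryStructureTrack(
        structure_id=f"{structure.pdb_code}:{chain_id}", codes=codes
    )
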