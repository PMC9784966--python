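"""Independent reference implementations used to check the package.

Each oracle applies the relevant definition literally and naively
(all-pairs scans, exhaustive enumeration), sharing only data tables with
the implementation under test — never its algorithms.
"""

from __future__ import annotations

import math
import numpy as np

from msaligmap._tables import partner_atom_polarity, protein_atom_polarity


def brute_force_contacts(structure, protein_chain, partner_comp, criteria):
    """All-pairs distance scan; returns {(author_number, icode, class)}.

    Applies the contact criteria literally to every (protein heavy atom,
    partner heavy atom) pair.
    """
    out = set()
    chain = next(c for c in structure.chains if c.chain_id == protein_chain)
    partner_atoms = []
    for ch in structure.chains:
        for res in ch.residues:
            if res.comp_id == partner_comp:
                for atom in res.atoms:
                    if atom.element.upper() not in ("H", "D"):
                        partner_atoms.append(atom)
    for res in chain.residues:
        if res.comp_id == partner_comp or res.comp_id == "HOH":
            continue
        for atom in res.atoms:
            if atom.element.upper() in ("H", "D"):
                continue
            for patom in partner_atoms:
                d = math.dist(atom.coords, patom.coords)
                if d <= 0:
                    continue
                is_hb = False
                if criteria.hbond_min <= d <= criteria.hbond_max:
                    p = protein_atom_polarity(res.comp_id, atom.name)
                    q = partner_atom_polarity(patom.element)
                    if (p in ("donor", "both") and q in ("acceptor", "both")) or (
                        p in ("acceptor", "both") and q in ("donor", "both")
                    ):
                        is_hb = True
                if is_hb:
                    out.add((res.author_number, res.insertion_code, "hydrogen_bond"))
                elif d <= criteria.nonbonded_max:
                    out.add((res.author_number, res.insertion_code, "non_bonded"))
    return out


def kabsch_sander_energy(n_i, h_i, c_j, o_j):
    """Electrostatic H-bond energy for donor NH(i), acceptor CO(j), kcal/mol."""
    r_on = math.dist(o_j, n_i)
    r_ch = math.dist(c_j, h_i)
    r_oh = math.dist(o_j, h_i)
    r_cn = math.dist(c_j, n_i)
    return 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def brute_force_backbone_hbonds(residues):
    """All-(i,j)-pairs Kabsch-Sander scan over a residue dict list.

    ``residues``: list of {'N','CA','C','O'} coordinate dicts.  Returns
    the set of (acceptor, donor) index pairs with E < -0.5 kcal/mol, with
    amide H reconstructed from the previous peptide's C=O and a minimum
    sequence separation of 2.
    """
    n = len(residues)
    h = [None] * n
    for d in range(1, n):
        co = np.asarray(residues[d - 1]["C"]) - np.asarray(residues[d - 1]["O"])
        h[d] = np.asarray(residues[d]["N"]) + co / np.linalg.norm(co)
    bonds = set()
    for a in range(n):
        for d in range(n):
            if abs(d - a) < 2 or h[d] is None:
                continue
            e = kabsch_sander_energy(
                residues[d]["N"], h[d], residues[a]["C"], residues[a]["O"]
            )
            if e < -0.5:
                bonds.add((a, d))
    return bonds


def enumerate_alignment_optimum(seq_a, seq_b, score, gap_open, gap_extend):
    """Optimal global alignment score by exhaustive enumeration.

    Recursively generates every gapped alignment of the two sequences
    (no dynamic programming) and scores it with run-aware affine gap
    costs: a run of L gap columns costs gap_open + (L-1)*gap_extend.
    Feasible only for short sequences.
    """

    best = -math.inf

    def recurse(i, j, total, last_op):
        nonlocal best
        if i == len(seq_a) and j == len(seq_b):
            best = max(best, total)
            return
        if i < len(seq_a) and j < len(seq_b):
            recurse(i + 1, j + 1, total + score(seq_a[i], seq_b[j]), "M")
        if i < len(seq_a):
            pen = gap_extend if last_op == "A" else gap_open
            recurse(i + 1, j, total + pen, "A")
        if j < len(seq_b):
            pen = gap_extend if last_op == "B" else gap_open
            recurse(i, j + 1, total + pen, "B")

    recurse(0, 0, 0.0, "M")
    return best
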