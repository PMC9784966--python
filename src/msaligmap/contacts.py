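"""Protein–partner contact detection and PDBsum-style list ingestion.

Contacts are classified with distance-only criteria into the two classes
the report styles distinguish: *hydrogen_bond* (a donor/acceptor heavy-atom
pair within the H-bond window) and *non_bonded* (any other heavy-atom pair
within van-der-Waals contact range).  The default windows, 2.70–3.35 Å for
hydrogen bonds and 2.90–3.90 Å for non-bonded contacts, follow LigPlot's
documented conventions.  No angular test and no explicit hydrogens: the
distance criterion is the reproducible core, and deposited structures
rarely carry hydrogens anyway.

The partner may be a ligand chemical component (searched in every chain),
a peptide chain, or the union of all DNA chains (a duplex binds as one
entity).  Waters never mediate and hydrogens are ignored throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import WATER_COMPONENTS, partner_atom_polarity, protein_atom_polarity
from .errors import LookupError_, ParseError
from .structure_io import Residue, Structure, amino_residues

HYDROGEN_BOND = "hydrogen_bond"
NON_BONDED = "non_bonded"


@dataclass(frozen=True)
class ContactCriteria:
    """Distance windows (Å) for the two contact classes."""

    hbond_min: float = 2.70
    hbond_max: float = 3.35
    nonbonded_min: float = 2.90
    nonbonded_max: float = 3.90

    def __post_init__(self) -> None:
        if not (0 < self.hbond_min < self.hbond_max):
            raise ValueError("require 0 < hbond_min < hbond_max")
        if not (0 < self.nonbonded_min < self.nonbonded_max):
            raise ValueError("require 0 < nonbonded_min < nonbonded_max")

    @property
    def search_radius(self) -> float:
        return max(self.hbond_max, self.nonbonded_max)


@dataclass(frozen=True)
class InteractionRecord:
    comp_id: str
    author_number: int
    insertion_code: str
    chain_id: str
    partner_id: str
    interaction_class: str
    min_distance: float | None  # None when ingested from a residue list
    atom_pair: tuple[str, str] = ("", "")
    clash: bool = False  # closer than the non-bonded reporting floor

    @property
    def residue_key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    def residue_label(self) -> str:
        return f"{self.comp_id} {self.author_number}{self.insertion_code}({self.chain_id})"


@dataclass
class BindingSite:
    structure_id: str  # "pdbcode:chain"
    partner_label: str  # ligand code, "DNA", or peptide chain id
    records: list[InteractionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_class(self, interaction_class: str) -> list[InteractionRecord]:
        return [r for r in self.records if r.interaction_class == interaction_class]

    def residue_keys(self, interaction_class: str | None = None) -> list[tuple[int, str]]:
        recs = self.records if interaction_class is None else self.by_class(interaction_class)
        return [r.residue_key for r in recs]


def _sorted_records(records: list[InteractionRecord]) -> list[InteractionRecord]:
    order = {HYDROGEN_BOND: 0, NON_BONDED: 1}
    return sorted(
        records,
        key=lambda r: (r.author_number, r.insertion_code, order[r.interaction_class]),
    )


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.upper()
    return el in {"H", "D"} or (not el and name.strip().startswith("H"))


def _partner_residues(structure: Structure, partner: str) -> tuple[list[tuple[Residue, str]], str]:
    """Resolve a partner selector to (residue, chain_id) pairs and a label.

    Selector forms: ``ligand:NDP`` (component code anywhere), ``chain:B``
    (peptide chain), ``dna`` (all DNA chains).
    """
    kind, _, value = partner.partition(":")
    out: list[tuple[Residue, str]] = []
    if kind == "ligand":
        for chain in structure.chains:
            for res in chain.residues:
                if res.comp_id == value.upper():
                    out.append((res, chain.chain_id))
        label = value.upper()
    elif kind == "chain":
        chain = structure.get_chain(value)
        out = [(r, chain.chain_id) for r in chain.residues if r.comp_id not in WATER_COMPONENTS]
        label = value
    elif kind == "dna":
        for chain in structure.chains:
            if chain.entity_kind == "dna":
                out.extend((r, chain.chain_id) for r in chain.residues)
        label = "DNA"
    else:
        raise LookupError_(f"unknown partner selector {partner!r}")
    if not out:
        raise LookupError_(f"partner {partner!r} not found in {structure.pdb_code}")
    return out, label


def detect_contacts(
    structure: Structure,
    protein_chain: str,
    partner: str,
    criteria: ContactCriteria = ContactCriteria(),
) -> BindingSite:
    """Find the protein residues of ``protein_chain`` contacting ``partner``.

    For every heavy-atom pair within range: *hydrogen_bond* when the two
    atoms are complementary donor/acceptor and the distance lies in the
    H-bond window; otherwise *non_bonded* when within the contact window.
    Per (residue, class) only the minimum-distance atom pair is kept; a
    residue may legitimately appear once in each class.
    """
    chain = structure.get_chain(protein_chain)
    if chain.entity_kind != "protein":
        raise LookupError_(f"chain {protein_chain} is not a protein chain")
    partner_res, label = _partner_residues(structure, partner)

    prot_atoms: list[tuple[Residue, int]] = []  # (residue, atom index within residue)
    prot_coords = []
    for res in amino_residues(structure, protein_chain):
        if res.comp_id in WATER_COMPONENTS:
            continue
        for ai, atom in enumerate(res.atoms):
            if _is_hydrogen(atom.element, atom.name):
                continue
            prot_atoms.append((res, ai))
            prot_coords.append(atom.coords)

    part_atoms: list[tuple[Residue, str, int]] = []
    part_coords = []
    for res, cid in partner_res:
        for ai, atom in enumerate(res.atoms):
            if _is_hydrogen(atom.element, atom.name):
                continue
            part_atoms.append((res, cid, ai))
            part_coords.append(atom.coords)

    site = BindingSite(
        structure_id=f"{structure.pdb_code}:{protein_chain}", partner_label=label
    )
    if not prot_coords or not part_coords:
        return site

    ptree = cKDTree(np.asarray(prot_coords))
    qtree = cKDTree(np.asarray(part_coords))
    pairs = ptree.query_ball_tree(qtree, r=criteria.search_radius)

    best: dict[tuple[tuple[int, str], str], InteractionRecord] = {}
    pcoords = np.asarray(prot_coords)
    qcoords = np.asarray(part_coords)
    for pi, hits in enumerate(pairs):
        res, ai = prot_atoms[pi]
        patom = res.atoms[ai]
        for qi in hits:
            pres, pcid, pai = part_atoms[qi]
            if pres is res:
                continue  # self-contact guard for shared chain ids
            qatom = pres.atoms[pai]
            dist = float(np.linalg.norm(pcoords[pi] - qcoords[qi]))
            if dist <= 0:
                continue
            cls = _classify_pair(res.comp_id, patom, qatom, dist, criteria)
            if cls is None:
                continue
            key = (res.key, cls)
            prev = best.get(key)
            if prev is None or dist < prev.min_distance:
                best[key] = InteractionRecord(
                    comp_id=res.comp_id,
                    author_number=res.author_number,
                    insertion_code=res.insertion_code,
                    chain_id=protein_chain,
                    partner_id=label,
                    interaction_class=cls,
                    min_distance=dist,
                    atom_pair=(patom.name, qatom.name),
                    clash=(cls == NON_BONDED and dist < criteria.nonbonded_min),
                )
    site.records = _sorted_records(list(best.values()))
    return site


def _classify_pair(comp_id, protein_atom, partner_atom, dist, criteria) -> str | None:
    if criteria.hbond_min <= dist <= criteria.hbond_max:
        p = protein_atom_polarity(comp_id, protein_atom.name)
        q = partner_atom_polarity(partner_atom.element)
        donor_ok = p in ("donor", "both") and q in ("acceptor", "both")
        accep_ok = p in ("acceptor", "both") and q in ("donor", "both")
        if donor_ok or accep_ok:
            return HYDROGEN_BOND
    if dist <= criteria.nonbonded_max:
        return NON_BONDED
    return None


_PDBSUM_LINE = re.compile(
    r"^\s*([A-Z0-9]{1,3})\s+(\d+)([A-Za-z]?)\(([A-Za-z0-9])\)\s*$"
)


def parse_pdbsum_residue_list(
    text: str,
    class_hint: str,
    structure_id: str = "",
    partner_label: str = "",
) -> BindingSite:
    """Parse a plain residue list (one ``COMP NUM[ICODE](CHAIN)`` per line).

    This is the ingestion path for interaction lists exported from
    PDBsum/LigPlot/NucPlot, letting published residue sets drive the
    mapping without recomputing geometry.  Distances are unset.
    """
    if class_hint not in (HYDROGEN_BOND, NON_BONDED):
        raise ValueError(f"class_hint must be {HYDROGEN_BOND} or {NON_BONDED}")
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _PDBSUM_LINE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: cannot parse residue token {line.strip()!r}")
        comp, num, icode, chain = m.groups()
        records.append(
            InteractionRecord(
                comp_id=comp,
                author_number=int(num),
                insertion_code=icode.upper(),
                chain_id=chain,
                partner_id=partner_label,
                interaction_class=class_hint,
                min_distance=None,
            )
        )
    site = BindingSite(structure_id=structure_id, partner_label=partner_label)
    # deduplicate (residue, class) keeping first occurrence
    seen = set()
    for rec in records:
        key = (rec.residue_key, rec.interaction_class)
        if key not in seen:
            seen.add(key)
            site.records.append(rec)
    site.records = _sorted_records(site.records)
    return site


def merge_sites(site_a: BindingSite, site_b: BindingSite) -> BindingSite:
    """Union two sites for the same structure chain (e.g., H-bond + non-bonded lists)."""
    if site_a.structure_id != site_b.structure_id:
        raise ValueError("cannot merge sites from different structure chains")
    merged = BindingSite(
        structure_id=site_a.structure_id,
        partner_label=site_a.partner_label or site_b.partner_label,
    )
    best: dict[tuple[tuple[int, str], str], InteractionRecord] = {}
    for rec in site_a.records + site_b.records:
        key = (rec.residue_key, rec.interaction_class)
        prev = best.get(key)
        if prev is None or (
            rec.min_distance is not None
            and (prev.min_distance is None or rec.min_distance < prev.min_distance)
        ):
            best[key] = rec
    merged.records = _sorted_records(list(best.values()))
    return merged
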