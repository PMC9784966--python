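"""Synthetic structures, sequences and DSSP files with known ground truth.

Everything the test-suite and offline demos need is generated here
programmatically: ideal-geometry peptides (helix, extended strand,
two-strand sheet) built from standard bond lengths/angles and preset
phi/psi torsions, ligand and DNA partner atoms placed at exact offsets
from named protein atoms so the expected contact records follow from the
distance criteria by construction, and homolog sets with controlled
substitutions/indels so conservation statuses are predictable.

The emitted PDB text uses legal fixed-column records (ATOM/HETATM/TER/
END, MODRES when modified residues are requested) so fixtures exercise
the real parser.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np

from ._tables import ONE_TO_THREE
from .alignment import SeqRecord, write_fasta
from .contacts import (
    HYDROGEN_BOND,
    NON_BONDED,
    BindingSite,
    ContactCriteria,
    InteractionRecord,
)
from ._tables import partner_atom_polarity, protein_atom_polarity
from .errors import ContractError

# Standard backbone geometry (lengths in Angstrom, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0

PRESET_TORSIONS = {
    "ideal_helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position d with |c-d| = bond, angle(b,c,d) = angle, torsion(a,b,c,d)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, tor = math.radians(angle), math.radians(torsion)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(
    torsions: list[tuple[float, float]], with_cb: bool = True
) -> list[dict[str, np.ndarray]]:
    """Backbone (and CB) coordinates for a chain from (phi, psi) per residue.

    phi of the first residue is undefined and ignored; psi of the last is
    still used to place its carbonyl oxygen.
    """
    n_res = len(torsions)
    if n_res < 1:
        raise ContractError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = torsions[i - 1][1]
        phi_i = torsions[i][0]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_i)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            psi = torsions[i][1]
        else:
            psi = torsions[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        if with_cb:
            res["CB"] = place_atom(res["C"], res["N"], res["CA"], _B_CA_CB, 110.5, 122.6)
    return residues


@dataclass
class LigandAtom:
    """One partner atom at an exact offset from a named protein atom."""

    element: str
    anchor_residue: int  # 0-based index into the protein chain
    anchor_atom: str
    offset: tuple[float, float, float]
    name: str = ""


@dataclass
class ToySpec:
    n_residues: int = 10
    geometry: str = "ideal_helix"  # ideal_helix | extended | hairpin
    sequence: str | None = None  # 1-letter; default poly-ALA
    ligand_atoms: list[LigandAtom] = field(default_factory=list)
    dna: bool = False
    start_number: int = 1
    insertion_at: int | None = None  # this 0-based position repeats the previous number with icode A
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ContractError("n_residues must be >= 3")
        for la in self.ligand_atoms:
            if not all(math.isfinite(x) for x in la.offset):
                raise ContractError("ligand offsets must be finite")


def _hairpin_coords(n_res: int) -> list[dict[str, np.ndarray]]:
    """Two antiparallel extended strands of n_res//2 residues each.

    The second strand is a rigid copy of the first placed by the sheet's
    pseudo two-fold symmetry so cross-strand N...O distances sit in
    hydrogen-bond range.
    """
    half = n_res // 2
    if half < 3:
        raise ContractError("hairpin needs at least 6 residues")
    strand_a = build_backbone([PRESET_TORSIONS["extended"]] * half)
    # Antiparallel pseudo-symmetry: strand B is strand A rotated 180 deg
    # about the sheet normal through the strand centre, then shifted in
    # the sheet plane.  The in-plane offsets (-2.5 A along the strand
    # axis, 3.5 A across it) register the NH/CO groups so cross-strand
    # Kabsch-Sander bonds form an antiparallel ladder.
    ca = np.array([r["CA"] for r in strand_a])
    xhat = ca[-1] - ca[0]
    xhat /= np.linalg.norm(xhat)
    co = np.array([r["O"] - r["C"] for r in strand_a]).mean(axis=0)
    nhat = np.cross(xhat, co)
    nhat /= np.linalg.norm(nhat)
    phat = np.cross(nhat, xhat)
    center = ca.mean(axis=0)
    rot = 2.0 * np.outer(nhat, nhat) - np.eye(3)
    t = center - 2.5 * xhat + 3.5 * phat
    strand_b = [
        {k: rot @ (v - center) + t for k, v in r.items()} for r in strand_a
    ]
    return strand_a + strand_b


def toy_coordinates(spec: ToySpec) -> list[dict[str, np.ndarray]]:
    if spec.geometry == "hairpin":
        return _hairpin_coords(spec.n_residues)
    if spec.geometry not in PRESET_TORSIONS:
        raise ContractError(f"unknown geometry preset {spec.geometry!r}")
    return build_backbone([PRESET_TORSIONS[spec.geometry]] * spec.n_residues)


def _numbering(spec: ToySpec) -> list[tuple[int, str]]:
    numbers = []
    num = spec.start_number
    for i in range(spec.n_residues):
        if spec.insertion_at is not None and i == spec.insertion_at and i > 0:
            numbers.append((numbers[-1][0], "A"))
        else:
            numbers.append((num, ""))
            num += 1
    return numbers


def _pdb_atom_line(
    serial: int, name: str, comp: str, chain: str, resnum: int, icode: str,
    xyz, element: str, het: bool = False, occupancy: float = 1.0,
) -> str:
    record = "HETATM" if het else "ATOM  "
    if len(name) < 4 and len(element) < 2:
        name_field = f" {name:<3}"
    else:
        name_field = f"{name:<4}"
    return (
        f"{record}{serial:>5} {name_field} {comp:>3} {chain}{resnum:>4}"
        f"{icode or ' '}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2}"
    )


_DNA_COMPS = ["DA", "DT", "DG", "DC"]


def make_toy_complex(
    spec: ToySpec, criteria: ContactCriteria = ContactCriteria()
) -> tuple[str, BindingSite, str]:
    """Generate PDB text plus the expected binding site and track pattern.

    The expected :class:`BindingSite` is derived by a literal all-pairs
    scan over the atoms this generator just placed — ground truth by
    construction, independent of the package's KD-tree search path.  The
    expected secondary-structure pattern uses ``?`` as a wildcard at
    positions the preset does not constrain (termini, turn regions).
    """
    coords = toy_coordinates(spec)
    sequence = spec.sequence or "A" * spec.n_residues
    if len(sequence) != spec.n_residues:
        raise ContractError("sequence length must equal n_residues")
    numbering = _numbering(spec)

    lines: list[str] = []
    serial = 1
    protein_atoms: list[tuple[int, tuple[int, str], str, str, np.ndarray]] = []
    # (residue index, (num, icode), comp, atom name, xyz)
    for i, res in enumerate(coords):
        comp = ONE_TO_THREE[sequence[i].upper()]
        num, icode = numbering[i]
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CB" and comp == "GLY":
                continue
            if name not in res:
                continue
            xyz = res[name]
            lines.append(
                _pdb_atom_line(serial, name, comp, spec.chain_id, num, icode, xyz,
                               name[0])
            )
            protein_atoms.append((i, (num, icode), comp, name, xyz))
            serial += 1
    lines.append(f"TER   {serial:>5}      {ONE_TO_THREE[sequence[-1].upper()]:>3} "
                 f"{spec.chain_id}{numbering[-1][0]:>4}")
    serial += 1

    partner_atoms: list[tuple[str, str, np.ndarray]] = []  # (atom name, element, xyz)
    if spec.ligand_atoms:
        for k, la in enumerate(spec.ligand_atoms):
            anchor = None
            for idx, _, _, name, xyz in protein_atoms:
                if idx == la.anchor_residue and name == la.anchor_atom:
                    anchor = xyz
                    break
            if anchor is None:
                raise ContractError(
                    f"anchor atom {la.anchor_atom} of residue {la.anchor_residue} not found"
                )
            xyz = anchor + np.asarray(la.offset, dtype=float)
            name = la.name or f"{la.element.upper()}{k + 1}"
            for _, _, pxyz in partner_atoms:
                if np.linalg.norm(xyz - pxyz) < 0.5:
                    raise ContractError("degenerate geometry: partner atoms < 0.5 A apart")
            for _, _, _, _, pxyz in protein_atoms:
                if np.linalg.norm(xyz - pxyz) < 0.5:
                    raise ContractError("degenerate geometry: partner atom < 0.5 A from protein")
            partner_atoms.append((name, la.element.upper(), xyz))
            lines.append(
                _pdb_atom_line(serial, name, "LIG", "L", 1, "", xyz, la.element.upper(),
                               het=True)
            )
            serial += 1

    if spec.dna:
        # a minimal 4-nucleotide duplex parked 25 A away on +z: far enough
        # to add realistic extra chains without creating protein contacts
        base = coords[0]["CA"] + np.array([0.0, 0.0, 25.0])
        for ci, chain in enumerate("CD"):
            for k in range(4):
                comp = _DNA_COMPS[k]
                origin = base + np.array([6.0 * k, 4.0 * ci, 0.0])
                for j, (aname, el) in enumerate((("P", "P"), ("C1'", "C"), ("N1", "N"))):
                    lines.append(
                        _pdb_atom_line(serial, aname, comp, chain, k + 1, "",
                                       origin + np.array([0.0, 1.4 * j, 0.0]), el)
                    )
                    serial += 1
            lines.append(f"TER   {serial:>5}      {_DNA_COMPS[3]:>3} {chain}{4:>4}")
            serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    expected = _brute_force_site(protein_atoms, partner_atoms, spec, criteria)
    expected_track = _expected_track(spec)
    return pdb_text, expected, expected_track


def _brute_force_site(
    protein_atoms, partner_atoms, spec: ToySpec, criteria: ContactCriteria
) -> BindingSite:
    """Literal all-pairs application of the distance criteria.

    Distances are computed from coordinates rounded to the 3 decimals the
    PDB text carries, so the expectation matches what any parser reads back.
    """
    best: dict[tuple[tuple[int, str], str], InteractionRecord] = {}
    for _, key, comp, pname, pxyz in protein_atoms:
        for qname, qel, qxyz in partner_atoms:
            dist = float(np.linalg.norm(np.round(pxyz, 3) - np.round(qxyz, 3)))
            if dist <= 0:
                continue
            cls = None
            if criteria.hbond_min <= dist <= criteria.hbond_max:
                p = protein_atom_polarity(comp, pname)
                q = partner_atom_polarity(qel)
                if (p in ("donor", "both") and q in ("acceptor", "both")) or (
                    p in ("acceptor", "both") and q in ("donor", "both")
                ):
                    cls = HYDROGEN_BOND
            if cls is None and dist <= criteria.nonbonded_max:
                cls = NON_BONDED
            if cls is None:
                continue
            mkey = (key, cls)
            prev = best.get(mkey)
            if prev is None or dist < prev.min_distance:
                best[mkey] = InteractionRecord(
                    comp_id=comp,
                    author_number=key[0],
                    insertion_code=key[1],
                    chain_id=spec.chain_id,
                    partner_id="LIG",
                    interaction_class=cls,
                    min_distance=dist,
                    atom_pair=(pname, qname),
                    clash=(cls == NON_BONDED and dist < criteria.nonbonded_min),
                )
    site = BindingSite(structure_id=f"xxxx:{spec.chain_id}", partner_label="LIG")
    site.records = sorted(
        best.values(),
        key=lambda r: (r.author_number, r.insertion_code,
                       0 if r.interaction_class == HYDROGEN_BOND else 1),
    )
    return site


def _expected_track(spec: ToySpec) -> str:
    n = spec.n_residues
    if spec.geometry == "ideal_helix":
        # interiors helical; termini unconstrained
        return "?" + "H" * (n - 2) + "?"
    if spec.geometry == "extended":
        # an isolated strand has no bridge partner: no E anywhere
        return " " * n
    return "?" * n  # hairpin: asserted against the energy oracle in tests


def make_random_complex(
    seed: int, max_atoms: int = 50, chain_id: str = "A"
) -> str:
    """A random small protein fragment plus a random ligand atom cloud.

    Used by the contact-detection equivalence checks: no expected output
    is attached; the oracle is an independent brute-force scan.
    """
    rng = np.random.default_rng(seed)
    n_res = int(rng.integers(3, 8))
    torsions = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
                for _ in range(n_res)]
    coords = build_backbone(torsions)
    letters = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_res))
    lines = []
    serial = 1
    anchor_pool = []
    for i, res in enumerate(coords):
        comp = ONE_TO_THREE[letters[i]]
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CB" and comp == "GLY":
                continue
            lines.append(_pdb_atom_line(serial, name, comp, chain_id, i + 1, "",
                                        res[name], name[0]))
            anchor_pool.append(res[name])
            serial += 1
    lines.append(f"TER   {serial:>5}      {ONE_TO_THREE[letters[-1]]:>3} {chain_id}{n_res:>4}")
    serial += 1
    n_lig = int(rng.integers(1, max(2, max_atoms - serial + 2)))
    n_lig = min(n_lig, 12)
    for k in range(n_lig):
        anchor = anchor_pool[int(rng.integers(0, len(anchor_pool)))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = float(rng.uniform(1.0, 6.0))
        xyz = anchor + dist * direction
        element = str(rng.choice(["O", "N", "C", "S", "P"]))
        lines.append(_pdb_atom_line(serial, f"{element}{k + 1}", "LIG", "L", 1, "",
                                    xyz, element, het=True))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class HomologSet:
    records: list[SeqRecord]
    edited_positions: dict[str, set[int]]  # id -> base-sequence indices changed


def make_homolog_set(
    base_sequence: str,
    n: int,
    mutation_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    forced_substitutions: dict[int, str] | None = None,
    id_prefix: str = "target",
) -> HomologSet:
    """Derive ``n`` target sequences from a base with tracked edits.

    ``forced_substitutions`` maps base indices to replacement letters and
    is applied to every derived sequence (after random substitutions, so
    the forced letter always wins); random point substitutions and short
    indels are drawn per sequence from a seeded generator.  The returned
    ``edited_positions`` give, per record, the base indices whose letter
    no longer matches the base sequence — the ground truth for
    conservation classification downstream.
    """
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    records = []
    edited: dict[str, set[int]] = {}
    forced = forced_substitutions or {}
    for k in range(n):
        letters = list(base_sequence)
        changed: set[int] = set()
        for i in range(len(letters)):
            if mutation_rate > 0 and rng.random() < mutation_rate:
                choices = [c for c in alphabet if c != letters[i]]
                letters[i] = str(rng.choice(choices))
                changed.add(i)
        for i, repl in forced.items():
            if repl != base_sequence[i]:
                letters[i] = repl
                changed.add(i)
            else:
                changed.discard(i)
        # indels: mark deleted base positions as edited; insertions add
        # letters without touching base positions
        keep = [True] * len(letters)
        inserts: dict[int, str] = {}
        for i in range(len(letters)):
            if indel_rate > 0 and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    span = int(rng.integers(1, 4))
                    for j in range(i, min(i + span, len(letters))):
                        keep[j] = False
                        changed.add(j)
                else:
                    span = int(rng.integers(1, 4))
                    inserts[i] = "".join(rng.choice(list(alphabet), size=span))
        out = []
        for i, ch in enumerate(letters):
            if i in inserts:
                out.append(inserts[i])
            if keep[i]:
                out.append(ch)
        rid = f"{id_prefix}{k + 1}"
        seq = "".join(out)
        if not seq:
            seq = base_sequence  # degenerate full deletion; fall back to copy
            changed = set()
        records.append(SeqRecord(id=rid, sequence=seq))
        edited[rid] = changed
    return HomologSet(records=records, edited_positions=edited)


def make_dssp_text(chain_id: str, codes: list[tuple[int, str, str]],
                   breaks: set[int] | None = None) -> str:
    """Emit classic DSSP layout for tests: (resnum, aa letter, ss code) rows.

    ``breaks`` inserts a '!' chain-break line before the given row index.
    """
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE ...",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    rows = []
    counter = 1
    breaks = breaks or set()
    for k, (num, aa, ss) in enumerate(codes):
        if k in breaks:
            rows.append(f"{counter:>5}        !              0   0    0")
            counter += 1
        rows.append(f"{counter:>5} {num:>4} {chain_id} {aa}  {ss}             0   0    0")
        counter += 1
    return "\n".join(header + rows) + "\n"


_DEMO_SEQ_POOL = "ADKLSTRWYEQNGFHVIMPC"


@click.command(name="msaligmap-fixtures")
@click.option("--out", "out_dir", type=click.Path(file_okay=False), required=True)
@click.option("--geometry", type=click.Choice(["ideal_helix", "extended", "hairpin"]),
              default="ideal_helix", show_default=True)
@click.option("--n-residues", default=12, show_default=True)
@click.option("--n-targets", default=3, show_default=True)
@click.option("--mutation-rate", default=0.0, show_default=True)
@click.option("--forced-substitution/--no-forced-substitution", default=True,
              show_default=True,
              help="substitute one known binding residue in every target")
@click.option("--seed", default=0, show_default=True)
def main(out_dir, geometry, n_residues, n_targets, mutation_rate,
         forced_substitution, seed):
    """Write a fixture bundle: toy PDB + target FASTA + expected JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequence = (_DEMO_SEQ_POOL * (n_residues // len(_DEMO_SEQ_POOL) + 1))[:n_residues]
    spec = ToySpec(
        n_residues=n_residues,
        geometry=geometry,
        sequence=sequence,
        ligand_atoms=[
            LigandAtom("O", min(5, n_residues - 1), "N", (2.6, 1.2, 0.6)),
            LigandAtom("N", min(8, n_residues - 1), "O", (1.8, 1.8, 1.2)),
            LigandAtom("C", 2, "CB", (2.8, 2.0, 0.0)),
        ],
        seed=seed,
    )
    pdb_text, expected_site, expected_track = make_toy_complex(spec)
    (out / "pdb").mkdir(exist_ok=True)
    # named like a download-cache entry so the bundle is runnable offline
    (out / "pdb" / "1tst.pdb").write_text(pdb_text)
    base = spec.sequence or "A" * n_residues
    forced = {}
    if forced_substitution:
        # substitute the first hydrogen-bonded residue so exactly one
        # binding column is non-identical downstream
        hb = [r for r in expected_site.records
              if r.interaction_class == HYDROGEN_BOND]
        if hb:
            idx = hb[0].author_number - spec.start_number
            repl = "G" if base[idx] != "G" else "A"
            forced = {idx: repl}
    homologs = make_homolog_set(base, n_targets, mutation_rate=mutation_rate,
                                forced_substitutions=forced, seed=seed)
    write_fasta(homologs.records, out / "targets.fasta")
    payload = {
        "expected_site": [
            {
                "comp_id": r.comp_id,
                "author_number": r.author_number,
                "insertion_code": r.insertion_code,
                "class": r.interaction_class,
                "min_distance": r.min_distance,
            }
            for r in expected_site.records
        ],
        "expected_track_pattern": expected_track,
        "edited_positions": {k: sorted(v) for k, v in homologs.edited_positions.items()},
    }
    (out / "expected.json").write_text(json.dumps(payload, indent=2) + "\n")
    click.echo(f"wrote fixture bundle to {out}")


if __name__ == "__main__":
    main()
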