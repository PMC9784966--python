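"""PDB structure parsing and chain-sequence extraction.

The coordinate model is deliberately small: ``Structure`` / ``Chain`` /
``Residue`` / ``Atom`` hold exactly what downstream contact detection and
sequence mapping need, with author residue numbering (number + insertion
code) preserved faithfully.  Record-level PDB parsing is delegated to gemmi;
this module owns the policy decisions layered on top of it:

* only the first MODEL of a multi-model (NMR) file is kept,
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by file order),
* chain entity kinds (protein / dna / rna / water / ligand / other) are
  classified from chemical component codes,
* sequences come from the observed ATOM residues, never from SEQRES, so
  author-numbering gaps stay visible in the ``ResidueNumberMap``.
"""

from __future__ import annotations

import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi

from ._tables import (
    DNA_COMPONENTS,
    LEGACY_DNA_COMPONENTS,
    MODIFIED_TO_CANONICAL,
    RNA_COMPONENTS,
    STANDARD_AA,
    THREE_TO_ONE,
    WATER_COMPONENTS,
)
from .errors import (
    AvailabilityError,
    EntityTypeError,
    LookupError_,
    NetworkError,
    ParseError,
    ValidationError,
)

PDB_CODE_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

DEFAULT_FETCH_URL = "https://files.rcsb.org/download/{code}.pdb"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""


@dataclass
class Residue:
    comp_id: str
    author_number: int
    insertion_code: str
    atoms: list[Atom]
    het_flag: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]
    entity_kind: str = "other"

    def __iter__(self):
        return iter(self.residues)


@dataclass
class Structure:
    pdb_code: str
    chains: list[Chain]
    model_number: int = 1
    modres_map: dict[str, str] = field(default_factory=dict)

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise LookupError_(
            f"chain {chain_id!r} not found in {self.pdb_code} "
            f"(have: {', '.join(c.chain_id for c in self.chains)})"
        )

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


@dataclass
class ResidueNumberMap:
    """Bijection between 0-based sequence index and author numbering.

    ``entries[i] = (i, author_number, insertion_code, one_letter_code)``;
    concatenating the letters gives the extracted chain sequence.
    """

    entries: list[tuple[int, int, str, str]]

    def __post_init__(self) -> None:
        self._by_author = {(num, icode): idx for idx, num, icode, _ in self.entries}
        if len(self._by_author) != len(self.entries):
            raise ParseError("duplicate (author_number, insertion_code) in chain")

    def __len__(self) -> int:
        return len(self.entries)

    def index_of(self, author_number: int, insertion_code: str = "") -> int | None:
        return self._by_author.get((author_number, insertion_code))

    def author_of(self, index: int) -> tuple[int, str]:
        _, num, icode, _ = self.entries[index]
        return num, icode

    @property
    def sequence(self) -> str:
        return "".join(e[3] for e in self.entries)


def _validate_coordinate_columns(pdb_text: str) -> None:
    """Reject ATOM/HETATM lines whose coordinate fields are not numeric.

    gemmi zero-fills unparseable fields silently; the contract here is a
    parse error that names the offending line.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: coordinate record too short")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {what} coordinate "
                    f"{line[lo:hi].strip()!r}"
                ) from None


def _resolve_alt_locs(residue: gemmi.Residue) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties by file order."""
    best: dict[str, tuple[float, int, gemmi.Atom]] = {}
    for order, atom in enumerate(residue):
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev[0]:
            best[atom.name] = (atom.occ, order, atom)
    chosen = sorted(best.values(), key=lambda t: t[1])
    out = []
    for _, _, atom in chosen:
        element = atom.element.name.strip()
        if not element:
            element = re.sub(r"[^A-Za-z]", "", atom.name)[:1]
        alt = atom.altloc if atom.altloc not in ("\x00", " ", "") else ""
        out.append(
            Atom(
                name=atom.name,
                element=element,
                coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                occupancy=atom.occ,
                alt_loc=alt,
            )
        )
    return out


def _is_amino(comp_id: str, modres_map: dict[str, str]) -> bool:
    if comp_id in STANDARD_AA:
        return True
    return modres_map.get(comp_id, MODIFIED_TO_CANONICAL.get(comp_id)) in STANDARD_AA


def _classify_chain(chain: Chain, modres_map: dict[str, str]) -> str:
    comps = [r.comp_id for r in chain.residues]
    if all(c in WATER_COMPONENTS for c in comps):
        return "water"
    if any(_is_amino(c, modres_map) for c in comps):
        return "protein"
    non_water = [c for c in comps if c not in WATER_COMPONENTS]
    nucleic = DNA_COMPONENTS | RNA_COMPONENTS | LEGACY_DNA_COMPONENTS
    if non_water and all(c in nucleic for c in non_water):
        if any(c in DNA_COMPONENTS | LEGACY_DNA_COMPONENTS for c in non_water):
            return "dna"
        return "rna"
    if non_water and all(
        r.het_flag for r in chain.residues if r.comp_id not in WATER_COMPONENTS
    ):
        return "ligand"
    return "other"


def parse_structure(pdb_text: str, pdb_code: str = "") -> Structure:
    """Parse PDB-format text into a single-model :class:`Structure`.

    Only the first MODEL's coordinates are kept (NMR ensembles deposit
    many); MODRES records populate ``modres_map``; chains are classified
    into entity kinds by component code.
    """
    _validate_coordinate_columns(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(str(exc)) from exc
    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        raise ParseError("no ATOM or HETATM records found")

    modres_map = {
        mr.res_id.name: mr.parent_comp_id
        for mr in st.mod_residues
        if mr.parent_comp_id in STANDARD_AA
    }

    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = _resolve_alt_locs(gres)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    comp_id=gres.name,
                    author_number=gres.seqid.num,
                    insertion_code=icode,
                    atoms=atoms,
                    het_flag=(gres.het_flag == "H"),
                )
            )
        if not residues:
            continue
        chain = Chain(chain_id=gchain.name, residues=residues)
        chain.entity_kind = _classify_chain(chain, modres_map)
        chains.append(chain)

    code = (pdb_code or st.name or "").strip().lower()
    if not PDB_CODE_RE.match(code):
        code = code[:4] if code else "xxxx"
    model_number = model.num if hasattr(model, "num") else 1
    return Structure(
        pdb_code=code,
        chains=chains,
        model_number=model_number or 1,
        modres_map=modres_map,
    )


def one_letter_code(comp_id: str, modres_map: dict[str, str] | None = None) -> str:
    """3-letter (or modified) component code -> 1-letter; unknown -> 'X'."""
    if comp_id in THREE_TO_ONE:
        return THREE_TO_ONE[comp_id]
    modres_map = modres_map or {}
    parent = modres_map.get(comp_id) or MODIFIED_TO_CANONICAL.get(comp_id)
    if parent in THREE_TO_ONE:
        return THREE_TO_ONE[parent]
    return "X"


def extract_chain_sequence(
    structure: Structure, chain_id: str
) -> tuple[str, ResidueNumberMap]:
    """Extract the observed amino-acid sequence of a protein chain.

    The sequence reflects residues present in the coordinates only;
    author-numbering gaps are not filled, they simply show up as
    discontinuities in the returned :class:`ResidueNumberMap`.
    """
    chain = structure.get_chain(chain_id)
    if chain.entity_kind != "protein":
        raise EntityTypeError(
            f"chain {chain_id} of {structure.pdb_code} is {chain.entity_kind}, "
            "not protein"
        )
    entries = []
    idx = 0
    for res in chain.residues:
        if not _is_amino(res.comp_id, structure.modres_map) and res.het_flag:
            # co-crystallised ligand/water sharing the chain id
            continue
        letter = one_letter_code(res.comp_id, structure.modres_map)
        entries.append((idx, res.author_number, res.insertion_code, letter))
        idx += 1
    seq = "".join(e[3] for e in entries)
    return seq, ResidueNumberMap(entries)


def amino_residues(structure: Structure, chain_id: str) -> list[Residue]:
    """The residues backing :func:`extract_chain_sequence`, in order."""
    chain = structure.get_chain(chain_id)
    return [
        r
        for r in chain.residues
        if _is_amino(r.comp_id, structure.modres_map) or not r.het_flag
    ]


def fetch_structure(
    pdb_code: str,
    cache_dir: str | Path,
    offline: bool = False,
    url_template: str = DEFAULT_FETCH_URL,
) -> str:
    """Return PDB text for ``pdb_code``, from cache or the download endpoint.

    ``offline=True`` never touches the network; a cache miss is then an
    :class:`AvailabilityError`.
    """
    code = pdb_code.strip().lower()
    if not PDB_CODE_RE.match(code):
        raise ValidationError(f"not a valid PDB code: {pdb_code!r}")
    cache_dir = Path(cache_dir)
    for candidate in (f"{code}.pdb", f"{code.upper()}.pdb", f"pdb{code}.ent"):
        path = cache_dir / candidate
        if path.is_file():
            return path.read_text()
    if offline:
        raise AvailabilityError(
            f"{code}.pdb not present in {cache_dir} and offline mode is on"
        )
    url = url_template.format(code=code.upper())
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except urllib.error.HTTPError as exc:
        raise NetworkError(f"download of {code} failed: HTTP {exc.code}") from exc
    except urllib.error.URLError as exc:
        raise NetworkError(f"download of {code} failed: {exc.reason}") from exc
    cache_dir.mkdir(parents=True, exist_ok=True)
    (cache_dir / f"{code}.pdb").write_text(text)
    return text
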