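"""Projection of binding sites and structure tracks through MSA columns.

This is the transfer step: a binding residue known in a structure chain is
located in that chain's alignment row, its column is read down through
every other row, and the column is classified *identical* (the same
residue letter in every sequence) or *substituted* (any mismatch — a gap
at a binding column counts as substituted, since a deletion at a binding
site is functionally a substitution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import MSA
from .contacts import HYDROGEN_BOND, NON_BONDED, BindingSite, InteractionRecord
from .errors import ContractError, LookupError_
from .secondary_structure import SecondaryStructureTrack
from .structure_io import ResidueNumberMap

IDENTICAL = "identical"
SUBSTITUTED = "substituted"


@dataclass
class ColumnMap:
    """Bidirectional residue-index <-> alignment-column map for one row."""

    record_id: str
    seq_to_col: list[int]
    col_to_seq: list[int | None]  # None at gap columns

    def __post_init__(self) -> None:
        for i, col in enumerate(self.seq_to_col):
            if self.col_to_seq[col] != i:
                raise ContractError("column map round-trip violated")


def build_column_map(msa: MSA, record_id: str) -> ColumnMap:
    """Scan one aligned row once, recording where each residue sits."""
    try:
        row = msa.row(record_id)
    except KeyError:
        raise LookupError_(f"record {record_id!r} not in alignment") from None
    seq_to_col: list[int] = []
    col_to_seq: list[int | None] = []
    for col, ch in enumerate(row):
        if ch == "-":
            col_to_seq.append(None)
        else:
            col_to_seq.append(len(seq_to_col))
            seq_to_col.append(col)
    return ColumnMap(record_id=record_id, seq_to_col=seq_to_col, col_to_seq=col_to_seq)


@dataclass
class MappedSite:
    column: int
    source_structure: str  # "pdbcode:chain"
    source_record: InteractionRecord
    per_record: dict[str, tuple[str, int | None]]  # id -> (letter or '-', seq index)

    @property
    def interaction_class(self) -> str:
        return self.source_record.interaction_class

    @property
    def status(self) -> str:
        letters = {letter for letter, _ in self.per_record.values()}
        if "-" in letters or len(letters) != 1:
            return SUBSTITUTED
        return IDENTICAL


@dataclass
class ConservationReport:
    sites: list[MappedSite] = field(default_factory=list)
    unmappable: list[tuple[str, InteractionRecord]] = field(default_factory=list)

    def sites_of_class(self, interaction_class: str) -> list[MappedSite]:
        return [s for s in self.sites if s.interaction_class == interaction_class]

    def summary(self) -> dict[str, dict[str, int]]:
        """Per interaction class: site / identical / substituted / unmappable counts.

        A column reached from several structures counts once per class
        (equivalent residues of two structures occupy one column).
        """
        out: dict[str, dict[str, int]] = {}
        for cls in (HYDROGEN_BOND, NON_BONDED):
            seen: dict[int, str] = {}
            for site in self.sites_of_class(cls):
                seen.setdefault(site.column, site.status)
            n_unmap = sum(
                1 for _, rec in self.unmappable if rec.interaction_class == cls
            )
            if not seen and not n_unmap:
                continue
            n_ident = sum(1 for s in seen.values() if s == IDENTICAL)
            out[cls] = {
                "n_sites": len(seen),
                "n_identical": n_ident,
                "n_substituted": len(seen) - n_ident,
                "n_unmappable": n_unmap,
            }
        return out

    def binding_columns(self) -> list[int]:
        """Deduplicated alignment columns carrying any binding site, in order."""
        return sorted({s.column for s in self.sites})


def project_binding_site(
    site: BindingSite,
    num_map: ResidueNumberMap,
    col_map: ColumnMap,
    msa: MSA,
) -> tuple[list[MappedSite], list[tuple[str, InteractionRecord]]]:
    """Map each interaction record of one structure chain to its column.

    Records whose residue is absent from the coordinates-derived numbering
    map (e.g. a published list names a residue unresolved in the ATOM
    records) are returned in the unmappable list, never dropped silently.
    """
    mapped: list[MappedSite] = []
    unmappable: list[tuple[str, InteractionRecord]] = []
    rows = dict(msa.records)
    structure_row = rows[col_map.record_id]
    col_maps = {rid: build_column_map(msa, rid) for rid in rows}
    for rec in site.records:
        idx = num_map.index_of(rec.author_number, rec.insertion_code)
        if idx is None:
            unmappable.append((site.structure_id, rec))
            continue
        col = col_map.seq_to_col[idx]
        if structure_row[col] == "-":
            raise ContractError("structure row has a gap at its own residue column")
        per_record: dict[str, tuple[str, int | None]] = {}
        for rid, row in rows.items():
            letter = row[col]
            if letter == "-":
                per_record[rid] = ("-", None)
            else:
                per_record[rid] = (letter, col_maps[rid].col_to_seq[col])
        mapped.append(
            MappedSite(
                column=col,
                source_structure=site.structure_id,
                source_record=rec,
                per_record=per_record,
            )
        )
    return mapped, unmappable


def classify_conservation(
    sites: list[MappedSite],
    unmappable: list[tuple[str, InteractionRecord]] | None = None,
) -> ConservationReport:
    """Bundle mapped sites into a report; statuses derive from the letters."""
    return ConservationReport(sites=list(sites), unmappable=list(unmappable or []))


def project_track(track: SecondaryStructureTrack, col_map: ColumnMap) -> str:
    """Spread a per-residue code string across its row's alignment columns."""
    if len(track) != len(col_map.seq_to_col):
        raise ContractError(
            f"track length {len(track)} != residue count {len(col_map.seq_to_col)}"
        )
    out = ["-"] * len(col_map.col_to_seq)
    for i, col in enumerate(col_map.seq_to_col):
        out[col] = track.codes[i]
    return "".join(out)


def project_all(
    msa: MSA,
    structure_sites: list[tuple[BindingSite, ResidueNumberMap, str]],
) -> ConservationReport:
    """Project several structures' sites through one alignment.

    ``structure_sites`` pairs each BindingSite with its numbering map and
    the MSA record id of the structure row.
    """
    all_sites: list[MappedSite] = []
    all_unmap: list[tuple[str, InteractionRecord]] = []
    for site, num_map, record_id in structure_sites:
        col_map = build_column_map(msa, record_id)
        mapped, unmap = project_binding_site(site, num_map, col_map, msa)
        all_sites.extend(mapped)
        all_unmap.extend(unmap)
    return classify_conservation(all_sites, all_unmap)
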