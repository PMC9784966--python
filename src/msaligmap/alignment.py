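"""Multiple sequence alignment of structure-derived and target sequences.

Two aligner routes share one contract (ungapping every output row must
recover the corresponding input byte-for-byte, rows in input order):

* :func:`align_external` shells out to MAFFT or Clustal Omega, and
* :func:`align_builtin` is a deterministic progressive aligner (k-mer
  distances, UPGMA guide tree with lexicographic tie-breaks,
  profile–profile Needleman–Wunsch with BLOSUM62 and affine gaps) that
  needs no external binary.

Homology-transfer quality degrades below the twilight zone, so pairwise
identities under 30 % are flagged (a warning, never an error).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .errors import EnvironmentError_, ParseError, ToolError, ContractError

logger = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5
TWILIGHT_THRESHOLD = 30.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass
class SeqRecord:
    id: str
    sequence: str
    description: str = ""
    is_structure: bool = False
    source: tuple[str, str] | None = None  # (pdb_code, chain) when is_structure

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _VALID_LETTERS
        if bad:
            raise ContractError(
                f"record {self.id!r} contains invalid letters: {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()


@dataclass
class MSA:
    records: list[tuple[str, str]]  # (id, aligned string with '-')

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ParseError(f"aligned rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, record_id: str) -> str:
        for rid, s in self.records:
            if rid == record_id:
                return s
        raise KeyError(record_id)


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, percent
    twilight_threshold: float = TWILIGHT_THRESHOLD

    def flagged_pairs(self) -> list[tuple[str, str, float]]:
        """Pairs whose identity falls below the twilight threshold."""
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if self.values[i, j] < self.twilight_threshold:
                    out.append((self.ids[i], self.ids[j], float(self.values[i, j])))
        return out


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path_or_handle) -> list[SeqRecord]:
    """Read a multi-FASTA file; '*' stop symbols are stripped with a warning."""
    records = []
    seen = set()
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("record %s: stripping '*' stop symbol(s)", rec.id)
            seq = seq.replace("*", "")
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records, handle_or_path, width: int = 60) -> None:
    """Write records as multi-FASTA wrapped at ``width`` columns."""
    own = isinstance(handle_or_path, (str, Path))
    handle = open(handle_or_path, "w") if own else handle_or_path
    try:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, SeqRecord) else rec
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# Builtin progressive aligner

def _substitution_score(a: str, b: str) -> float:
    if a == "-" or b == "-":
        return 0.0
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return float(_BLOSUM62["X", "X"])


def _profile_column_score(col_a: str, col_b: str) -> float:
    total = 0.0
    for a in col_a:
        for b in col_b:
            total += _substitution_score(a, b)
    return total / (len(col_a) * len(col_b))


def _align_profiles(
    prof_a: list[str], prof_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str], float]:
    """Global affine-gap alignment of two profiles (lists of aligned rows).

    Returns gapped copies of both profiles and the optimal score.  A gap
    run of length L costs ``gap_open + (L-1) * gap_extend``; terminal gaps
    are penalised like any other.
    """
    cols_a = ["".join(r[i] for r in prof_a) for i in range(len(prof_a[0]))]
    cols_b = ["".join(r[i] for r in prof_b) for i in range(len(prof_b[0]))]
    n, m = len(cols_a), len(cols_b)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in B (consumes A columns)
    Y = np.full((n + 1, m + 1), neg)  # gap in A (consumes B columns)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    # traceback: 0=M,1=X,2=Y; store predecessor state per cell
    tb = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    tb[1, 1:, 0] = 1
    tb[2, 0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _profile_column_score(cols_a[i - 1], cols_b[j - 1])
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = cands[k] + s
            tb[0, i, j] = k
            cands = (
                M[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open,
            )
            k = int(np.argmax(cands))
            X[i, j] = cands[k]
            tb[1, i, j] = k
            cands = (
                M[i, j - 1] + gap_open,
                X[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
            )
            k = int(np.argmax(cands))
            Y[i, j] = cands[k]
            tb[2, i, j] = k
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    best = float(finals[state])
    # traceback
    ops = []  # 'D' diagonal, 'A' consume A (gap in B), 'B' consume B
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(tb[state, i, j])
        if state == 0:
            ops.append("D")
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("A")
            i -= 1
        else:
            ops.append("B")
            j -= 1
        state = prev
    ops.reverse()
    out_a = ["" for _ in prof_a]
    out_b = ["" for _ in prof_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(prof_a):
                out_a[r] += row[ia]
            for r, row in enumerate(prof_b):
                out_b[r] += row[ib]
            ia += 1
            ib += 1
        elif op == "A":
            for r, row in enumerate(prof_a):
                out_a[r] += row[ia]
            for r in range(len(prof_b)):
                out_b[r] += "-"
            ia += 1
        else:
            for r in range(len(prof_a)):
                out_a[r] += "-"
            for r, row in enumerate(prof_b):
                out_b[r] += row[ib]
            ib += 1
    return out_a, out_b, best


def pairwise_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Global Needleman–Wunsch alignment of two sequences (BLOSUM62, affine)."""
    a, b, score = _align_profiles([seq_a], [seq_b], gap_open, gap_extend)
    return a[0], b[0], score


def _kmer_distance(seq_a: str, seq_b: str, k: int = 3) -> float:
    k = min(k, len(seq_a), len(seq_b))
    if k == 0:
        return 1.0

    def counts(s):
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            d[kmer] = d.get(kmer, 0) + 1
        return d

    ca, cb = counts(seq_a), counts(seq_b)
    shared = sum(min(ca[kmer], cb.get(kmer, 0)) for kmer in ca)
    denom = min(len(seq_a), len(seq_b)) - k + 1
    return 1.0 - shared / denom


def _upgma(ids: list[str], dist: np.ndarray) -> list:
    """UPGMA guide tree as nested tuples; ties broken lexicographically.

    Each cluster is keyed by its lexicographically smallest member id so
    joins are deterministic regardless of input order.
    """
    clusters: dict[str, dict] = {
        rid: {"tree": rid, "members": [i], "key": rid} for i, rid in enumerate(ids)
    }
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = clusters[keys[i]], clusters[keys[j]]
                d = np.mean([dist[p, q] for p in a["members"] for q in b["members"]])
                cand = (d, keys[i], keys[j])
                if best is None or cand < best:
                    best = cand
        _, ka, kb = best
        a, b = clusters.pop(ka), clusters.pop(kb)
        merged = {
            "tree": (a["tree"], b["tree"]),
            "members": a["members"] + b["members"],
            "key": min(ka, kb),
        }
        clusters[merged["key"]] = merged
    return next(iter(clusters.values()))["tree"]


def align_builtin(
    records: list[SeqRecord],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MSA:
    """Progressive multiple alignment without external binaries."""
    if len(records) < 2:
        raise ContractError("alignment requires at least two sequences")
    ids = [r.id for r in records]
    seqs = {r.id: r.sequence for r in records}
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _kmer_distance(records[i].sequence, records[j].sequence)
            dist[i, j] = dist[j, i] = d
    tree = _upgma(ids, dist)

    def descend(node) -> tuple[list[str], list[str]]:
        if isinstance(node, str):
            return [node], [seqs[node]]
        (ids_a, prof_a), (ids_b, prof_b) = descend(node[0]), descend(node[1])
        out_a, out_b, _ = _align_profiles(prof_a, prof_b, gap_open, gap_extend)
        return ids_a + ids_b, out_a + out_b

    got_ids, rows = descend(tree)
    by_id = dict(zip(got_ids, rows))
    msa = MSA(records=[(rid, by_id[rid]) for rid in ids])
    _validate_alignment(msa, records)
    return msa


# ---------------------------------------------------------------------------
# External aligners

_ALIGNER_COMMANDS = {
    "mafft": lambda path: ["mafft", "--auto", "--amino", "--preservecase", str(path)],
    "clustalo": lambda path: [
        "clustalo", "-i", str(path), "--output-order=input-order", "--force",
    ],
}


def align_external(records: list[SeqRecord], tool: str = "mafft") -> MSA:
    """Align via an external program (``mafft`` or ``clustalo``)."""
    if tool not in _ALIGNER_COMMANDS:
        raise ContractError(f"unknown aligner {tool!r}")
    if len(records) < 2:
        raise ContractError("alignment requires at least two sequences")
    if shutil.which(tool) is None:
        raise EnvironmentError_(
            f"{tool} not found on PATH; use --aligner builtin as a fallback"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "input.fasta"
        write_fasta(records, fasta)
        proc = subprocess.run(
            _ALIGNER_COMMANDS[tool](fasta),
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise ToolError(f"{tool} exited {proc.returncode}: {proc.stderr[-2000:]}")
        aligned = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(StringIO(proc.stdout), "fasta")
        }
    missing = [r.id for r in records if r.id not in aligned]
    if missing:
        raise ToolError(f"{tool} output is missing input id(s): {missing}")
    msa = MSA(records=[(r.id, aligned[r.id]) for r in records])
    _validate_alignment(msa, records)
    return msa


def _validate_alignment(msa: MSA, records: list[SeqRecord]) -> None:
    originals = {r.id: r.sequence for r in records}
    for rid, row in msa.records:
        if row.replace("-", "") != originals[rid]:
            raise ToolError(
                f"alignment row {rid!r} does not ungap to its input sequence"
            )


def align(records: list[SeqRecord], aligner: str = "builtin") -> MSA:
    """Dispatch to the selected aligner."""
    if aligner == "builtin":
        return align_builtin(records)
    return align_external(records, tool=aligner)


# ---------------------------------------------------------------------------
# Percent identity

def pairwise_identity(msa: MSA, twilight_threshold: float = TWILIGHT_THRESHOLD) -> IdentityMatrix:
    """Pairwise percent identity over columns where either row has a residue.

    identity(a, b) = 100 * matches / columns with >=1 non-gap of the pair.
    """
    ids = msa.ids
    n = len(ids)
    values = np.full((n, n), 100.0)
    rows = [row for _, row in msa.records]
    for i in range(n):
        for j in range(i + 1, n):
            matches = denom = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" and b == "-":
                    continue
                denom += 1
                if a != "-" and b != "-" and a.upper() == b.upper():
                    matches += 1
            pct = 100.0 * matches / denom if denom else 0.0
            values[i, j] = values[j, i] = pct
    matrix = IdentityMatrix(ids=ids, values=values, twilight_threshold=twilight_threshold)
    for a, b, pct in matrix.flagged_pairs():
        logger.warning(
            "identity %s vs %s = %.1f%% is below the %.0f%% twilight threshold; "
            "annotation transfer may be unreliable", a, b, pct, twilight_threshold,
        )
    return matrix
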