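"""Rendering of the annotated alignment in plain text and HTML.

Two output sections mirror the analysis product:

1. the full blocked alignment, each structure row preceded by its aligned
   secondary-structure track, residues coloured by ClustalX
   physicochemical class, hydrogen-bonded binding positions bold and
   non-bonded ones underlined;
2. the binding-site sub-alignment — only the binding columns, in
   alignment order, with a red background where the position is identical
   in every sequence and blue where any sequence substitutes (or deletes)
   it, headed by the structure's author residue numbers.

The plain-text twin encodes the same styles as marker lines: ``h`` /
``n`` / ``b`` under a row for hydrogen-bond / non-bonded / both classes,
and ``*`` (identical) or ``+`` (substituted) under the ruler.  Coil is
rendered ``-`` in text track lines.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field

from ._tables import CLUSTALX_CLASS, CLUSTALX_COLORS
from .alignment import MSA
from .contacts import HYDROGEN_BOND, NON_BONDED
from .mapping import IDENTICAL, ConservationReport

_CLASS_MARK = {frozenset(): "", frozenset({HYDROGEN_BOND}): "h",
               frozenset({NON_BONDED}): "n",
               frozenset({HYDROGEN_BOND, NON_BONDED}): "b"}


@dataclass
class AnnotatedAlignment:
    msa: MSA
    tracks: dict[str, str] = field(default_factory=dict)  # record id -> aligned codes
    report: ConservationReport = field(default_factory=ConservationReport)

    @classmethod
    def build(cls, msa: MSA, tracks: dict[str, str], report: ConservationReport):
        for rid, track in tracks.items():
            if len(track) != msa.length:
                raise ValueError(f"track for {rid!r} has wrong length")
        return cls(msa=msa, tracks=dict(tracks), report=report)

    def column_classes(self) -> dict[int, set[str]]:
        """Interaction classes mapped at each binding column."""
        out: dict[int, set[str]] = {}
        for site in self.report.sites:
            out.setdefault(site.column, set()).add(site.interaction_class)
        return out

    def column_status(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for site in self.report.sites:
            out.setdefault(site.column, site.status)
        return out


# ---------------------------------------------------------------------------
# Plain text

def render_text(annotated: AnnotatedAlignment, block_width: int = 60) -> str:
    msa = annotated.msa
    col_classes = annotated.column_classes()
    col_status = annotated.column_status()
    name_w = max((len(rid) for rid in msa.ids), default=0) + 2
    lines: list[str] = []
    lines.append("Section 1: annotated alignment")
    lines.append("")
    for start in range(0, msa.length, block_width):
        stop = min(start + block_width, msa.length)
        for rid, row in msa.records:
            if rid in annotated.tracks:
                track = annotated.tracks[rid][start:stop].replace(" ", "-")
                lines.append(f"{rid + ' 2D':<{name_w}}{track}")
            lines.append(f"{rid:<{name_w}}{row[start:stop]}")
            marks = "".join(
                _CLASS_MARK[frozenset(col_classes.get(c, set()))] or " "
                for c in range(start, stop)
            )
            if marks.strip():
                lines.append(f"{'':<{name_w}}{marks}")
        ruler = "".join(
            ("*" if col_status[c] == IDENTICAL else "+") if c in col_status else " "
            for c in range(start, stop)
        )
        if ruler.strip():
            lines.append(f"{'':<{name_w}}{ruler}")
        lines.append("")
    lines.append("Section 2: binding-site alignment")
    lines.append("")
    lines.extend(_text_section2(annotated, name_w))
    return "\n".join(lines) + "\n"


def _site_headers(annotated: AnnotatedAlignment) -> list[tuple[int, str]]:
    """(column, 'STRUCT resnum') header entries for binding columns."""
    headers: dict[int, str] = {}
    for site in annotated.report.sites:
        rec = site.source_record
        label = f"{site.source_structure.upper()} {rec.author_number}{rec.insertion_code}"
        headers.setdefault(site.column, label)
    return sorted(headers.items())


def _text_section2(annotated: AnnotatedAlignment, name_w: int) -> list[str]:
    cols = annotated.report.binding_columns()
    if not cols:
        return ["no binding sites mapped"]
    col_status = annotated.column_status()
    lines = []
    for col, label in _site_headers(annotated):
        status = col_status[col]
        mark = "*" if status == IDENTICAL else "+"
        lines.append(f"  column {col + 1:>5}  {label:<20} {mark} {status}")
    lines.append("")
    for rid, row in annotated.msa.records:
        lines.append(f"{rid:<{name_w}}{''.join(row[c] for c in cols)}")
    lines.append(
        f"{'':<{name_w}}"
        + "".join("*" if col_status[c] == IDENTICAL else "+" for c in cols)
    )
    if annotated.report.unmappable:
        lines.append("")
        lines.append("unmappable records (residue absent from coordinates):")
        for sid, rec in annotated.report.unmappable:
            lines.append(f"  {sid.upper()}  {rec.residue_label()}  {rec.interaction_class}")
    return lines


# ---------------------------------------------------------------------------
# HTML

_STYLESHEET = """
body { font-family: sans-serif; }
pre.aln { font-family: monospace; font-size: 13px; line-height: 1.35; }
.hb { font-weight: bold; }
.nb { text-decoration: underline; }
.ident { background-color: #e02020; color: white; }
.subst { background-color: #2040e0; color: white; }
""" + "\n".join(
    f".cx-{name} {{ background-color: {color}; }}"
    for name, color in CLUSTALX_COLORS.items()
) + "\n" + "\n".join(
    f".subst-g{i} {{ background-color: rgb({32 + 40 * i}, {64 + 30 * i}, 224); color: white; }}"
    for i in range(5)
)


def _residue_span(letter: str, classes: list[str]) -> str:
    if letter == "-" and not classes:
        return "-"
    cls = " ".join(classes) if classes else ""
    attr = f' class="{cls}"' if cls else ""
    return f"<span{attr}>{html.escape(letter)}</span>"


def render_html(
    annotated: AnnotatedAlignment, block_width: int = 60, graded: bool = False
) -> str:
    """Self-contained HTML report (inline stylesheet, deterministic bytes)."""
    msa = annotated.msa
    col_classes = annotated.column_classes()
    col_status = annotated.column_status()
    name_w = max((len(rid) for rid in msa.ids), default=0) + 2
    match_fraction = _match_fractions(annotated) if graded else {}

    parts: list[str] = []
    parts.append("<!DOCTYPE html>")
    parts.append("<html><head><meta charset=\"utf-8\"/>")
    parts.append("<title>binding-site annotation report</title>")
    parts.append(f"<style>{_STYLESHEET}</style></head><body>")
    parts.append("<h2>Section 1: annotated alignment</h2>")
    parts.append('<pre class="aln">')
    for start in range(0, msa.length, block_width):
        stop = min(start + block_width, msa.length)
        for rid, row in msa.records:
            if rid in annotated.tracks:
                track = html.escape(annotated.tracks[rid][start:stop])
                parts.append(f"{html.escape(rid + ' 2D'):<{name_w}}{track}")
            spans = []
            for c in range(start, stop):
                letter = row[c]
                classes = []
                if letter != "-":
                    classes.append(f"cx-{CLUSTALX_CLASS.get(letter.upper(), 'unconserved')}")
                marks = col_classes.get(c, set())
                if HYDROGEN_BOND in marks:
                    classes.append("hb")
                if NON_BONDED in marks:
                    classes.append("nb")
                spans.append(_residue_span(letter, classes if letter != "-" else []))
            parts.append(f"{html.escape(rid):<{name_w}}" + "".join(spans))
        parts.append("")
    parts.append("</pre>")
    parts.append("<h2>Section 2: binding-site alignment</h2>")
    cols = annotated.report.binding_columns()
    if not cols:
        parts.append("<p>no binding sites mapped</p>")
    else:
        headers = dict(_site_headers(annotated))
        parts.append('<table border="0" cellspacing="1"><tr><th></th>')
        for c in cols:
            parts.append(f'<th style="font-size:10px">{html.escape(headers[c])}</th>')
        parts.append("</tr>")
        for rid, row in msa.records:
            parts.append(f"<tr><td>{html.escape(rid)}</td>")
            for c in cols:
                letter = row[c]
                if col_status[c] == IDENTICAL:
                    cls = "ident"
                elif graded:
                    grade = min(4, int(match_fraction.get(c, 0.0) * 5))
                    cls = f"subst-g{grade}"
                else:
                    cls = "subst"
                parts.append(f'<td class="{cls}">{html.escape(letter)}</td>')
            parts.append("</tr>")
        parts.append("</table>")
    if annotated.report.unmappable:
        parts.append("<h3>Unmappable records</h3><ul>")
        for sid, rec in annotated.report.unmappable:
            parts.append(
                f"<li>{html.escape(sid.upper())} {html.escape(rec.residue_label())}"
                f" ({rec.interaction_class})</li>"
            )
        parts.append("</ul>")
    parts.append("</body></html>")
    return "\n".join(parts)


def _match_fractions(annotated: AnnotatedAlignment) -> dict[int, float]:
    """Per binding column: fraction of rows matching the structure residue."""
    out: dict[int, float] = {}
    for site in annotated.report.sites:
        letters = [letter for letter, _ in site.per_record.values()]
        source_letter = letters[0]
        for rid, (letter, _) in site.per_record.items():
            if rid.lower() == site.source_structure.lower():
                source_letter = letter
                break
        frac = sum(1 for x in letters if x == source_letter) / len(letters)
        out.setdefault(site.column, frac)
    return out


# ---------------------------------------------------------------------------
# Summary table

def summarize(
    report: ConservationReport, per_structure: bool = True
) -> str:
    """Tabulate site counts per interaction class, per structure and pooled."""
    lines = []
    header = f"{'scope':<16}{'class':<15}{'sites':>6}{'identical':>11}{'substituted':>13}{'unmappable':>12}"
    lines.append(header)
    lines.append("-" * len(header))

    def emit(scope: str, summary: dict[str, dict[str, int]]):
        shown = False
        for cls in (HYDROGEN_BOND, NON_BONDED):
            if cls not in summary:
                continue
            s = summary[cls]
            lines.append(
                f"{scope:<16}{cls:<15}{s['n_sites']:>6}{s['n_identical']:>11}"
                f"{s['n_substituted']:>13}{s['n_unmappable']:>12}"
            )
            shown = True
        if not shown:
            lines.append(f"{scope:<16}{'-':<15}{0:>6}{0:>11}{0:>13}{0:>12}")

    if per_structure:
        structures = sorted({s.source_structure for s in report.sites}
                            | {sid for sid, _ in report.unmappable})
        for sid in structures:
            sub = ConservationReport(
                sites=[s for s in report.sites if s.source_structure == sid],
                unmappable=[(x, r) for x, r in report.unmappable if x == sid],
            )
            emit(sid.upper(), sub.summary())
    emit("pooled", report.summary())
    return "\n".join(lines) + "\n"
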