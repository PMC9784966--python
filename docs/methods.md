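# Methods

This note documents the models, criteria and numerical choices behind
msaligmap, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Problem setting

Binding-site knowledge lives in solved 3D complexes; most protein
sequences have none. When a homolog with a solved complex exists, the
binding residues can be transferred by sequence alignment: locate each
binding residue's column in a multiple sequence alignment that contains
the structure's own (coordinate-derived) sequence, and read that column
in every other sequence. The product is a per-position conservation
call — *identical* (every sequence shows the same residue) or
*substituted* (any mismatch or deletion) — plus summary counts per
interaction class. Transfer is a homology inference: it degrades below
the twilight zone, so every sequence pair under 30 % identity triggers a
warning (a caveat, not an error — short or divergent inputs are still
processed).

## Structure model

PDB text is parsed with gemmi; the package layers its policy on top:

* **First model only.** NMR ensembles deposit many models; contact
  geometry needs a single coordinate set. No averaging is attempted.
* **Alternate locations** resolve to the highest-occupancy conformer,
  ties broken by file order (the standard convention).
* **Sequences come from ATOM records, not SEQRES.** Contacts require
  coordinates, so unresolved residues cannot carry annotations anyway;
  numbering gaps stay visible in the residue-number map, which is an
  explicit bijection between dense 0-based indices and author
  (number, insertion-code) pairs. MODRES records plus a small built-in
  table (MSE→M, SEP→S, …) map modified residues to canonical letters;
  anything else becomes `X`.
* **Entity classification** is by component code: a chain with any
  standard (or mapped-modified) amino acid is protein; all-nucleotide
  chains are DNA/RNA; all-water chains water; remaining all-HETATM
  chains ligand.

## Contact criteria

Interactions are classified by heavy-atom distance only:

| parameter       | default | meaning                                   |
|-----------------|---------|-------------------------------------------|
| `hbond_min`     | 2.70 Å  | lower bound of the hydrogen-bond window   |
| `hbond_max`     | 3.35 Å  | upper bound of the hydrogen-bond window   |
| `nonbonded_min` | 2.90 Å  | reporting floor; closer pairs are flagged as clashes, never dropped |
| `nonbonded_max` | 3.90 Å  | van-der-Waals contact cutoff              |

These are LigPlot's documented ranges. A pair is a hydrogen bond when
one atom is a donor and the other an acceptor (typed from a built-in
table for the 20 standard residues: backbone N donor except proline, O
acceptor, sidechain O/N per residue chemistry; partner atoms are typed
by element, with O/N treated as both donor and acceptor because ligand
protonation states are unknown — deliberately the permissive superset).
Any other pair within `nonbonded_max` is non-bonded. Per (residue,
class) only the minimum-distance atom pair is recorded; a residue may
appear in both classes and is then styled bold *and* underlined. Waters
never mediate; hydrogens are ignored. No angular criterion and no
explicit-hydrogen placement: distance-only is the reproducible core, and
deposited structures rarely include hydrogens. Neighbour search uses a
KD-tree; correctness is checked against a literal all-pairs scan.

Published residue lists (PDBsum/LigPlot/NucPlot exports, one
`COMP NUM[ICODE](CHAIN)` token per line) can be ingested in place of
geometry, so a published interaction set can drive the mapping exactly.

## Secondary structure

A supplied classic DSSP file is the primary source (per-chain summary
codes, chain-break `!` lines skipped, post-classic codes such as `P`
mapped to coil). Without one, a simplified Kabsch–Sander assignment
runs: amide hydrogens are rebuilt 1.0 Å from N along the preceding
C=O direction; a backbone H-bond exists when the electrostatic energy
`0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` is below −0.5 kcal/mol
(pairs closer than 2 in sequence are excluded — the peptide-unit
geometry otherwise fabricates bonds; a 9 Å CA–CA prefilter bounds the
scan). Two stacked n-turns yield G/H/I helices (n = 3/4/5), bridge
patterns yield B and ladders E, remaining turn spans T, CA-trace bends
above 70° S, assembled with priority H > E/B > G > I > T > S. This is
*not* a bit-exact DSSP clone: helix-termination and bulged-ladder corner
rules differ, π-helix preference toggles and the PPII class are absent.
Coil renders as blank in tracks, `-` in reports. Residues missing
backbone atoms are coded coil and logged.

## Alignment

The built-in aligner is the deterministic default: k-mer (k = 3)
distances, UPGMA guide tree with joins tie-broken by lexicographic
cluster key, then profile–profile Needleman–Wunsch with BLOSUM62,
affine gaps (open −10, extend −0.5; a run of L gap columns costs
open + (L−1)·extend; terminal gaps are penalised normally; gap
characters inside profile columns score 0). Pairwise optimality is
verified against exhaustive enumeration at short lengths. MAFFT and
Clustal Omega wrappers are provided for production-quality alignments;
their output is validated (every row must ungap to its input) and
reordered to input order. The default is the built-in aligner because it
is always present and byte-deterministic; external aligners are a flag
away (`--aligner mafft`).

Percent identity between two rows = 100 × matching columns (both
non-gap, case-insensitive) / columns where at least one row is non-gap.
The denominator choice is conservative (terminal overhangs count
against identity) and is stated here because no single convention is
universal.

## Projection and conservation

Column maps are built by a single scan per row and are bijections
between residue indices and non-gap columns (property-tested). A
binding record maps through author number → sequence index → column;
records naming residues absent from the coordinates (possible with
ingested lists) are reported in an explicit *unmappable* category so
records are conserved: mapped + unmappable = total. A column is
identical only when all rows agree and none is a gap — a deletion at a
binding position is functionally a substitution. Summaries count a
residue once per interaction class, and pooled counts across several
structures deduplicate by alignment column, since equivalent residues
of two structures occupy one column.

## Rendering

Section 1 is the blocked alignment (default 60 columns) with one
secondary-structure line above each structure row per block; residues
are coloured by the canonical ClustalX physicochemical classes
(embedded as a fixed class→colour table), hydrogen-bond columns bold,
non-bonded underlined. Section 2 is the binding-site sub-alignment in
alignment order with author-number headers, red = identical,
blue = substituted; `--graded` shades substituted cells by the fraction
of sequences matching the structure residue (five bins). The plain-text
twin uses marker lines (`h`/`n`/`b`, `*`/`+`). HTML output is a single
self-contained file; stripping its markup recovers the alignment rows
byte-for-byte, which the tests assert.

## Synthetic data

The generator builds peptides from standard bond lengths/angles and
preset torsions (helix −57/−47, extended −139/135; the two-strand sheet
places a rigid copy of an extended strand by the sheet's pseudo
two-fold symmetry at offsets chosen so cross-strand Kabsch–Sander bonds
form an antiparallel ladder). Partner atoms sit at exact offsets from
named protein atoms, so the expected contact set follows from the
criteria by construction; the generator derives it with its own literal
all-pairs scan over coordinates rounded to the 3 decimals the PDB text
carries, keeping the expectation consistent with what any parser reads
back. Homolog sets apply tracked point substitutions and short indels
from a seeded generator; forced substitutions at chosen indices give
exact conservation ground truth.

What the fixtures do **not** emulate: sidechains beyond CB, real ligand
chemistry and geometry, crystallographic noise, missing residues and
disorder, genuinely divergent homologs whose alignment is ambiguous.
Passing tests therefore demonstrate algorithmic correctness against the
stated criteria, not robustness of biological conclusions on difficult
real inputs — on real data the alignment quality remains the dominant
error source, which is exactly why the twilight-zone warning exists.

Verification problem sizes (200 random complexes of ≤ 50 atoms for the
contact oracle, 100 constructed cases for mapping closure, 20 pairs of
length ≤ 8 for alignment enumeration) were chosen so each check runs in
seconds while exercising every code path; the enumeration oracle is
exponential in sequence length, which caps the pair length.

## Degenerate inputs and tie-breaks

Zero detected contacts is a valid empty result, not an error. Malformed
structure tokens demote to plain target sequences with a warning.
Duplicate FASTA ids, unparseable coordinate fields and truncated DSSP
lines are hard errors naming the offending line. Equal-occupancy
altlocs keep the first conformer in file order; equal UPGMA joins merge
the lexicographically smallest pair; equal-distance atom pairs keep the
first encountered. All randomness is behind explicit seeds.

## Limitations

* Distance-only hydrogen bonds (no HBPLUS-style angles) over-call
  donors/acceptors in ambiguous geometry; counts can differ from
  LigPlot/NucPlot on real complexes. The list-ingestion path exists
  precisely to reproduce published interaction sets exactly.
* The built-in assignment approximates DSSP; for publication-grade
  tracks supply real DSSP files via `--dssp-dir`.
* mmCIF, assemblies/symmetry, multi-character chain ids, water-mediated
  bridges and backbone-vs-sidechain discrimination are out of scope.
* Conservation is binary per position; no entropy or
  substitution-matrix-weighted similarity grading beyond the `--graded`
  display option.
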