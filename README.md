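# msaligmap

Identify the amino-acid residues of a PDB structure that bind a ligand, a
peptide chain, or DNA, and transfer that binding-site annotation onto
homologous protein sequences that have no structure — for example novel
sequences from a genome project, or variants from different strains or
species. The tool aligns the structure-derived sequences with the user's
sequences, reads each binding position down through the alignment columns,
and reports which positions are **identical** in every sequence and which
are **substituted** (or deleted), alongside per-residue secondary-structure
tracks.

It is aimed at structural bioinformaticians and molecular biologists who
want to ask: *given a crystal/NMR complex of a homolog, which of my
sequences conserve the binding residues, and where should I expect
mutations to matter?* Annotation transfer of this kind is only trustworthy
when sequence identity is above the twilight zone (~30 %); the tool warns
on every pair below that threshold.

## Method

1. **Sequence extraction.** Chain sequences are read from the observed
   ATOM records (first model only; alternate locations resolved to the
   highest-occupancy conformer), preserving author numbering — gaps and
   insertion codes included — in a bijective residue-index ↔
   (number, icode) map.
2. **Contact detection.** For every protein/partner heavy-atom pair,
   an interaction is a *hydrogen bond* when the atoms are complementary
   donor/acceptor types at distance 2.70–3.35 Å, else *non-bonded* at
   ≤ 3.90 Å (LigPlot-style distance criteria; no angular term). Partner =
   a ligand component code, a peptide chain, or the union of DNA chains.
   Published residue lists (PDBsum/LigPlot/NucPlot exports) can be
   ingested instead of computing geometry.
3. **Alignment.** MAFFT or Clustal Omega if available, otherwise a
   deterministic built-in progressive aligner (k-mer distances, UPGMA
   guide tree, profile–profile Needleman–Wunsch, BLOSUM62, affine gaps
   −10/−0.5).
4. **Secondary structure.** Classic DSSP files are parsed when supplied;
   otherwise a built-in Kabsch–Sander-style assignment computes backbone
   H-bonds from the electrostatic energy
   `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`
   and derives H/G/I/E/B/T/S codes.
5. **Projection & classification.** Each binding residue is mapped to its
   alignment column; a column is *identical* only when every sequence
   shows the same residue letter (a gap counts as substituted). Counts
   are tallied per interaction class, per structure and pooled across
   structures (pooled sites deduplicated by column).

Reports are written as plain text, self-contained HTML (ClustalX residue
palette, bold = hydrogen bond, underline = non-bonded, red = identical,
blue = substituted) and a machine-readable TSV.

## Worked example

Everything runs offline from generated data. Build a toy complex — a
12-residue helix with three ligand atoms placed at exact distances — and
three homologs carrying one forced binding-site substitution:

```sh
msaligmap-fixtures --out demo --n-residues 12 --n-targets 3 --seed 5
```

then analyse it from inside `demo/` (the bundle's `pdb/` directory acts
as a local download cache):

```python
from msaligmap.cli import RunConfig, run
from msaligmap.report import summarize

report = run(RunConfig(
    mode="ligand", fasta_path="targets.fasta",
    structure_tokens=["1TST:A"], ligand_code="LIG",
    pdb_dir="pdb", offline=True, out_text="out.txt",
))
print(summarize(report))
```

which prints:

```
scope           class           sites  identical  substituted  unmappable
-------------------------------------------------------------------------
1TST:A          hydrogen_bond       3          2            1           0
1TST:A          non_bonded          9          8            1           0
pooled          hydrogen_bond       3          2            1           0
pooled          non_bonded          9          8            1           0
```

Three residues hydrogen-bond the ligand and nine make non-bonded
contacts; the forced substitution (T→G at author residue 6) is the one
substituted site in each class, visible in the text report's
binding-site sub-alignment:

```
1TST:A   DKSTRWYEN
target1  DKSGRWYEN
target2  DKSGRWYEN
target3  DKSGRWYEN
         ***+*****
```

`*` marks binding columns identical across all sequences, `+` the
substituted column. The equivalent CLI call is
`msaligmap ligand --fasta targets.fasta --structures 1TST:A --ligand LIG
--pdb-dir pdb --offline --out-text out.txt`.

With network access the same workflow runs on real complexes, e.g.
`msaligmap ligand --fasta por.fasta --structures 3WXB:A,3O26:A --ligand NDP`
for NADPH-binding-site transfer from two short-chain dehydrogenase
structures, or DNA mode with structure tokens such as `2LEX:A` in the
FASTA headers.

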