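# Methods

This note records the model implemented by `cbedesign`, every default
parameter, and the deliberate design decisions — enough to re-derive any
number the package prints.

## 1. Coordinates and orientation conventions

Internally all sequence arithmetic is 0-based half-open; every public
record and emitted table is 1-based inclusive (GenBank convention).

A protospacer is reported in its own 5'→3' orientation with position 1 at
the PAM-distal end; the PAM lies immediately 3' of position 20.
`Protospacer.genomic_start` is the plus-strand-numbered coordinate of
position 1, so minus-strand protospacers run toward decreasing
coordinates and position *p* maps to `genomic_start − p + 1` (plus strand:
`genomic_start + p − 1`).

Minus-strand CDS are reverse-complemented into coding orientation on
extraction; `cds_seq` always reads 5'→3' in the protein frame.  CDS whose
length is not divisible by 3, or whose translation carries an internal
STOP, are flagged `partial` and excluded from scanning.

## 2. Editing model

The cytidine base editor converts C·G→T·A.  A window cytidine on the
protospacer strand becomes T; viewed from the coding strand that is C→T
when the protospacer is the coding strand and G→A when it is the template
strand.

Defaults (`ScanParams`):

| parameter | default | notes |
| --- | --- | --- |
| PAM | `NGG` | IUPAC pattern; `NGA` works as an alternative |
| protospacer length | 20 | |
| editing window | positions 2–7 | presets: `ugi` = 2–9, `no-ugi` = 4–8 |
| preceding-G exclusion | on | a C directly 3' of a G is not edited |
| genome-wide uniqueness | on | exact 20-mer, either strand, PAM excluded |

The window presets reflect that blocking uracil excision (UGI) widens the
effective window; the narrow 2–7 window is the conservative choice used
for genome-wide statistics.

**Co-editing convention.**  When several window cytidines are eligible,
in vivo they are usually converted together.  The realized codon is
therefore computed with *all* eligible window Cs edited; where a single
edit alone already creates the STOP, that minimal plan is additionally
emitted as an `edit_plan="single"` alternative.  Genome-wide statistics
count co-edit candidates only (single-site plans target the same codons).

**STOP creation.**  Sense-strand C→T: CAA→TAA, CAG→TAG, CGA→TGA.
Template-strand editing (coding G→A): TGG→TAG/TGA (single G) or TAA (both
Gs).  The gene's natural terminal STOP is never a target.  Candidates are
labelled `gene^Q10*` (codon 10, Gln, to STOP).  Collateral changes in
neighbouring codons caused by co-editing are annotated (e.g. `A12V`).

**Recoding.**  `design_recode(gene, "D159N", …)` returns protospacers
whose realized edit produces exactly the requested substitution;
collateral synonymous changes are allowed and annotated, any collateral
amino-acid change disqualifies the candidate.

## 3. Uniqueness

A candidate survives only if its bare 20-mer occurs exactly once in the
genome counting both strands (`unique_include_pam=True` appends the PAM
to the query).  Counting uses a sorted numpy array of 2-bit-encoded
k-mers and binary search; a palindromic query is counted once.  This is
an exact-match filter — near-match off-target scoring is out of scope.

## 4. Efficiency categories

Editing efficiency depends on the base 5' of the target C (T ≫ C > A, and
essentially none behind G), decays with distance from the window centre
(position 6), and collapses for guanine-rich protospacers.  These
observations exist as plots, not tables, so the package assigns ordinal
categories only: preceding-base rank T(3)/C(2)/A(1)/G(0) maps to
`high`/`medium`/`medium`/`none`; the candidate's best site decides; a G
fraction > 0.45 caps the category at `low`.  Ranking is deterministic:
(codon index ascending, category descending, centre distance, genomic
coordinate) — earliest STOP first, efficiency breaking ties.

## 5. Reversion statistics

With per-base per-generation mutation frequency z (default 10⁻⁹), a STOP
codon reverts to sense when a substitution does not re-create a STOP.
TAA: any change of base 1, and 2 of 3 changes at bases 2 and 3 →
P₁ = (1 + ⅔ + ⅔)·z = (7/3)·z.  TAG and TGA: P₂ = (1 + 1 + ⅔)·z = (8/3)·z.
Weighting TAA and TAG/TGA equally gives a mean of 2.5·z, and n
independent STOPs in one ORF co-revert with (2.5·z)ⁿ — with two STOPs,
6.25·10⁻¹⁸ per generation, i.e. practically irreversible.

## 6. Golden Gate cassette model

Each gRNA repeat unit is `[4-nt junction overhang][spacer 20 nt][sgRNA
scaffold][Cas6 recognition site]`; a Cas6/Csy4 endoribonuclease site after
every guide releases the individual gRNAs from one transcript.  The
terminal Cas6 site is kept by default (it raises the last guide's
efficiency); disabling it ends the cassette in a 7-T poly-U terminator.

Oligos follow a fixed grammar.  Forward (spacer-specific):
`ATCGAGGTCTCC + [slot overhang] + spacer + scaffold handle (20 nt)`.
Reverse (position-specific, reusable): `ATCGAGGTCTCC + [reverse complement
of the downstream junction overhang] + TTAGCTGCCTATACGGCAGT`.

BsaI (`GGTCTC`, cuts 1 nt downstream top / 5 nt bottom) leaves 4-nt 5'
overhangs; overhangs are written as the top-strand 4-mer of the junction,
so two ends ligate exactly when their 4-mers are equal.  The shipped
13-overhang set (supporting up to 12 gRNAs) is pairwise distinct, free of
palindromes and of reverse-complement pairs; `check_overhang_fidelity`
enforces the same constraints on user-supplied sets.  `assemble_plan`
digests each simulated PCR product and walks the ligation graph from the
vector backbone; any ambiguity raises `FidelityError`, any open or
incomplete chain raises `AssemblyError`.

The vector backbone, its msfGFP dropout stub, and the default Cas6 site
(the reverse complement of the reverse primer's 3' block) are **synthetic
stand-ins** exposing the documented interface, not the sequence of a
specific plasmid; all are overridable.

## 7. Synthetic fixtures and oracle

`fixtures.synth_genome` builds a compact bacterial chromosome from a
seeded generator: by default 8 non-overlapping CDS of 60–140 codons on
random strands, 55% GC, separated by 15–60 bp intergenic stretches.  The
sizes are chosen so a full brute-force rescan stays under ~0.1 s; they
are this package's own testing choice.  Planted contexts with a recorded
truth table cover each design path: a sense-strand CAG (window position
5, preceded by T), a template-strand TGG with both Cs in the window, a
GAC→AAC recoding target, and a protospacer duplicated across two genes to
exercise the uniqueness filter.

`fixtures.brute_force_scan` re-derives the genome report by literal
enumeration — its own codon table, reverse complement, overlapping
substring counting, and edit-and-retranslate codon verification — sharing
no scanning logic with the fast path, and is the oracle for the
equivalence tests.  `mirror_genome` reverse-complements the genome and
its annotations for strand-symmetry tests.

## 8. Limitations

- Exact-match uniqueness only; no mismatch-tolerant off-target model.
- Ordinal efficiency only; measured editing rates, titers and growth
  phenotypes are wet-lab quantities outside the model.
- Bacterial genetic code (table 11), single-chromosome bacterial genomes;
  compound (join) CDS locations are supported but splicing-specific
  eukaryotic features are not.
- The assembly simulation models exact 4-nt overhang complementarity;
  it does not model ligase mismatch tolerance.
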