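# cbedesign

Design toolkit for CRISPR cytidine-base-editor (CBE) gene knockouts in
bacteria.  A CBE (deaminase–nCas9 fusion) converts C·G base pairs to T·A
within a short window of the protospacer, without cutting the chromosome.
Aimed at the right codon, that single chemistry inactivates a gene by
writing a premature STOP codon:

- on the coding strand, C→T turns CAA→TAA, CAG→TAG and CGA→TGA
  (Gln or Arg → STOP);
- on the template strand, C→T reads as G→A on the coding strand and turns
  TGG (Trp) into TAG, TGA or TAA.

`cbedesign` scans annotated genomes for such opportunities, ranks them by
empirical context rules, designs the matching multiplex gRNA cassettes
with a simulated Golden Gate assembly, and quantifies how stable the
introduced STOPs are against spontaneous reversion.

## What's in the box

| module | purpose |
| --- | --- |
| `cbedesign.genome_io` | GenBank/FASTA + GFF3 reading, strand-exact CDS extraction, writers |
| `cbedesign.target_scan` | protospacer enumeration, editing-window rules, STOP/recoding design, genome-wide scans, exact 20-mer uniqueness |
| `cbedesign.efficiency` | ordinal efficiency categories from sequence context |
| `cbedesign.cassette` | Golden Gate oligo design, BsaI digestion and ligation simulation |
| `cbedesign.reversion` | exact STOP-reversion probabilities |
| `cbedesign.fixtures` | deterministic synthetic genomes with planted, known-truth targets, plus a brute-force scanning oracle |
| `cbedesign.cli` | `cbedesign` command-line tool (`scan`, `cassette`, `stats`, `fixtures`) |

## Worked example

Everything below is real output.  Start from a synthetic genome with a
known truth table (no downloads needed):

```console
$ cbedesign fixtures --seed 1 --out-prefix demo
wrote demo.gb (2963 bp, 8 genes) and demo_truth.tsv
$ cat demo_truth.tsv
gene_id	kind	codon_index	label	expect_unique	protospacer
SYN_0001	stop_sense	10	SYN_0001^Q10*	True	TATTCAGATTGATGGTGCTA
SYN_0002	stop_antisense	12	SYN_0002^W12*	True	TAATCCAAGTAACATCACGA
SYN_0003	recode	15	SYN_0003^D15N	True	ATGTCAGTGAGTGGTTGCAG
SYN_0004	duplicate	9	SYN_0004^Q9*	False	TATTCAGATTGATAGTGCTA
SYN_0005	duplicate	9	SYN_0005^Q9*	False	TATTCAGATTGATAGTGCTA
```

**Genome-wide scan** (NGG PAM, window 2–7, preceding-G exclusion,
genome-wide 20-mer uniqueness — the defaults):

```console
$ cbedesign scan --genome demo.gb --out-prefix scan
ORFs: 8  targetable: 6 (75.0%)  untargetable: 2
```

The two untargetable ORFs are the deliberately duplicated pair: their only
planted protospacer occurs twice in the genome and is removed by the
uniqueness filter.

**Single-gene knockout design** recovers the planted Gln→STOP site,
`gene^Q10*` meaning "codon 10, Gln, converted to STOP":

```console
$ cbedesign scan --genome demo.gb --genes SYN_0001 --out-prefix g1
1 candidates -> g1_candidates.tsv
$ cut -f2,3,6,7,10,11,15 g1_candidates.tsv | tail -1
SYN_0001^Q10*	10	+	TATTCAGATTGATGGTGCTA	5	T	high
```

One candidate: the CAG's C sits at protospacer position 5 preceded by a T,
the best-editing context, hence category `high`.

**Recoding** (precise amino-acid changes rather than knockouts):

```console
$ cbedesign scan --genome demo.gb --genes SYN_0003 --recode D15N --out-prefix rec
2 candidates -> rec_candidates.tsv
$ cut -f2,3,7,8,12 rec_candidates.tsv | tail -2
SYN_0003^D15N	15	ATGTCAGTGAGTGGTTGCAG	AGG	co-edit
SYN_0003^D15N	15	TGTCAGTGAGTGGTTGCAGA	GGG	co-edit
```

**Multiplex cassette**: two spacers → Golden Gate oligo sheet, with the
assembly verified by simulated BsaI digestion/ligation:

```console
$ printf 'q10\tTATTCAGATTGATGGTGCTA\nw12\tTAATCCAAGTAACATCACGA\n' > spacers.txt
$ cbedesign cassette --spacers spacers.txt --out-prefix cas
2 gRNAs assembled in order q10,w12; oligo sheet -> cas_oligos.tsv
$ cat cas_oligos.tsv
name	sequence	role	position
q10_fwd	ATCGAGGTCTCCAATGTATTCAGATTGATGGTGCTAGTTTTAGAGCTAGAAATAGC	spacer_forward	1
pos1_rev	ATCGAGGTCTCCACCTTTAGCTGCCTATACGGCAGT	position_reverse	1
w12_fwd	ATCGAGGTCTCCAGGTTAATCCAAGTAACATCACGAGTTTTAGAGCTAGAAATAGC	spacer_forward	2
pos2_rev	ATCGAGGTCTCCAAGCTTAGCTGCCTATACGGCAGT	position_reverse	2
```

Each slot needs one spacer-specific forward oligo; the reverse primers
depend only on cassette position and are reusable across designs.

**Reversion statistics** — with per-base mutation frequency z = 10⁻⁹ a TAA
STOP reverts with (7/3)·z, TAG/TGA with (8/3)·z, the composition-weighted
mean is 2.5·z, and two STOPs in one ORF revert together with (2.5·z)²:

```console
$ cbedesign stats --reversion --stops 2
            quantity        value
            P1 (TAA) 2.333333e-09
        P2 (TAG/TGA) 2.666667e-09
    mean single STOP 2.500000e-09
2 STOP(s) in one ORF 6.250000e-18
```

## Testing and reproducing results

```bash
python -m pytest -q tests/            # unit + property tests, all offline
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script computes the package's headline quantities at
runtime (reversion probabilities, synthetic-genome scan statistics,
fast-scan vs brute-force-oracle agreement over 20 seeded fixtures, Golden
Gate round trips for 1–12 gRNAs, the position-primer template) and writes
them as JSON.

Three acceptance tests additionally validate genome-wide targetability
statistics and worked-example recovery against published *Pseudomonas*
genomes.  Those genomes are not shipped; the tests fail with instructions
until you place the GenBank files as described in
`tests/data/real/README.md`.

## Scope and limitations

- Uniqueness is exact-match only (20-mer on either strand); near-match
  off-target scoring is out of scope.
- Efficiency scores are ordinal categories (`high`/`medium`/`low`/`none`)
  derived from sequence-context rules, not calibrated probabilities —
  measured editing rates, product titers and growth phenotypes cannot be
  computed from sequence.
- The Golden Gate vector model and its Cas6/Csy4 recognition site are
  synthetic stand-ins with the documented interface, not the sequence of
  any specific plasmid.  Override them via the `cassette` module if you
  have the real sequences.

See `docs/methods.md` for the underlying model and every default
parameter.
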