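"""Deterministic synthetic genomes with known ground truth, plus a
brute-force scanning oracle.

The generator emulates a compact bacterial chromosome: non-overlapping CDS
on both strands separated by short intergenic stretches, with controllable
GC content.  Specific editable contexts are planted at known codons —
a sense-strand CAG (Q→STOP), a template-strand TGG (W→STOP via G→A), a
GAC recoding target (D→N), and duplicated protospacers for uniqueness
tests — so every scanning operation can be checked against a truth table
without any external data.  ``brute_force_scan`` re-derives the genome
report by naive enumeration, sharing no scanning logic with the fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from cbedesign.genome_io import (
    GeneRecord,
    Genome,
    extract_cds,
    write_genbank,
)
from cbedesign.target_scan import GenomeScanReport, GeneScanResult, ScanParams, IUPAC


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class Plant:
    """One planted feature: a known editable context at a known codon."""

    kind: str  # stop_sense | stop_antisense | recode | duplicate
    gene_index: int
    codon_index: int


@dataclass
class FixtureSpec:
    n_genes: int = 8
    gene_length_codons: tuple[int, int] = (60, 140)
    gc_content: float = 0.55
    intergenic_range: tuple[int, int] = (15, 60)
    seed: int = 0
    contig_id: str = "synthctg1"
    planted: list[Plant] = field(
        default_factory=lambda: [
            Plant("stop_sense", 0, 10),
            Plant("stop_antisense", 1, 12),
            Plant("recode", 2, 15),
            Plant("duplicate", 3, 9),
            Plant("duplicate", 4, 9),
        ]
    )


@dataclass(frozen=True)
class TruthRow:
    gene_id: str
    kind: str
    codon_index: int
    label: str
    expect_unique: bool
    protospacer: str  # coding-orientation 20-mer of the planted target


# ---------------------------------------------------------------------------
# construction helpers (coding-strand codon surgery)

_STOPS = {"TAA", "TAG", "TGA"}

# planted sense-strand context: protospacer TATTCAGATTGATGGTGCTA + PAM CGG,
# CAG codon-aligned with its C at window position 5
_SENSE_PLANT = "TATT" + "CAG" + "ATTGATGGTGCTA" + "CGG"
# same grammar, distinct 20-mer, used for the deliberately-duplicated pair
_DUP_PLANT = "TATT" + "CAG" + "ATTGATAGTGCTA" + "CGG"


_BASES = np.array(list("ATGC"))


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _rand_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _rand_seq(rng, 3, gc)
        if codon not in _STOPS:
            return codon


def _set_codon(codons: list[str], index_1based: int, value: str) -> None:
    codons[index_1based - 1] = value


def _plant_sense_stop(codons: list[str], k: int, plant: str = _SENSE_PLANT) -> None:
    """Overwrite so the CDS carries the plant string with CAG at codon k."""
    if k < 4 or k + 7 > len(codons):
        raise GenerationError(f"codon {k} out of plantable range for sense STOP")
    flat = list("".join(codons))
    start = 3 * (k - 1) - 4  # plant begins at the 3rd base of codon k-2
    flat[start : start + len(plant)] = plant
    new = ["".join(flat[i : i + 3]) for i in range(0, len(flat), 3)]
    codons[:] = new
    if any(c in _STOPS for c in codons[:-1]):
        raise GenerationError("sense STOP plant created an internal STOP")


def _plant_antisense_stop(codons: list[str], k: int) -> None:
    """TGG at codon k with a minus-strand protospacer: both template Cs in
    window (positions 5 and 6), PAM provided by codons k-6/k-5."""
    if k < 8 or k + 2 > len(codons):
        raise GenerationError(f"codon {k} out of plantable range for antisense STOP")
    _set_codon(codons, k - 6, "GCC")  # Ala: supplies plus C at CDS pos 3k-18
    _set_codon(codons, k - 5, "CAT")  # His: supplies plus C at 3k-17 (minus PAM GG)
    _set_codon(codons, k - 1, "ACT")  # Thr: keeps window positions 8-9 C-free
    _set_codon(codons, k, "TGG")
    _set_codon(codons, k + 1, "ATT")  # Ile: no extra minus-window C, non-G before target


def _plant_recode(codons: list[str], k: int) -> None:
    """GAC (Asp) at codon k, editable to AAC (Asn) via the template strand."""
    if k < 8 or k + 2 > len(codons):
        raise GenerationError(f"codon {k} out of plantable range for recode")
    _set_codon(codons, k - 6, "CCT")  # Pro: plus Cs at 3k-20/3k-19 (minus PAM GG)
    _set_codon(codons, k - 1, "ACT")
    _set_codon(codons, k, "GAC")
    _set_codon(codons, k + 1, "ATT")


def _build_gene(rng: np.random.Generator, spec: FixtureSpec, plants: list[Plant]) -> tuple[str, list[TruthRow]]:
    lo, hi = spec.gene_length_codons
    need = max((p.codon_index + 8 for p in plants), default=0)
    n_codons = int(rng.integers(max(lo, need), max(hi, need + 1) + 1))
    codons = ["ATG"] + [_rand_codon(rng, spec.gc_content) for _ in range(n_codons - 2)] + ["TAA"]
    truths = []
    for p in plants:
        if p.kind == "stop_sense":
            _plant_sense_stop(codons, p.codon_index)
            truths.append((p, "Q", "*"))
        elif p.kind == "duplicate":
            _plant_sense_stop(codons, p.codon_index, _DUP_PLANT)
            truths.append((p, "Q", "*"))
        elif p.kind == "stop_antisense":
            _plant_antisense_stop(codons, p.codon_index)
            truths.append((p, "W", "*"))
        elif p.kind == "recode":
            _plant_recode(codons, p.codon_index)
            truths.append((p, "D", "N"))
        else:
            raise GenerationError(f"unknown plant kind {p.kind!r}")
    cds = "".join(codons)
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in _STOPS:
            raise GenerationError("internal STOP after planting; adjust the spec")
    return cds, truths


def synth_genome(spec: FixtureSpec) -> tuple[Genome, list[GeneRecord], list[TruthRow]]:
    """Generate a synthetic annotated genome plus its truth table.

    Same spec + seed produce identical output.  Genes alternate strands
    deterministically from the seeded generator; planted features live at
    the codons named in the spec regardless of genomic strand.
    """
    if any(p.gene_index >= spec.n_genes for p in spec.planted):
        raise GenerationError("planted gene_index beyond n_genes")
    rng = np.random.default_rng(spec.seed)
    pieces: list[str] = []
    genes: list[GeneRecord] = []
    truth: list[TruthRow] = []
    pos = 0
    for gi in range(spec.n_genes):
        gap = int(rng.integers(*spec.intergenic_range))
        pieces.append(_rand_seq(rng, gap, spec.gc_content))
        pos += gap
        plants = [p for p in spec.planted if p.gene_index == gi]
        cds, truths = _build_gene(rng, spec, plants)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SYN_{gi + 1:04d}"
        genomic = cds if strand == "+" else _naive_rc(cds)
        start = pos + 1
        end = pos + len(cds)
        pieces.append(genomic)
        pos = end
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=spec.contig_id,
                start=start,
                end=end,
                strand=strand,
                cds_seq=cds,
                product=f"synthetic protein {gi + 1}",
            )
        )
        for p, orig_aa, new_sym in truths:
            expect_unique = p.kind != "duplicate"
            label = f"{gene_id}^{orig_aa}{p.codon_index}{new_sym}"
            proto = _planted_protospacer(cds, p)
            truth.append(
                TruthRow(gene_id, p.kind, p.codon_index, label, expect_unique, proto)
            )
    pieces.append(_rand_seq(rng, int(rng.integers(*spec.intergenic_range)), spec.gc_content))
    contig = "".join(pieces)
    genome = Genome(contigs=[(spec.contig_id, contig)], source=f"synthetic(seed={spec.seed})")
    _attach_annotations(genome, genes)
    return genome, genes, truth


def _planted_protospacer(cds: str, p: Plant) -> str:
    k = p.codon_index
    if p.kind in ("stop_sense", "duplicate"):
        start = 3 * (k - 1) - 4
        return cds[start : start + 20]  # both plants share this layout
    if p.kind == "stop_antisense":
        # minus-strand protospacer 5' end at CDS position 3k+4 (1-based)
        return _naive_rc(cds[3 * k + 4 - 20 : 3 * k + 4])
    if p.kind == "recode":
        return _naive_rc(cds[3 * k + 2 - 20 : 3 * k + 2])
    raise GenerationError(p.kind)


def _attach_annotations(genome: Genome, genes: list[GeneRecord]) -> None:
    """Attach SeqRecords with CDS features so extract_cds() works."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    records = []
    for cid, seq in genome.contigs:
        rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description="synthetic fixture")
        rec.annotations["molecule_type"] = "DNA"
        for g in genes:
            if g.contig_id != cid:
                continue
            strand = -1 if g.strand == "-" else 1
            feat = SeqFeature(
                FeatureLocation(g.start - 1, g.end, strand=strand),
                type="CDS",
                qualifiers={"locus_tag": [g.gene_id], "product": [g.product]},
            )
            rec.features.append(feat)
        records.append(rec)
    genome._records = records  # type: ignore[attr-defined]


def write_fixture(genome: Genome, genes: list[GeneRecord], truth: list[TruthRow], gb_path, truth_path) -> None:
    """Write fixture GenBank + truth-table TSV."""
    import pandas as pd

    write_genbank(genome, genes, gb_path)
    pd.DataFrame([t.__dict__ for t in truth]).to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# calibration protospacers (alternating-C layout)


def calibration_protospacers(preceding_base: str) -> list[str]:
    """Seven 20-mers with cytidines alternating against a fixed base.

    Spacer j carries Cs at positions 2+j, 4+j, ... so that across the set
    the cytidines span protospacer positions 2-9; every non-C position is
    the requested preceding base.
    """
    preceding_base = preceding_base.upper()
    if preceding_base not in "ACGT":
        raise ValueError("preceding_base must be one of A, C, G, T")
    spacers = []
    for j in range(7):
        first = 2 + j
        cs = set(range(first, 21, 2))
        spacers.append(
            "".join("C" if p in cs else preceding_base for p in range(1, 21))
        )
    return spacers


# ---------------------------------------------------------------------------
# brute-force oracle

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_ORACLE_CODON_TABLE = {}
_bases = "TCAG"
_aa = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_aa):
    _ORACLE_CODON_TABLE[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a


def _naive_rc(seq: str) -> str:
    return "".join(_RC.get(b, "N") for b in reversed(seq))


def _naive_translate(cds: str) -> str:
    return "".join(
        _ORACLE_CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


def _pam_ok(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(seq, pattern)
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def brute_force_scan(
    genome: Genome,
    params: ScanParams,
    genes: Optional[list[GeneRecord]] = None,
) -> GenomeScanReport:
    """Naive re-derivation of the genome scan for oracle comparisons.

    Every position on both strands is tested literally; realized codons are
    obtained by editing a copy of the contig and re-translating the gene.
    Counts co-edited (all eligible window C) candidates, matching the
    genome-report convention.  The per-candidate key set is exposed as a
    ``candidate_keys`` attribute on the returned report.
    """
    if len(genome) > 100_000:
        raise GenerationError("brute-force oracle restricted to genomes <= 100 kb")
    if genes is None:
        genes = extract_cds(genome)
    genes = [g for g in genes if not g.partial]
    plen = params.protospacer_len
    wlo, whi = params.window

    # enumerate protospacers naively, with plus-strand edit lists
    protos = []  # (contig_id, strand, start_coord_1based, spacer, edits=[(coord, base)])
    for cid, seq in genome.contigs:
        L = len(seq)
        for strand, s in ((("+"), seq), (("-"), _naive_rc(seq))):
            for i in range(0, L - plen - len(params.pam) + 1):
                spacer = s[i : i + plen]
                pam = s[i + plen : i + plen + len(params.pam)]
                if any(b not in "ACGT" for b in spacer) or not _pam_ok(pam, params.pam):
                    continue
                upstream = s[i - 1] if i > 0 else None
                edits = []
                for p in range(wlo, whi + 1):
                    if spacer[p - 1] != "C":
                        continue
                    prev = spacer[p - 2] if p > 1 else upstream
                    if params.forbid_preceding_g and prev == "G":
                        continue
                    if strand == "+":
                        coord = i + p  # 1-based plus coordinate
                        edits.append((coord, "T"))
                    else:
                        coord = L - i - p + 1
                        edits.append((coord, "A"))
                if not edits:
                    continue
                start_coord = i + 1 if strand == "+" else L - i
                protos.append((cid, strand, start_coord, spacer, edits))

    per_gene: dict[str, GeneScanResult] = {}
    histogram = [0] * 10
    n_targetable = 0
    candidate_keys = set()
    seq_by_id = dict(genome.contigs)

    for gene in genes:
        contig = seq_by_id[gene.contig_id]
        n_codons = len(gene.cds_seq) // 3
        found = []  # (codon_index, strand, start_coord, spacer)
        for cid, strand, start_coord, spacer, edits in protos:
            if cid != gene.contig_id:
                continue
            span_lo = min(start_coord, start_coord + (plen - 1) * (1 if strand == "+" else -1))
            span_hi = max(start_coord, start_coord + (plen - 1) * (1 if strand == "+" else -1))
            if span_hi < gene.start or span_lo > gene.end:
                continue
            mutable = list(contig)
            for coord, base in edits:
                mutable[coord - 1] = base
            edited_contig = "".join(mutable)
            raw = "".join(edited_contig[s - 1 : e] for s, e in gene.parts)
            cds = raw if gene.strand == "+" else _naive_rc(raw)
            aa_old = _naive_translate(gene.cds_seq)
            aa_new = _naive_translate(cds)
            for ci in range(n_codons - 1):  # exclude terminal STOP
                if aa_old[ci] != "*" and aa_new[ci] == "*":
                    found.append((ci + 1, strand, start_coord, spacer))
        if params.max_orf_fraction < 1.0:
            found = [f for f in found if f[0] / n_codons <= params.max_orf_fraction]
        if params.require_unique:
            kept = []
            for ci, strand, start_coord, spacer in found:
                total = 0
                for cid2, seq2 in genome.contigs:
                    total += _count_occurrences(seq2, spacer)
                    rc = _naive_rc(spacer)
                    if rc != spacer:
                        total += _count_occurrences(seq2, rc)
                if total == 1:
                    kept.append((ci, strand, start_coord, spacer))
            found = kept
        if found:
            n_targetable += 1
            best_ci = min(f[0] for f in found)
            histogram[min(int(best_ci / n_codons * 10), 9)] += 1
            per_gene[gene.gene_id] = GeneScanResult(
                gene.gene_id, True, None, len(found),
                all(f[1] != gene.strand for f in found),
            )
            per_gene[gene.gene_id].best_codon_index = best_ci  # type: ignore[attr-defined]
            for ci, strand, start_coord, _ in found:
                candidate_keys.add((gene.gene_id, ci, strand, start_coord))
        else:
            per_gene[gene.gene_id] = GeneScanResult(gene.gene_id, False, None, 0)

    n_orfs = len(genes)
    report = GenomeScanReport(
        n_orfs=n_orfs,
        n_targetable=n_targetable,
        n_untargetable=n_orfs - n_targetable,
        percent_targetable=100.0 * n_targetable / n_orfs if n_orfs else 0.0,
        histogram=histogram,
        per_gene=per_gene,
        params=params,
        n_antisense_only=sum(1 for r in per_gene.values() if r.antisense_only),
    )
    report.candidate_keys = candidate_keys  # type: ignore[attr-defined]
    return report


def mirror_genome(genome: Genome, genes: list[GeneRecord]) -> tuple[Genome, list[GeneRecord]]:
    """Reverse-complement every contig and mirror the annotations.

    Used by strand-symmetry tests: scanning the mirrored genome must yield a
    coordinate-mirrored candidate set.
    """
    contigs = [(cid, _naive_rc(seq)) for cid, seq in genome.contigs]
    lengths = {cid: len(seq) for cid, seq in genome.contigs}
    mirrored = Genome(contigs=contigs, source=genome.source + "|mirrored")
    new_genes = []
    for g in genes:
        L = lengths[g.contig_id]
        parts = sorted((L - e + 1, L - s + 1) for s, e in g.parts)
        new_genes.append(
            GeneRecord(
                gene_id=g.gene_id,
                contig_id=g.contig_id,
                start=L - g.end + 1,
                end=L - g.start + 1,
                strand="-" if g.strand == "+" else "+",
                cds_seq=g.cds_seq,
                product=g.product,
                gene_name=g.gene_name,
                partial=g.partial,
                parts=parts,
            )
        )
    _attach_annotations(mirrored, new_genes)
    return mirrored, new_genes
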