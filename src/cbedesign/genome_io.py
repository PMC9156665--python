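"""Genome and annotation I/O with exact strand/frame semantics.

Coordinates are 0-based half-open internally and 1-based inclusive on every
public record and emitted table (GenBank convention).  Minus-strand CDS are
reverse-complemented into coding orientation on extraction, so ``cds_seq``
always reads 5'→3' in the frame of the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BACTERIAL_TABLE = 11

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds_seq: str) -> str:
    """Translate a CDS with the bacterial code, keeping STOPs as '*'."""
    return str(Seq(cds_seq).translate(table=BACTERIAL_TABLE))


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed or violates invariants."""


@dataclass
class Genome:
    """A set of contigs (id, uppercase DNA over {A,C,G,T,N})."""

    contigs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        clean: list[tuple[str, str]] = []
        for cid, seq in self.contigs:
            if cid in seen:
                raise GenomeFormatError(f"duplicate contig id: {cid}")
            seen.add(cid)
            seq = seq.upper()
            # degenerate IUPAC bases are collapsed to N: they never match a
            # PAM or protospacer position downstream
            seq = "".join(b if b in "ACGTN" else "N" for b in seq)
            clean.append((cid, seq))
        self.contigs = clean

    def __len__(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(f"unknown contig: {contig_id}")


@dataclass
class GeneRecord:
    """One CDS in coding orientation.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the full
    feature span; ``parts`` lists (start, end) pairs in genomic order for
    compound (join) locations, a single pair for the common contiguous case.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cds_seq: str
    product: str = ""
    gene_name: str = ""
    partial: bool = False
    parts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parts:
            self.parts = [(self.start, self.end)]

    @property
    def display_name(self) -> str:
        return self.gene_name or self.gene_id

    @property
    def protein_length(self) -> int:
        """Number of codons including the terminal STOP."""
        return len(self.cds_seq) // 3

    def translation(self) -> str:
        return translate_cds(self.cds_seq)

    def genomic_to_cds(self, coord: int) -> Optional[int]:
        """Map a 1-based genomic coordinate to a 0-based CDS offset.

        Returns None when the coordinate falls outside every part (e.g. in
        the gap of a join), in which case an edit there cannot change the
        protein.
        """
        offset = 0
        plus_offset = None
        for s, e in self.parts:
            if s <= coord <= e:
                plus_offset = offset + (coord - s)
                break
            offset += e - s + 1
        if plus_offset is None:
            return None
        if self.strand == "+":
            return plus_offset
        return len(self.cds_seq) - 1 - plus_offset


def read_genome(path_or_handle, format: str = "genbank") -> Genome:
    """Read a genome from GenBank or FASTA.

    GenBank CDS annotations are kept on the returned object (``Genome``
    gains a private ``_records`` attribute used by :func:`extract_cds`).
    """
    if format not in {"genbank", "fasta"}:
        raise ValueError(f"unsupported format: {format}")
    try:
        records = list(SeqIO.parse(path_or_handle, format))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise GenomeFormatError(f"cannot parse {path_or_handle!r} as {format}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"no sequence records found in {path_or_handle!r}")
    source = str(path_or_handle) if isinstance(path_or_handle, (str, Path)) else "<handle>"
    genome = Genome(
        contigs=[(rec.id, str(rec.seq)) for rec in records],
        source=source,
    )
    genome._records = records  # type: ignore[attr-defined]
    return genome


def _feature_gene_id(feature: SeqFeature, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"CDS_{index:05d}"


def extract_cds(genome: Genome, annotations: Optional[Iterable] = None) -> list[GeneRecord]:
    """Extract one GeneRecord per CDS feature.

    ``annotations`` may be an iterable of (contig_id, SeqFeature) pairs; by
    default the features carried by a GenBank-read genome are used.  CDS
    whose length is not divisible by three, or whose translation carries an
    internal STOP, are flagged ``partial`` (they are kept in the returned
    list but excluded from scanning downstream).
    """
    pairs: list[tuple[str, SeqFeature]] = []
    if annotations is None:
        records = getattr(genome, "_records", None)
        if records is None:
            raise ValueError("genome carries no annotations; pass them explicitly")
        for rec in records:
            for feat in rec.features:
                if feat.type == "CDS":
                    pairs.append((rec.id, feat))
    else:
        pairs = list(annotations)

    seq_by_id = dict(genome.contigs)
    genes: list[GeneRecord] = []
    for i, (contig_id, feat) in enumerate(pairs):
        if contig_id not in seq_by_id:
            raise GenomeFormatError(f"annotation references unknown contig {contig_id}")
        contig_seq = seq_by_id[contig_id]
        loc = feat.location
        strand = "-" if loc.strand == -1 else "+"
        parts = [(int(p.start) + 1, int(p.end)) for p in loc.parts]
        parts.sort()
        start, end = parts[0][0], parts[-1][1]
        if start < 1 or end > len(contig_seq):
            raise GenomeFormatError(
                f"CDS {_feature_gene_id(feat, i)} coordinates outside contig {contig_id}"
            )
        cds = "".join(contig_seq[s - 1 : e] for s, e in parts)
        if strand == "-":
            cds = revcomp(cds)
        gene = GeneRecord(
            gene_id=_feature_gene_id(feat, i),
            contig_id=contig_id,
            start=start,
            end=end,
            strand=strand,
            cds_seq=cds,
            product=feat.qualifiers.get("product", [""])[0],
            gene_name=feat.qualifiers.get("gene", [""])[0],
            parts=parts,
        )
        if len(cds) % 3 != 0:
            gene.partial = True
            logger.warning("CDS %s length %d not divisible by 3; flagged partial", gene.gene_id, len(cds))
        else:
            aa = gene.translation()
            if "*" in aa[:-1]:
                gene.partial = True
                logger.warning("CDS %s has internal STOP; flagged partial", gene.gene_id)
        genes.append(gene)
    return genes


def read_gff3_cds(gff_path) -> list[tuple[str, SeqFeature]]:
    """Minimal GFF3 CDS reader for FASTA genomes (optional input path).

    Groups CDS lines by their ID/Parent attribute so compound CDS become a
    single joined feature, mirroring GenBank behaviour.
    """
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            contig, _, _, start, end, _, strand, _, attrs = cols[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            key = attr.get("ID") or attr.get("Parent") or f"{contig}:{start}-{end}"
            g = groups.setdefault(
                key,
                {"contig": contig, "strand": strand, "parts": [], "attrs": attr},
            )
            g["parts"].append((int(start), int(end)))
            if key not in order:
                order.append(key)

    pairs: list[tuple[str, SeqFeature]] = []
    for key in order:
        g = groups[key]
        strand = -1 if g["strand"] == "-" else 1
        locs = [FeatureLocation(s - 1, e, strand=strand) for s, e in sorted(g["parts"])]
        location = locs[0] if len(locs) == 1 else sum(locs[1:], locs[0])
        qualifiers = {}
        attrs = g["attrs"]
        name = attrs.get("locus_tag") or attrs.get("Name") or attrs.get("ID") or key
        qualifiers["locus_tag"] = [name]
        if "product" in attrs:
            qualifiers["product"] = [attrs["product"]]
        if "gene" in attrs:
            qualifiers["gene"] = [attrs["gene"]]
        feat = SeqFeature(location, type="CDS", qualifiers=qualifiers)
        pairs.append((g["contig"], feat))
    return pairs


def write_genbank(genome: Genome, genes: list[GeneRecord], path) -> None:
    """Write a Genome plus its GeneRecords back to a GenBank flat file."""
    records = []
    for cid, seq in genome.contigs:
        rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        for g in genes:
            if g.contig_id != cid:
                continue
            strand = -1 if g.strand == "-" else 1
            locs = [FeatureLocation(s - 1, e, strand=strand) for s, e in g.parts]
            location = locs[0] if len(locs) == 1 else sum(locs[1:], locs[0])
            qualifiers = {"locus_tag": [g.gene_id]}
            if g.product:
                qualifiers["product"] = [g.product]
            if g.gene_name:
                qualifiers["gene"] = [g.gene_name]
            rec.features.append(SeqFeature(location, type="CDS", qualifiers=qualifiers))
        records.append(rec)
    SeqIO.write(records, path, "genbank")


def write_gene_table(genes: list[GeneRecord], path) -> None:
    """TSV of gene records (gene_id, contig, start, end, strand, length, product)."""
    import pandas as pd

    rows = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "length": len(g.cds_seq),
            "partial": g.partial,
            "product": g.product,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
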