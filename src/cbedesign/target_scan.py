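"""Protospacer enumeration and STOP-codon / recoding edit-candidate design.

The deaminase of a cytidine base editor acts on cytidines lying in a short
window of the protospacer, counted 1-based from the PAM-distal 5' end.  A
C→T change on the protospacer strand creates a premature STOP when it hits
CAA/CAG/CGA on the coding strand (Q, Q, R) or — as a G→A change seen from
the coding strand — converts TGG (W) into TAG, TGA or TAA.  Cytidines
immediately preceded by a G are sterically shielded and are discarded; all
remaining window cytidines are treated as co-edited when computing the
realized codon (multi-C conversion is the common outcome in vivo), with
single-site realizations additionally emitted as minimal-edit alternatives.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from cbedesign.genome_io import GeneRecord, Genome, revcomp, translate_cds

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

WINDOW_PRESETS = {
    "default": (2, 7),  # six bases from position two: the genome-scan window
    "ugi": (2, 9),      # widened window with the uracil-glycosylase inhibitor
    "no-ugi": (4, 8),   # narrow window without UGI
}


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the protospacer / editing-window scan.

    window positions are 1-based within the protospacer, counted from the
    PAM-distal 5' end; the PAM sits immediately 3' of position
    ``protospacer_len``.
    """

    pam: str = "NGG"
    protospacer_len: int = 20
    window: tuple[int, int] = (2, 7)
    forbid_preceding_g: bool = True
    require_unique: bool = True
    max_orf_fraction: float = 1.0
    unique_include_pam: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_len):
            raise ScanError(f"invalid window {self.window} for protospacer length {self.protospacer_len}")
        if any(b not in IUPAC for b in self.pam):
            raise ScanError(f"PAM {self.pam!r} is not an IUPAC pattern")

    @classmethod
    def with_preset(cls, preset: str, **overrides) -> "ScanParams":
        if preset not in WINDOW_PRESETS:
            raise ScanError(f"unknown window preset {preset!r}; choose from {sorted(WINDOW_PRESETS)}")
        overrides.setdefault("window", WINDOW_PRESETS[preset])
        return cls(**overrides)


@dataclass(frozen=True)
class Protospacer:
    """A candidate 20-nt target in its own 5'→3' orientation.

    ``genomic_start`` is the 1-based plus-strand-numbered coordinate of the
    protospacer's 5' end (position 1); for minus-strand protospacers the
    sequence therefore runs toward decreasing coordinates.
    ``upstream_base`` is the genomic base 5' of position 1 on the
    protospacer strand (None at a contig edge).
    """

    contig_id: str
    genomic_start: int
    strand: str
    seq: str
    pam_seq: str
    upstream_base: Optional[str] = None

    def position_to_genomic(self, position: int) -> int:
        """Plus-strand 1-based coordinate of protospacer ``position``."""
        if self.strand == "+":
            return self.genomic_start + position - 1
        return self.genomic_start - position + 1

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive plus-strand coordinate range covered by the protospacer."""
        a = self.position_to_genomic(1)
        b = self.position_to_genomic(len(self.seq))
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EditSite:
    """One editable cytidine within the window of a protospacer."""

    protospacer: Protospacer
    position: int
    preceding_base: Optional[str]
    genomic_coordinate: int  # plus-strand 1-based coordinate of the C


@dataclass
class StopCandidate:
    """A concrete plan to knock a gene out with a premature STOP codon."""

    gene_id: str
    codon_index: int  # 1-based amino-acid numbering
    original_aa: str
    original_codon: str
    edited_codon: str
    edit_sites: list[EditSite]
    protospacer: Protospacer
    orf_fraction: float
    label: str
    collateral: list[str] = field(default_factory=list)  # e.g. ["A12V", "L13L"]
    edit_plan: str = "co-edit"  # or "single"
    unique: Optional[bool] = None
    efficiency: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (
            self.gene_id,
            self.codon_index,
            self.protospacer.strand,
            self.protospacer.genomic_start,
            self.edit_plan,
            tuple(s.position for s in self.edit_sites),
        )


@dataclass
class RecodeCandidate(StopCandidate):
    """Like StopCandidate but the edited codon is a sense codon (e.g. D→N)."""

    new_aa: str = ""


@dataclass
class GeneScanResult:
    gene_id: str
    targetable: bool
    best: Optional[StopCandidate]
    n_candidates: int
    antisense_only: bool = False  # reachable only via W codons on the template strand


@dataclass
class GenomeScanReport:
    n_orfs: int
    n_targetable: int
    n_untargetable: int
    percent_targetable: float
    histogram: list[int]  # earliest-STOP orf_fraction in 10 % bins
    per_gene: dict[str, GeneScanResult]
    params: ScanParams
    n_antisense_only: int = 0


# ---------------------------------------------------------------------------
# protospacer enumeration


def _pam_regex(pam: str) -> str:
    return "".join(f"[{IUPAC[b]}]" for b in pam)


def _enumerate_on_strand(seq: str, params: ScanParams) -> list[tuple[int, str, str, Optional[str]]]:
    """All (start0, protospacer, pam, upstream) on the given oriented sequence."""
    plen = params.protospacer_len
    pattern = re.compile(f"(?=([ACGT]{{{plen}}})({_pam_regex(params.pam)}))")
    out = []
    for m in pattern.finditer(seq):
        i = m.start()
        upstream = seq[i - 1] if i > 0 else None
        if upstream is not None and upstream not in "ACGT":
            upstream = None
        out.append((i, m.group(1), m.group(2), upstream))
    return out


def enumerate_protospacers(
    contig_seq: str,
    params: ScanParams,
    contig_id: str = "contig",
    region: Optional[tuple[int, int]] = None,
) -> list[Protospacer]:
    """Enumerate protospacers with a matching PAM on both strands.

    ``region`` (1-based inclusive, plus-strand coordinates) restricts output
    to protospacers whose 20-nt span overlaps it; enumeration still sees
    enough flanking sequence that results equal a whole-contig scan.
    """
    L = len(contig_seq)
    plen = params.protospacer_len
    lo, hi = (1, L) if region is None else region
    # margin: a protospacer overlapping [lo, hi] starts at most plen-1 before
    # lo; +PAM and +1 upstream base of context on each side
    margin = plen + len(params.pam) + 1
    a = max(0, lo - 1 - margin)
    b = min(L, hi + margin)
    window_seq = contig_seq[a:b]

    protos: list[Protospacer] = []
    for i, spacer, pam, upstream in _enumerate_on_strand(window_seq, params):
        gi = a + i  # 0-based plus index of position 1
        if a > 0 and i == 0:
            upstream = None  # cannot trust edge of the slice
        if a > 0 and upstream is None and gi > 0:
            up = contig_seq[gi - 1]
            upstream = up if up in "ACGT" else None
        protos.append(
            Protospacer(contig_id, gi + 1, "+", spacer, pam, upstream)
        )
    rc = revcomp(window_seq)
    for j, spacer, pam, upstream in _enumerate_on_strand(rc, params):
        # rc index j corresponds to plus-strand 1-based coordinate b - j
        start_coord = b - j
        if j == 0 and b < L:
            up = contig_seq[b]  # plus base just right of the slice
            up = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(up)
            upstream = up
        protos.append(
            Protospacer(contig_id, start_coord, "-", spacer, pam, upstream)
        )
    if region is not None:
        protos = [
            p for p in protos
            if not (p.span[1] < lo or p.span[0] > hi)
        ]
    protos.sort(key=lambda p: (p.span[0], p.strand))
    return protos


# ---------------------------------------------------------------------------
# editable cytidines


def editable_positions(protospacer: Protospacer, params: ScanParams) -> list[EditSite]:
    """Window cytidines, minus those immediately preceded by a G.

    The preceding base of position 1 is the genomic base 5' of the
    protospacer; when that base is unknown (contig edge, N) the site is
    conservatively kept.
    """
    lo, hi = params.window
    sites = []
    for pos in range(lo, hi + 1):
        if protospacer.seq[pos - 1] != "C":
            continue
        preceding = protospacer.seq[pos - 2] if pos > 1 else protospacer.upstream_base
        if params.forbid_preceding_g and preceding == "G":
            continue
        sites.append(
            EditSite(protospacer, pos, preceding, protospacer.position_to_genomic(pos))
        )
    return sites


# ---------------------------------------------------------------------------
# realized-codon computation

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _apply_edits(gene: GeneRecord, edits: Iterable[tuple[int, str]]) -> Optional[str]:
    """Apply plus-strand (coordinate, new_base) edits to the gene's CDS.

    Edits outside the CDS are ignored (they cannot change the protein).
    Returns the edited CDS, or None if no edit landed inside the CDS.
    """
    cds = list(gene.cds_seq)
    hit = False
    for coord, plus_base in edits:
        off = gene.genomic_to_cds(coord)
        if off is None:
            continue
        cds[off] = plus_base if gene.strand == "+" else _COMP[plus_base]
        hit = True
    if not hit:
        return None
    return "".join(cds)


def _realize(
    gene: GeneRecord,
    protospacer: Protospacer,
    edit_sites: list[EditSite],
) -> Optional[tuple[str, list[tuple[int, str, str]]]]:
    """Edited CDS and per-codon changes for a set of edit sites.

    Changes are (codon_index_1based, original_codon, edited_codon).
    """
    new_base = "T" if protospacer.strand == "+" else "A"
    edited = _apply_edits(gene, [(s.genomic_coordinate, new_base) for s in edit_sites])
    if edited is None:
        return None
    changes = []
    for ci in range(len(gene.cds_seq) // 3):
        a = gene.cds_seq[3 * ci : 3 * ci + 3]
        b = edited[3 * ci : 3 * ci + 3]
        if a != b:
            changes.append((ci + 1, a, b))
    return edited, changes


def _collateral_notes(changes: list[tuple[int, str, str]], skip_codon: int) -> list[str]:
    notes = []
    for ci, a, b in changes:
        if ci == skip_codon:
            continue
        aa_a, aa_b = translate_cds(a), translate_cds(b)
        notes.append(f"{aa_a}{ci}{aa_b}")
    return notes


def stop_conversions(
    gene: GeneRecord,
    protospacer: Protospacer,
    edit_sites: list[EditSite],
    params: ScanParams,
) -> list[StopCandidate]:
    """STOP-creating candidates for one protospacer over one gene.

    The realized codon assumes all eligible window cytidines are co-edited;
    where a single edit alone already creates the STOP, that minimal plan is
    emitted as an additional ``edit_plan='single'`` alternative.  The
    terminal (natural) STOP codon is never a target.
    """
    if not edit_sites:
        return []
    n_codons = len(gene.cds_seq) // 3
    protein = gene.translation()

    out: list[StopCandidate] = []

    def emit(sites: list[EditSite], plan: str, seen: set) -> None:
        realized = _realize(gene, protospacer, sites)
        if realized is None:
            return
        edited_cds, changes = realized
        for ci, orig, new in changes:
            if ci >= n_codons:  # terminal STOP codon position
                continue
            if translate_cds(new) != "*":
                continue
            key = (ci, plan, tuple(s.position for s in sites))
            if key in seen:
                continue
            seen.add(key)
            out.append(
                StopCandidate(
                    gene_id=gene.gene_id,
                    codon_index=ci,
                    original_aa=protein[ci - 1],
                    original_codon=orig,
                    edited_codon=new,
                    edit_sites=list(sites),
                    protospacer=protospacer,
                    orf_fraction=ci / n_codons,
                    label=f"{gene.display_name}^{protein[ci - 1]}{ci}*",
                    collateral=_collateral_notes(changes, ci),
                    edit_plan=plan,
                )
            )

    seen: set = set()
    emit(edit_sites, "co-edit", seen)
    if len(edit_sites) > 1:
        for site in edit_sites:
            emit([site], "single", seen)
    return out


def design_recode(
    gene: GeneRecord,
    target_aa_change: str,
    genome: Genome,
    params: ScanParams,
    kmer_index: Optional["KmerIndex"] = None,
) -> list[RecodeCandidate]:
    """All protospacers realizing exactly a requested substitution (e.g. D159N).

    Collateral synonymous changes are allowed (and annotated); any collateral
    amino-acid change disqualifies the candidate.  Returns an empty list when
    the substitution is not reachable by C→T (coding) or G→A (template).
    """
    m = re.fullmatch(r"([A-Y*])(\d+)([A-Y*])", target_aa_change)
    if not m:
        raise ScanError(f"cannot parse amino-acid change {target_aa_change!r}")
    orig_aa, idx, new_aa = m.group(1), int(m.group(2)), m.group(3)
    protein = gene.translation()
    if idx < 1 or idx > len(protein):
        raise ScanError(f"codon index {idx} outside {gene.gene_id} (length {len(protein)})")
    if protein[idx - 1] != orig_aa:
        raise ScanError(
            f"{gene.gene_id} codon {idx} encodes {protein[idx - 1]}, not {orig_aa}"
        )

    contig_seq = genome.sequence(gene.contig_id)
    protos = enumerate_protospacers(
        contig_seq, params, gene.contig_id, region=(gene.start, gene.end)
    )
    out: list[RecodeCandidate] = []
    for proto in protos:
        sites = editable_positions(proto, params)
        if not sites:
            continue
        plans = [("co-edit", sites)]
        if len(sites) > 1:
            plans += [("single", [s]) for s in sites]
        for plan, plan_sites in plans:
            realized = _realize(gene, proto, plan_sites)
            if realized is None:
                continue
            _, changes = realized
            target = [c for c in changes if c[0] == idx]
            if not target:
                continue
            _, orig_codon, new_codon = target[0]
            if translate_cds(new_codon) != new_aa:
                continue
            ok = True
            for ci, a, b in changes:
                if ci != idx and translate_cds(a) != translate_cds(b):
                    ok = False
                    break
            if not ok:
                continue
            out.append(
                RecodeCandidate(
                    gene_id=gene.gene_id,
                    codon_index=idx,
                    original_aa=orig_aa,
                    original_codon=orig_codon,
                    edited_codon=new_codon,
                    edit_sites=list(plan_sites),
                    protospacer=proto,
                    orf_fraction=idx / (len(gene.cds_seq) // 3),
                    label=f"{gene.display_name}^{orig_aa}{idx}{new_aa}",
                    collateral=_collateral_notes(changes, idx),
                    edit_plan=plan,
                    new_aa=new_aa,
                )
            )
    if params.require_unique:
        out = uniqueness_filter(out, genome, params, kmer_index)  # type: ignore[assignment]
    return out


# ---------------------------------------------------------------------------
# genome-wide 20-mer uniqueness

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class KmerIndex:
    """Exact k-mer occurrence counts over the plus strand of all contigs.

    Occurrences "on either strand" of a query are counted as matches of the
    query plus matches of its reverse complement against the plus strand,
    which is equivalent to scanning both strands.
    """

    def __init__(self, genome: Genome, k: int = 20):
        if k > 31:
            raise ValueError("k must fit in 62 bits")
        self.k = k
        codes = []
        for _, seq in genome.contigs:
            if len(seq) < k:
                continue
            vals = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            valid = vals != 255
            v = np.where(valid, vals, 0).astype(np.uint64)
            n = len(seq) - k + 1
            code = np.zeros(n, dtype=np.uint64)
            ok = np.ones(n, dtype=bool)
            for off in range(k):
                code = code * np.uint64(4) + v[off : off + n]
                ok &= valid[off : off + n]
            codes.append(code[ok])
        allcodes = np.concatenate(codes) if codes else np.zeros(0, dtype=np.uint64)
        self._sorted = np.sort(allcodes)

    def _count_code(self, code: int) -> int:
        lo = int(np.searchsorted(self._sorted, np.uint64(code), side="left"))
        hi = int(np.searchsorted(self._sorted, np.uint64(code), side="right"))
        return hi - lo

    @staticmethod
    def encode(seq: str) -> Optional[int]:
        code = 0
        for b in seq:
            v = _BASE_CODE[ord(b)]
            if v == 255:
                return None
            code = code * 4 + int(v)
        return code

    def count(self, seq: str) -> int:
        """Occurrences of ``seq`` on either strand of the genome."""
        if len(seq) != self.k:
            raise ValueError(f"index built for k={self.k}, got {len(seq)}-mer")
        fwd = self.encode(seq)
        if fwd is None:
            return 0
        rc = self.encode(revcomp(seq))
        if fwd == rc:
            return self._count_code(fwd)
        return self._count_code(fwd) + self._count_code(rc)


def uniqueness_filter(
    candidates: list[StopCandidate],
    genome: Genome,
    params: ScanParams,
    kmer_index: Optional[KmerIndex] = None,
) -> list[StopCandidate]:
    """Keep candidates whose protospacer occurs exactly once genome-wide.

    Matching is the bare 20-mer on either strand by default; with
    ``params.unique_include_pam`` the protospacer+PAM (k+3)-mer is counted
    instead.  Removed candidates get ``unique=False`` and are dropped.
    """
    if not candidates:
        return []
    k = params.protospacer_len + (len(params.pam) if params.unique_include_pam else 0)
    if kmer_index is None or kmer_index.k != k:
        kmer_index = KmerIndex(genome, k)
    kept = []
    for cand in candidates:
        query = cand.protospacer.seq
        if params.unique_include_pam:
            query = query + cand.protospacer.pam_seq
        n = kmer_index.count(query)
        cand.unique = n == 1
        if cand.unique:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# per-gene and genome-wide scans


def _candidates_for_gene(
    gene: GeneRecord,
    protos: list[Protospacer],
    params: ScanParams,
) -> list[StopCandidate]:
    out: list[StopCandidate] = []
    for proto in protos:
        sites = editable_positions(proto, params)
        if not sites:
            continue
        out.extend(stop_conversions(gene, proto, sites, params))
    if params.max_orf_fraction < 1.0:
        out = [c for c in out if c.orf_fraction <= params.max_orf_fraction]
    return out


def scan_gene(
    gene: GeneRecord,
    genome: Genome,
    params: ScanParams,
    kmer_index: Optional[KmerIndex] = None,
) -> list[StopCandidate]:
    """All STOP candidates for one gene, ordered by codon index then rank."""
    from cbedesign.efficiency import EfficiencyParams, rank_candidates, score_candidate

    if gene.partial:
        return []
    contig_seq = genome.sequence(gene.contig_id)
    protos = enumerate_protospacers(
        contig_seq, params, gene.contig_id, region=(gene.start, gene.end)
    )
    cands = _candidates_for_gene(gene, protos, params)
    if params.require_unique:
        cands = uniqueness_filter(cands, genome, params, kmer_index)
    eff = EfficiencyParams()
    for c in cands:
        c.efficiency = score_candidate(c, eff).category
    return rank_candidates(cands, eff, by_codon_first=True)


def scan_genome(
    genome: Genome,
    params: ScanParams,
    genes: Optional[list[GeneRecord]] = None,
) -> GenomeScanReport:
    """Genome-wide targetability statistics.

    Per-gene statistics count realized (co-edit) candidates; single-site
    alternatives target the same codons and would not change them.
    """
    from cbedesign.genome_io import extract_cds
    from cbedesign.efficiency import EfficiencyParams, score_candidate

    if genes is None:
        genes = extract_cds(genome)
    genes = [g for g in genes if not g.partial]

    kmer_index = KmerIndex(
        genome,
        params.protospacer_len + (len(params.pam) if params.unique_include_pam else 0),
    )
    eff = EfficiencyParams()

    per_gene: dict[str, GeneScanResult] = {}
    histogram = [0] * 10
    n_targetable = 0
    n_antisense_only = 0

    protos_by_contig: dict[str, list[Protospacer]] = {}
    starts_by_contig: dict[str, list[int]] = {}
    for cid, seq in genome.contigs:
        plist = enumerate_protospacers(seq, params, cid)
        protos_by_contig[cid] = plist
        starts_by_contig[cid] = [p.span[0] for p in plist]

    span = params.protospacer_len + len(params.pam)
    for gene in genes:
        plist = protos_by_contig[gene.contig_id]
        starts = starts_by_contig[gene.contig_id]
        lo = bisect_left(starts, gene.start - span)
        hi = bisect_right(starts, gene.end)
        overlapping = [
            p for p in plist[lo:hi] if not (p.span[1] < gene.start or p.span[0] > gene.end)
        ]
        cands = [
            c for c in _candidates_for_gene(gene, overlapping, params)
            if c.edit_plan == "co-edit"
        ]
        if params.require_unique:
            cands = uniqueness_filter(cands, genome, params, kmer_index)
        if cands:
            for c in cands:
                c.efficiency = score_candidate(c, eff).category
            best = min(
                cands,
                key=lambda c: (c.codon_index, -_eff_order(c.efficiency), c.protospacer.genomic_start),
            )
            n_targetable += 1
            frac = best.orf_fraction
            histogram[min(int(frac * 10), 9)] += 1
            antisense_only = all(c.protospacer.strand != gene.strand for c in cands)
            if antisense_only:
                n_antisense_only += 1
            per_gene[gene.gene_id] = GeneScanResult(
                gene.gene_id, True, best, len(cands), antisense_only
            )
        else:
            per_gene[gene.gene_id] = GeneScanResult(gene.gene_id, False, None, 0)

    n_orfs = len(genes)
    n_untargetable = n_orfs - n_targetable
    return GenomeScanReport(
        n_orfs=n_orfs,
        n_targetable=n_targetable,
        n_untargetable=n_untargetable,
        percent_targetable=100.0 * n_targetable / n_orfs if n_orfs else 0.0,
        histogram=histogram,
        per_gene=per_gene,
        params=params,
        n_antisense_only=n_antisense_only,
    )


def _eff_order(category: Optional[str]) -> int:
    return {"high": 3, "medium": 2, "low": 1, "none": 0}.get(category or "none", 0)


def summarize(report: GenomeScanReport):
    """Decile histogram of earliest-STOP position plus an untargetable bin."""
    import pandas as pd

    rows = [
        {"bin": f"[{10 * i},{10 * (i + 1)}{')' if i < 9 else ']'}", "n_genes": report.histogram[i]}
        for i in range(10)
    ]
    rows.append({"bin": "untargetable", "n_genes": report.n_untargetable})
    return pd.DataFrame(rows)
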