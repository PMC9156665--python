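"""Protospacer enumeration, editable windows, STOP/recoding design, uniqueness."""

import pytest
from hypothesis import given, settings, strategies as st

from cbedesign.fixtures import (
    FixtureSpec,
    _naive_rc,
    brute_force_scan,
    mirror_genome,
    synth_genome,
)
from cbedesign.genome_io import Genome, revcomp
from cbedesign.target_scan import (
    KmerIndex,
    Protospacer,
    ScanError,
    ScanParams,
    design_recode,
    editable_positions,
    enumerate_protospacers,
    scan_gene,
    scan_genome,
    summarize,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=120)


# ---------------------------------------------------------------------------
# enumeration


def test_enumerate_single_plus_strand_hit():
    seq = "A" * 20 + "TGG"
    protos = enumerate_protospacers(seq, ScanParams())
    assert len(protos) == 1
    p = protos[0]
    assert (p.strand, p.genomic_start, p.seq, p.pam_seq) == ("+", 1, "A" * 20, "TGG")
    assert p.upstream_base is None  # contig edge


def test_enumerate_minus_strand_coordinates():
    # CCA + 20 nt: the minus strand reads [rc of 20-mer] + TGG
    core = "ATGCATGCATGCATGCATGC"
    seq = "CCA" + core
    protos = [p for p in enumerate_protospacers(seq, ScanParams()) if p.strand == "-"]
    hit = [p for p in protos if p.genomic_start == len(seq)]
    assert len(hit) == 1
    p = hit[0]
    assert p.seq == revcomp(core)
    assert p.pam_seq == revcomp("CCA")[-3:] == "TGG"
    # position p maps toward decreasing plus coordinates
    assert p.position_to_genomic(1) == len(seq)
    assert p.position_to_genomic(20) == 4
    assert p.span == (4, len(seq))


def test_enumerate_no_pam_no_hits():
    assert enumerate_protospacers("AT" * 30, ScanParams()) == []


def test_enumerate_n_bases_excluded():
    seq = "A" * 10 + "N" + "A" * 9 + "TGG"
    assert enumerate_protospacers(seq, ScanParams()) == []


def test_region_equals_whole_contig_scan(fixture_genome):
    genome, genes, _ = fixture_genome
    seq = genome.contigs[0][1]
    params = ScanParams()
    whole = enumerate_protospacers(seq, params, "c")
    for g in genes[:3]:
        sub = enumerate_protospacers(seq, params, "c", region=(g.start, g.end))
        expected = [
            p for p in whole if not (p.span[1] < g.start or p.span[0] > g.end)
        ]
        assert [(p.strand, p.genomic_start) for p in sub] == [
            (p.strand, p.genomic_start) for p in expected
        ]


@settings(max_examples=60, derandomize=True)
@given(DNA)
def test_enumeration_matches_naive(seq):
    """Regex fast path equals literal enumeration on random sequence."""
    params = ScanParams()
    got = {
        (p.strand, p.genomic_start, p.seq, p.pam_seq, p.upstream_base)
        for p in enumerate_protospacers(seq, params)
    }
    expect = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", _naive_rc(seq))):
        for i in range(L - 22):
            spacer, pam = s[i : i + 20], s[i + 20 : i + 23]
            if pam[1:] != "GG":
                continue
            upstream = s[i - 1] if i > 0 else None
            start = i + 1 if strand == "+" else L - i
            expect.add((strand, start, spacer, pam, upstream))
    assert got == expect


# ---------------------------------------------------------------------------
# editable windows


def _proto(spacer, upstream=None):
    return Protospacer("c", 100, "+", spacer, "TGG", upstream)


def test_editable_positions_window_and_preceding_g():
    # Cs at 2, 4, 6 preceded by T; C at 9 outside default window
    spacer = "TCTCTCAGCTTTTTTTTTTT"
    sites = editable_positions(_proto(spacer), ScanParams())
    assert [s.position for s in sites] == [2, 4, 6]
    assert all(s.preceding_base == "T" for s in sites)
    # widen to 2-9: the C at 9 is preceded by G and stays excluded
    ugi = ScanParams.with_preset("ugi")
    assert [s.position for s in editable_positions(_proto(spacer), ugi)] == [2, 4, 6]
    free = ScanParams(window=(2, 9), forbid_preceding_g=False)
    assert [s.position for s in editable_positions(_proto(spacer), free)] == [2, 4, 6, 9]


def test_editable_position_one_uses_upstream_base():
    spacer = "C" + "A" * 19
    params = ScanParams(window=(1, 7))
    assert editable_positions(_proto(spacer, upstream="G"), params) == []
    kept = editable_positions(_proto(spacer, upstream="T"), params)
    assert [s.position for s in kept] == [1]
    # unknown upstream base: conservatively kept
    assert [s.position for s in editable_positions(_proto(spacer, None), params)] == [1]


def test_edit_site_genomic_coordinates():
    p = Protospacer("c", 200, "-", "TC" + "A" * 18, "TGG", None)
    (site,) = editable_positions(p, ScanParams())
    assert site.position == 2
    assert site.genomic_coordinate == 199  # minus strand: start - position + 1


# ---------------------------------------------------------------------------
# STOP design on planted fixtures


def test_sense_plant_recovered(fixture_genome):
    genome, genes, truth = fixture_genome
    row = next(t for t in truth if t.kind == "stop_sense")
    gene = next(g for g in genes if g.gene_id == row.gene_id)
    cands = scan_gene(gene, genome, ScanParams())
    planted = [c for c in cands if c.codon_index == row.codon_index]
    assert planted, f"planted sense STOP at codon {row.codon_index} not found"
    c = planted[0]
    assert c.original_codon == "CAG" and c.edited_codon == "TAG"
    assert c.label == row.label
    assert c.protospacer.seq == row.protospacer
    assert c.unique is True


def test_antisense_plant_recovered(fixture_genome):
    genome, genes, truth = fixture_genome
    row = next(t for t in truth if t.kind == "stop_antisense")
    gene = next(g for g in genes if g.gene_id == row.gene_id)
    cands = scan_gene(gene, genome, ScanParams())
    planted = [c for c in cands if c.codon_index == row.codon_index]
    assert planted
    assert all(c.original_codon == "TGG" for c in planted)
    # co-edit of both template Cs gives TAA; single-site plans give TAG/TGA
    by_plan = {c.edit_plan: set() for c in planted}
    for c in by_plan:
        by_plan[c] = {x.edited_codon for x in planted if x.edit_plan == c}
    assert by_plan["co-edit"] == {"TAA"}
    assert by_plan.get("single", set()) == {"TAG", "TGA"}
    # the planted protospacer sits on the strand opposite the coding strand
    proto_strand = {c.protospacer.strand for c in planted}
    assert proto_strand == {"-" if gene.strand == "+" else "+"}


def test_recode_plant_recovered(fixture_genome):
    genome, genes, truth = fixture_genome
    row = next(t for t in truth if t.kind == "recode")
    gene = next(g for g in genes if g.gene_id == row.gene_id)
    change = f"D{row.codon_index}N"
    cands = design_recode(gene, change, genome, ScanParams())
    assert cands, f"planted recode {change} not found"
    c = cands[0]
    assert (c.original_codon, c.edited_codon) == ("GAC", "AAC")
    assert c.label == row.label
    # collateral amino-acid changes are disqualifying, synonymous ones allowed
    for cand in cands:
        for note in cand.collateral:
            assert note[0] == note[-1], f"non-synonymous collateral {note} kept"


def test_recode_errors():
    genome, genes, truth = synth_genome(FixtureSpec(seed=1))
    row = next(t for t in truth if t.kind == "recode")
    gene = next(g for g in genes if g.gene_id == row.gene_id)
    with pytest.raises(ScanError, match="encodes"):
        design_recode(gene, f"W{row.codon_index}N", genome, ScanParams())
    with pytest.raises(ScanError, match="outside"):
        design_recode(gene, "D9999N", genome, ScanParams())
    with pytest.raises(ScanError, match="parse"):
        design_recode(gene, "notachange", genome, ScanParams())
    # D->E is not reachable by C->T / G->A at this codon
    assert design_recode(gene, f"D{row.codon_index}E", genome, ScanParams()) == []


def test_duplicate_protospacers_filtered(fixture_genome):
    genome, genes, truth = fixture_genome
    dups = [t for t in truth if t.kind == "duplicate"]
    assert len(dups) == 2
    for row in dups:
        gene = next(g for g in genes if g.gene_id == row.gene_id)
        with_unique = scan_gene(gene, genome, ScanParams())
        assert not any(
            c.protospacer.seq == row.protospacer for c in with_unique
        ), "duplicated protospacer survived the uniqueness filter"
        without = scan_gene(gene, genome, ScanParams(require_unique=False))
        assert any(c.protospacer.seq == row.protospacer for c in without)


def test_terminal_stop_never_targeted(fixture_genome):
    genome, genes, _ = fixture_genome
    for gene in genes:
        for c in scan_gene(gene, genome, ScanParams(require_unique=False)):
            assert c.codon_index < gene.protein_length


# ---------------------------------------------------------------------------
# k-mer uniqueness


def test_kmer_index_counts_match_naive():
    import numpy as np

    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
    genome = Genome(contigs=[("c1", seq), ("c2", seq[:500])])
    idx = KmerIndex(genome, 8)

    def naive(query):
        total = 0
        for _, s in genome.contigs:
            for probe in {query, _naive_rc(query)}:
                start = 0
                while (i := s.find(probe, start)) >= 0:
                    total += 1
                    start = i + 1
        return total

    for i in range(0, 200, 7):
        q = seq[i : i + 8]
        assert idx.count(q) == naive(q)
    # palindromic query must not double-count
    pal = "ACGTACGT"
    assert pal == _naive_rc(pal)
    assert idx.count(pal) == naive(pal)


def test_kmer_index_rejects_wrong_length(fixture_genome):
    genome, _, _ = fixture_genome
    idx = KmerIndex(genome, 20)
    with pytest.raises(ValueError, match="k=20"):
        idx.count("ACGT")


# ---------------------------------------------------------------------------
# genome scan invariants


def test_summarize_conserves_gene_count(fixture_genome):
    genome, genes, _ = fixture_genome
    report = scan_genome(genome, ScanParams(), genes)
    table = summarize(report)
    assert int(table["n_genes"].sum()) == report.n_orfs
    assert int(table["n_genes"].iloc[:10].sum()) == report.n_targetable
    assert table["bin"].iloc[-1] == "untargetable"


def test_window_widening_is_monotone():
    for seed in range(4):
        genome, genes, _ = synth_genome(FixtureSpec(seed=seed))
        narrow = scan_genome(genome, ScanParams(window=(2, 7)), genes)
        wide = scan_genome(genome, ScanParams(window=(2, 9)), genes)
        assert wide.n_targetable >= narrow.n_targetable
        for gid in narrow.per_gene:
            assert wide.per_gene[gid].targetable >= narrow.per_gene[gid].targetable


def test_preceding_g_rule_only_removes_candidates():
    genome, genes, _ = synth_genome(FixtureSpec(seed=2))
    strict = scan_genome(genome, ScanParams(forbid_preceding_g=True), genes)
    loose = scan_genome(genome, ScanParams(forbid_preceding_g=False), genes)
    assert loose.n_targetable >= strict.n_targetable


def test_strand_symmetry():
    for seed in (0, 3):
        genome, genes, _ = synth_genome(FixtureSpec(seed=seed))
        report = scan_genome(genome, ScanParams(), genes)
        mirrored, mgenes = mirror_genome(genome, genes)
        mreport = scan_genome(mirrored, ScanParams(), mgenes)
        assert mreport.n_targetable == report.n_targetable
        assert mreport.histogram == report.histogram
        for gid, r in report.per_gene.items():
            m = mreport.per_gene[gid]
            assert (m.targetable, m.n_candidates) == (r.targetable, r.n_candidates)
            if r.best is not None:
                # tie-breaking by coordinate flips under mirroring, so the
                # chosen protospacer may differ; the target codon may not
                assert m.best.codon_index == r.best.codon_index
        # the full candidate set mirrors exactly (oracle keys, mirror-mapped)
        L = len(genome.contigs[0][1])
        keys = brute_force_scan(genome, ScanParams(), genes).candidate_keys
        mkeys = brute_force_scan(mirrored, ScanParams(), mgenes).candidate_keys
        flip = {"+": "-", "-": "+"}
        assert mkeys == {
            (gid, ci, flip[strand], L - start + 1) for gid, ci, strand, start in keys
        }


def test_oracle_agreement_single_seed():
    genome, genes, _ = synth_genome(FixtureSpec(seed=11))
    params = ScanParams()
    fast = scan_genome(genome, params, genes)
    oracle = brute_force_scan(genome, params, genes)
    assert fast.n_targetable == oracle.n_targetable
    assert fast.histogram == oracle.histogram
    for gid, r in fast.per_gene.items():
        o = oracle.per_gene[gid]
        assert (r.targetable, r.n_candidates) == (o.targetable, o.n_candidates)
        if r.best is not None:
            assert r.best.codon_index == o.best_codon_index


def test_invalid_params_rejected():
    with pytest.raises(ScanError):
        ScanParams(window=(0, 7))
    with pytest.raises(ScanError):
        ScanParams(window=(8, 7))
    with pytest.raises(ScanError):
        ScanParams(pam="NGZ")
    with pytest.raises(ScanError):
        ScanParams.with_preset("bogus")
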