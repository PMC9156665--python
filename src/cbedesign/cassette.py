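"""Golden Gate oligo design and assembly simulation for multiplex gRNA cassettes.

Each guide in a Cas6-processed cassette is produced by PCR with one
spacer-specific forward oligo and one reusable, position-specific reverse
primer.  Both primers carry outward-cutting BsaI sites, so one-pot
digestion/ligation drops the fragments into a vector whose msfGFP stuffer
is flanked by BsaI sites, in an order dictated entirely by 4-nt overhangs.
The assembled repeat unit is: [overhang]-[spacer 20 nt]-[sgRNA scaffold]-
[Cas6/Csy4 recognition site]-..., with a 4-bp adapter at the 3' end of each
Cas6 site serving as the junction overhang.

BsaI (GGTCTC) cuts 1 nt downstream on the top strand and 5 nt on the
bottom, leaving 4-nt 5' overhangs.  Overhangs here are always written as
the top-strand 4-mer of the junction; two ends ligate when those 4-mers are
equal (i.e. the protruding single strands are complementary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from cbedesign.genome_io import revcomp

BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"

# Printed reverse-primer grammar: BsaI prefix, position linker, Cas6 anneal
PRIMER_PREFIX = "ATCGAGGTCTCC"
PRIMER_CAS6_ANNEAL = "TTAGCTGCCTATACGGCAGT"

# Reverse complement of the reverse primer's 3' block; stands in for the
# Cas6f (Csy4) recognition site of the editing vector, whose exact sequence
# is a property of that unpublished plasmid.  Override via config.
DEFAULT_CAS6_SITE = revcomp(PRIMER_CAS6_ANNEAL)  # ACTGCCGTATAGGCAGCTAA

# Canonical S. pyogenes single-guide scaffold (DNA sense); the 5' 20 nt are
# the annealing handle of the forward oligo.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

POLY_U_TERMINATOR = "TTTTTTT"  # seven consecutive uracils (DNA: T)

MAX_SPACERS = 12

# Shipped default overhang set: entry junction + 12 inter-unit/exit
# junctions, pairwise distinct, none the reverse complement of another,
# none palindromic (validated by OverhangSet and by the test suite).
DEFAULT_OVERHANGS = (
    "AATG", "AGGT", "GCTT", "CAGA", "TGCT", "ACTC", "GGTA",
    "CGAA", "TACA", "CTTC", "GTGA", "ATCG", "AGCG",
)


class DesignError(ValueError):
    pass


class FidelityError(DesignError):
    """Overhang collisions that would make the ligation graph ambiguous."""


class AssemblyError(DesignError):
    """No unique closed assembly product."""


@dataclass(frozen=True)
class OverhangSet:
    """Ordered junction linkers: overhangs[0] is the vector-exit/first-unit
    junction, overhangs[i] joins unit i to unit i+1, and the last used
    overhang returns into the vector."""

    overhangs: tuple[str, ...] = DEFAULT_OVERHANGS

    def __post_init__(self) -> None:
        object.__setattr__(self, "overhangs", tuple(o.upper() for o in self.overhangs))
        problems = check_overhang_fidelity(self.overhangs)
        if problems:
            raise FidelityError("; ".join(problems))

    def __len__(self) -> int:
        return len(self.overhangs)

    def junction(self, i: int) -> str:
        try:
            return self.overhangs[i]
        except IndexError:
            raise DesignError(f"no overhang assigned for junction {i}") from None


def check_overhang_fidelity(overhangs: Sequence[str]) -> list[str]:
    """Problems that would allow mis-ligation: duplicates, reverse-complement
    pairs, palindromes, wrong length/alphabet."""
    problems = []
    seen: dict[str, int] = {}
    for i, o in enumerate(overhangs):
        if len(o) != 4 or any(b not in "ACGT" for b in o):
            problems.append(f"overhang {o!r} is not a 4-nt DNA sequence")
            continue
        if o in seen:
            problems.append(f"duplicate overhang {o} (junctions {seen[o]} and {i})")
        seen[o] = i
        if o == revcomp(o):
            problems.append(f"palindromic overhang {o}")
    for i, o in enumerate(overhangs):
        for j, p in enumerate(overhangs):
            if i < j and o == revcomp(p):
                problems.append(f"overhang {o} is the reverse complement of {p}")
    return problems


@dataclass(frozen=True)
class Oligo:
    name: str
    sequence: str
    role: str  # spacer_forward | position_reverse
    cassette_position: int

    def bsai_site_count(self) -> int:
        """Recognition sites on either strand (must be exactly one)."""
        return self.sequence.count(BSAI_SITE) + self.sequence.count(BSAI_SITE_RC)


@dataclass
class CassettePlan:
    spacers: list[str]
    spacer_names: list[str]
    overhang_set: OverhangSet
    cas6_site: str = DEFAULT_CAS6_SITE
    scaffold: str = DEFAULT_SCAFFOLD
    terminal_cas6: bool = True

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def handle_seq(self) -> str:
        return self.scaffold[:20]

    def unit_sequence(self, i: int) -> str:
        """Assembled repeat unit i: overhang + spacer + scaffold + Cas6 site."""
        tail = self.cas6_site
        if i == self.n_spacers - 1 and not self.terminal_cas6:
            tail = POLY_U_TERMINATOR
        return self.overhang_set.junction(i) + self.spacers[i] + self.scaffold + tail

    def expected_cassette(self) -> str:
        """Insert sequence between the vector's entry and exit junctions."""
        out = "".join(self.unit_sequence(i) for i in range(self.n_spacers))
        return out + self.overhang_set.junction(self.n_spacers)


@dataclass
class AssembledCassette:
    sequence: str
    junctions: list[str]
    spacer_order: list[str]
    circular: bool = True


@dataclass(frozen=True)
class Fragment:
    """A digested dsDNA piece: top strand starting with its left 5' overhang;
    the right overhang (next fragment's first 4 nt) is not part of ``top``."""

    name: str
    top: str
    left_oh: str
    right_oh: str


@dataclass(frozen=True)
class VectorModel:
    """Abstract acceptor: a BsaI-flanked dropout (msfGFP) inside a backbone.

    ``entry_oh`` is the overhang the first insert ligates onto; ``exit_oh``
    receives the last insert's right overhang.
    """

    entry_oh: str
    exit_oh: str
    backbone: str = "ATGCGTAAAGGCGAAGAGCTGTTCACTGGTATGCGTAAAGGC"  # placeholder stub
    dropout: str = "ATGAGTAAAGGAGAAGAACTTTTCACTGGAGTTGTCCCAATT"  # msfGFP stub

    def sequence(self) -> str:
        """Linearized circular vector sequence, starting at the backbone.

        Layout (circular): [exit_oh][backbone][entry_oh]A GAGACC [dropout]
        GGTCTC A[back to exit_oh].  Digestion releases the dropout with both
        BsaI sites and leaves the backbone carrying entry/exit overhangs.
        """
        return (
            self.exit_oh
            + self.backbone
            + self.entry_oh
            + "A" + BSAI_SITE_RC
            + self.dropout
            + BSAI_SITE + "A"
        )

    def backbone_fragment(self) -> Fragment:
        return Fragment("vector-backbone", self.exit_oh + self.backbone, self.exit_oh, self.entry_oh)


# ---------------------------------------------------------------------------
# oligo design


def _check_spacer(spacer: str) -> None:
    spacer = spacer.upper()
    if len(spacer) != 20:
        raise DesignError(f"spacer must be 20 nt, got {len(spacer)}: {spacer}")
    if any(b not in "ACGT" for b in spacer):
        raise DesignError(f"spacer contains non-ACGT bases: {spacer}")
    if BSAI_SITE in spacer or BSAI_SITE_RC in spacer:
        raise DesignError(
            f"spacer {spacer} contains an internal BsaI site; choose an "
            "alternative candidate for this target"
        )


def position_primer(position: int, overhang_set: OverhangSet) -> Oligo:
    """Reusable reverse primer selecting the cassette position.

    Its 4-nt linker is the reverse complement of the downstream junction
    overhang, so the PCR product presents that overhang after digestion.
    """
    linker = revcomp(overhang_set.junction(position + 1))
    return position_primer_from_linker(linker, position)


def position_primer_from_linker(linker: str, position: int = 0) -> Oligo:
    if len(linker) != 4 or any(b not in "ACGT" for b in linker.upper()):
        raise DesignError(f"linker must be a 4-nt DNA sequence, got {linker!r}")
    seq = PRIMER_PREFIX + linker.upper() + PRIMER_CAS6_ANNEAL
    return Oligo(f"pos{position + 1}_rev", seq, "position_reverse", position)


def spacer_oligo(
    spacer: str,
    position: int,
    overhang_set: OverhangSet,
    handle_seq: str = DEFAULT_SCAFFOLD[:20],
    name: Optional[str] = None,
) -> Oligo:
    """Forward oligo: BsaI prefix + entry overhang + spacer + scaffold handle."""
    spacer = spacer.upper()
    _check_spacer(spacer)
    seq = PRIMER_PREFIX + overhang_set.junction(position) + spacer + handle_seq
    oligo = Oligo(name or f"spacer{position + 1}_fwd", seq, "spacer_forward", position)
    if oligo.bsai_site_count() != 1:
        raise DesignError(
            f"oligo {oligo.name} carries {oligo.bsai_site_count()} BsaI sites (must be exactly 1)"
        )
    return oligo


def plan_cassette(
    spacers: Sequence[str],
    overhang_set: Optional[OverhangSet] = None,
    names: Optional[Sequence[str]] = None,
    terminal_cas6: bool = True,
    cas6_site: str = DEFAULT_CAS6_SITE,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> CassettePlan:
    """Deterministic cassette plan for 1-12 spacers.

    A Cas6 recognition site follows every gRNA, including (by default) the
    last one — the terminal site raises the last guide's editing efficiency;
    without it the cassette ends in a poly-U terminator instead.
    """
    spacers = [s.upper() for s in spacers]
    if not 1 <= len(spacers) <= MAX_SPACERS:
        raise DesignError(
            f"a cassette holds 1-{MAX_SPACERS} gRNAs, got {len(spacers)} spacers"
        )
    for s in spacers:
        _check_spacer(s)
    if len(set(spacers)) != len(spacers):
        raise DesignError("duplicate spacer sequences in cassette")
    overhang_set = overhang_set or OverhangSet()
    if len(overhang_set) < len(spacers) + 1:
        raise DesignError(
            f"overhang set provides {len(overhang_set)} linkers; "
            f"{len(spacers) + 1} junctions needed"
        )
    names = list(names) if names else [f"spacer{i + 1}" for i in range(len(spacers))]
    return CassettePlan(
        spacers=spacers,
        spacer_names=names,
        overhang_set=overhang_set,
        cas6_site=cas6_site,
        scaffold=scaffold,
        terminal_cas6=terminal_cas6,
    )


def plan_oligos(plan: CassettePlan) -> list[Oligo]:
    """Order sheet: one spacer-specific forward oligo plus the reusable
    position-specific reverse primer per cassette slot."""
    oligos = []
    for i, (spacer, name) in enumerate(zip(plan.spacers, plan.spacer_names)):
        oligos.append(spacer_oligo(spacer, i, plan.overhang_set, plan.handle_seq, f"{name}_fwd"))
        oligos.append(position_primer(i, plan.overhang_set))
    return oligos


# ---------------------------------------------------------------------------
# BsaI digestion and ligation simulation


def digest_bsai(seq: str, name: str = "fragment") -> list[Fragment]:
    """Type-IIS digestion of a linear top-strand sequence.

    Cuts 1 nt after GGTCTC on the top strand and 5 nt on the bottom (and
    mirror-image for GAGACC), producing 4-nt 5' overhangs.  Returns the
    resulting fragments left to right; terminal pieces keep blunt/undefined
    outer ends (empty overhang strings).
    """
    cuts = []  # (top_cut, overhang) with overhang = seq[top_cut-?]; see below
    for i in range(len(seq) - len(BSAI_SITE) + 1):
        hexamer = seq[i : i + 6]
        if hexamer == BSAI_SITE:
            top_cut = i + 7
            if top_cut + 4 <= len(seq):
                cuts.append((top_cut, seq[top_cut : top_cut + 4]))
        elif hexamer == BSAI_SITE_RC:
            top_cut = i - 5
            if top_cut >= 0:
                cuts.append((top_cut, seq[top_cut : top_cut + 4]))
    cuts.sort()
    fragments = []
    prev_pos, prev_oh = 0, ""
    for k, (pos, oh) in enumerate(cuts):
        fragments.append(Fragment(f"{name}.{k}", seq[prev_pos:pos], prev_oh, oh))
        prev_pos, prev_oh = pos, oh
    fragments.append(Fragment(f"{name}.{len(cuts)}", seq[prev_pos:], prev_oh, ""))
    return fragments


def pcr_product(plan: CassettePlan, i: int) -> str:
    """Top strand of the PCR product for cassette slot i.

    Forward oligo extends through the scaffold and Cas6 site of the
    template; the reverse primer appends the position linker and the
    outward-cutting BsaI site.
    """
    tail = plan.cas6_site
    if i == plan.n_spacers - 1 and not plan.terminal_cas6:
        tail = POLY_U_TERMINATOR
    return (
        PRIMER_PREFIX
        + plan.overhang_set.junction(i)
        + plan.spacers[i]
        + plan.scaffold
        + tail
        + plan.overhang_set.junction(i + 1)
        + revcomp(PRIMER_PREFIX)  # GGAGACCTCGAT: outward-cutting BsaI + tail
    )


def _insert_fragment(plan: CassettePlan, i: int) -> Fragment:
    frags = digest_bsai(pcr_product(plan, i), plan.spacer_names[i])
    middles = [f for f in frags if f.left_oh and f.right_oh]
    if len(middles) != 1:
        raise AssemblyError(
            f"PCR product for {plan.spacer_names[i]} digested into "
            f"{len(middles)} double-overhang fragments (expected 1)"
        )
    return Fragment(plan.spacer_names[i], middles[0].top, middles[0].left_oh, middles[0].right_oh)


def simulate_golden_gate(
    fragments: Sequence[Fragment],
    vector: Optional[VectorModel] = None,
) -> AssembledCassette:
    """Exact-overhang one-pot ligation of digested fragments into the vector.

    Raises FidelityError when the junction overhangs are ambiguous
    (duplicates or reverse-complement pairs, which permit mis- or
    flipped-orientation ligation) and AssemblyError when no single closed
    product exists.
    """
    pieces = list(fragments)
    if vector is not None:
        pieces = [vector.backbone_fragment()] + pieces

    overhangs = [f.left_oh for f in pieces]
    problems = check_overhang_fidelity(overhangs)
    if problems:
        raise FidelityError("ambiguous ligation graph: " + "; ".join(problems))

    by_left = {f.left_oh: f for f in pieces}
    rights = [f.right_oh for f in pieces]
    if len(set(rights)) != len(rights):
        raise FidelityError(f"duplicate right overhangs: {sorted(rights)}")

    start = pieces[0]
    chain = [start]
    current = start
    while True:
        nxt = by_left.get(current.right_oh)
        if nxt is None:
            raise AssemblyError(
                f"no fragment presents overhang {current.right_oh} after {current.name}"
            )
        if nxt is start:
            break
        if nxt in chain:
            raise AssemblyError(f"ligation revisits fragment {nxt.name} before closing")
        chain.append(nxt)
        current = nxt
    if len(chain) != len(pieces):
        leftover = [f.name for f in pieces if f not in chain]
        raise AssemblyError(f"fragments left out of the closed product: {leftover}")

    sequence = "".join(f.top for f in chain)
    return AssembledCassette(
        sequence=sequence,
        junctions=[f.left_oh for f in chain[1:]] + [start.left_oh],
        spacer_order=[f.name for f in chain if not f.name.startswith("vector")],
        circular=True,
    )


def assemble_plan(plan: CassettePlan, vector: Optional[VectorModel] = None) -> AssembledCassette:
    """Digest the per-slot PCR products and assemble them into the vector."""
    if vector is None:
        vector = VectorModel(
            entry_oh=plan.overhang_set.junction(0),
            exit_oh=plan.overhang_set.junction(plan.n_spacers),
        )
    inserts = [_insert_fragment(plan, i) for i in range(plan.n_spacers)]
    return simulate_golden_gate(inserts, vector)


def validate_spacer(spacer: str, cas6_site: str = DEFAULT_CAS6_SITE, g_rich_fraction: float = 0.45) -> list[str]:
    """Advisory warnings for a spacer: internal BsaI site, Cas6-motif
    containment, guanine richness (poorly edited protospacers)."""
    spacer = spacer.upper()
    warnings = []
    if BSAI_SITE in spacer or BSAI_SITE_RC in spacer:
        warnings.append("spacer contains a BsaI recognition site")
    if spacer in cas6_site or cas6_site in spacer or spacer in revcomp(cas6_site) or revcomp(cas6_site) in spacer:
        warnings.append("spacer overlaps the Cas6 recognition motif")
    if len(spacer) == 20:
        g = spacer.count("G") / 20
        if g > g_rich_fraction:
            warnings.append(f"guanine-rich spacer (G fraction {g:.2f}): expect little or no editing")
    return warnings
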