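"""Ordinal efficiency ranking of edit candidates from sequence context.

Empirically, deamination efficiency depends on the base 5' of the target
cytidine (T >> C > A, and essentially none behind a G), falls off with
distance from the centre of the editing window (protospacer position 6),
and collapses for guanine-rich protospacers.  Those observations are coarse
— published as plots, not tables — so scores here are ordinal categories
with a deterministic sort key, not calibrated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from cbedesign.target_scan import StopCandidate

# rank of the base preceding the target cytidine, best first
DEFAULT_PRECEDING_RANK = {"T": 3, "C": 2, "A": 1, "G": 0}

CATEGORY_BY_RANK = {3: "high", 2: "medium", 1: "medium", 0: "none"}
CATEGORY_ORDER = {"high": 3, "medium": 2, "low": 1, "none": 0}


@dataclass(frozen=True)
class EfficiencyParams:
    preceding_rank: dict = field(default_factory=lambda: dict(DEFAULT_PRECEDING_RANK))
    window_center: int = 6
    ugi: bool = True
    g_rich_warn_fraction: float = 0.45

    def __post_init__(self) -> None:
        if self.preceding_rank.get("G", 0) != 0:
            raise ValueError("a preceding G always maps to rank 0 (no editing)")


@dataclass(frozen=True)
class EfficiencyScore:
    category: str  # high / medium / low / none
    sort_key: tuple  # larger sorts earlier
    site_ranks: tuple  # (preceding rank, -distance from centre) per edit site
    g_rich: bool


def _site_rank(site, params: EfficiencyParams) -> tuple[int, int]:
    # unknown preceding base (contig edge) is scored conservatively like A
    rank = params.preceding_rank.get(site.preceding_base or "A", 1)
    return (rank, -abs(site.position - params.window_center))


def score_candidate(candidate: StopCandidate, params: Optional[EfficiencyParams] = None) -> EfficiencyScore:
    """Category determined by the candidate's best edit site.

    The preceding-base rank dominates; distance from the window centre
    breaks ties.  A guanine-rich protospacer caps the category at 'low'; a
    candidate whose every site sits behind a G is 'none'.
    """
    params = params or EfficiencyParams()
    ranks = tuple(sorted((_site_rank(s, params) for s in candidate.edit_sites), reverse=True))
    best = ranks[0] if ranks else (0, 0)
    g_frac = candidate.protospacer.seq.count("G") / len(candidate.protospacer.seq)
    g_rich = g_frac > params.g_rich_warn_fraction
    if best[0] == 0 or not ranks:
        category = "none"
    else:
        category = CATEGORY_BY_RANK[best[0]]
        if g_rich and CATEGORY_ORDER[category] > CATEGORY_ORDER["low"]:
            category = "low"
    return EfficiencyScore(
        category=category,
        sort_key=(CATEGORY_ORDER[category],) + best,
        site_ranks=ranks,
        g_rich=g_rich,
    )


def rank_candidates(
    candidates: list[StopCandidate],
    params: Optional[EfficiencyParams] = None,
    by_codon_first: bool = True,
) -> list[StopCandidate]:
    """Deterministic stable ordering of candidates.

    Default key: (codon index asc, category desc, genomic coordinate asc) —
    the earliest STOP wins, efficiency breaks ties.  With
    ``by_codon_first=False`` the category dominates instead.
    """
    params = params or EfficiencyParams()

    def key(c: StopCandidate):
        s = score_candidate(c, params)
        if by_codon_first:
            return (c.codon_index, -s.sort_key[0], -s.sort_key[1], -s.sort_key[2], c.protospacer.genomic_start)
        return (-s.sort_key[0], c.codon_index, -s.sort_key[1], -s.sort_key[2], c.protospacer.genomic_start)

    return sorted(candidates, key=key)
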