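"""Spontaneous reversion statistics for engineered STOP codons.

With a per-base per-generation mutation frequency z, a TAA STOP reverts to
a sense codon with probability P1 = (1 + 2/3 + 2/3)·z: any change of the
first base gives a sense codon, while only two of the three changes at each
of the second and third positions do (the third re-creates a STOP).  TAG
and TGA each revert with P2 = (1 + 1 + 2/3)·z.  Since roughly half of all
STOP codons are TAA, the average reversion probability is 2.5·z, and n
independent STOPs in the same ORF revert together with (2.5·z)^n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STOP_CODONS = {"TAA", "TAG", "TGA"}

_FACTORS = {
    "TAA": 1 + 2 / 3 + 2 / 3,  # 7/3
    "TAG": 1 + 1 + 2 / 3,      # 8/3
    "TGA": 1 + 1 + 2 / 3,      # 8/3
}


@dataclass(frozen=True)
class ReversionModel:
    """z and the STOP-codon composition assumed by the mean."""

    z: float = 1e-9
    stop_fractions: dict = field(default_factory=lambda: {"TAA": 0.5, "TAG+TGA": 0.5})

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("mutation frequency z must be positive")
        if abs(sum(self.stop_fractions.values()) - 1.0) > 1e-12:
            raise ValueError("stop_fractions must sum to 1")


def single_stop_reversion(stop_codon: str, z: float = 1e-9) -> float:
    """Per-generation probability that one STOP codon reverts to sense."""
    codon = stop_codon.upper().replace("U", "T")
    if codon not in STOP_CODONS:
        raise ValueError(f"{stop_codon!r} is not a STOP codon")
    return _FACTORS[codon] * z


def mean_reversion(z: float = 1e-9) -> float:
    """Average reversion probability over the STOP-codon composition: 2.5·z."""
    return 0.5 * _FACTORS["TAA"] * z + 0.5 * _FACTORS["TAG"] * z


def multi_stop_reversion(n_stops: int, z: float = 1e-9) -> float:
    """Probability that n independent STOPs in one ORF all revert: (2.5·z)^n."""
    if not isinstance(n_stops, int) or n_stops < 1:
        raise ValueError("n_stops must be an integer >= 1")
    return mean_reversion(z) ** n_stops
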