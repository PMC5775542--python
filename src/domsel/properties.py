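"""Amino-acid property partitions and the radical/conservative call.

A substitution is *radical* when the two amino acids fall into different
categories under at least one enabled property partition (charge,
polarity or volume by default), and *conservative* otherwise.  The
default category memberships follow common published conventions and are
fully configurable, since different classification schemes exist in the
literature.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codes import AMINO_ACIDS

RADICAL = "RADICAL"
CONSERVATIVE = "CONSERVATIVE"
SYNONYMOUS = "SYNONYMOUS"


@dataclass(frozen=True)
class PropertyScheme:
    """Named partition of the 20 amino acids into >= 2 categories."""

    name: str
    categories: tuple  # tuple of (category_name, frozenset of residues)

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError(f"{self.name}: need at least 2 categories")
        seen = set()
        for _, members in self.categories:
            if seen & members:
                raise ValueError(f"{self.name}: categories overlap")
            seen |= members
        if seen != set(AMINO_ACIDS):
            raise ValueError(
                f"{self.name}: categories must tile the 20 amino acids "
                f"(missing {set(AMINO_ACIDS) - seen}, extra {seen - set(AMINO_ACIDS)})")

    def category_of(self, aa: str) -> str:
        for cname, members in self.categories:
            if aa in members:
                return cname
        raise ValueError(f"non-standard amino acid {aa!r}")

    @classmethod
    def from_dict(cls, name: str, mapping: dict) -> "PropertyScheme":
        return cls(name, tuple((k, frozenset(v)) for k, v in mapping.items()))


CHARGE = PropertyScheme.from_dict("CHARGE", {
    "positive": "RHK",
    "negative": "DE",
    "neutral": "ANCQGILMFPSTWYV",
})

POLARITY = PropertyScheme.from_dict("POLARITY", {
    "polar": "RNDCQEHKSTWY",
    "nonpolar": "AGILMFPV",
})

VOLUME = PropertyScheme.from_dict("VOLUME", {
    "small": "AGSCDNPTV",
    "large": "REQHILKMFWY",
})

DEFAULT_SCHEMES = (CHARGE, POLARITY, VOLUME)


def classify_change(from_aa: str, to_aa: str,
                    schemes=DEFAULT_SCHEMES) -> str:
    """RADICAL iff the pair crosses categories under any enabled scheme."""
    if from_aa == to_aa:
        raise ValueError(f"identical amino acids ({from_aa})")
    if not schemes:
        raise ValueError("need at least one property scheme")
    for aa in (from_aa, to_aa):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard amino acid {aa!r}")
    for scheme in schemes:
        if scheme.category_of(from_aa) != scheme.category_of(to_aa):
            return RADICAL
    return CONSERVATIVE
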