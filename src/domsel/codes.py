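"""Genetic code tables and codon-level helpers.

The codon substitution machinery works on the 61 sense codons of the
standard nuclear genetic code.  Stop codons are excluded from the state
space; alignments containing in-frame stops are rejected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

NUCLEOTIDES = "TCAG"

# Standard genetic code, TCAG order (the classical codon-table layout).
_STANDARD_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map together with its ordered sense codons."""

    codon_to_aa: dict = field(repr=False)
    sense_codons: tuple = field(repr=False)

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 codons")
        stops = [c for c, aa in self.codon_to_aa.items() if aa == "*"]
        if len(self.sense_codons) != 64 - len(stops):
            raise ValueError("sense codon list inconsistent with stop set")

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        return self._codon_index[codon]

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    @property
    def _codon_index(self) -> dict:
        idx = self.__dict__.get("_idx_cache")
        if idx is None:
            idx = {c: i for i, c in enumerate(self.sense_codons)}
            object.__setattr__(self, "_idx_cache", idx)
        return idx

    @property
    def aa_of_state(self) -> tuple:
        """Amino acid of each sense-codon state, in state order."""
        cached = self.__dict__.get("_aa_cache")
        if cached is None:
            cached = tuple(self.codon_to_aa[c] for c in self.sense_codons)
            object.__setattr__(self, "_aa_cache", cached)
        return cached


def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons)."""
    codon_to_aa = {}
    for i, (n1, n2, n3) in enumerate(product(NUCLEOTIDES, repeat=3)):
        codon_to_aa[n1 + n2 + n3] = _STANDARD_AA[i]
    sense = tuple(c for c in codon_to_aa if codon_to_aa[c] != "*")
    return GeneticCode(codon_to_aa=codon_to_aa, sense_codons=sense)


STANDARD_CODE = standard_code()
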