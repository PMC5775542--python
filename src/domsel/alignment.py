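"""In-frame codon alignments and codon-frequency estimation.

A :class:`CodonAlignment` holds one gene's aligned coding sequences.  The
unit of analysis is the codon column; codons containing gaps or ambiguous
bases are treated as fully missing data downstream (their likelihood
contribution sums over all sense codons), so no column is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import NUCLEOTIDES, GeneticCode, STANDARD_CODE

MISSING = -1  # state code for a gapped/ambiguous codon

_VALID_BASES = frozenset("ACGT")


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences for one gene.

    Parameters
    ----------
    gene_id :
        Identifier used in all per-gene output tables.
    taxa :
        Ordered, unique sequence names.
    sequences :
        Upper-case DNA strings, one per taxon, equal length, length a
        multiple of 3, no in-frame stop codons.
    """

    gene_id: str
    taxa: list
    sequences: list
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError(f"{self.gene_id}: {len(self.taxa)} taxa but "
                             f"{len(self.sequences)} sequences")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.gene_id}: duplicate taxon names")
        if not self.sequences:
            raise ValueError(f"{self.gene_id}: empty alignment")
        length = len(self.sequences[0])
        for name, seq in zip(self.taxa, self.sequences):
            if len(seq) != length:
                raise ValueError(
                    f"{self.gene_id}/{name}: length {len(seq)} != {length}")
            if len(seq) % 3:
                raise ValueError(
                    f"{self.gene_id}/{name}: length {len(seq)} not a multiple of 3")
        for name, seq in zip(self.taxa, self.sequences):
            for i in range(0, length, 3):
                codon = seq[i:i + 3]
                if set(codon) <= _VALID_BASES and self.code.is_stop(codon):
                    raise ValueError(
                        f"{self.gene_id}/{name}: in-frame stop codon "
                        f"{codon} at codon column {i // 3 + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codon(self, taxon_idx: int, col: int) -> str:
        return self.sequences[taxon_idx][3 * col:3 * col + 3]

    def state_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) array of sense-codon state indices.

        Codons containing gaps or ambiguity codes map to ``MISSING``.
        """
        mat = np.empty((self.n_taxa, self.n_codons), dtype=np.int32)
        index = self.code.index
        for t, seq in enumerate(self.sequences):
            for c in range(self.n_codons):
                codon = seq[3 * c:3 * c + 3]
                if set(codon) <= _VALID_BASES:
                    mat[t, c] = index(codon)
                else:
                    mat[t, c] = MISSING
        return mat


def codon_frequencies(aln: CodonAlignment, model: str = "F3X4") -> np.ndarray:
    """Estimate sense-codon stationary frequencies from an alignment.

    ``EQUAL`` gives the flat 1/61 vector; ``F1X4`` builds codon
    frequencies from overall nucleotide frequencies; ``F3X4`` uses
    position-within-codon specific nucleotide frequencies.  Stop codons
    are excluded and the vector renormalised over the sense codons.
    """
    code = aln.code
    n = code.n_states
    if model == "EQUAL":
        return np.full(n, 1.0 / n)

    # position-specific nucleotide counts with a unit pseudocount so no
    # frequency is exactly zero (a zero stationary frequency makes the
    # chain reducible)
    counts = np.ones((3, 4))
    base_idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    for seq in aln.sequences:
        for i, base in enumerate(seq):
            j = base_idx.get(base)
            if j is not None:
                counts[i % 3, j] += 1
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    if model == "F1X4":
        overall = counts.sum(axis=0) / counts.sum()
        pos_freqs = np.tile(overall, (3, 1))
    elif model != "F3X4":
        raise ValueError(f"unknown frequency model {model!r}")

    freqs = np.array([
        pos_freqs[0, base_idx[c[0]]]
        * pos_freqs[1, base_idx[c[1]]]
        * pos_freqs[2, base_idx[c[2]]]
        for c in code.sense_codons
    ])
    return freqs / freqs.sum()
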