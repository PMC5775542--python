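"""Counting-method Ka/Ks for a sequence pair (Nei-Gojobori style).

This is an independent, model-free cross-check for the maximum-likelihood
omega estimates: per-codon synonymous/nonsynonymous site fractions,
pathway-averaged difference counts between codon pairs, and a
Jukes-Cantor multiple-hit correction.  Mutation pathways passing through
stop codons are excluded; a proportion of differences >= 3/4 saturates
the correction and the corresponding rate is returned as NaN with a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .codes import NUCLEOTIDES, GeneticCode, STANDARD_CODE


@dataclass
class KaKsResult:
    ka: float
    ks: float
    nonsyn_sites: float
    syn_sites: float
    nonsyn_diffs: float
    syn_diffs: float
    ka_saturated: bool = False
    ks_saturated: bool = False


def _codon_site_fractions(codon: str, code: GeneticCode) -> tuple:
    """(synonymous sites, nonsynonymous sites) of one codon.

    Each position contributes the fraction of its non-stop single-base
    changes that are synonymous; the three positions sum to 3 sites.
    """
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:]
                for b in NUCLEOTIDES if b != codon[pos]]
        alts = [c for c in alts if not code.is_stop(c)]
        if alts:
            syn += sum(code.translate(c) == code.translate(codon)
                       for c in alts) / len(alts)
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str, code: GeneticCode) -> tuple:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All orderings of the differing positions are enumerated; orderings
    passing through a stop codon are discarded (all orderings are kept
    if every one is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
                break
            steps.append(code.translate(cur) == code.translate(nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # all pathways hit a stop; fall back to counting through
        for order in permutations(diff_pos):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                steps.append(code.translate(cur) == code.translate(nxt))
                cur = nxt
            paths.append(steps)
    syn = sum(sum(steps) for steps in paths) / len(paths)
    return syn, len(diff_pos) - syn


def _jukes_cantor(p: float) -> tuple:
    """JC-corrected distance and saturation flag for a proportion p."""
    if p >= 0.75:
        return math.nan, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def counting_kaks(seq_a: str, seq_b: str,
                  code: GeneticCode = STANDARD_CODE) -> KaKsResult:
    """Nei-Gojobori Ka and Ks for one in-frame pair of coding sequences.

    Codons containing gaps or ambiguity codes in either sequence are
    skipped entirely (sites and differences).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3:
        raise ValueError(f"length {len(seq_a)} is not a multiple of 3")
    valid = set("ACGT")

    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for i in range(0, len(seq_a), 3):
        c1, c2 = seq_a[i:i + 3], seq_b[i:i + 3]
        if not (set(c1) <= valid and set(c2) <= valid):
            continue
        if code.is_stop(c1) or code.is_stop(c2):
            raise ValueError(f"in-frame stop codon at position {i + 1}")
        s1, n1 = _codon_site_fractions(c1, code)
        s2, n2 = _codon_site_fractions(c2, code)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = _pathway_diffs(c1, c2, code)
        s_diffs += sd
        n_diffs += nd

    if s_sites <= 0 or n_sites <= 0:
        raise ValueError("no usable codons in the pair")
    ks, ks_sat = _jukes_cantor(s_diffs / s_sites)
    ka, ka_sat = _jukes_cantor(n_diffs / n_sites)
    return KaKsResult(ka=ka, ks=ks, nonsyn_sites=n_sites, syn_sites=s_sites,
                      nonsyn_diffs=n_diffs, syn_diffs=s_diffs,
                      ka_saturated=ka_sat, ks_saturated=ks_sat)
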