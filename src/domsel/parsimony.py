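"""Parsimony assignment of substitutions to branches.

Per codon column, substitutions are placed on branches by unit-cost
(Fitch) parsimony: nonsynonymous events are reconstructed over amino
acids, and synonymous events over codons at columns whose observed amino
acids are invariant.  When several equally parsimonious ancestral
labelings exist, every minimum-change labeling is counted and each
branch change receives the fraction of optimal labelings in which it
occurs, so per-column weights always sum to the parsimony score.

The tie-splitting weights are computed exactly by dynamic programming:
a downward (Sankoff-style) pass computes per-subtree minimum costs and
optimal-labeling counts, an upward pass computes the same quantities for
the complement of each subtree, and joining the two across a branch
yields the number of optimal labelings realising each (parent state,
child state) pair on that branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iproduct

import numpy as np

from .alignment import MISSING, CodonAlignment
from .codes import GeneticCode, STANDARD_CODE
from .properties import (CONSERVATIVE, DEFAULT_SCHEMES, RADICAL, SYNONYMOUS,
                         classify_change)
from .trees import DOMESTIC, WILD, TaggedTree

_INF = np.inf


@dataclass
class BranchSubstitution:
    branch_id: str
    site: int                  # 1-based codon column
    from_aa: str               # amino acids (nonsyn) or codons (syn)
    to_aa: str
    is_nonsynonymous: bool
    weight: float
    classification: str = ""

    def __post_init__(self):
        if not 0.0 < self.weight <= 1.0 + 1e-12:
            raise ValueError(f"weight {self.weight} outside (0, 1]")
        if self.is_nonsynonymous and self.from_aa == self.to_aa:
            raise ValueError("nonsynonymous change with identical amino acids")


@dataclass
class LineageMutationCounts:
    """Weighted substitution totals per branch class, additive over genes."""

    counts: dict = field(default_factory=lambda: {
        cls: {RADICAL: 0.0, CONSERVATIVE: 0.0, SYNONYMOUS: 0.0}
        for cls in (WILD, DOMESTIC)})

    def add(self, branch_class: str, classification: str, weight: float):
        self.counts[branch_class][classification] += weight

    def get(self, branch_class: str, classification: str) -> float:
        return self.counts[branch_class][classification]

    def nonsynonymous_total(self, branch_class: str) -> float:
        c = self.counts[branch_class]
        return c[RADICAL] + c[CONSERVATIVE]

    def __add__(self, other: "LineageMutationCounts") -> "LineageMutationCounts":
        out = LineageMutationCounts()
        for cls in (WILD, DOMESTIC):
            for kind in (RADICAL, CONSERVATIVE, SYNONYMOUS):
                out.counts[cls][kind] = self.counts[cls][kind] + other.counts[cls][kind]
        return out


def _column_change_weights(tree: TaggedTree, leaf_states: dict) -> dict:
    """Expected change count per (branch, from_state, to_state) over all
    minimum-change labelings, weighting each optimal labeling equally.

    ``leaf_states`` maps leaf branch_id -> state index or None (missing).
    State space is the set of observed states; missing leaves may take
    any observed state at no cost.  Returns {} for <2 observed states.
    """
    observed = sorted({s for s in leaf_states.values() if s is not None})
    k = len(observed)
    if k < 2:
        return {}
    state_pos = {s: i for i, s in enumerate(observed)}

    post = tree.postorder()
    down_cost = {}
    down_count = {}
    # per (parent, child): edge-minimised child cost/count as seen from a
    # given parent state, reused by the upward pass
    edge_min_cost = {}
    edge_min_count = {}

    for node in post:
        if node.is_leaf:
            cost = np.full(k, _INF)
            count = np.zeros(k)
            s = leaf_states[node.branch_id]
            if s is None:
                cost[:] = 0.0
                count[:] = 1.0
            else:
                cost[state_pos[s]] = 0.0
                count[state_pos[s]] = 1.0
        else:
            cost = np.zeros(k)
            count = np.ones(k)
            for child in node.children:
                cc, cn = down_cost[id(child)], down_count[id(child)]
                best_any = cc.min()
                m = np.minimum(cc, best_any + 1.0)   # unit-cost Fitch step
                cnt = np.zeros(k)
                for a in range(k):
                    match = cc + (np.arange(k) != a) - m[a]
                    cnt[a] = cn[np.abs(match) < 1e-9].sum()
                edge_min_cost[(id(node), id(child))] = m
                edge_min_count[(id(node), id(child))] = cnt
                cost = cost + m
                count = count * cnt
        down_cost[id(node)] = cost
        down_count[id(node)] = count

    root = tree.root
    total_cost = down_cost[id(root)].min()
    opt = np.abs(down_cost[id(root)] - total_cost) < 1e-9
    total_count = down_count[id(root)][opt].sum()

    # upward pass: cost/count of the tree minus subtree(v), conditioned on
    # the state of v's parent (comp_*), then on the state of v (above_*)
    comp_cost = {}
    comp_count = {}
    above_cost = {id(root): np.zeros(k)}
    above_count = {id(root): np.ones(k)}
    for node in tree.preorder():
        for child in node.children:
            cc = above_cost[id(node)].copy()
            cn = above_count[id(node)].copy()
            for sib in node.children:
                if sib is child:
                    continue
                cc = cc + edge_min_cost[(id(node), id(sib))]
                cn = cn * edge_min_count[(id(node), id(sib))]
            comp_cost[id(child)] = cc       # conditioned on parent state
            comp_count[id(child)] = cn
            # fold the parent->child edge to condition on the child state
            ac = np.full(k, _INF)
            an = np.zeros(k)
            for b in range(k):
                tot = cc + (np.arange(k) != b)
                m = tot.min()
                ac[b] = m
                an[b] = cn[np.abs(tot - m) < 1e-9].sum()
            above_cost[id(child)] = ac
            above_count[id(child)] = an

    weights = {}
    for node in tree.branches:
        cc, cn = comp_cost[id(node)], comp_count[id(node)]
        dc, dn = down_cost[id(node)], down_count[id(node)]
        for a in range(k):
            for b in range(k):
                if a == b:
                    continue
                total = cc[a] + 1.0 + dc[b]
                if abs(total - total_cost) < 1e-9:
                    n_opt = cn[a] * dn[b]
                    if n_opt > 0:
                        key = (node.branch_id, observed[a], observed[b])
                        weights[key] = weights.get(key, 0.0) + n_opt / total_count
    return weights


def assign_branch_substitutions(aln: CodonAlignment, tree: TaggedTree,
                                code: GeneticCode = STANDARD_CODE,
                                ) -> list:
    """Parsimony substitution assignment for every codon column of a gene.

    Returns unclassified :class:`BranchSubstitution` records; synonymous
    records carry the two codons in the from/to fields.
    """
    tree.check_taxa(aln.taxa)
    states = aln.state_matrix()
    taxon_row = {name: i for i, name in enumerate(aln.taxa)}
    aa_of = code.aa_of_state
    aa_index = {}
    subs = []

    for col in range(aln.n_codons):
        codon_states = {}
        for leaf in tree.leaves:
            s = states[taxon_row[leaf.name], col]
            codon_states[leaf.branch_id] = None if s == MISSING else int(s)
        observed = {s for s in codon_states.values() if s is not None}
        if len(observed) < 2:
            continue
        observed_aa = {aa_of[s] for s in observed}

        if len(observed_aa) > 1:
            # nonsynonymous events: parsimony over amino acids
            aa_states = {
                bid: (None if s is None
                      else aa_index.setdefault(aa_of[s], len(aa_index)))
                for bid, s in codon_states.items()}
            aa_name = {v: k for k, v in aa_index.items()}
            for (bid, a, b), w in _column_change_weights(tree, aa_states).items():
                subs.append(BranchSubstitution(
                    branch_id=bid, site=col + 1,
                    from_aa=aa_name[a], to_aa=aa_name[b],
                    is_nonsynonymous=True, weight=w))
        else:
            # amino-acid invariant column: synonymous events over codons
            for (bid, a, b), w in _column_change_weights(tree, codon_states).items():
                subs.append(BranchSubstitution(
                    branch_id=bid, site=col + 1,
                    from_aa=code.sense_codons[a], to_aa=code.sense_codons[b],
                    is_nonsynonymous=False, weight=w))
    return subs


def count_lineage_mutations(subs: list, tree: TaggedTree,
                            schemes=DEFAULT_SCHEMES) -> LineageMutationCounts:
    """Classify substitutions and total their weights per branch class."""
    class_of = {node.branch_id: node.branch_class for node in tree.branches}
    out = LineageMutationCounts()
    for sub in subs:
        if sub.branch_id not in class_of:
            raise ValueError(f"unknown branch id {sub.branch_id!r}")
        if sub.is_nonsynonymous:
            kind = classify_change(sub.from_aa, sub.to_aa, schemes)
        else:
            kind = SYNONYMOUS
        sub.classification = kind
        out.add(class_of[sub.branch_id], kind, sub.weight)
    return out
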