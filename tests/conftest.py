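"""Shared fixtures: tiny alignments, tagged trees and oracle helpers."""

import itertools

import numpy as np
import pytest

from domsel import (CodonAlignment, CodonModelParams, STANDARD_CODE,
                    TaggedTree, transition_matrix)
from domsel.trees import WILD, DOMESTIC


@pytest.fixture
def equal_freqs():
    n = STANDARD_CODE.n_states
    return np.full(n, 1.0 / n)


@pytest.fixture
def simple_params(equal_freqs):
    return CodonModelParams(kappa=2.0,
                            omega_by_class={WILD: 0.5, DOMESTIC: 0.5},
                            codon_freqs=equal_freqs, freq_model="EQUAL")


@pytest.fixture
def four_taxon_tree():
    return TaggedTree.from_newick(
        "((w1:0.1,w2:0.1):0.05,(d1 #1:0.1,d2 #1:0.1) #1:0.05);")


@pytest.fixture
def four_taxon_alignment():
    return CodonAlignment(
        "toy", ["w1", "w2", "d1", "d2"],
        ["ATGAAATTGGCT", "ATGAAATTGGCT", "ATGAAGTTGGCT", "ATGCAATTGGCA"])


def brute_force_lnl(aln, tree, params):
    """Exhaustive ancestral-state summation likelihood (tiny trees only).

    Independent of the pruning engine: enumerates every assignment of
    sense codons to internal nodes and multiplies branch transition
    probabilities computed one matrix exponential at a time.
    """
    code = aln.code
    n = code.n_states
    states = aln.state_matrix()
    taxon_row = {name: i for i, name in enumerate(aln.taxa)}
    internals = [nd for nd in tree.postorder() if not nd.is_leaf]
    assert len(internals) <= 3, "oracle is exponential in internal nodes"
    P = {id(nd): transition_matrix(params, nd.branch_class, nd.length)
         for nd in tree.branches}

    # every assignment of sense codons to internal nodes, as index columns
    grid = np.array(list(itertools.product(range(n), repeat=len(internals))))
    slot = {id(nd): k for k, nd in enumerate(internals)}

    total = 0.0
    for col in range(aln.n_codons):
        like = params.codon_freqs[grid[:, slot[id(tree.root)]]].copy()
        for nd in tree.branches:
            parent = _parent(tree, nd)
            parent_states = grid[:, slot[id(parent)]]
            if nd.is_leaf:
                child = states[taxon_row[nd.name], col]
                if child == -1:      # missing codon: marginalise (factor 1)
                    continue
                like *= P[id(nd)][parent_states, child]
            else:
                like *= P[id(nd)][parent_states, grid[:, slot[id(nd)]]]
        total += np.log(like.sum())
    return total


def _parent(tree, node):
    for cand in tree.preorder():
        if node in cand.children:
            return cand
    raise AssertionError("node not in tree")
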