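"""Parsimony substitution assignment and radical/conservative counting."""

import itertools

import numpy as np
import pytest

from domsel import (CodonAlignment, STANDARD_CODE, TaggedTree,
                    assign_branch_substitutions, count_lineage_mutations,
                    classify_change, simulate_alignment)
from domsel.parsimony import (CONSERVATIVE, RADICAL, SYNONYMOUS,
                              LineageMutationCounts, _column_change_weights)
from domsel.properties import DEFAULT_SCHEMES
from domsel.simulate import SimulationConfig
from domsel.trees import DOMESTIC, WILD
from domsel.codes import AMINO_ACIDS


def brute_force_weights(tree, leaf_states):
    """Average per-branch change indicators over all minimum-change
    labelings, enumerating internal (and missing-leaf) states directly."""
    observed = sorted({s for s in leaf_states.values() if s is not None})
    if len(observed) < 2:
        return {}, 0
    nodes = tree.preorder()
    free = [n for n in nodes
            if (n.is_leaf and leaf_states[n.branch_id] is None)
            or not n.is_leaf]
    best, labelings = None, []
    for assign in itertools.product(observed, repeat=len(free)):
        state = {id(n): a for n, a in zip(free, assign)}
        for n in nodes:
            if n.is_leaf and leaf_states[n.branch_id] is not None:
                state[id(n)] = leaf_states[n.branch_id]
        cost, changes = 0, []
        stack = [tree.root]
        while stack:
            u = stack.pop()
            for c in u.children:
                if state[id(u)] != state[id(c)]:
                    cost += 1
                    changes.append((c.branch_id, state[id(u)], state[id(c)]))
                stack.append(c)
        if best is None or cost < best:
            best, labelings = cost, [changes]
        elif cost == best:
            labelings.append(changes)
    weights = {}
    for changes in labelings:
        for key in changes:
            weights[key] = weights.get(key, 0.0) + 1.0 / len(labelings)
    return weights, best


class TestChangeWeights:
    @pytest.mark.parametrize("newick", [
        "(a:1,b:1,c:1);",
        "((a:1,b:1):1,(c:1,d:1):1);",
        "((a:1,b:1):1,c:1,d:1);",
        "(a:1,(b:1,(c:1,d:1):1):1);",
    ])
    def test_matches_brute_force_on_random_columns(self, newick):
        tree = TaggedTree.from_newick(newick)
        rng = np.random.default_rng(hash(newick) % 2**31)
        for _ in range(40):
            leaf_states = {}
            for name in tree.leaf_names:
                draw = rng.integers(0, 5)
                leaf_states[name] = None if draw == 4 else int(draw)
            got = _column_change_weights(tree, leaf_states)
            expected, score = brute_force_weights(tree, leaf_states)
            assert set(got) == set(expected)
            for key in expected:
                assert got[key] == pytest.approx(expected[key], abs=1e-9)
            assert sum(got.values()) == pytest.approx(score, abs=1e-9)

    def test_invariant_column_yields_nothing(self):
        tree = TaggedTree.from_newick("(a:1,b:1,c:1);")
        assert _column_change_weights(tree, {"a": 3, "b": 3, "c": 3}) == {}

    def test_three_taxon_star_single_change(self):
        # column (K, K, E): one K<->E change on the E branch, weight 1
        tree = TaggedTree.from_newick("(a:1,b:1,c:1);")
        got = _column_change_weights(tree, {"a": 0, "b": 0, "c": 1})
        assert got == {("c", 0, 1): pytest.approx(1.0)}


class TestAssignSubstitutions:
    def test_star_column_example(self):
        tree = TaggedTree.from_newick("(a:1,b:1,c #1:1);")
        aln = CodonAlignment("g", ["a", "b", "c"],
                             ["AAA", "AAA", "GAA"])  # K, K, E
        subs = assign_branch_substitutions(aln, tree)
        assert len(subs) == 1
        sub = subs[0]
        assert (sub.branch_id, sub.from_aa, sub.to_aa) == ("c", "K", "E")
        assert sub.weight == pytest.approx(1.0)
        assert sub.is_nonsynonymous

    def test_synonymous_only_at_invariant_aa_columns(self):
        tree = TaggedTree.from_newick("(a:1,b:1,c #1:1);")
        aln = CodonAlignment("g", ["a", "b", "c"],
                             ["GGA", "GGA", "GGG"])  # all glycine
        subs = assign_branch_substitutions(aln, tree)
        assert len(subs) == 1
        assert not subs[0].is_nonsynonymous
        assert {subs[0].from_aa, subs[0].to_aa} == {"GGA", "GGG"}

    def test_all_missing_column_contributes_nothing(self):
        tree = TaggedTree.from_newick("(a:1,b:1,c #1:1);")
        aln = CodonAlignment("g", ["a", "b", "c"], ["---", "---", "---"])
        assert assign_branch_substitutions(aln, tree) == []

    def test_counts_additive_over_genes(self):
        tree = TaggedTree.from_newick("((w1:1,w2:1):1,(d1 #1:1,d2 #1:1) #1:1);")
        a1 = CodonAlignment("g1", ["w1", "w2", "d1", "d2"],
                            ["AAAGGA", "AAAGGA", "GAAGGA", "GAAGGG"])
        a2 = CodonAlignment("g2", ["w1", "w2", "d1", "d2"],
                            ["TTATCA", "TTGTCA", "TTATCA", "TTATCA"])
        concat = CodonAlignment("g12", ["w1", "w2", "d1", "d2"], [
            s1 + s2 for s1, s2 in zip(a1.sequences, a2.sequences)])
        sep = (count_lineage_mutations(
                   assign_branch_substitutions(a1, tree), tree)
               + count_lineage_mutations(
                   assign_branch_substitutions(a2, tree), tree))
        joint = count_lineage_mutations(
            assign_branch_substitutions(concat, tree), tree)
        for cls in (WILD, DOMESTIC):
            for kind in (RADICAL, CONSERVATIVE, SYNONYMOUS):
                assert sep.get(cls, kind) == pytest.approx(
                    joint.get(cls, kind), abs=1e-12)

    def test_radical_plus_conservative_equals_nonsynonymous(self):
        aln, tree, _ = simulate_alignment(SimulationConfig(
            omega_W=0.5, omega_D=0.8, n_codons=200, seed=33, gene_id="c"))
        subs = assign_branch_substitutions(aln, tree)
        counts = count_lineage_mutations(subs, tree)
        for cls in (WILD, DOMESTIC):
            nonsyn_weight = sum(s.weight for s in subs
                                if s.is_nonsynonymous and
                                _cls_of(tree, s.branch_id) == cls)
            assert (counts.get(cls, RADICAL) + counts.get(cls, CONSERVATIVE)
                    == pytest.approx(nonsyn_weight, abs=1e-9))

    def test_correlates_with_true_history(self):
        # parsimony counts per class should track the logged truth
        truth_nonsyn, inferred_nonsyn = [], []
        for seed in range(30):
            aln, tree, hist = simulate_alignment(SimulationConfig(
                omega_W=0.4, omega_D=0.7, n_codons=150, seed=1000 + seed,
                gene_id=f"g{seed}"))
            cls_of = {n.branch_id: n.branch_class for n in tree.branches}
            counts = count_lineage_mutations(
                assign_branch_substitutions(aln, tree), tree)
            for cls in (WILD, DOMESTIC):
                truth_nonsyn.append(sum(
                    1 for e in hist.events
                    if not e.synonymous and cls_of[e.branch_id] == cls))
                inferred_nonsyn.append(counts.nonsynonymous_total(cls))
        r = np.corrcoef(truth_nonsyn, inferred_nonsyn)[0, 1]
        assert r > 0.9

    def test_unknown_branch_id_rejected(self):
        tree = TaggedTree.from_newick("(a:1,b:1,c #1:1);")
        from domsel.parsimony import BranchSubstitution
        bad = BranchSubstitution("zz", 1, "K", "E", True, 1.0)
        with pytest.raises(ValueError, match="unknown branch"):
            count_lineage_mutations([bad], tree)


def _cls_of(tree, branch_id):
    for n in tree.branches:
        if n.branch_id == branch_id:
            return n.branch_class
    raise KeyError(branch_id)


class TestClassifyChange:
    def test_conservative_within_all_categories(self):
        assert classify_change("K", "R") == CONSERVATIVE

    def test_radical_across_charge(self):
        assert classify_change("D", "K") == RADICAL

    def test_symmetric(self):
        for a, b in [("A", "G"), ("D", "K"), ("F", "S"), ("K", "R")]:
            assert classify_change(a, b) == classify_change(b, a)

    def test_every_distinct_pair_classified(self):
        for a, b in itertools.combinations(AMINO_ACIDS, 2):
            assert classify_change(a, b) in (RADICAL, CONSERVATIVE)

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError):
            classify_change("A", "A")

    def test_nonstandard_symbol_rejected(self):
        with pytest.raises(ValueError):
            classify_change("A", "B")
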