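"""Event-level codon simulation and study generation."""

import numpy as np
import pytest

from domsel import (STANDARD_CODE, build_rate_matrix, simulate_alignment,
                    simulate_study)
from domsel.codon_model import CodonModelParams, _pair_structure
from domsel.simulate import SimulationConfig, StudyConfig, build_study_tree
from domsel.trees import DOMESTIC, WILD


class TestSimulateAlignment:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(omega_W=0.3, omega_D=0.7, n_codons=60, seed=4)
        a1, _, h1 = simulate_alignment(cfg)
        a2, _, h2 = simulate_alignment(cfg)
        assert a1.sequences == a2.sequences
        assert [(e.branch_id, e.site, e.from_codon, e.to_codon)
                for e in h1.events] == \
               [(e.branch_id, e.site, e.from_codon, e.to_codon)
                for e in h2.events]

    def test_different_seed_differs(self):
        a1, _, _ = simulate_alignment(SimulationConfig(n_codons=200, seed=1))
        a2, _, _ = simulate_alignment(SimulationConfig(n_codons=200, seed=2))
        assert a1.sequences != a2.sequences

    def test_omega_zero_suppresses_domestic_nonsynonymous_events(self):
        cfg = SimulationConfig(omega_W=0.5, omega_D=0.0, n_codons=150, seed=6)
        _, tree, hist = simulate_alignment(cfg)
        cls_of = {n.branch_id: n.branch_class for n in tree.branches}
        dom_nonsyn = [e for e in hist.events
                      if cls_of[e.branch_id] == DOMESTIC and not e.synonymous]
        assert dom_nonsyn == []
        assert any(cls_of[e.branch_id] == DOMESTIC for e in hist.events)

    def test_event_log_reconstructs_leaf_sequences(self):
        cfg = SimulationConfig(omega_W=0.4, omega_D=0.9, n_codons=80, seed=12)
        aln, tree, hist = simulate_alignment(cfg)
        idx = {name: i for i, name in enumerate(aln.taxa)}

        def walk(node, states):
            states = states.copy()
            for e in hist.events_on(node.branch_id):
                assert STANDARD_CODE.sense_codons[states[e.site - 1]] == \
                    e.from_codon
                states[e.site - 1] = STANDARD_CODE.index(e.to_codon)
            if node.is_leaf:
                seq = "".join(STANDARD_CODE.sense_codons[s] for s in states)
                assert seq == aln.sequences[idx[node.name]]
            for child in node.children:
                walk(child, states)

        for child in tree.root.children:
            walk(child, hist.node_states["root"])

    def test_every_event_is_single_nucleotide_change(self):
        _, _, hist = simulate_alignment(SimulationConfig(
            omega_W=0.5, omega_D=1.5, n_codons=100, seed=19))
        assert hist.events
        for e in hist.events:
            diff = sum(a != b for a, b in zip(e.from_codon, e.to_codon))
            assert diff == 1
            syn = (STANDARD_CODE.translate(e.from_codon)
                   == STANDARD_CODE.translate(e.to_codon))
            assert e.synonymous == syn

    def test_nonsynonymous_event_fraction_matches_generator(self):
        # single neutral branch: the nonsynonymous share of events should
        # match the nonsynonymous share of flux in the rate matrix
        cfg = SimulationConfig(n_wild=1, n_domestic=1, branch_length=0.5,
                               kappa=1.0, omega_W=1.0, omega_D=1.0,
                               n_codons=10_000, seed=23)
        _, _, hist = simulate_alignment(cfg)
        pi = np.full(61, 1.0 / 61)
        params = CodonModelParams(kappa=1.0,
                                  omega_by_class={WILD: 1.0, DOMESTIC: 1.0},
                                  codon_freqs=pi, freq_model="EQUAL")
        Q = build_rate_matrix(params, WILD)
        I, J, _, ns = _pair_structure(STANDARD_CODE)
        flux = pi[I] * Q[I, J]
        expected = flux[ns].sum() / flux.sum()
        events = hist.events
        observed = sum(not e.synonymous for e in events) / len(events)
        se = np.sqrt(expected * (1 - expected) / len(events))
        assert abs(observed - expected) < 3 * se

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_wild=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_codons=0)


class TestStudyTree:
    def test_domestic_clade_fully_tagged(self):
        tree = build_study_tree(3, 3, 0.1)
        dom = [n for n in tree.branches if n.branch_class == DOMESTIC]
        wild = [n for n in tree.branches if n.branch_class == WILD]
        # domestic clade: 3 terminal + 1 internal + 1 stem; wild side is
        # opened at the basal trifurcation: 3 terminal + 1 internal
        assert len(dom) == 5 and len(wild) == 4
        assert len(tree.root.children) == 3
        assert sorted(n.name for n in tree.leaves) == \
            ["d1", "d2", "d3", "w1", "w2", "w3"]

    def test_unrooting_collapses_degree_two_root(self):
        from domsel import TaggedTree
        rooted = TaggedTree.from_newick(
            "((w1:0.1,w2:0.1):0.05,(d1 #1:0.1,d2 #1:0.1) #1:0.07);")
        flat = rooted.unrooted()
        assert len(flat.root.children) == 3
        merged = [n for n in flat.branches if not n.is_leaf]
        # merged stem keeps the DOMESTIC tag and the summed length
        assert any(n.branch_class == DOMESTIC
                   and abs(n.length - 0.12) < 1e-12 for n in flat.branches)
        assert flat.total_length() == pytest.approx(rooted.total_length())


class TestSimulateStudy:
    def test_deterministic_and_structured(self):
        cfg = StudyConfig(species_ne={"a": 1e4, "b": 3e4, "c": 1e5},
                          genes_per_species=2, n_codons=30, seed=9)
        b1 = simulate_study(cfg)
        b2 = simulate_study(cfg)
        assert set(b1.species_data) == {"a", "b", "c"}
        for sp in b1.species_data:
            assert len(b1.species_data[sp].alignments) == 2
            assert [a.sequences for a in b1.species_data[sp].alignments] == \
                [a.sequences for a in b2.species_data[sp].alignments]

    def test_effect_map_monotone_in_ne(self):
        cfg = StudyConfig(species_ne={"lo": 1e4, "mid": 3e4, "hi": 1e5},
                          effect_slope=0.5, genes_per_species=1,
                          n_codons=10, seed=1)
        b = simulate_study(cfg)
        assert b.true_effects["lo"] == pytest.approx(0.0)
        assert b.true_effects["lo"] < b.true_effects["mid"] < \
            b.true_effects["hi"]
        assert b.true_effects["hi"] == pytest.approx(0.5)  # 10-fold range

    def test_trm_fraction_controls_contrast(self):
        cfg = StudyConfig(species_ne={"a": 1e4, "b": 3e4, "c": 1e5},
                          fraction_trm=0.0, genes_per_species=5,
                          n_codons=10, seed=2)
        b = simulate_study(cfg)
        for sp in b.species_data.values():
            for h in sp.histories:
                assert h.model == "ORM"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            StudyConfig(species_ne={"a": 1e4, "b": 2e4})
        with pytest.raises(ValueError, match="genes_per_species"):
            StudyConfig(species_ne={"a": 1e4, "b": 2e4, "c": 3e4},
                        genes_per_species=0)
        with pytest.raises(ValueError, match="unidentifiable"):
            StudyConfig(species_ne={"a": 1e4, "b": 1e4, "c": 1e4},
                        effect_slope=0.5)
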