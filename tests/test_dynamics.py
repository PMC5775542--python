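"""Selection-dynamics taxonomy and species-level summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domsel import classify_dynamics, dynamics_table, summarize_species
from domsel.dynamics import (CATEGORIES, IPR, IPS, NON_UN_CATEGORIES, PRT,
                             PST, RPR, RPS, UN, SpeciesSummary)
from domsel.fitting import GeneFitResult
from domsel.parsimony import (CONSERVATIVE, RADICAL, SYNONYMOUS,
                              LineageMutationCounts)
from domsel.trees import DOMESTIC, WILD


def make_result(gene_id, omega_W, omega_D, significant, p=0.01):
    lnl = -100.0
    return GeneFitResult(
        gene_id=gene_id, lnL_ORM=lnl, lnL_TRM=lnl + 5, omega_shared=0.3,
        omega_W=omega_W, omega_D=omega_D, kappa_ORM=2.0, kappa_TRM=2.0,
        lrt_stat=10.0, df=1, p_value=p if significant else 0.9,
        extreme_flag="NONE", significant=significant, converged=True)


def make_counts(d_rad=0.0, d_con=0.0, w_rad=0.0, w_con=0.0):
    c = LineageMutationCounts()
    c.counts[DOMESTIC][RADICAL] = d_rad
    c.counts[DOMESTIC][CONSERVATIVE] = d_con
    c.counts[WILD][RADICAL] = w_rad
    c.counts[WILD][CONSERVATIVE] = w_con
    return c


class TestClassifyDynamics:
    @pytest.mark.parametrize("w,d,expected", [
        (0.2, 0.5, RPR),   # relaxed purifying: 1 > D > W
        (0.5, 0.2, IPR),   # intensified purifying: 1 > W > D
        (1.5, 2.5, IPS),   # intensified positive: D > W > 1
        (2.5, 1.5, RPS),   # relaxed positive: W > D > 1
        (0.5, 1.5, PST),   # purifying -> positive transition
        (1.5, 0.5, PRT),   # positive -> purifying transition
    ])
    def test_six_directions(self, w, d, expected):
        assert classify_dynamics(w, d, significant=True) == expected

    def test_not_significant_is_unchanged(self):
        assert classify_dynamics(0.2, 0.5, significant=False) == UN

    def test_equal_omegas_are_unchanged(self):
        assert classify_dynamics(0.7, 0.7, significant=True) == UN

    def test_omega_at_one_is_unchanged(self):
        assert classify_dynamics(1.0, 0.5, significant=True) == UN
        assert classify_dynamics(0.5, 1.0, significant=True) == UN

    def test_grid_produces_exactly_six_non_un_categories(self):
        grid = [0.2, 0.5, 0.9, 1.1, 2.0, 5.0]
        seen = {classify_dynamics(w, d, significant=True)
                for w, d in itertools.product(grid, grid) if w != d}
        assert seen == set(NON_UN_CATEGORIES)

    def test_non_positive_omega_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamics(0.0, 0.5, significant=True)

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(w=st.floats(0.01, 10.0), d=st.floats(0.01, 10.0))
    def test_taxonomy_tiles_the_plane(self, w, d):
        """Away from ties, exactly one non-UN category's inequalities hold."""
        cat = classify_dynamics(w, d, significant=True, tol=1e-9)
        ties = abs(w - d) <= 1e-9 or abs(w - 1) <= 1e-9 or abs(d - 1) <= 1e-9
        if ties:
            assert cat == UN
        else:
            holds = {
                RPR: 1 > d > w, IPR: 1 > w > d, IPS: d > w > 1,
                RPS: w > d > 1, PST: w < 1 < d, PRT: d < 1 < w}
            assert [c for c, ok in holds.items() if ok] == [cat]


class TestSummarizeSpecies:
    def test_hand_computed_means_and_ratio(self):
        results = [make_result("g1", 0.2, 0.4, True),
                   make_result("g2", 0.5, 0.7, True)]
        counts = [make_counts(), make_counts()]
        s = summarize_species(results, counts, "spA")
        assert s.mean_omega_W == pytest.approx(0.35)
        assert s.mean_omega_D == pytest.approx(0.55)
        assert s.ratio_omega == pytest.approx(11.0 / 7.0)
        assert s.n_genes_significant == 2

    def test_cattle_like_ratio_below_one(self):
        # cattle-like published means (D=185.16, W=200.47) give D/W < 1
        s = SpeciesSummary(species="cattle", n_genes_total=1,
                           n_genes_significant=1,
                           mean_omega_D=185.16, mean_omega_W=200.47,
                           ratio_omega=185.16 / 200.47)
        assert s.ratio_omega == pytest.approx(0.9236, abs=2e-4)
        assert s.ratio_omega < 1

    def test_no_significant_genes_all_undefined(self):
        results = [make_result("g1", 0.2, 0.4, False)]
        counts = [make_counts(d_rad=1.0)]
        s = summarize_species(results, counts, "spB")
        assert {"mean_omega_W", "mean_omega_D", "ratio_omega",
                "ratio_radical", "ratio_conservative"} <= s.undefined
        assert math.isnan(s.metric("ratio_omega"))
        assert s.dynamics_counts[UN] == 1

    def test_count_ratios_from_summed_significant_genes(self):
        results = [make_result("g1", 0.2, 0.4, True),
                   make_result("g2", 0.2, 0.4, False)]
        counts = [make_counts(d_rad=2.0, d_con=1.0, w_rad=1.0, w_con=2.0),
                  make_counts(d_rad=50.0, w_rad=50.0)]  # excluded: not sig.
        s = summarize_species(results, counts, "spC")
        assert s.ratio_radical == pytest.approx(2.0)
        assert s.ratio_conservative == pytest.approx(0.5)

    def test_permutation_invariant(self):
        results = [make_result(f"g{i}", w, d, sig) for i, (w, d, sig) in
                   enumerate([(0.2, 0.4, True), (0.5, 0.3, True),
                              (1.2, 2.0, True), (0.9, 0.9, False)])]
        counts = [make_counts(i, i, i + 1, i + 1) for i in range(4)]
        s1 = summarize_species(results, counts, "spD")
        order = [2, 0, 3, 1]
        s2 = summarize_species([results[i] for i in order],
                               [counts[i] for i in order], "spD")
        assert s1.mean_omega_W == pytest.approx(s2.mean_omega_W)
        assert s1.ratio_radical == pytest.approx(s2.ratio_radical)
        assert s1.dynamics_counts == s2.dynamics_counts

    def test_direction_coherence(self):
        # all-RPR species (D > W below 1) must have ratio_omega > 1
        results = [make_result(f"g{i}", 0.1 * (i + 1), 0.1 * (i + 1) + 0.2,
                               True) for i in range(3)]
        counts = [make_counts()] * 3
        s = summarize_species(results, counts, "spE")
        assert s.ratio_omega > 1


class TestDynamicsTable:
    def test_counting_row(self):
        s = SpeciesSummary(species="x", n_genes_total=3,
                           n_genes_significant=2,
                           dynamics_counts={UN: 1, IPS: 2, PST: 0, RPR: 0,
                                            RPS: 0, IPR: 0, PRT: 0})
        table = dynamics_table([s])
        assert list(table.columns) == ["UN", "PST", "IPS", "RPR", "RPS",
                                       "IPR", "PRT"]
        assert table.loc["x"].tolist() == [1, 0, 2, 0, 0, 0, 0]
        assert table.loc["x"].sum() == s.n_genes_total

    def test_duplicate_species_rejected(self):
        s = SpeciesSummary(species="x", n_genes_total=0,
                           n_genes_significant=0, dynamics_counts={})
        with pytest.raises(ValueError, match="duplicate"):
            dynamics_table([s, s])
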