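"""Exact MSC + JC69 math: densities, likelihood, priors, conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from cardcoal import (
    ConstraintError,
    GeneTree,
    LocusAlignment,
    SpeciesTree,
    coalescent_log_density,
    gamma_log_prior,
    jc69_log_likelihood,
    jc69_transition,
    mtdna_scale,
    ne_from_theta,
    tau_from_years,
    theta_from_ne,
    years_from_tau,
)
from cardcoal.core import GammaPrior


def cherry(age, pops=(0, 0), labels=("x", "y"), pop_names=("A",)):
    return GeneTree(list(labels), [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
                    [0.0, 0.0, age], list(pops), pop_names=list(pop_names))


class TestJC69Transition:
    def test_zero_distance(self):
        ps, pd = jc69_transition(0.0)
        assert ps == 1.0 and pd == 0.0

    def test_stationarity_at_large_distance(self):
        ps, pd = jc69_transition(50.0)
        assert ps == pytest.approx(0.25, abs=1e-12)
        assert pd == pytest.approx(0.25, abs=1e-12)

    def test_total_difference_probability(self):
        _, pd = jc69_transition(0.1)
        assert 3 * pd == pytest.approx(0.09362, abs=5e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            jc69_transition(-0.01)

    @given(st.floats(min_value=0.0, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_rows_sum_to_one(self, d):
        ps, pd = jc69_transition(d)
        assert ps + 3 * pd == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= pd <= 0.25 <= ps <= 1.0


class TestCoalescentDensity:
    def test_single_lineage_is_zero(self, one_pop_tree):
        g = GeneTree(["x"], [-1], [-1], [-1], [0.0], [0], pop_names=["A"])
        assert coalescent_log_density(g, one_pop_tree) == 0.0

    def test_two_lineages_one_population_closed_form(self, one_pop_tree):
        # rate 2/theta = 200; density at t = 200*exp(-200*0.005)
        g = cherry(0.005)
        assert coalescent_log_density(g, one_pop_tree) == pytest.approx(
            math.log(200) - 1.0, abs=1e-12)

    def test_cross_population_closed_form(self, two_pop_tree):
        # one lineage per population; coalescence in the ancestor at 0.006:
        # rate 2/theta_anc = 100 over 0.002 of exposure
        g = cherry(0.006, pops=(0, 1), pop_names=["A", "B", "AB"])
        assert coalescent_log_density(g, two_pop_tree) == pytest.approx(
            math.log(100) - 0.2, abs=1e-12)

    def test_scaler_enters_rate(self, one_pop_tree):
        g = cherry(0.005)
        # theta -> theta/4: rate 800, exposure 800*0.005
        expect = math.log(800) - 4.0
        assert coalescent_log_density(g, one_pop_tree, scaler=0.25) == \
            pytest.approx(expect, abs=1e-12)

    def test_violating_tau_raises_not_minus_inf(self, two_pop_tree):
        g = cherry(0.003, pops=(0, 1), pop_names=["A", "B", "AB"])
        with pytest.raises(ConstraintError):
            coalescent_log_density(g, two_pop_tree)

    def test_two_lineage_density_integrates_to_one(self, one_pop_tree):
        def dens(t):
            g = cherry(t)
            return math.exp(coalescent_log_density(g, one_pop_tree))

        val, _ = integrate.quad(dens, 0, 1.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestJC69Likelihood:
    def test_single_sequence_stationary(self):
        aln = LocusAlignment(ids=["x"], seqs=["ACGTACGTAC"])
        g = GeneTree(["x"], [-1], [-1], [-1], [0.0], [0], pop_names=["A"])
        assert jc69_log_likelihood(aln, g) == pytest.approx(
            10 * math.log(0.25), abs=1e-12)

    def test_identical_cherry_closed_form(self):
        aln = LocusAlignment(ids=["x", "y"], seqs=["A", "A"])
        g = cherry(0.01)  # total path 0.02
        ps, _ = jc69_transition(0.02)
        expect = math.log(0.25 * ps)
        assert jc69_log_likelihood(aln, g) == pytest.approx(expect, abs=1e-12)

    def test_missing_data_marginalizes(self):
        # an all-N sequence contributes nothing: likelihood equals the
        # remaining sequence's stationary probability
        aln = LocusAlignment(ids=["x", "y"], seqs=["ACG", "NNN"])
        g = cherry(0.01)
        assert jc69_log_likelihood(aln, g) == pytest.approx(
            3 * math.log(0.25), abs=1e-12)

    def test_unknown_sequence_id_rejected(self):
        aln = LocusAlignment(ids=["x", "z"], seqs=["A", "A"])
        with pytest.raises(ValueError, match="z"):
            jc69_log_likelihood(aln, cherry(0.01))

    def test_matches_enumeration_oracle(self, rng):
        from helpers import enumeration_log_likelihood, random_gene_tree

        for _ in range(25):
            n_tips = int(rng.integers(2, 6))
            n_sites = int(rng.integers(1, 13))
            g = random_gene_tree(n_tips, rng)
            bases = "ACGTN"
            seqs = ["".join(rng.choice(list(bases), size=n_sites,
                                       p=[.23, .23, .23, .23, .08]))
                    for _ in range(n_tips)]
            aln = LocusAlignment(ids=list(g.labels), seqs=seqs,
                                 rate_multiplier=float(rng.uniform(0.2, 2.0)))
            assert jc69_log_likelihood(aln, g) == pytest.approx(
                enumeration_log_likelihood(aln, g), abs=1e-10)


class TestPriorsAndConversions:
    def test_gamma_prior_means(self):
        assert GammaPrior(1, 100).mean == pytest.approx(0.01)
        assert GammaPrior(1, 670).mean == pytest.approx(1 / 670)

    def test_exponential_special_case(self):
        b = 40.0
        p = GammaPrior(1.0, b)
        x = 0.013
        assert gamma_log_prior(x, p) == pytest.approx(
            math.log(b) - b * x, abs=1e-12)
        assert math.exp(gamma_log_prior(1e-12, p)) == pytest.approx(b, rel=1e-6)

    def test_nonpositive_support(self):
        assert gamma_log_prior(0.0, GammaPrior(1, 100)) == -math.inf
        assert gamma_log_prior(-1.0, GammaPrior(1, 100)) == -math.inf

    def test_cozumel_calibration(self):
        # 121 kyr at the reference mtDNA clock: tau = 1.4883e-3, and the
        # mean-matched exponential prior has beta ~ 672, i.e. (1, 670) at
        # the precision that prior is stated
        tau = tau_from_years(121_000, 1.23e-8)
        assert tau == pytest.approx(1.4883e-3, rel=1e-4)
        beta = 1.0 / tau
        assert beta == pytest.approx(671.9, abs=0.1)
        assert round(beta, -1) == 670

    def test_tau_round_trip_and_pleistocene_scale(self):
        assert tau_from_years(0, 1e-8) == 0.0
        t_my = years_from_tau(1 / 40, 1.23e-8) / 1e6
        assert t_my == pytest.approx(2.03, abs=0.01)
        with pytest.raises(ValueError):
            tau_from_years(-1, 1e-8)

    def test_ne_theta_conversions(self):
        assert ne_from_theta(0.0, 1e-8) == 0.0
        assert ne_from_theta(0.00738, 1.23e-8) == pytest.approx(150_000)
        th = 0.0123
        assert theta_from_ne(ne_from_theta(th, 1.23e-8), 1.23e-8) == \
            pytest.approx(th, abs=1e-12)
        with pytest.raises(ValueError):
            ne_from_theta(0.01, 0.0)


class TestMtdnaScale:
    def test_divides_every_theta_by_four(self, two_pop_tree):
        s = mtdna_scale(two_pop_tree)
        assert np.allclose(s.theta, np.array([0.01, 0.01, 0.02]) / 4)

    def test_applied_twice_is_sixteenth(self, two_pop_tree):
        s = mtdna_scale(mtdna_scale(two_pop_tree))
        assert np.allclose(s.theta, np.array([0.01, 0.01, 0.02]) / 16)

    def test_tau_unchanged(self, two_pop_tree):
        s = mtdna_scale(two_pop_tree)
        assert np.array_equal(s.tau, two_pop_tree.tau)


class TestSpeciesTree:
    def test_json_round_trip(self, two_pop_tree):
        back = SpeciesTree.from_json(two_pop_tree.to_json())
        assert back.names == two_pop_tree.names
        assert np.allclose(back.tau, two_pop_tree.tau)
        assert np.allclose(back.theta, two_pop_tree.theta)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpeciesTree(["A", "B", "AB"], [2, 2, -1], [-1, -1, 0],
                        [-1, -1, 1], [0, 0, 0.004], [0.01, -0.01, 0.02])
        with pytest.raises(ValueError):  # parent tau below child
            SpeciesTree.from_newick("((a,b)x,c)r;",
                                    theta={n: 0.01 for n in
                                           ("a", "b", "c", "x", "r")},
                                    tau={"x": 0.01, "r": 0.004})

    def test_two_pop_subtree(self, two_pop_tree):
        sub = two_pop_tree.two_pop_subtree("A", "B")
        assert sub.n_pops == 2
        assert sub.tau[sub.root] == pytest.approx(0.004)
        with pytest.raises(ValueError):
            two_pop_tree.two_pop_subtree("A", "AB")
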