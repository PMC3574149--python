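"""Bayesian estimator: summaries, ESS, initialization, sampler correctness.

The sampler's incremental caches are validated by comparing its maintained
log-posterior against the pure-Python reference density/likelihood at the
final state, and its stationary distribution by prior recovery and a KS
test of the data-free theta marginal.
"""

import math

import numpy as np
import pytest
from scipy import stats

from cardcoal import (
    SpeciesTree,
    coalescent_log_density,
    effective_sample_size,
    gamma_log_prior,
    initialize_state,
    jc69_log_likelihood,
    mcmc_run,
    posterior_summary,
    simulate_alignment,
    simulate_gene_tree,
)
from cardcoal.config import McmcSettings, PriorSet
from cardcoal.core import GammaPrior


class TestPosteriorSummary:
    def test_constant_trace(self):
        m, lo, hi = posterior_summary(np.full(50, 3.2))
        assert m == pytest.approx(3.2)
        assert lo == pytest.approx(3.2)
        assert hi == pytest.approx(3.2)

    def test_linear_interpolation_percentiles(self):
        m, lo, hi = posterior_summary(np.arange(1.0, 101.0))
        assert m == pytest.approx(50.5)
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=500)
        assert posterior_summary(x) == pytest.approx(
            posterior_summary(rng.permutation(x)))

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(np.array([]))


class TestEffectiveSampleSize:
    def test_iid_trace(self, rng):
        x = rng.normal(size=10_000)
        assert 8_000 <= effective_sample_size(x) <= 12_000

    def test_ar1_closed_form(self, rng):
        # AR(1) with rho: ESS/n -> (1-rho)/(1+rho) = 1/3 at rho = 0.5
        n, rho = 60_000, 0.5
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        assert effective_sample_size(x) == pytest.approx(n / 3, rel=0.15)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5.0))

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.ones(100))


class TestInitializeState:
    def test_one_population(self, one_pop_tree, priors, rng):
        g = simulate_gene_tree(one_pop_tree, {"A": 3}, rng=rng)
        aln = simulate_alignment(g, 100, rng=rng)
        st = initialize_state([aln], one_pop_tree, priors, rng)
        assert st.species.theta[0] > 0
        assert st.species.n_pops == 1

    def test_gene_trees_respect_tau(self, two_pop_tree, priors, rng):
        g = simulate_gene_tree(two_pop_tree, {"A": 3, "B": 3}, rng=rng)
        aln = simulate_alignment(g, 100, rng=rng)
        st = initialize_state([aln], two_pop_tree, priors, rng)
        assert st.species.tau[st.species.root] > 0
        for gt in st.gene_trees:
            gt.node_pops(st.species)  # raises on violation

    def test_finite_posterior_over_random_configs(self, two_pop_tree, priors, rng):
        for _ in range(20):
            counts = {"A": int(rng.integers(1, 4)),
                      "B": int(rng.integers(1, 4))}
            g = simulate_gene_tree(two_pop_tree, counts, rng=rng)
            aln = simulate_alignment(g, int(rng.integers(10, 200)), rng=rng)
            st = initialize_state([aln], two_pop_tree, priors, rng)
            lp = 0.0
            for a, gt in zip(st.loci, st.gene_trees):
                lp += coalescent_log_density(gt, st.species, a.scaler)
                lp += jc69_log_likelihood(a, gt)
            assert math.isfinite(lp)

    def test_unmapped_sample_rejected(self, two_pop_tree, priors, rng):
        g = simulate_gene_tree(two_pop_tree, {"A": 2, "B": 2}, rng=rng)
        aln = simulate_alignment(g, 50, rng=rng)
        aln.pop_map = {k: v for k, v in list(aln.pop_map.items())[:-1]}
        with pytest.raises(ValueError, match="without population"):
            initialize_state([aln], two_pop_tree, priors, rng)


def _reference_log_posterior(state):
    """Pure-Python posterior density of an McmcState (the slow route)."""
    s = state.species
    lp = 0.0
    for i in range(s.n_nodes):
        lp += gamma_log_prior(s.theta[i], state.priors.theta)
        if not s.is_tip(i):
            lp += gamma_log_prior(s.tau[i], state.priors.tau_for(s.names[i]))
    for aln, g in zip(state.loci, state.gene_trees):
        lp += coalescent_log_density(g, s, aln.scaler)
        lp += jc69_log_likelihood(aln, g)
    return lp


class TestSamplerCorrectness:
    def test_incremental_caches_match_reference(self, priors, rng):
        """After hundreds of incremental moves, the kernel's maintained
        log-posterior must equal the reference computed from scratch."""
        six = SpeciesTree.from_newick(
            "(a,((b,c)X,(d,e)Y)Z)R;",
            theta={n: 0.02 for n in
                   ("a", "b", "c", "d", "e", "X", "Y", "Z", "R")},
            tau={"X": 0.003, "Y": 0.004, "Z": 0.008, "R": 0.012})
        for topo, counts in [
            (six, {"a": 2, "b": 3, "c": 1, "d": 2, "e": 2}),
            (six, {"a": 1, "b": 1, "c": 1, "d": 1, "e": 1}),
        ]:
            alns = []
            for i in range(3):
                g = simulate_gene_tree(topo, counts, rng=rng)
                alns.append(simulate_alignment(g, 120, rng=rng,
                                               name=f"L{i}"))
            alns[0].scaler = 0.25  # exercise the inheritance scaler too
            st = initialize_state(alns, topo, priors, rng)
            burn = 700  # < resync interval: purely incremental bookkeeping
            tr = mcmc_run(st, McmcSettings(generations=burn + 1, burnin=burn,
                                           thinning=1, tune=False), rng=rng)
            assert len(tr) == 1
            assert tr.df["lnP"].iloc[0] == pytest.approx(
                _reference_log_posterior(st), abs=1e-6)

    def test_data_free_theta_marginal_is_the_prior(self, one_pop_tree,
                                                   priors, rng):
        """Stationarity: with the likelihood disabled the theta marginal is
        its Gamma prior (KS test on an approximately independent subsample)."""
        g = simulate_gene_tree(one_pop_tree, {"A": 4}, rng=rng)
        aln = simulate_alignment(g, 30, rng=rng)
        st = initialize_state([aln], one_pop_tree, priors, rng)
        tr = mcmc_run(st, McmcSettings(generations=120_000, burnin=10_000,
                                       thinning=20), rng=rng,
                      use_likelihood=False)
        x = tr.df["theta_A"].to_numpy()
        ess = effective_sample_size(x)
        step = max(1, int(math.ceil(3 * len(x) / ess)))
        sub = x[::step]
        p = stats.kstest(sub, stats.gamma(a=1, scale=0.01).cdf).pvalue
        assert p > 0.01

    def test_posterior_sd_shrinks_with_locus_count(self, priors):
        """More loci -> tighter tau posterior (averaged over replicates)."""
        truth = SpeciesTree(["A", "B", "AB"], [2, 2, -1], [-1, -1, 0],
                            [-1, -1, 1], [0, 0, 0.005], [0.01, 0.01, 0.01])
        sds = []
        for n_loci in (1, 5, 10):
            vals = []
            for rep in range(2):
                rng = np.random.default_rng([n_loci, rep])
                alns = []
                for i in range(n_loci):
                    g = simulate_gene_tree(truth, {"A": 4, "B": 4}, rng=rng)
                    alns.append(simulate_alignment(g, 300, rng=rng,
                                                   name=f"L{i}"))
                st = initialize_state(alns, truth, priors, rng)
                tr = mcmc_run(st, McmcSettings(generations=12_000,
                                               burnin=3_000, thinning=10),
                              rng=rng)
                vals.append(tr.df["tau_AB"].std())
            sds.append(np.mean(vals))
        assert sds[0] > sds[1] > sds[2]

    def test_trace_length_contract(self, one_pop_tree, priors, rng):
        g = simulate_gene_tree(one_pop_tree, {"A": 2}, rng=rng)
        aln = simulate_alignment(g, 50, rng=rng)
        st = initialize_state([aln], one_pop_tree, priors, rng)
        tr = mcmc_run(st, McmcSettings(generations=1000, burnin=200,
                                       thinning=7), rng=rng)
        assert len(tr) == math.ceil((1000 - 200) / 7)
        summ = tr.summary()
        assert ((summ["lower95"] <= summ["mean"])
                & (summ["mean"] <= summ["upper95"])).all()
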