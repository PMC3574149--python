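"""Bayesian estimation of divergence times (tau) and population sizes (theta)
on a fixed species topology, integrating over per-locus gene trees.

The sampler cycles Metropolis-Hastings moves over (a) gene-tree node-age
slides, (b) lineage regrafts, (c) log-scale theta updates, (d) tau
rubber-band updates that linearly rescale the gene-tree ages they bound,
and (e) a mixing move scaling all dimensions jointly.  Per-node gamma priors
are placed on every tau and theta; the parent >= child ordering of tau is
enforced by the proposal bounds.

Multi-locus likelihoods assume free recombination between loci and none
within.  An mtDNA locus enters the coalescent with its inheritance scaler
(0.25) multiplying theta, so reported theta stays in nuclear (autosomal)
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernel import run_chain
from .config import McmcSettings, PriorSet
from .core import LocusAlignment
from .simulate import simulate_gene_tree
from .trees import GeneTree, SpeciesTree

__all__ = ["McmcSettings", "McmcState", "PosteriorTrace",
           "initialize_state", "mcmc_run",
           "posterior_summary", "effective_sample_size"]


@dataclass
class McmcState:
    species: SpeciesTree
    loci: list          # LocusAlignment per locus
    gene_trees: list    # GeneTree per locus, tips named like the alignments
    priors: PriorSet


class PosteriorTrace:
    """Thinned post-burn-in samples of every tau and theta.

    ``df`` has one column per parameter (``tau_<node>``, ``theta_<node>``)
    plus ``lnP``; summaries are arithmetic means with equal-tail 95%
    intervals (2.5/97.5 percentiles, linear interpolation).
    """

    def __init__(self, df: pd.DataFrame, settings: McmcSettings,
                 acceptance: dict | None = None):
        self.df = df
        self.settings = settings
        self.acceptance = acceptance or {}

    def __len__(self):
        return len(self.df)

    @property
    def params(self):
        return [c for c in self.df.columns if c != "lnP"]

    def mean(self, param: str) -> float:
        return float(self.df[param].mean())

    def summary(self) -> pd.DataFrame:
        rows = {}
        for p in self.params:
            mean, lo, hi = posterior_summary(self, p)
            x = self.df[p].to_numpy()
            try:
                ess = effective_sample_size(x)
            except ValueError:
                ess = float("nan")
            rows[p] = {"mean": mean, "lower95": lo, "upper95": hi, "ess": ess}
        return pd.DataFrame(rows).T

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def initialize_state(alignments, topology, priors: PriorSet,
                     rng: np.random.Generator,
                     max_tries: int = 1000) -> McmcState:
    """Draw a valid starting state: tau/theta from the priors (rejecting
    draws that violate parent >= child), then per-locus gene trees simulated
    compatibly with them."""
    if isinstance(topology, SpeciesTree):
        base = topology
    else:
        raise TypeError("topology must be a SpeciesTree")
    for aln in alignments:
        if aln.pop_map is None:
            raise ValueError(f"locus {aln.name!r}: alignment has no population map")
        missing = [s for s in aln.ids if s not in aln.pop_map]
        if missing:
            raise ValueError(
                f"locus {aln.name!r}: samples without population: {missing}")
        bad = set(aln.pop_map[s] for s in aln.ids) - set(base.tip_names)
        if bad:
            raise ValueError(
                f"locus {aln.name!r}: populations {sorted(bad)} not in topology")

    s = base.copy()
    internal = [i for i in range(s.n_nodes) if not s.is_tip(i)]
    for _ in range(max_tries):
        for i in internal:
            pr = priors.tau_for(s.names[i])
            s.tau[i] = rng.gamma(pr.alpha, 1.0 / pr.beta)
        ok = all(s.tau[i] >= max(s.tau[int(s.left[i])], s.tau[int(s.right[i])])
                 for i in internal)
        if ok and all(s.tau[i] > 0 for i in internal):
            break
    else:
        raise RuntimeError(
            "could not draw tau satisfying parent >= child after "
            f"{max_tries} tries; consider wider (less conflicting) tau priors")
    for i in range(s.n_nodes):
        s.theta[i] = rng.gamma(priors.theta.alpha, 1.0 / priors.theta.beta)
        while s.theta[i] <= 0:
            s.theta[i] = rng.gamma(priors.theta.alpha, 1.0 / priors.theta.beta)

    gene_trees = []
    for aln in alignments:
        counts: dict = {}
        by_pop: dict = {}
        for sid in aln.ids:
            p = aln.pop_map[sid]
            counts[p] = counts.get(p, 0) + 1
            by_pop.setdefault(p, []).append(sid)
        g = simulate_gene_tree(s, counts, scaler=aln.scaler, rng=rng)
        # rename simulated tips to the alignment's sample ids (within-pop
        # order is arbitrary; lineages are exchangeable)
        remaining = {p: list(v) for p, v in by_pop.items()}
        labels = []
        for v in range(g.n_tips):
            pop = s.names[g.tip_pop[v]]
            labels.append(remaining[pop].pop())
        g.labels = labels
        gene_trees.append(g)
    return McmcState(species=s, loci=list(alignments), gene_trees=gene_trees,
                     priors=priors)


def _pack(state: McmcState):
    s = state.species
    S = s.n_nodes
    L = len(state.loci)
    nt = np.array([g.n_tips for g in state.gene_trees], dtype=np.int64)
    Tmax = int(nt.max())
    Gmax = 2 * Tmax - 1

    gpar = np.full((L, Gmax), -1, dtype=np.int64)
    gl = np.full((L, Gmax), -1, dtype=np.int64)
    gr = np.full((L, Gmax), -1, dtype=np.int64)
    gage = np.zeros((L, Gmax))
    gbase = np.zeros((L, Gmax), dtype=np.int64)
    groot = np.zeros(L, dtype=np.int64)
    tipop = np.zeros((L, Gmax), dtype=np.int64)

    pat_list, w_list = [], []
    for aln in state.loci:
        p, w = aln.site_patterns()
        pat_list.append(p)
        w_list.append(w)
    Pmax = max(p.shape[1] for p in pat_list)
    pat = np.full((L, Gmax, Pmax), 4, dtype=np.int8)
    patw = np.zeros((L, Pmax))
    npat = np.zeros(L, dtype=np.int64)

    for l, (aln, g) in enumerate(zip(state.loci, state.gene_trees)):
        ng = g.n_nodes
        gpar[l, :ng] = g.parent
        gl[l, :ng] = g.left
        gr[l, :ng] = g.right
        gage[l, :ng] = g.age
        groot[l] = g.root
        tipop[l, :g.n_tips] = g.tip_pop
        row = {sid: k for k, sid in enumerate(aln.ids)}
        P = pat_list[l].shape[1]
        npat[l] = P
        patw[l, :P] = w_list[l]
        for v in range(g.n_tips):
            pat[l, v, :P] = pat_list[l][row[g.labels[v]]]

    scaler = np.array([a.scaler for a in state.loci])
    mult = np.array([a.rate_multiplier for a in state.loci])
    return (nt, gpar, gl, gr, gage, gbase, groot, tipop, pat, patw, npat,
            scaler, mult)


def mcmc_run(state: McmcState, settings: McmcSettings,
             rng: np.random.Generator | None = None,
             use_likelihood: bool = True) -> PosteriorTrace:
    """Run the sampler and return the thinned post-burn-in trace.

    ``use_likelihood=False`` samples from the prior (times the coalescent
    gene-tree density), which is the data-free validation mode.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    s = state.species
    S = s.n_nodes
    anc = s.ancestor_matrix()
    internal = np.array([i for i in range(S) if not s.is_tip(i)],
                        dtype=np.int64)

    ta_a = np.ones(S)
    ta_b = np.ones(S)
    for i in internal:
        pr = state.priors.tau_for(s.names[int(i)])
        ta_a[i], ta_b[i] = pr.alpha, pr.beta
    th_a = np.full(S, state.priors.theta.alpha)
    th_b = np.full(S, state.priors.theta.beta)

    (nt, gpar, gl, gr, gage, gbase, groot, tipop, pat, patw, npat,
     scaler, mult) = _pack(state)

    th_mean = state.priors.theta.mean
    tau_sd = state.priors.tau_default.sd
    w = np.array([
        settings.w_age if settings.w_age else 0.3 * th_mean,
        settings.w_tau if settings.w_tau else 0.3 * tau_sd,
        settings.w_logtheta,
        settings.w_mix,
    ])
    w_exp = 0.5 * th_mean

    n_samples = max(0, -(-(settings.generations - settings.burnin)
                         // settings.thinning))
    n_par = len(internal) + S + 1
    trace = np.empty((n_samples, n_par))
    acc = np.zeros((5, 2), dtype=np.int64)
    tau = s.tau.copy()
    theta = s.theta.copy()

    got = run_chain(s.parent, s.left, s.right, tau, theta, anc,
                    ta_a, ta_b, th_a, th_b,
                    nt, gpar, gl, gr, gage, gbase, groot, tipop,
                    pat, patw, npat, scaler, mult,
                    internal, use_likelihood,
                    settings.generations, settings.burnin, settings.thinning,
                    w, w_exp, settings.tune, rng, trace, acc)
    assert got == n_samples

    # fold the final state back so chains can be continued or inspected
    s.tau[:] = tau
    s.theta[:] = theta
    for l, g in enumerate(state.gene_trees):
        ng = g.n_nodes
        g.parent = gpar[l, :ng].copy()
        g.left = gl[l, :ng].copy()
        g.right = gr[l, :ng].copy()
        g.age = gage[l, :ng].copy()
        g.root = int(groot[l])

    cols = ([f"tau_{s.names[int(i)]}" for i in internal]
            + [f"theta_{n}" for n in s.names] + ["lnP"])
    move_names = ["age", "regraft", "theta", "tau", "mix"]
    acceptance = {m: (acc[i, 0] / acc[i, 1] if acc[i, 1] else float("nan"))
                  for i, m in enumerate(move_names)}
    return PosteriorTrace(pd.DataFrame(trace, columns=cols), settings,
                          acceptance)


def posterior_summary(trace, param: str | None = None):
    """(mean, lower95, upper95) with equal-tail percentile bounds."""
    if isinstance(trace, PosteriorTrace):
        if param is None:
            raise ValueError("param required for a PosteriorTrace")
        x = trace.df[param].to_numpy()
    else:
        x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(x.mean()), float(lo), float(hi)


def effective_sample_size(x) -> float:
    """ESS = n / (1 + 2 sum rho_k), truncating the autocorrelation sum at
    the first non-positive term."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("trace too short for ESS (need >= 10 samples)")
    xc = x - x.mean()
    v0 = float(np.dot(xc, xc)) / n
    if v0 == 0:
        raise ValueError("ESS undefined for a constant trace")
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))
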