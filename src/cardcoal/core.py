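"""Exact math of the multispecies coalescent with Jukes-Cantor sequences.

The time unit throughout is expected substitutions per site at the
reference (mitochondrial) locus rate; per-locus rate multipliers convert
node-age differences into branch lengths for that locus.  theta is the
population mutation rate 4*Ne*mu per site; an inheritance scaler multiplies
theta inside the coalescent density (1 for autosomes, 0.25 for mtDNA,
0.75 for Z-linked loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import ConstraintError, GeneTree, SpeciesTree

__all__ = [
    "GammaPrior", "LocusAlignment",
    "coalescent_log_density", "jc69_transition", "jc69_log_likelihood",
    "gamma_log_prior", "tau_from_years", "years_from_tau",
    "ne_from_theta", "theta_from_ne", "mtdna_scale",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_MISSING = frozenset("N-?")


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(alpha, beta) prior with mean alpha/beta and variance alpha/beta^2."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma prior requires alpha > 0 and beta > 0")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta

    @property
    def var(self) -> float:
        return self.alpha / self.beta**2

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus.

    ``scaler`` is the inheritance scaler multiplying theta in the coalescent
    (0.25 for mtDNA) and ``rate_multiplier`` converts reference-rate time into
    branch lengths for this locus.
    """

    ids: list
    seqs: list
    pop_map: dict | None = None
    scaler: float = 1.0
    rate_multiplier: float = 1.0
    name: str = ""
    genetic_code: str = "standard"

    def __post_init__(self):
        if not self.ids:
            raise ValueError("alignment must contain at least one sequence")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("sequences must all have equal length")
        if self.scaler <= 0 or self.rate_multiplier <= 0:
            raise ValueError("scaler and rate_multiplier must be > 0")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s.upper()) - set("ACGTN-?")
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains unsupported symbols {sorted(bad)}; "
                    "only A/C/G/T plus N/- missing data are accepted"
                )

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """Integer matrix, A/C/G/T -> 0..3 and N/-/? -> 4."""
        out = np.empty((self.n_seqs, self.n_sites), dtype=np.int8)
        for i, s in enumerate(self.seqs):
            su = s.upper()
            for j, ch in enumerate(su):
                out[i, j] = _CODE.get(ch, 4)
        return out

    def site_patterns(self):
        """Unique site patterns and their counts (column compression)."""
        enc = self.encoded()
        pats, counts = np.unique(enc, axis=1, return_counts=True)
        return np.ascontiguousarray(pats), counts.astype(np.float64)


# ---------------------------------------------------------------------------
# coalescent density


def coalescent_log_density(g: GeneTree, s: SpeciesTree, scaler: float = 1.0) -> float:
    """Log-density of a genealogy under the multispecies coalescent.

    Within every population interval with ``j`` active lineages, the waiting
    time to the next coalescence is exponential with rate ``j(j-1)/theta'``
    where ``theta' = theta * scaler``, and each coalescence contributes a
    factor ``2/theta'``.  Raises :class:`ConstraintError` for genealogies
    incompatible with the species tree rather than returning -inf.
    """
    if scaler <= 0:
        raise ValueError("scaler must be > 0")
    pops = g.node_pops(s)  # raises ConstraintError if invalid
    logp = 0.0
    for p in range(s.n_nodes):
        th = s.theta[p] * scaler
        t0 = s.tau[p]
        parent = int(s.parent[p])
        t1 = s.tau[parent] if parent >= 0 else math.inf
        # lineages crossing into this population at t0
        j = 0
        for v in range(g.n_nodes):
            u = int(g.parent[v])
            if u < 0:
                continue
            if g.age[v] <= t0 < g.age[u] and _is_anc(s, p, int(pops[v])):
                j += 1
        events = sorted(
            g.age[v] for v in range(g.n_tips, g.n_nodes) if pops[v] == p
        )
        if p == s.root and j == 0 and g.n_nodes == 1:
            continue  # single sampled lineage, nothing happens anywhere
        t = t0
        for te in events:
            logp += -j * (j - 1) / th * (te - t) + math.log(2.0 / th)
            j -= 1
            t = te
        if math.isfinite(t1):
            logp += -j * (j - 1) / th * (t1 - t)
    return logp


def _is_anc(s: SpeciesTree, p: int, q: int) -> bool:
    while q >= 0:
        if q == p:
            return True
        q = int(s.parent[q])
    return False


# ---------------------------------------------------------------------------
# Jukes-Cantor


def jc69_transition(d: float):
    """JC69 transition probabilities at branch length ``d`` substitutions/site.

    Returns ``(p_same, p_diff)`` where ``p_diff`` is the probability of each
    one of the three alternative target bases; ``p_same + 3*p_diff = 1``.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    e = math.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def jc69_log_likelihood(aln: LocusAlignment, g: GeneTree) -> float:
    """Felsenstein-pruning log-likelihood under JC69 with uniform root.

    Branch lengths are node-age differences times the locus rate multiplier.
    Sites with N or '-' are marginalized at the corresponding tip.
    """
    tip_index = {lab: i for i, lab in enumerate(g.labels)}
    for sid in aln.ids:
        if sid not in tip_index:
            raise ValueError(f"sequence id {sid!r} missing from gene tree")
    pats, counts = aln.site_patterns()
    n_pat = pats.shape[1]
    partial = np.empty((g.n_nodes, n_pat, 4))
    row = {sid: k for k, sid in enumerate(aln.ids)}
    for v in g.postorder():
        v = int(v)
        if g.is_tip(v):
            obs = pats[row[g.labels[v]]]
            pt = np.zeros((n_pat, 4))
            known = obs < 4
            pt[known, obs[known]] = 1.0
            pt[~known, :] = 1.0
            partial[v] = pt
        else:
            acc = np.ones((n_pat, 4))
            for c in (int(g.left[v]), int(g.right[v])):
                d = (g.age[v] - g.age[c]) * aln.rate_multiplier
                ps, pd = jc69_transition(d)
                tot = partial[c].sum(axis=1, keepdims=True)
                acc *= (ps - pd) * partial[c] + pd * tot
            partial[v] = acc
    site_lik = 0.25 * partial[g.root].sum(axis=1)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.dot(counts, np.log(site_lik)))


# ---------------------------------------------------------------------------
# priors and unit conversions


def gamma_log_prior(x: float, p: GammaPrior) -> float:
    """Gamma log-density; -inf for x <= 0 by contract."""
    if x <= 0:
        return -math.inf
    return (p.alpha * math.log(p.beta) - math.lgamma(p.alpha)
            + (p.alpha - 1.0) * math.log(x) - p.beta * x)


def tau_from_years(t_years: float, mu_per_site_year: float) -> float:
    """Divergence time in years -> tau in expected substitutions/site."""
    if t_years < 0 or mu_per_site_year <= 0:
        raise ValueError("require T >= 0 and mu > 0")
    return t_years * mu_per_site_year


def years_from_tau(tau: float, mu_per_site_year: float) -> float:
    if tau < 0 or mu_per_site_year <= 0:
        raise ValueError("require tau >= 0 and mu > 0")
    return tau / mu_per_site_year


def ne_from_theta(theta: float, mu_per_site_generation: float,
                  generation_years: float = 1.0) -> float:
    """Effective population size Ne = theta / (4 mu) for a diploid locus."""
    if mu_per_site_generation <= 0 or generation_years <= 0:
        raise ValueError("require mu > 0 and generation time > 0")
    if theta < 0:
        raise ValueError("require theta >= 0")
    return theta / (4.0 * mu_per_site_generation)


def theta_from_ne(ne: float, mu_per_site_generation: float,
                  generation_years: float = 1.0) -> float:
    if mu_per_site_generation <= 0 or generation_years <= 0:
        raise ValueError("require mu > 0 and generation time > 0")
    if ne < 0:
        raise ValueError("require Ne >= 0")
    return 4.0 * ne * mu_per_site_generation


def mtdna_scale(s: SpeciesTree) -> SpeciesTree:
    """Species tree with every theta divided by 4 (mtDNA effective size)."""
    out = s.copy()
    out.theta = out.theta / 4.0
    return out
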