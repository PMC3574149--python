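"""Forward generators: genealogies under the MSC, sequences under JC69,
and a codon-level simulator with branch-specific omega.

All randomness flows through a single :class:`numpy.random.Generator`
threaded by the caller, so a fixed seed reproduces every dataset exactly.
"""

from __future__ import annotations

import math

import numpy as np

from .codes import get_code, sense_codons
from .core import LocusAlignment, jc69_transition
from .trees import GeneTree, SpeciesTree

__all__ = ["simulate_gene_tree", "simulate_alignment",
           "simulate_codon_alignment"]


def simulate_gene_tree(s: SpeciesTree, samples_per_pop: dict,
                       scaler: float = 1.0,
                       rng: np.random.Generator | None = None) -> GeneTree:
    """Simulate a genealogy backward in time under the multispecies coalescent.

    Within each population interval with ``j`` lineages the next coalescence
    waits an exponential time with rate ``j(j-1)/(theta*scaler)``; lineages
    surviving past the top of a population merge into the ancestral one.

    ``samples_per_pop`` maps extant population names to sample counts (absent
    populations contribute no samples).
    """
    if rng is None:
        rng = np.random.default_rng()
    counts = {p: int(samples_per_pop.get(p, 0)) for p in s.tip_names}
    n_tips = sum(counts.values())
    if n_tips < 1:
        raise ValueError("at least one sample is required")
    if any(c < 0 for c in counts.values()):
        raise ValueError("sample counts must be >= 0")
    if scaler <= 0:
        raise ValueError("scaler must be > 0")

    labels, tip_pop = [], []
    for p in s.tip_names:
        for k in range(counts[p]):
            labels.append(f"{p}^{k + 1}")
            tip_pop.append(s.index(p))

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    next_node = n_tips

    # active lineages per species node, filled bottom-up in postorder
    active = {}
    for i, p in enumerate(s.tip_names):
        active[s.index(p)] = [v for v in range(n_tips) if tip_pop[v] == s.index(p)]

    post = sorted(range(s.n_nodes), key=lambda i: (s.tau[i], i))
    for sp in post:
        lineages = active.get(sp, [])
        if not s.is_tip(sp):
            lineages = active.get(int(s.left[sp]), []) + active.get(int(s.right[sp]), [])
        t = float(s.tau[sp])
        pa = int(s.parent[sp])
        t_end = float(s.tau[pa]) if pa >= 0 else math.inf
        th = float(s.theta[sp]) * scaler
        while len(lineages) > 1:
            j = len(lineages)
            wait = rng.exponential(th / (j * (j - 1)))
            if t + wait >= t_end:
                break
            t += wait
            i1, i2 = rng.choice(j, size=2, replace=False)
            a, b = lineages[i1], lineages[i2]
            v = next_node
            next_node += 1
            left[v], right[v] = a, b
            parent[a] = parent[b] = v
            age[v] = t
            lineages = [x for x in lineages if x not in (a, b)] + [v]
        active[sp] = lineages

    return GeneTree(labels, parent, left, right, age, tip_pop,
                    pop_names=s.names)


def simulate_alignment(g: GeneTree, n_sites: int, rate_multiplier: float = 1.0,
                       rng: np.random.Generator | None = None,
                       scaler: float = 1.0, name: str = "",
                       branch_scale: np.ndarray | None = None) -> LocusAlignment:
    """Evolve JC69 sequences down a genealogy.

    The root sequence is uniform over {A,C,G,T}; each branch mutates sites
    independently with total change probability ``3 * p_diff(d)`` where
    ``d = (age difference) * rate_multiplier * branch_scale``.  The optional
    per-node ``branch_scale`` array multiplies the branch above each node
    (used to impose lineage-specific rate accelerations).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    seqs = {}
    seqs[g.root] = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    order = g.postorder()[::-1]  # preorder: parents before children
    for v in order:
        v = int(v)
        if v == g.root:
            continue
        u = int(g.parent[v])
        d = (g.age[u] - g.age[v]) * rate_multiplier
        if branch_scale is not None:
            d *= float(branch_scale[v])
        _, pd = jc69_transition(d)
        seq = seqs[u].copy()
        hit = rng.random(n_sites) < 3.0 * pd
        n_hit = int(hit.sum())
        if n_hit:
            shift = rng.integers(1, 4, size=n_hit, dtype=np.int8)
            seq[hit] = (seq[hit] + shift) % 4
        seqs[v] = seq

    bases = np.array(list("ACGT"))
    out_seqs = ["".join(bases[seqs[v]]) for v in range(g.n_tips)]
    pop_map = None
    if g.pop_names is not None:
        pop_map = {g.labels[v]: g.pop_names[g.tip_pop[v]]
                   for v in range(g.n_tips)}
    return LocusAlignment(ids=list(g.labels), seqs=out_seqs, pop_map=pop_map,
                          scaler=scaler, rate_multiplier=rate_multiplier,
                          name=name)


def simulate_codon_alignment(g: GeneTree, n_codons: int,
                             omega_per_branch, genetic_code: str = "standard",
                             rng: np.random.Generator | None = None,
                             rate_multiplier: float = 1.0,
                             name: str = "") -> LocusAlignment:
    """Simulate codon sequences with branch-specific dN/dS by thinning.

    Candidate single-nucleotide events arise along each branch at the JC69
    rate; a candidate that would create a stop codon is rejected, a
    nonsynonymous candidate is accepted with probability ``omega`` for that
    branch, and synonymous candidates are always accepted.

    ``omega_per_branch`` is either a scalar or an array of length
    ``g.n_nodes`` giving omega for the branch above each node.
    """
    if rng is None:
        rng = np.random.default_rng()
    code = get_code(genetic_code)
    senses = sense_codons(genetic_code)
    if np.isscalar(omega_per_branch):
        omega = np.full(g.n_nodes, float(omega_per_branch))
    else:
        omega = np.asarray(omega_per_branch, dtype=float)
        if omega.shape != (g.n_nodes,):
            raise ValueError("omega_per_branch must be scalar or per-node array")
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")

    codon_list = list(senses)
    idx_of = {c: i for i, c in enumerate(codon_list)}
    aa = [code[c] for c in codon_list]

    state = {g.root: rng.integers(0, len(codon_list), size=n_codons)}
    order = [int(v) for v in g.postorder()[::-1]]
    for v in order:
        if v == g.root:
            continue
        u = int(g.parent[v])
        d = (g.age[u] - g.age[v]) * rate_multiplier
        w = float(omega[v])
        cur = state[u].copy()
        n_events = rng.poisson(3.0 * d, size=n_codons)
        for ci in np.flatnonzero(n_events):
            codon = codon_list[cur[ci]]
            for _ in range(int(n_events[ci])):
                pos = int(rng.integers(0, 3))
                shift = int(rng.integers(1, 4))
                old = "ACGT".index(codon[pos])
                new_base = "ACGT"[(old + shift) % 4]
                cand = codon[:pos] + new_base + codon[pos + 1:]
                if code[cand] == "*":
                    continue  # stop codons are inaccessible
                if code[cand] == code[codon] or rng.random() < w:
                    codon = cand
            cur[ci] = idx_of[codon]
        state[v] = cur

    out_seqs = ["".join(codon_list[i] for i in state[v])
                for v in range(g.n_tips)]
    pop_map = None
    if g.pop_names is not None:
        pop_map = {g.labels[v]: g.pop_names[g.tip_pop[v]]
                   for v in range(g.n_tips)}
    return LocusAlignment(ids=list(g.labels), seqs=out_seqs, pop_map=pop_map,
                          scaler=1.0, rate_multiplier=rate_multiplier,
                          name=name, genetic_code=genetic_code)
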