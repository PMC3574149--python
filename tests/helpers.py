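"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: the likelihood
oracle sums over all internal-state assignments explicitly, and the NG86
oracle enumerates mutational pathways with its own recursion.
"""

import math
from itertools import product

import numpy as np

from cardcoal import GeneTree
from cardcoal.codes import get_code
from cardcoal.core import jc69_transition


def random_gene_tree(n_tips: int, rng) -> GeneTree:
    """Random coalescent-style topology with ordered random ages."""
    n = 2 * n_tips - 1
    parent = [-1] * n
    left = [-1] * n
    right = [-1] * n
    active = list(range(n_tips))
    ages = [0.0] * n
    t = 0.0
    nxt = n_tips
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        t += float(rng.exponential(0.05))
        left[nxt], right[nxt] = a, b
        parent[a] = parent[b] = nxt
        ages[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    labels = [f"t{i}" for i in range(n_tips)]
    return GeneTree(labels, parent, left, right, ages, [0] * n_tips,
                    pop_names=["A"])


def enumeration_log_likelihood(aln, g: GeneTree) -> float:
    """Brute-force JC69 likelihood: sum over all internal-state tuples."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    n_tips = g.n_tips
    internals = list(range(n_tips, g.n_nodes))
    row = {sid: k for k, sid in enumerate(aln.ids)}
    tip_states = [[code.get(ch.upper(), 4) for ch in aln.seqs[row[g.labels[v]]]]
                  for v in range(n_tips)]
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for assign in product(range(4), repeat=len(internals)):
            state = {}
            for v in range(n_tips):
                state[v] = tip_states[v][site]
            for k, v in enumerate(internals):
                state[v] = assign[k]
            p = 0.25  # uniform root
            ok = True
            for v in range(g.n_nodes):
                if v == g.root:
                    continue
                u = int(g.parent[v])
                d = (g.age[u] - g.age[v]) * aln.rate_multiplier
                ps, pd = jc69_transition(d)
                sv = state[v]
                if sv == 4:  # missing tip: marginalize (sums to 1)
                    continue
                p *= ps if state[u] == sv else pd
                if p == 0.0:
                    ok = False
                    break
            if ok:
                site_lik += p
        total += math.log(site_lik)
    return total


def ng86_pathway_oracle(c1: str, c2: str, genetic_code: str):
    """(syn, nonsyn) difference counts by depth-first pathway enumeration."""
    code = get_code(genetic_code)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    blocked = []

    def walk(cur, remaining, sd, nd, hit_stop):
        if not remaining:
            (blocked if hit_stop else results).append((sd, nd))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            syn = code[nxt] == code[cur]
            walk(nxt, [q for q in remaining if q != pos],
                 sd + (1 if syn else 0), nd + (0 if syn else 1),
                 hit_stop or code[nxt] == "*")

    walk(c1, diff, 0, 0, False)
    use = results if results else blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def ng86_sites_oracle(codon: str, genetic_code: str):
    """Site counts by explicit neighbour enumeration."""
    code = get_code(genetic_code)
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            cand = codon[:pos] + b + codon[pos + 1:]
            if code[cand] == "*":
                continue
            outcomes.append(code[cand] == code[codon])
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def patristic_oracle(tree, a: str, b: str) -> float:
    """Path-sum distance via root paths (independent of dendropy's PDM)."""
    nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    def path_to_root(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out

    pa = path_to_root(nodes[a])
    pb = path_to_root(nodes[b])
    seen = {id(n): n for n in pa}
    mrca = next(n for n in pb if id(n) in seen)

    def dist_up(nd, stop):
        d = 0.0
        while nd is not stop:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return d

    return dist_up(nodes[a], mrca) + dist_up(nodes[b], mrca)
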