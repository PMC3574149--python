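"""Species trees and gene trees for the multispecies coalescent.

A :class:`SpeciesTree` is a fixed rooted bifurcating topology over named
populations.  Each internal node carries a divergence time ``tau`` and every
node (extant population or ancestral lineage) carries a population mutation
rate ``theta`` = 4*Ne*mu per site.  Times are expressed in expected
substitutions per site at the reference-locus rate; tips sit at time 0.

A :class:`GeneTree` is a binary genealogy of sampled sequences embedded in a
species tree: node ages are in the same time units and every coalescence must
be at least as old as the species divergence separating the populations of
the lineages it joins.
"""

from __future__ import annotations

import json

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "GeneTree", "ConstraintError"]


class ConstraintError(ValueError):
    """A gene tree (or parameter set) violates the species-tree constraints."""


def _read_dendropy(source: str) -> dendropy.Tree:
    if "(" in source:
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip names in newick input")
    return tree


class SpeciesTree:
    """Rooted bifurcating population tree with tau and theta per node.

    Node indexing convention (shared with the MCMC kernel): tips occupy
    indices ``0 .. n_pops-1`` in left-to-right newick order; internal nodes
    follow in postorder, so the root is always the last index.
    """

    def __init__(self, names, parent, left, right, tau, theta):
        self.names = list(names)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.tau = np.asarray(tau, dtype=np.float64)
        self.theta = np.asarray(theta, dtype=np.float64)
        self.n_nodes = len(self.names)
        self.n_pops = (self.n_nodes + 1) // 2
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self._index = {n: i for i, n in enumerate(self.names)}
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, theta: dict, tau: dict | None = None):
        """Build from a newick topology plus per-node theta (and tau) maps.

        ``theta`` maps node labels to theta values and must cover every node.
        Internal nodes may be labelled in the newick string; unlabelled
        internal nodes are named by joining their descendant tip names with
        ``-`` in sorted order.  If ``tau`` is None, divergence times are taken
        from the newick branch lengths (the tree must then be ultrametric).
        """
        tree = _read_dendropy(source)
        names, parent, left, right = [], [], [], []
        depths = {}

        def label_of(nd):
            if nd.is_leaf():
                return nd.taxon.label
            if nd.label:
                return nd.label
            tips = sorted(lf.taxon.label for lf in nd.leaf_iter())
            return "-".join(tips)

        # assign indices: tips first (leaf order), internals in postorder
        leaves = [nd for nd in tree.leaf_node_iter()]
        internals = [nd for nd in tree.postorder_internal_node_iter()]
        order = leaves + internals
        idx = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = [-1] * n
        left = [-1] * n
        right = [-1] * n
        names = [label_of(nd) for nd in order]
        for nd in internals:
            ch = nd.child_nodes()
            if len(ch) != 2:
                raise ValueError("species tree must be bifurcating")
            i = idx[id(nd)]
            left[i], right[i] = idx[id(ch[0])], idx[id(ch[1])]
            parent[left[i]] = i
            parent[right[i]] = i

        if tau is None:
            # node depth below root from branch lengths, then time above tips
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    depths[id(nd)] = 0.0
                else:
                    bl = nd.edge.length
                    if bl is None:
                        raise ValueError(
                            "newick lacks branch lengths; supply tau explicitly"
                        )
                    depths[id(nd)] = depths[id(nd.parent_node)] + bl
            height = max(depths[id(lf)] for lf in leaves)
            for lf in leaves:
                if abs(depths[id(lf)] - height) > 1e-9 * max(height, 1.0):
                    raise ValueError("tree not ultrametric; supply tau explicitly")
            tau_arr = [0.0] * n
            for nd in internals:
                tau_arr[idx[id(nd)]] = height - depths[id(nd)]
        else:
            tau_arr = [0.0] * n
            for nd in internals:
                lab = label_of(nd)
                if lab not in tau:
                    raise ValueError(f"tau missing for internal node {lab!r}")
                tau_arr[idx[id(nd)]] = float(tau[lab])

        theta_arr = []
        for lab in names:
            if lab not in theta:
                raise ValueError(f"theta missing for node {lab!r}")
            theta_arr.append(float(theta[lab]))
        return cls(names, parent, left, right, tau_arr, theta_arr)

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if self.n_nodes != 2 * self.n_pops - 1:
            raise ValueError("species tree must be binary")
        if np.any(self.theta <= 0):
            raise ValueError("all theta must be > 0")
        for i in range(self.n_nodes):
            if self.is_tip(i):
                if self.tau[i] != 0.0:
                    raise ValueError("tip tau must be 0")
            else:
                if self.tau[i] <= 0.0:
                    raise ValueError("internal tau must be > 0")
                for c in (self.left[i], self.right[i]):
                    if self.tau[i] < self.tau[c]:
                        raise ValueError("tau(parent) must be >= tau(child)")

    # -- queries -----------------------------------------------------------

    def is_tip(self, i: int) -> bool:
        return self.left[i] < 0

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def tip_names(self):
        return self.names[: self.n_pops]

    def ancestor_matrix(self) -> np.ndarray:
        """anc[i, j] is True when node i is an ancestor of j (or i == j)."""
        anc = np.zeros((self.n_nodes, self.n_nodes), dtype=np.bool_)
        for j in range(self.n_nodes):
            p = j
            while p >= 0:
                anc[p, j] = True
                p = int(self.parent[p])
        return anc

    def mrca(self, a: str | int, b: str | int) -> int:
        ia = a if isinstance(a, (int, np.integer)) else self.index(a)
        ib = b if isinstance(b, (int, np.integer)) else self.index(b)
        anc = self.ancestor_matrix()
        p = ia
        while not anc[p, ib]:
            p = int(self.parent[p])
        return p

    # -- transforms ---------------------------------------------------------

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(
            self.names, self.parent.copy(), self.left.copy(), self.right.copy(),
            self.tau.copy(), self.theta.copy(),
        )

    def with_params(self, tau=None, theta=None) -> "SpeciesTree":
        out = self.copy()
        if tau is not None:
            for lab, v in tau.items():
                out.tau[out.index(lab)] = v
        if theta is not None:
            for lab, v in theta.items():
                out.theta[out.index(lab)] = v
        out.validate()
        return out

    def two_pop_subtree(self, pop_a: str, pop_b: str) -> "SpeciesTree":
        """Extract the two-population tree spanned by sister populations."""
        m = self.mrca(pop_a, pop_b)
        ia, ib = self.index(pop_a), self.index(pop_b)
        if {int(self.left[m]), int(self.right[m])} != {ia, ib}:
            raise ValueError(f"{pop_a!r} and {pop_b!r} are not sister populations")
        anc_name = self.names[m]
        return SpeciesTree(
            [pop_a, pop_b, anc_name],
            [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
            [0.0, 0.0, self.tau[m]],
            [self.theta[ia], self.theta[ib], self.theta[m]],
        )

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def rec(i):
            if self.is_tip(i):
                return self.names[i]
            l, r = int(self.left[i]), int(self.right[i])
            bl_l = self.tau[i] - self.tau[l]
            bl_r = self.tau[i] - self.tau[r]
            return f"({rec(l)}:{bl_l:.12g},{rec(r)}:{bl_r:.12g}){self.names[i]}"

        return rec(self.root) + ";"

    def params_dict(self) -> dict:
        return {
            "tau": {self.names[i]: float(self.tau[i])
                    for i in range(self.n_nodes) if not self.is_tip(i)},
            "theta": {self.names[i]: float(self.theta[i])
                      for i in range(self.n_nodes)},
        }

    def to_json(self) -> str:
        return json.dumps({"newick": self.to_newick(), **self.params_dict()},
                          indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SpeciesTree":
        d = json.loads(text)
        return cls.from_newick(d["newick"], theta=d["theta"], tau=d["tau"])

    def __repr__(self):
        return (f"SpeciesTree({self.n_pops} populations, "
                f"root tau={self.tau[self.root]:.4g})")


class GeneTree:
    """Binary genealogy with node ages and tip population assignments.

    Tips occupy indices ``0 .. n_tips-1``; internal nodes follow.  ``tip_pop``
    gives, for each tip, the index of its population in the species tree the
    genealogy is embedded in (a name list is kept alongside for i/o).
    """

    def __init__(self, labels, parent, left, right, age, tip_pop, pop_names=None):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        self.tip_pop = np.asarray(tip_pop, dtype=np.int64)
        self.pop_names = list(pop_names) if pop_names is not None else None
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("gene tree must have a single root")
        self.root = int(roots[0])
        self.validate()

    def validate(self) -> None:
        if self.n_nodes != 2 * self.n_tips - 1:
            raise ValueError("gene tree must be binary")
        if np.any(self.age[: self.n_tips] != 0.0):
            raise ValueError("tip ages must be 0")
        for v in range(self.n_tips, self.n_nodes):
            for c in (self.left[v], self.right[v]):
                if self.age[v] <= self.age[c]:
                    raise ConstraintError("node ages must increase rootward")

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def postorder(self) -> np.ndarray:
        order = np.empty(self.n_nodes, dtype=np.int64)
        stack = [self.root]
        k = self.n_nodes
        while stack:
            v = stack.pop()
            k -= 1
            order[k] = v
            if not self.is_tip(v):
                stack.append(int(self.left[v]))
                stack.append(int(self.right[v]))
        return order

    def base_pops(self, species: SpeciesTree) -> np.ndarray:
        """Species MRCA of each node's descendant tip populations."""
        anc = species.ancestor_matrix()
        base = np.full(self.n_nodes, -1, dtype=np.int64)
        for v in self.postorder():
            if self.is_tip(v):
                base[v] = self.tip_pop[v]
            else:
                p = base[int(self.left[v])]
                q = base[int(self.right[v])]
                while not anc[p, q]:
                    p = int(species.parent[p])
                base[v] = p
        return base

    def node_pops(self, species: SpeciesTree) -> np.ndarray:
        """Species-tree branch containing each node, resolved by its age.

        Raises :class:`ConstraintError` when a coalescence is younger than
        the species divergence of the populations it joins.
        """
        base = self.base_pops(species)
        pops = np.empty(self.n_nodes, dtype=np.int64)
        for v in range(self.n_nodes):
            p = int(base[v])
            a = self.age[v]
            if a < species.tau[p] - 1e-15:
                raise ConstraintError(
                    f"coalescence at age {a} predates species divergence "
                    f"tau={species.tau[p]} of population {species.names[p]}"
                )
            while species.parent[p] >= 0 and a >= species.tau[species.parent[p]]:
                p = int(species.parent[p])
            pops[v] = p
        return pops

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        for v in range(self.n_nodes):
            if self.parent[v] >= 0:
                bl[v] = self.age[self.parent[v]] - self.age[v]
        return bl

    def to_newick(self) -> str:
        def rec(v):
            bl = 0.0 if self.parent[v] < 0 else self.age[self.parent[v]] - self.age[v]
            if self.is_tip(v):
                return f"{self.labels[v]}:{bl:.12g}"
            return (f"({rec(int(self.left[v]))},{rec(int(self.right[v]))})"
                    f":{bl:.12g}")

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, source: str, pop_of_sample: dict, species: SpeciesTree):
        """Read a genealogy with branch lengths; ages from tip depth."""
        tree = _read_dendropy(source)
        leaves = list(tree.leaf_node_iter())
        internals = list(tree.postorder_internal_node_iter())
        order = leaves + internals
        idx = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = [-1] * n
        left = [-1] * n
        right = [-1] * n
        depth = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                depth[id(nd)] = 0.0
            else:
                depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        height = max(depth[id(lf)] for lf in leaves)
        age = [height - depth[id(nd)] for nd in order]
        for i in range(len(leaves)):
            age[i] = 0.0
        for nd in internals:
            ch = nd.child_nodes()
            if len(ch) != 2:
                raise ValueError("gene tree must be bifurcating")
            i = idx[id(nd)]
            left[i], right[i] = idx[id(ch[0])], idx[id(ch[1])]
            parent[left[i]] = i
            parent[right[i]] = i
        labels = [lf.taxon.label for lf in leaves]
        tip_pop = [species.index(pop_of_sample[lab]) for lab in labels]
        return cls(labels, parent, left, right, age, tip_pop,
                   pop_names=species.names)

    def __repr__(self):
        return (f"GeneTree({self.n_tips} tips, "
                f"tmrca={self.age[self.root]:.4g})")
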