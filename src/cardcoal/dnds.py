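"""NG86 dN/dS machinery and substitution-rate diagnostics.

Implements Nei-Gojobori (1986) counting with equal-weight averaging over all
minimal mutational pathways that avoid stop codons, Jukes-Cantor correction
of the proportions, per-lineage dN/dS against a common outgroup, an
island/mainland ratio, a per-codon dN-dS neutrality test on parsimony-
inferred changes, fixed amino-acid changes, uncorrected distances,
outgroup-scaled relative substitution rates, and patristic branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .codes import get_code
from .core import LocusAlignment

__all__ = [
    "DnDsRecord", "CodonSiteTest", "UndefinedCorrectionError",
    "ng86_site_counts", "ng86_pairwise", "ng86_codon_differences",
    "lineage_dnds",
    "island_mainland_ratio", "codon_site_test", "fixed_aa_changes",
    "p_distance", "relative_rate", "branch_length_to_outgroup",
]

_NT = "ACGT"


class UndefinedCorrectionError(ValueError):
    """Jukes-Cantor correction undefined (proportion >= 3/4)."""


@dataclass
class DnDsRecord:
    """Synonymous/nonsynonymous site and difference counts for a comparison."""

    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    n_codons: int
    ps: float = field(init=False)
    pn: float = field(init=False)
    ds: float = field(init=False)
    dn: float = field(init=False)

    def __post_init__(self):
        self.ps = self.s_diffs / self.s_sites if self.s_sites > 0 else 0.0
        self.pn = self.n_diffs / self.n_sites if self.n_sites > 0 else 0.0
        # JC correction saturates at p = 3/4; distances are NaN beyond it
        self.ds = (-0.75 * math.log1p(-4.0 * self.ps / 3.0)
                   if self.ps < 0.75 else float("nan"))
        self.dn = (-0.75 * math.log1p(-4.0 * self.pn / 3.0)
                   if self.pn < 0.75 else float("nan"))

    @property
    def ratio(self) -> float:
        """dN/dS; NaN when dS = 0 (undefined-by-zero)."""
        if self.ds == 0.0:
            return float("nan")
        return self.dn / self.ds

    @property
    def defined(self) -> bool:
        return self.ds > 0.0


@dataclass
class CodonSiteTest:
    """Per-codon dN-dS statistics from parsimony-inferred changes."""

    table: pd.DataFrame          # codon, s_diffs, n_diffs, dn, ds, stat, p
    n_changes: float
    ties_flagged: int            # parsimony ties broken alphabetically

    def positive(self) -> pd.DataFrame:
        return self.table[self.table["stat"] > 0]


def ng86_site_counts(codon: str, genetic_code: str = "standard"):
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    Each position contributes the fraction of its single-nucleotide
    neighbours that are synonymous, with mutations to stop codons excluded
    from the denominator; S + N = 3 always.
    """
    code = get_code(genetic_code)
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _NT for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = code[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for b in _NT:
            if b == codon[pos]:
                continue
            cand = codon[:pos] + b + codon[pos + 1:]
            if code[cand] == "*":
                continue
            viable += 1
            if code[cand] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


def _pathway_counts(c1: str, c2: str, code: dict):
    """Average (syn, nonsyn) step counts over minimal stop-free pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff)
    if k == 0:
        return 0.0, 0.0
    valid = []
    fallback = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code[nxt] == "*":
                blocked = True
            if code[nxt] == code[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if blocked else valid).append((sd, nd))
    paths = valid if valid else fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _codons(seq: str):
    seq = seq.upper()
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def ng86_pairwise(seq1: str, seq2: str,
                  genetic_code: str = "standard") -> DnDsRecord:
    """NG86 pairwise dN/dS with pathway averaging and JC correction.

    Codons containing N/-/ambiguity in either sequence are excluded
    (pairwise deletion); internal stop codons are an error.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    code = get_code(genetic_code)
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    n_used = 0
    for c1, c2 in zip(_codons(seq1), _codons(seq2)):
        if any(b not in _NT for b in c1 + c2):
            continue
        if code[c1] == "*" or code[c2] == "*":
            raise ValueError(f"internal stop codon in comparison: {c1}/{c2}")
        s1, _ = ng86_site_counts(c1, genetic_code)
        s2, _ = ng86_site_counts(c2, genetic_code)
        s_sites += 0.5 * (s1 + s2)
        n_sites += 3.0 - 0.5 * (s1 + s2)
        sd, nd = _pathway_counts(c1, c2, code)
        s_diffs += sd
        n_diffs += nd
        n_used += 1
    if n_used == 0:
        raise ValueError("no comparable codons")
    rec = DnDsRecord(s_sites=s_sites, n_sites=n_sites,
                     s_diffs=s_diffs, n_diffs=n_diffs, n_codons=n_used)
    for p in (rec.ps, rec.pn):
        if p >= 0.75:
            raise UndefinedCorrectionError(
                f"proportion {p:.3f} >= 3/4; JC correction undefined")
    return rec


def ng86_codon_differences(c1: str, c2: str,
                           genetic_code: str = "standard"):
    """(synonymous, nonsynonymous) difference counts for one codon pair,
    averaged over minimal stop-free mutational pathways."""
    code = get_code(genetic_code)
    for c in (c1, c2):
        if len(c) != 3 or any(b not in _NT for b in c.upper()):
            raise ValueError(f"invalid codon {c!r}")
        if code[c.upper()] == "*":
            raise ValueError(f"stop codon {c!r}")
    return _pathway_counts(c1.upper(), c2.upper(), code)


@dataclass
class LineageDnDs:
    per_haplotype: pd.DataFrame        # group, haplotype, dn, ds, ratio
    group_median: dict                 # group -> median ratio (NaN if undefined)
    overall_median: float


def lineage_dnds(codon_aln: LocusAlignment, groups: dict, outgroup_id: str,
                 genetic_code: str | None = None) -> LineageDnDs:
    """dN/dS of each haplotype against a common outgroup, summarized per group.

    ``groups`` maps group names to lists of sequence ids partitioning the
    ingroup; the group value is the median over its haplotypes and the
    across-group value is the median of group medians.
    """
    if genetic_code is None:
        genetic_code = codon_aln.genetic_code
    seq = dict(zip(codon_aln.ids, codon_aln.seqs))
    if outgroup_id not in seq:
        raise ValueError(f"outgroup {outgroup_id!r} not in alignment")
    rows = []
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} has no haplotypes")
        for hap in members:
            if hap not in seq:
                raise ValueError(f"haplotype {hap!r} not in alignment")
            rec = ng86_pairwise(seq[hap], seq[outgroup_id], genetic_code)
            rows.append({"group": gname, "haplotype": hap,
                         "dn": rec.dn, "ds": rec.ds, "ratio": rec.ratio})
    df = pd.DataFrame(rows)
    med = {}
    for gname in groups:
        vals = df.loc[df.group == gname, "ratio"].dropna()
        med[gname] = float(vals.median()) if len(vals) else float("nan")
    defined = [v for v in med.values() if not math.isnan(v)]
    overall = float(np.median(defined)) if defined else float("nan")
    return LineageDnDs(per_haplotype=df, group_median=med,
                       overall_median=overall)


def island_mainland_ratio(r_island: float, r_mainland: float) -> float:
    """(dN/dS island) / (dN/dS mainland); > 1 means faster island evolution."""
    if not r_mainland > 0:
        raise ValueError("mainland dN/dS must be > 0")
    return r_island / r_mainland


def _fitch_states(column: dict, tree, tiebreak_flags: list):
    """Fitch parsimony states for one nucleotide column on a rooted tree.

    ``column`` maps tip labels to observed bases ('N'/'-' = any).  Returns a
    dict node-id -> base.  Ties are broken by alphabetical base order and
    counted through ``tiebreak_flags``.
    """
    sets = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            b = column[nd.taxon.label]
            sets[id(nd)] = set(_NT) if b not in _NT else {b}
        else:
            ch = nd.child_nodes()
            inter = set.intersection(*(sets[id(c)] for c in ch))
            sets[id(nd)] = inter if inter else set.union(
                *(sets[id(c)] for c in ch))
    states = {}
    for nd in tree.preorder_node_iter():
        ss = sets[id(nd)]
        if nd.parent_node is None:
            if len(ss) > 1:
                tiebreak_flags.append(True)
            states[id(nd)] = min(ss)
        else:
            p = states[id(nd.parent_node)]
            if p in ss:
                states[id(nd)] = p
            else:
                if len(ss) > 1:
                    tiebreak_flags.append(True)
                states[id(nd)] = min(ss)
    return states


def _nj_guide_tree(codon_aln: LocusAlignment):
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor
    import dendropy

    ids = list(codon_aln.ids)
    matrix = []
    for i in range(len(ids)):
        row = []
        for j in range(i + 1):
            row.append(0.0 if i == j else
                       p_distance(codon_aln.seqs[i], codon_aln.seqs[j]))
        matrix.append(row)
    dm = DistanceMatrix(ids, matrix)
    nj = DistanceTreeConstructor().nj(dm)
    import io as _io
    buf = _io.StringIO()
    from Bio import Phylo
    Phylo.write(nj, buf, "newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                             suppress_internal_node_taxa=True)
    return tree


def codon_site_test(codon_aln: LocusAlignment, guide_tree=None,
                    genetic_code: str | None = None) -> CodonSiteTest:
    """Per-codon dN-dS test from parsimony-inferred changes on a guide tree.

    Ancestral nucleotides come from Fitch parsimony per position (ties broken
    alphabetically and flagged); per-codon synonymous/nonsynonymous change
    counts are scaled by the codon's NG86 site counts, and a two-sided
    binomial test with success probability N/(N+S) gives the p-value.
    Positive statistics indicate an overabundance of nonsynonymous change.
    """
    if genetic_code is None:
        genetic_code = codon_aln.genetic_code
    code = get_code(genetic_code)
    if codon_aln.n_sites % 3:
        raise ValueError("alignment length must be a multiple of 3")
    if guide_tree is None:
        guide_tree = _nj_guide_tree(codon_aln)
    tree_taxa = {lf.taxon.label for lf in guide_tree.leaf_node_iter()}
    if set(codon_aln.ids) - tree_taxa:
        raise ValueError("guide tree is missing alignment taxa")

    seq = dict(zip(codon_aln.ids, (s.upper() for s in codon_aln.seqs)))
    n_codons = codon_aln.n_sites // 3
    ties: list = []
    rows = []
    total_changes = 0.0
    for ci in range(n_codons):
        # per-position ancestral states
        states = []
        for off in range(3):
            pos = 3 * ci + off
            column = {sid: s[pos] for sid, s in seq.items()}
            states.append(_fitch_states(column, guide_tree, ties))
        node_codon = {}
        for nd in guide_tree.preorder_node_iter():
            node_codon[id(nd)] = "".join(st[id(nd)] for st in states)
        # observed site counts at this codon (mean over sense tip codons)
        tip_codons = [seq[sid][3 * ci:3 * ci + 3] for sid in codon_aln.ids]
        sense = [c for c in tip_codons
                 if all(b in _NT for b in c) and code[c] != "*"]
        if not sense:
            rows.append({"codon": ci + 1, "s_diffs": 0.0, "n_diffs": 0.0,
                         "dn": 0.0, "ds": 0.0, "stat": 0.0, "p": 1.0})
            continue
        s_site = float(np.mean([ng86_site_counts(c, genetic_code)[0]
                                for c in sense]))
        n_site = 3.0 - s_site
        sd = nd = 0.0
        for node in guide_tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            c_par = node_codon[id(node.parent_node)]
            c_ch = node_codon[id(node)]
            if node.is_leaf():
                obs = seq[node.taxon.label][3 * ci:3 * ci + 3]
                if any(b not in _NT for b in obs):
                    continue  # missing data: no inferred change at the tip
                c_ch = obs
            if c_par == c_ch:
                continue
            if code.get(c_par) == "*" or code.get(c_ch) == "*":
                continue  # parsimony artefact through a stop; skip
            psd, pnd = _pathway_counts(c_par, c_ch, code)
            sd += psd
            nd += pnd
        total_changes += sd + nd
        dn = nd / n_site if n_site > 0 else 0.0
        ds = sd / s_site if s_site > 0 else 0.0
        n_tot = int(round(sd + nd))
        if n_tot == 0:
            p = 1.0
        else:
            p0 = n_site / (n_site + s_site)
            p = float(stats.binomtest(min(int(round(nd)), n_tot), n_tot,
                                      p0).pvalue)
        rows.append({"codon": ci + 1, "s_diffs": sd, "n_diffs": nd,
                     "dn": dn, "ds": ds, "stat": dn - ds, "p": p})
    return CodonSiteTest(table=pd.DataFrame(rows), n_changes=total_changes,
                         ties_flagged=len(ties))


def fixed_aa_changes(codon_aln: LocusAlignment, focal_group,
                     genetic_code: str | None = None,
                     others=None):
    """Amino-acid positions fixed in the focal group and absent elsewhere.

    A position counts when every focal haplotype shares one residue that
    occurs in no non-focal haplotype (unknown residues are ignored; a
    position with any unknown focal residue cannot be called fixed).
    ``others`` restricts the comparison set (e.g. to the sister lineage);
    default is all non-focal sequences.
    """
    if genetic_code is None:
        genetic_code = codon_aln.genetic_code
    code = get_code(genetic_code)
    focal = list(focal_group)
    if not focal:
        raise ValueError("focal group must be non-empty")
    seq = dict(zip(codon_aln.ids, (s.upper() for s in codon_aln.seqs)))
    if others is None:
        others = [i for i in codon_aln.ids if i not in set(focal)]
    if not others:
        raise ValueError("need at least one non-focal sequence")

    def residue(sid, ci):
        c = seq[sid][3 * ci:3 * ci + 3]
        if any(b not in _NT for b in c):
            return None
        return code[c]

    positions = []
    for ci in range(codon_aln.n_sites // 3):
        focal_res = {residue(s, ci) for s in focal}
        if None in focal_res or len(focal_res) != 1:
            continue
        res = focal_res.pop()
        other_res = {residue(s, ci) for s in others} - {None}
        if other_res and res not in other_res:
            positions.append(ci + 1)
    return len(positions), positions


def p_distance(seq1: str, seq2: str) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion of N/-."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    comp = 0
    diff = 0
    for a, b in zip(s1, s2):
        if a in _NT and b in _NT:
            comp += 1
            if a != b:
                diff += 1
    if comp == 0:
        raise ValueError("no comparable sites")
    return diff / comp


def relative_rate(locus_aln: LocusAlignment, cytb_aln: LocusAlignment,
                  outgroup_id: str,
                  cytb_rate_per_lineage: float = 1.0e-8) -> float:
    """Substitution rate of a locus scaled to the cytochrome-b clock.

    rate = cytb_rate * (mean ingroup p-distance to the outgroup at the locus)
    / (same at cyt b).  The default cyt-b rate, 1.0e-8 per site per lineage
    per year, is the 2%-per-million-years between-lineage clock.
    """
    def mean_dist(aln):
        seq = dict(zip(aln.ids, aln.seqs))
        if outgroup_id not in seq:
            raise ValueError(f"outgroup {outgroup_id!r} not in alignment "
                             f"{aln.name!r}")
        ds = [p_distance(seq[i], seq[outgroup_id])
              for i in aln.ids if i != outgroup_id]
        if not ds:
            raise ValueError(f"no ingroup sequences in {aln.name!r}")
        return float(np.mean(ds))

    d_locus = mean_dist(locus_aln)
    d_cytb = mean_dist(cytb_aln)
    if d_cytb == 0:
        raise ValueError("zero cytochrome-b distance; rate undefined")
    return cytb_rate_per_lineage * d_locus / d_cytb


def branch_length_to_outgroup(tree, taxa, outgroup_id: str):
    """Patristic distance from a taxon (or mean over taxa) to the outgroup."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = {t.label: t for t in tree.taxon_namespace}
    if outgroup_id not in labels:
        raise ValueError(f"taxon {outgroup_id!r} not in tree")
    single = isinstance(taxa, str)
    names = [taxa] if single else list(taxa)
    out = []
    for name in names:
        if name not in labels:
            raise ValueError(f"taxon {name!r} not in tree")
        out.append(pdm.patristic_distance(labels[name], labels[outgroup_id]))
    return out[0] if single else float(np.mean(out))
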