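"""Synthetic datasets with the statistical structure of the cardinal study.

The default scenario is a six-population species tree — four mainland
lineages with large theta and two island lineages (mariae, saturatus) with
small theta — sampled for nine nuclear loci plus one 1041-bp mtDNA-like
protein-coding locus (inheritance scaler 0.25, rate roughly ten times the
nuclear mean).  Node labels follow the study's lettering: A is the root
(carneus versus the rest), D the recent island split (coccineus-saturatus,
prior calibrated to the island's re-emergence) and E the older island split
(igneus-mariae).  All defaults live in one table below and every one can be
overridden.

An optional acceleration multiplies the mtDNA branch lengths subtending one
lineage's samples before sequences are simulated, emulating a genuine
substitution-rate increase in a small island population; nuclear loci are
never touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import LocusSpec, PriorSet
from .core import GammaPrior
from .io import write_fasta, write_population_map
from .simulate import simulate_alignment, simulate_codon_alignment, simulate_gene_tree
from .trees import GeneTree, SpeciesTree

__all__ = ["CardinalScenario", "make_cardinal_scenario",
           "make_island_pair_scenario", "make_calibration_scenario",
           "generate_dataset", "generate_codon_dataset", "DEFAULTS"]

_MU = 1.23e-8  # reference (ND2) substitution rate, per site per year

# One table of scenario constants.  theta = 4 * Ne * mu with Ne (in
# individuals) from the multilocus estimates of the study system; tau in
# expected substitutions/site at the reference rate, ordered A > B > C > E > D
# with the older island split (E) about three times the recent one (D).
DEFAULTS = {
    "newick": ("(carneus,((igneus,mariae)E,"
               "(cardinalis,(coccineus,saturatus)D)C)B)A;"),
    "theta": {
        "cardinalis": 4 * 0.850e6 * _MU,
        "carneus": 4 * 0.583e6 * _MU,
        "igneus": 4 * 0.593e6 * _MU,
        "mariae": 4 * 0.197e6 * _MU,
        "saturatus": 4 * 0.132e6 * _MU,
        "coccineus": 4 * 0.311e6 * _MU,
        "D": 4 * 0.963e6 * _MU,
        "C": 4 * 1.274e6 * _MU,
        "E": 4 * 0.752e6 * _MU,
        "B": 4 * 0.907e6 * _MU,
        "A": 4 * 0.305e6 * _MU,
    },
    "tau": {"D": 0.0015, "E": 0.0045, "C": 0.008, "B": 0.011, "A": 0.014},
    "samples_per_pop": {"cardinalis": 6, "carneus": 5, "igneus": 6,
                        "mariae": 4, "coccineus": 5, "saturatus": 4},
    # locus: (length bp, substitution rate per site per year, scaler, ploidy)
    # nuclear loci are phased haplotypes: two sequences per individual
    "loci": {
        "ACA":    (1160, 1.29e-9, 1.0, 2),
        "ACO1":   (947, 1.02e-9, 0.75, 2),    # Z-linked
        "bact3":  (414, 2.18e-9, 1.0, 2),
        "EEF2":   (729, 2.05e-9, 1.0, 2),
        "FGB5":   (559, 1.02e-9, 1.0, 2),
        "HMGN2":  (788, 3.97e-9, 1.0, 2),
        "MYC":    (724, 7.68e-10, 1.0, 2),
        "ODC":    (676, 6.4e-10, 1.0, 2),
        "RHO":    (280, 1.54e-9, 1.0, 2),
        "ND2":    (1041, 1.23e-8, 0.25, 1),   # maternal, one sequence each
    },
    "outgroup": {"name": "sinuatus", "tau": 0.05, "theta": 0.012,
                 "theta_root": 0.015},
    "n_codons": 347,  # 1041 / 3, the mtDNA locus in codons
}


@dataclass
class CardinalScenario:
    species: SpeciesTree
    loci: list                      # LocusSpec per locus
    samples_per_pop: dict
    priors: PriorSet
    test_nodes: list = field(default_factory=lambda: [
        ["coccineus", "saturatus"], ["igneus", "mariae"]])
    mu: float = _MU

    @property
    def mt_locus(self) -> LocusSpec:
        return next(l for l in self.loci if l.mtdna)

    def truth_dict(self) -> dict:
        return {
            "newick": self.species.to_newick(),
            **self.species.params_dict(),
            "samples_per_pop": self.samples_per_pop,
            "loci": [vars(l) for l in self.loci],
            "mu": self.mu,
        }


def make_cardinal_scenario(overrides: dict | None = None,
                           rng=None) -> CardinalScenario:
    """Build the default six-population scenario, applying overrides.

    ``overrides`` may replace ``tau``/``theta`` entries (merged per node),
    ``samples_per_pop`` (merged per population), or ``loci`` wholesale.
    The construction is deterministic; ``rng`` is accepted for interface
    uniformity and unused.
    """
    ov = overrides or {}
    unknown = set(ov) - {"tau", "theta", "samples_per_pop", "loci"}
    if unknown:
        raise ValueError(f"unknown scenario overrides {sorted(unknown)}")
    theta = dict(DEFAULTS["theta"], **ov.get("theta", {}))
    tau = dict(DEFAULTS["tau"], **ov.get("tau", {}))
    species = SpeciesTree.from_newick(DEFAULTS["newick"], theta=theta, tau=tau)
    samples = dict(DEFAULTS["samples_per_pop"], **ov.get("samples_per_pop", {}))
    for p, c in samples.items():
        if c < 1:
            raise ValueError(f"samples_per_pop[{p}] must be >= 1")
    loci = []
    for name, (length, rate, scaler, ploidy) in ov.get(
            "loci", DEFAULTS["loci"]).items():
        loci.append(LocusSpec(
            name=name, length=length, scaler=scaler,
            rate_multiplier=rate / DEFAULTS["loci"]["ND2"][1],
            mtdna=(scaler == 0.25),
            genetic_code=("vertebrate-mitochondrial" if scaler == 0.25
                          else "standard"),
            ploidy=ploidy,
        ))
    priors = PriorSet(
        theta=GammaPrior(1.0, 100.0),
        tau_default=GammaPrior(1.0, 40.0),
        tau={"D": GammaPrior(1.0, 670.0)},
    )
    return CardinalScenario(species=species, loci=loci,
                            samples_per_pop=samples, priors=priors)


def make_island_pair_scenario(island: str = "mariae",
                              mainland: str = "igneus",
                              overrides: dict | None = None) -> CardinalScenario:
    """Two-population scenario for one island-mainland divergence.

    Extracts the sister pair's subtree (tau of their ancestor, the three
    thetas) from the six-population defaults and keeps the full locus table,
    sample sizes and priors, so a pipeline run on it mirrors the null-test
    study design at its natural scale.
    """
    full = make_cardinal_scenario(overrides)
    species = full.species.two_pop_subtree(island, mainland)
    samples = {p: full.samples_per_pop[p] for p in (island, mainland)}
    return CardinalScenario(species=species, loci=full.loci,
                            samples_per_pop=samples, priors=full.priors,
                            test_nodes=[[island, mainland]], mu=full.mu)


def make_calibration_scenario() -> CardinalScenario:
    """Two-population scenario for validating the stochasticity test itself.

    A well-identified island-mainland split (tau = 0.005, all theta = 0.01,
    five samples per population) with ten informative 500-bp loci plus the
    1041-bp mtDNA-like locus.  At these conditions tau is large relative to
    the mtDNA ancestral coalescent scale (theta/4/2), so the null test is
    calibrated *and* has power against a five-fold mtDNA rate acceleration
    -- unlike the island-pair conditions, where theta_anc/8 is comparable
    to tau and a single-locus test is underpowered by construction.
    """
    species = SpeciesTree(
        ["island", "mainland", "anc"],
        [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
        [0.0, 0.0, 0.005], [0.01, 0.01, 0.01],
    )
    loci = [LocusSpec(name=f"L{i + 1}", length=500) for i in range(10)]
    loci.append(LocusSpec(name="MT", length=1041, scaler=0.25, mtdna=True,
                          genetic_code="vertebrate-mitochondrial"))
    return CardinalScenario(
        species=species, loci=loci,
        samples_per_pop={"island": 5, "mainland": 5},
        priors=PriorSet(theta=GammaPrior(1.0, 100.0),
                        tau_default=GammaPrior(1.0, 40.0)),
        test_nodes=[["island", "mainland"]],
    )


def _focal_branch_scale(g: GeneTree, species: SpeciesTree, lineage: str,
                        multiplier: float) -> np.ndarray:
    """Per-node branch multipliers for a focal-lineage rate shift.

    Every branch all of whose descendant samples belong to ``lineage`` is
    multiplied, including each maximal focal clade's stem, so the focal
    lineage's mean branch length scales by the multiplier.
    """
    idx = species.index(lineage)
    base = g.base_pops(species)
    scale = np.ones(g.n_nodes)
    scale[base == idx] = multiplier
    return scale


def generate_dataset(scenario: CardinalScenario, accelerate=None,
                     rng: np.random.Generator | None = None,
                     out_dir=None) -> dict:
    """Simulate one full multi-locus dataset from the scenario.

    ``accelerate`` is ``None`` or ``(lineage, multiplier)``: the multiplier
    is applied to all mtDNA branch segments subtending the lineage's samples
    before sequence simulation; nuclear loci are unaffected.
    """
    if rng is None:
        rng = np.random.default_rng()
    s = scenario.species
    if accelerate is not None:
        lineage, mult = accelerate
        if lineage not in s.tip_names:
            raise ValueError(f"unknown lineage {lineage!r}")
        if not mult > 0:
            raise ValueError("acceleration multiplier must be > 0")
    alignments = {}
    gene_trees = {}
    for spec in scenario.loci:
        counts = {p: n * spec.ploidy
                  for p, n in scenario.samples_per_pop.items()}
        g = simulate_gene_tree(s, counts, scaler=spec.scaler, rng=rng)
        branch_scale = None
        if accelerate is not None and spec.mtdna:
            branch_scale = _focal_branch_scale(g, s, accelerate[0],
                                               accelerate[1])
        aln = simulate_alignment(g, spec.length, rate_multiplier=spec.rate_multiplier,
                                 rng=rng, scaler=spec.scaler, name=spec.name,
                                 branch_scale=branch_scale)
        aln.genetic_code = spec.genetic_code
        alignments[spec.name] = aln
        gene_trees[spec.name] = g

    truth = scenario.truth_dict()
    truth["accelerate"] = list(accelerate) if accelerate else None
    truth["gene_trees"] = {n: t.to_newick() for n, t in gene_trees.items()}
    result = {"alignments": alignments, "gene_trees": gene_trees,
              "truth": truth, "scenario": scenario}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in alignments.items():
            write_fasta(aln, out / f"{name}.fasta")
        pm: dict = {}
        for aln in alignments.values():
            pm.update(aln.pop_map)
        write_population_map(pm, out / "populations.tsv")
        (out / "species.nwk").write_text(s.to_newick() + "\n")
        (out / "species.json").write_text(s.to_json() + "\n")
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return result


def _outgroup_tree(scenario: CardinalScenario) -> SpeciesTree:
    og = DEFAULTS["outgroup"]
    s = scenario.species
    theta = {s.names[i]: float(s.theta[i]) for i in range(s.n_nodes)}
    tau = {s.names[i]: float(s.tau[i]) for i in range(s.n_nodes)
           if not s.is_tip(i)}
    theta[og["name"]] = og["theta"]
    theta["ROOT"] = og["theta_root"]
    tau["ROOT"] = og["tau"]
    nwk = f"({og['name']},{s.to_newick()[:-1]})ROOT;"
    return SpeciesTree.from_newick(nwk, theta=theta, tau=tau)


def generate_codon_dataset(scenario: CardinalScenario, omega_map: dict,
                           rng: np.random.Generator | None = None,
                           out_dir=None) -> dict:
    """Simulate the mtDNA-like locus at codon level with lineage-specific
    dN/dS, including a single outgroup sample for rooting comparisons.

    ``omega_map`` maps lineage names to omega; the ``"default"`` entry (0.05
    if absent) applies to all other branches.  Branch omegas follow the same
    subtending-samples rule as the rate acceleration.
    """
    if rng is None:
        rng = np.random.default_rng()
    omega_map = dict(omega_map)
    default_w = float(omega_map.pop("default", 0.05))
    ext = _outgroup_tree(scenario)
    for lin in omega_map:
        if lin not in ext.tip_names:
            raise ValueError(f"unknown lineage {lin!r} in omega_map")
        if not omega_map[lin] > 0:
            raise ValueError("omega must be > 0")

    samples = dict(scenario.samples_per_pop)
    samples[DEFAULTS["outgroup"]["name"]] = 1
    mt = scenario.mt_locus
    g = simulate_gene_tree(ext, samples, scaler=mt.scaler, rng=rng)
    omega = np.full(g.n_nodes, default_w)
    base = g.base_pops(ext)
    for lin, w in omega_map.items():
        omega[base == ext.index(lin)] = float(w)
    n_codons = DEFAULTS["n_codons"]
    aln = simulate_codon_alignment(g, n_codons, omega,
                                   genetic_code=mt.genetic_code, rng=rng,
                                   rate_multiplier=mt.rate_multiplier,
                                   name=f"{mt.name}_codon")
    truth = {"omega": {"default": default_w, **omega_map},
             "n_codons": n_codons, "gene_tree": g.to_newick(),
             "outgroup": DEFAULTS["outgroup"]["name"]}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(aln, out / f"{mt.name}_codon.fasta")
        (out / "codon_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return {"alignment": aln, "gene_tree": g, "truth": truth}
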