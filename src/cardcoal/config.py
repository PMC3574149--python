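"""Run configuration: a flat, human-editable YAML file.

One ``loci`` section lists the per-locus inputs (path, inheritance scaler,
rate multiplier); global sections carry the species topology, priors, MCMC
settings and simulation settings.  Unknown keys are rejected so typos fail
loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import GammaPrior

__all__ = ["LocusSpec", "McmcSettings", "SimSettings", "PriorSet",
           "RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class LocusSpec:
    name: str
    path: str | None = None
    length: int | None = None          # length hint; checked against the file
    scaler: float = 1.0                # inheritance scaler on theta
    rate_multiplier: float = 1.0       # relative to the reference (mtDNA) rate
    mtdna: bool = False
    genetic_code: str = "standard"
    ploidy: int = 1                    # haplotypes sampled per individual

    def __post_init__(self):
        if self.scaler <= 0 or self.rate_multiplier <= 0:
            raise ConfigError(
                f"locus {self.name!r}: scaler and rate_multiplier must be > 0")
        if self.ploidy < 1:
            raise ConfigError(f"locus {self.name!r}: ploidy must be >= 1")


@dataclass
class McmcSettings:
    """Sampler settings; defaults follow the empirical analysis scale."""

    generations: int = 100_000
    burnin: int = 10_000
    thinning: int = 5
    seed: int | None = None
    # proposal widths; None means auto (0.3 x prior SD, then tuned in burn-in)
    w_age: float | None = None
    w_tau: float | None = None
    w_logtheta: float = 0.5
    w_mix: float = 0.3
    tune: bool = True

    def __post_init__(self):
        if not (self.generations > self.burnin >= 0):
            raise ConfigError("require generations > burn-in >= 0")
        if self.thinning < 1:
            raise ConfigError("thinning must be >= 1")
        for w in (self.w_logtheta, self.w_mix):
            if w <= 0:
                raise ConfigError("proposal widths must be > 0")
        for w in (self.w_age, self.w_tau):
            if w is not None and w <= 0:
                raise ConfigError("proposal widths must be > 0")


@dataclass
class SimSettings:
    """Null-distribution simulation settings (defaults from the study design)."""

    n_sims: int = 100
    locus_length: int = 1041
    generations: int = 50_000
    burnin: int | None = None          # default: generations // 5

    def __post_init__(self):
        if self.n_sims < 1 or self.locus_length < 1:
            raise ConfigError("n_sims and locus_length must be >= 1")


@dataclass
class PriorSet:
    """Gamma priors: one for every theta, per-node gammas for tau."""

    theta: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 100.0))
    tau_default: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 40.0))
    tau: dict = field(default_factory=dict)   # node label -> GammaPrior

    def tau_for(self, label: str) -> GammaPrior:
        return self.tau.get(label, self.tau_default)


@dataclass
class RunConfig:
    loci: list
    pop_map: dict
    species_tree_source: str
    priors: PriorSet = field(default_factory=PriorSet)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    simulation: SimSettings = field(default_factory=SimSettings)
    test_nodes: list = field(default_factory=list)   # [[island, mainland], ...]
    base_dir: Path = field(default_factory=Path)

    def locus(self, name: str) -> LocusSpec:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "loci": [vars(l) for l in self.loci],
            "species_tree": self.species_tree_source,
            "mcmc": vars(self.mcmc),
            "simulation": vars(self.simulation),
            "priors": {
                "theta": vars(self.priors.theta),
                "tau_default": vars(self.priors.tau_default),
                "tau": {k: vars(v) for k, v in self.priors.tau.items()},
            },
            "test_nodes": self.test_nodes,
            "n_samples": len(self.pop_map),
        }


_TOP_KEYS = {"species_tree", "population_map", "priors", "mcmc",
             "simulation", "loci", "test_nodes"}
_LOCUS_KEYS = {"name", "path", "length", "scaler", "rate_multiplier",
               "mtdna", "genetic_code", "ploidy"}
_PRIOR_KEYS = {"theta", "tau_default", "tau"}
_MCMC_KEYS = {"generations", "burnin", "thinning", "seed",
              "w_age", "w_tau", "w_logtheta", "w_mix", "tune"}
_SIM_KEYS = {"n_sims", "locus_length", "generations", "burnin"}


def _gamma(d, where) -> GammaPrior:
    if not isinstance(d, dict) or set(d) - {"alpha", "beta"}:
        raise ConfigError(f"{where}: expected {{alpha, beta}}")
    return GammaPrior(float(d["alpha"]), float(d["beta"]))


def load_config(path) -> RunConfig:
    """Load, validate and resolve a YAML run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    base = path.parent

    loci = []
    for entry in raw.get("loci", []):
        bad = set(entry) - _LOCUS_KEYS
        if bad:
            raise ConfigError(
                f"{path}: locus {entry.get('name', '?')!r}: unknown keys {sorted(bad)}")
        spec = LocusSpec(**entry)
        if spec.path is not None:
            fp = base / spec.path
            if not fp.exists():
                raise ConfigError(
                    f"{path}: locus {spec.name!r}: file not found: {fp}")
            spec.path = str(fp)
        loci.append(spec)
    if not loci:
        raise ConfigError(f"{path}: at least one locus is required")
    names = [l.name for l in loci]
    if len(names) != len(set(names)):
        raise ConfigError(f"{path}: duplicate locus names")

    if "population_map" not in raw or "species_tree" not in raw:
        raise ConfigError(f"{path}: species_tree and population_map are required")
    from .io import read_population_map
    pop_map = read_population_map(base / raw["population_map"])

    pr = raw.get("priors", {}) or {}
    bad = set(pr) - _PRIOR_KEYS
    if bad:
        raise ConfigError(f"{path}: priors: unknown keys {sorted(bad)}")
    priors = PriorSet()
    if "theta" in pr:
        priors.theta = _gamma(pr["theta"], "priors.theta")
    if "tau_default" in pr:
        priors.tau_default = _gamma(pr["tau_default"], "priors.tau_default")
    for lab, d in (pr.get("tau") or {}).items():
        priors.tau[lab] = _gamma(d, f"priors.tau[{lab}]")

    mc = raw.get("mcmc", {}) or {}
    bad = set(mc) - _MCMC_KEYS
    if bad:
        raise ConfigError(f"{path}: mcmc: unknown keys {sorted(bad)}")
    mcmc = McmcSettings(**mc)

    sm = raw.get("simulation", {}) or {}
    bad = set(sm) - _SIM_KEYS
    if bad:
        raise ConfigError(f"{path}: simulation: unknown keys {sorted(bad)}")
    sim = SimSettings(**sm)

    tree_src = raw["species_tree"]
    if "(" not in tree_src:
        fp = base / tree_src
        if not fp.exists():
            raise ConfigError(f"{path}: species tree file not found: {fp}")
        tree_src = str(fp)

    return RunConfig(loci=loci, pop_map=pop_map, species_tree_source=tree_src,
                     priors=priors, mcmc=mcmc, simulation=sim,
                     test_nodes=[list(x) for x in raw.get("test_nodes", [])],
                     base_dir=base)
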