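# cardcoal

Coalescent tests for mitochondrial/multilocus divergence-time discordance
in structured species.

## The problem

Speciation times estimated from mtDNA alone are often older than estimates
from multilocus data, and the discrepancy is largest for small, isolated
populations — classically, island lineages that look "older than their
island". Two very different mechanisms produce this pattern:

1. **Coalescent stochasticity.** A single locus coalesces in the ancestral
   population; when the ancestral θ = 4·N_e·μ is large relative to the
   divergence time τ, the mtDNA gene divergence can predate the population
   split by a lot, purely by chance.
2. **A real substitution-rate acceleration.** Nearly neutral theory
   predicts that small populations fix slightly deleterious mutations at a
   higher rate; an elevated mtDNA substitution rate in a small island
   population stretches its branches and inflates mtDNA-based ages, while
   the (higher-N_e) nuclear genome is buffered.

`cardcoal` implements the complete analysis that separates the two, for
anyone working on island–mainland (or any shallow structured) systems:

* **Multispecies-coalescent machinery** — gene-tree simulation within a
  species tree, Jukes–Cantor likelihoods, and a Bayesian MCMC estimator of
  divergence times (τ) and population mutation rates (θ) on a fixed
  topology, integrating over per-locus genealogies (per-node gamma priors,
  inheritance scalers so mtDNA and Z-linked loci enter correctly).
* **The ΔT statistic** — per node, ΔT = 100·(t_mt − t_ml)/t_mt, the percent
  excess of the mtDNA-only age over the multilocus age.
* **The stochasticity test** — simulate many single mtDNA-like loci under
  the two-population model at the multilocus parameter estimates (θ ÷ 4
  for mitochondrial inheritance), re-estimate each by MCMC, and report
  P = proportion of simulated mean ages at least as old as the observed
  mtDNA estimate. P ≈ 0 means stochasticity cannot explain the discordance.
* **dN/dS diagnostics** — NG86 counting with stop-aware pathway averaging,
  per-lineage dN/dS against an outgroup, island/mainland ratios, a
  per-codon dN−dS neutrality test, fixed amino-acid changes, and
  outgroup-scaled relative substitution rates — the evidence that a
  rejection reflects relaxed purifying selection in the small population.
* **A synthetic-data generator** emulating the cardinal (\*Cardinalis
  cardinalis\*-like) study design: six populations with two small-θ island
  lineages, nine nuclear loci plus a 1041-bp mtDNA-like locus, and an
  optional lineage-specific mtDNA rate acceleration, so the entire pipeline
  runs and validates with no downloads.

See `docs/methods.md` for the model, priors, sampler and all defaults.

## Worked example

Generate an accelerated synthetic dataset and run the discordance test on
the old island node (the igneus–mariae split, node E), at a reduced desk
scale:

```python
import numpy as np
from cardcoal import generate_dataset, run_discordance
from cardcoal.config import McmcSettings, SimSettings
from cardcoal.experiments import ANC_THETA_MTDNA
from cardcoal import make_cardinal_scenario

scenario = make_cardinal_scenario(overrides={"theta": ANC_THETA_MTDNA})
data = generate_dataset(scenario, accelerate=("mariae", 5.0),
                        rng=np.random.default_rng(1))
report = run_discordance(
    list(data["alignments"].values()), scenario.species, scenario.priors,
    test_nodes=[["igneus", "mariae"]],
    settings=McmcSettings(generations=25_000, burnin=5_000, thinning=10),
    sim=SimSettings(n_sims=50, locus_length=1041, generations=30_000,
                    burnin=6_000),
    seed=1)
print(report.table[["node", "t_mt", "t_ml", "delta_t_pct", "p_value"]]
      .to_string(index=False))
```

which prints (node E is the accelerated island split; the other rows are
the remaining internal nodes, not tested against a null):

```
node     t_mt     t_ml  delta_t_pct  p_value
   E 0.011660 0.004598    60.568307      0.0
   D 0.001867 0.000792    57.596923      NaN
   C 0.009198 0.007860    14.546509      NaN
   B 0.016545 0.011326    31.542042      NaN
   A 0.020578 0.018592     9.646981      NaN
```

Reading: the mtDNA age of the island node E is 61% older than the
multilocus age (τ in substitutions/site at the mtDNA clock: 0.0117 vs
0.0046, i.e. about 0.95 vs 0.37 Mya at 1.23×10⁻⁸/site/yr), and none of the
50 null simulations reaches the observed value (P = 0.00) — coalescent
stochasticity is rejected, correctly, because this dataset carries a
five-fold mtDNA rate acceleration on mariae. The same pipeline on an
unaccelerated small-θ recent-island dataset produces positive ΔT with a
non-significant P (see the replication experiment in
`cardcoal.experiments`).

The same pipeline is available from the shell:

```bash
cardcoal --seed 1 --out-dir demo make-synthetic --accelerate mariae:5 \
         --codon-omega "default=0.04,mariae=0.18"
cardcoal --seed 1 --config run.yaml --out-dir results discordance
cardcoal --out-dir dnds_out dnds --fasta demo/ND2_codon.fasta \
         --pop-map demo/populations.tsv --outgroup 'sinuatus^1' \
         --island mariae --mainland igneus
```

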