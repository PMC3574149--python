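# Methods

`cardcoal` implements a complete analysis for deciding whether a
mitochondrial/multilocus divergence-time conflict in a structured species is
an artefact of coalescent stochasticity or evidence of a real
substitution-rate shift in a small (island) population. This note describes
the models, the estimator, the test, the synthetic data, the numerical
choices, and what the validation runs do and do not demonstrate.

## Model

**Multispecies coalescent (MSC).** A fixed rooted bifurcating species tree
over named populations carries a divergence time τ at every internal node
and a population mutation rate θ = 4·N_e·μ per site at every node (extant
and ancestral; ancestral θ are free parameters with the same prior as extant
ones). Time is measured in expected substitutions per site **at the
reference (mitochondrial ND2) rate**; per-locus rate multipliers convert
node-age differences into branch lengths for each locus, and per-locus
inheritance scalers multiply θ inside the coalescent density (1 autosomal,
0.75 Z-linked, 0.25 mtDNA). Within a population interval containing j
lineages, the next coalescence waits an exponential time with rate
j(j−1)/(θ·scaler); lineages surviving past a population's upper τ merge
into the ancestral population. No gene flow, no recombination within loci,
free recombination between loci.

**Sequences.** Jukes–Cantor (JC69) substitution with uniform base
frequencies and no site-rate heterogeneity; `N` and `-` are treated as
missing data and marginalized at the tip (indel resolution and richer
substitution models are upstream concerns outside this package's scope).

**Priors.** Independent Gamma(α, β) priors (mean α/β) on every θ and every
internal-node τ, with the τ ordering constraint (parent ≥ child) enforced by
rejection at initialization and by proposal bounds during sampling. Defaults
follow the study design: θ ~ Γ(1, 100) (mean 0.01); τ ~ Γ(1, 40) (mean
0.025, Early-Pleistocene scale at the 1.23×10⁻⁸/site/yr reference clock)
except the recent island node D, which gets Γ(1, 670) — the mean-matched
exponential for the island's re-emergence 121 kyr ago
(τ = 121 000 × 1.23×10⁻⁸ ≈ 1.488×10⁻³ ≈ 1/672).

## Posterior sampling

`mcmc_run` is a Metropolis–Hastings sampler over (τ, θ, per-locus gene
trees) on the fixed topology. One *generation* is one cycle of a fixed move
schedule (this package's unit for all generation counts):

* per locus, `1 + n_tips//6` **node-age slides** (uniform window with
  reflection at the constraint boundaries — children's ages, the species
  divergence below the node, the parent's age);
* per locus, with probability 0.4, a **lineage regraft**: a Wilson–Balding
  style move that detaches a subtree, picks a target branch uniformly, and
  re-coalesces on the compatible age interval (uniform density; exponential
  above the root), with the proposal-density ratio as the Hastings factor;
* a multiplicative log-scale update of **every θ** (Jacobian included);
* a **rubber-band update of one randomly chosen τ**: node ages inside the
  two child populations rescale linearly between the bounding times, ages in
  the parent interval rescale from above (or shift, at the root), with
  Hastings factor (new span/old span)^(#rescaled nodes);
* every second generation, a **mixing move** scaling all τ, θ and node ages
  by a common factor c = e^{λ(u−1/2)} with Hastings (#dimensions)·log c.

Proposal widths start at 0.3× the relevant prior SD and are tuned toward
20–40% acceptance during the first 80% of burn-in, then frozen, preserving
detailed balance in the sampling phase.

The implementation keeps incremental caches: the coalescent log-density is
stored per population as a coalescence count and a ∫j(j−1)dt integral (so θ
updates are O(1), age slides touch only the populations on the moved node's
time chain, and the mixing move rescales the integrals analytically), and
pruning partials are persistent with path-to-root updates for age slides.
All caches are rebuilt from scratch every 1024 generations, and the test
suite verifies the incrementally maintained log-posterior against the
pure-Python reference density/likelihood after hundreds of moves, so cache
bugs cannot hide. Correctness of the whole cycle is further checked by
data-free prior recovery (every move class active), by a KS test of the
data-free θ marginal against its Gamma prior, and by agreement with a
numeric-quadrature oracle for the one-population two-sequence posterior.

Summaries are arithmetic means with equal-tail 95% intervals (2.5/97.5
percentiles, linear interpolation between order statistics; the choice of
equal-tail over HPD is a convention of this package). ESS is
n/(1 + 2Σρ_k) with the autocorrelation sum truncated at the first
non-positive term.

An mtDNA-only fit keeps the inheritance scaler 0.25 inside the coalescent
density, so its reported θ stays in nuclear units and its τ is directly
comparable with multilocus fits.

## The discordance statistic and the stochasticity test

For each internal node, ΔT = 100·(t_mt − t_ml)/t_mt, where t_mt and t_ml
are the posterior-mean τ from the mtDNA-only and the multilocus fit. The
mtDNA estimate is the denominator, so ΔT is bounded above by 100% and
positive when mtDNA looks older.

For an island–mainland sister pair the test asks whether an old mtDNA
estimate is explained by single-locus coalescent variance. A two-population
tree is assembled from the multilocus posterior means (the pair's two
extant θ, the ancestral θ, and the node's τ), the mtDNA four-fold reduction
in effective size is applied, and `n_sims` replicates of a single 1041-bp
locus are simulated and re-estimated by MCMC with the same priors as the
empirical analysis (shorter chains; the defaults are 100 simulations and
50 000-generation fits). P is the exact proportion of simulated
posterior-mean τ at least as old as the observed mtDNA estimate, so
P·n_sims is an integer and P = 0.00 means "older than everything
simulated".

One calibration subtlety: the ÷4 adjustment is routed through the
inheritance scaler (simulate with scaler 0.25, fit with scaler 0.25) rather
than by pre-dividing the tree and fitting at scaler 1. The two simulation
processes are identical, but only the scaler route puts the null fits on
exactly the same effective prior scale as the mtDNA-only fit that produced
the observed statistic; fitting mt-unit θ against the nuclear-unit prior
would tilt P slightly. `build_null` supports both routes.

## Synthetic data

`make_cardinal_scenario` builds the six-population study design: topology
(carneus,((igneus,mariae)E,(cardinalis,(coccineus,saturatus)D)C)B)A with
the two island lineages (mariae, saturatus) having the smallest extant θ.
All defaults live in one table (`cardcoal.synth.DEFAULTS`):

* θ = 4·N_e·μ from the multilocus effective-size estimates of the study
  system at μ = 1.23×10⁻⁸/site/yr (extant 0.0065–0.042, ancestral
  0.015–0.063);
* τ: D = 0.0015 (the island-age calibration), E = 3×D = 0.0045, then
  C = 0.008, B = 0.011, A = 0.014 (root ≈ 1.1 Mya at the reference clock) —
  C/B/A are package choices on the Pleistocene scale the priors assume;
* nine nuclear loci with the study's lengths and relative rates
  (multipliers 0.05–0.32 relative to ND2) plus the 1041-bp mtDNA-like locus
  (scaler 0.25, multiplier 1);
* 4–6 *individuals* per population; nuclear loci are phased diploid
  haplotypes, so they carry two sequences per individual (ploidy 2), the
  maternal mtDNA one.

`generate_dataset` simulates one gene tree and alignment per locus. An
optional acceleration `(lineage, m)` multiplies every mtDNA branch whose
descendant samples all belong to the focal lineage by m — including each
focal clade's stem — so the lineage's mean mtDNA branch length scales by m;
nuclear loci are untouched. This emulates a genuine substitution-rate
increase confined to one island lineage's mitochondrial genome.

`generate_codon_dataset` produces the mtDNA locus at codon level (347
codons, vertebrate-mitochondrial code) with lineage-specific dN/dS: along
each branch, candidate single-nucleotide events arise at the JC rate;
candidates creating stops are rejected, nonsynonymous candidates are
accepted with probability ω, synonymous ones always (accept–reject thinning
rather than a 61×61 rate-matrix exponential — exact enough for calibration
at these scales and far simpler; the ω = 1 case reproduces NG86
dN/dS ≈ 1). A single outgroup lineage (diverging at τ = 0.05) is included
for the outgroup-referenced statistics.

**What the generator does not emulate:** phasing uncertainty, indels,
recombination, site-rate heterogeneity, non-JC substitution, gene flow.
Passing tests therefore demonstrate internal consistency of the analysis
under its own model assumptions, not robustness to their violation.

## dN/dS machinery

NG86 counting: per sense codon, each position contributes the fraction of
its non-stop single-nucleotide neighbours that are synonymous (S + N = 3);
per codon pair, differences are averaged with equal weight over all minimal
mutational pathways avoiding stops (if every pathway is blocked, the
blocked pathways are used); proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), with p ≥ 3/4 an error. Codons containing N/-/gaps
in either sequence are excluded (pairwise deletion). Per-lineage dN/dS is
the median over the lineage's haplotypes of the haplotype-vs-outgroup
ratio; ratios with dS = 0 are undefined and excluded from medians. The
island/mainland ratio is the simple quotient of the sister lineages'
values.

The per-codon selection test infers ancestral states by Fitch parsimony per
nucleotide position on a guide tree (default: neighbour joining on
p-distances; ties broken alphabetically and flagged), accumulates
synonymous/nonsynonymous changes over branches with pathway averaging,
scales them by the codon's site counts (mean NG86 counts over the observed
sense codons in the column), and reports dN − dS with a two-sided binomial
p-value (success probability N/(N+S), fractional counts rounded). The
binomial null is conservative at the small per-codon counts involved; the
neutral type-I rate is verified ≤ 8% at α = 0.05.

Relative locus rates are mean ingroup→outgroup p-distances scaled to the
cytochrome-b clock (2%/My between lineages = 1.0×10⁻⁸/site/lineage/yr),
with each alignment's own ingroup (the loci may have different individuals
sequenced). Branch lengths to the outgroup are patristic distances, with a
group mean over lineage members.

## Validation experiments and problem sizes

The experiment runners in `cardcoal.experiments` freeze the two validation
configurations; the test suite and `scripts/acceptance.py` both use them.

**Calibration/power of the stochasticity test** uses a well-identified
two-population scenario: τ = 0.005, all θ = 0.01 (the same conditions used
for parameter recovery), ten 500-bp loci plus the 1041-bp mtDNA locus,
five samples per population. Here τ is large against the mtDNA ancestral
coalescent scale (θ/4/2 ≈ 0.00125), so the full pipeline (multilocus fit →
null from the fitted parameters → P for the mtDNA fit) is both calibrated
under the null and powerful against a 5× island mtDNA acceleration. This
scenario choice is deliberate: at the island-pair conditions themselves
(τ_E = 0.0045 with multilocus ancestral θ giving θ_anc,mt/2 ≈ 0.0046), a
single-locus test is underpowered *by construction* — the same physics that
makes the recent island node discordant-but-unrejectable. Scaled runs use
n_sims = 50 and 20 000-generation fits.

**End-to-end island–mainland replication** runs the six-population
pipeline on two kinds of dataset, five replicates each (single datasets
are hostage to one mtDNA genealogy draw, so the accelerated claims are
checked by majority and the stochasticity-only discordance — whose
per-dataset sign is the noisiest quantity — by its mean across
replicates):

* *accelerated*: 5× mtDNA acceleration on mariae, with ancestral θ set
  from the mtDNA-based effective-size estimates (≈0.0093–0.0107). This is
  the regime the study system's mtDNA actually occupies — island lineages
  monophyletic with long stems — and the regime in which a rate
  acceleration is detectable. Under the large multilocus ancestral θ the
  simulated mtDNA genealogy is ILS-heavy at node E: island samples do not
  coalesce before joining the mainland lineages, the acceleration signal
  spreads into fitted ancestral θ and the deeper-node ages, and both ΔT
  and the test lose their target. The expected pattern (checked): largest
  ΔT at node E and P_E ≤ 0.05.
* *unaccelerated*: the large multilocus ancestral θ (the stochasticity
  driver) combined with the small mtDNA-based extant θ for the recent
  island pair (saturatus ≈ 0.0024, coccineus ≈ 0.0070) and a divergence
  younger than the island-age prior mean (τ_D = 0.0008 ≈ 65 kyr): the
  island's mtDNA enters the ancestral population as one or two lineages
  whose cross-coalescence wait — scale θ_anc,mt/2 — systematically exceeds
  τ_D, while the prior anchors the fits from below. This makes the
  discordance one-sided (with τ_D at the prior mean its per-dataset sign
  rides on a single genealogy draw) and the null conservative. Expected
  pattern: mean ΔT_D > 0 with P_D > 0.05 — discordance that the test
  correctly attributes to stochasticity.

Main fits use 25 000 generations, null fits 30 000, n_sims = 50. All
problem sizes here are the package's desk-scale defaults; the full-scale
study settings (100 000-generation fits, 100 simulations) remain the
configuration defaults.

## Numerical choices and edge cases

* Degenerate inputs: single-sample loci have zero coalescent density and a
  stationary-only likelihood; constant traces make ESS an error, not a
  number; an empty null distribution is an error.
* The sampler revalidates nothing silently: genealogy states that violate
  the species-tree constraints evaluate to −10³⁰⁰ and are rejected (they
  can only arise through bugs, since all moves are constraint-preserving by
  construction; the public density function raises instead).
* Pattern compression: site patterns are deduplicated per locus before
  likelihood evaluation.
* Pairwise deletion everywhere in distance computations; parsimony ties
  broken deterministically (alphabetical) and counted.
* Reported θ of mtDNA-containing fits are nuclear-unit (the scaler stays
  inside the density).

## Known limitations

* JC69 only; loci that strongly reject JC would need the out-of-scope
  richer models.
* The guide tree for the per-codon test is NJ by default; a poor guide
  tree biases per-codon counts (configurable).
* The stochasticity test inherits the plug-in error of the multilocus
  parameter estimates; with few informative loci the null center is noisy,
  and a strong mtDNA acceleration contaminates the multilocus fit itself
  (visible in the replication experiments as ΔT spreading into ancestral
  nodes).
* Power against island rate accelerations vanishes as θ_anc,mt/2
  approaches τ; this is a property of single-locus inference, not of the
  implementation.
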