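"""Canonical study-condition experiments.

These runners freeze the configurations used to validate the pipeline:
the calibration/power experiment for the coalescent-stochasticity test and
the end-to-end island-mainland replication arms.  Tests and the acceptance
script call them so every report comes from one definition.

Replication-arm configurations (full rationale in docs/methods.md):

* the accelerated arm sets the ancestral population sizes from the
  mtDNA-based estimates (``ANC_THETA_MTDNA``) — the regime in which island
  mtDNA lineages are monophyletic with long stems, where a five-fold rate
  acceleration on the old island lineage (mariae, node E) is detectable;
* the unaccelerated arm keeps the large multilocus ancestral sizes (the
  stochasticity driver) but gives the recent island pair the small
  mtDNA-based extant sizes and a divergence younger than the island-age
  prior mean ("very small island theta, recent tau"), producing robust
  mtDNA divergence-time discordance from coalescent stochasticity alone
  at node D (coccineus-saturatus).
"""

from __future__ import annotations

import numpy as np

from .config import McmcSettings, SimSettings
from .discordance import DiscordanceReport, run_discordance
from .synth import generate_dataset, make_calibration_scenario, make_cardinal_scenario

__all__ = ["stochasticity_replicate", "replication_arm",
           "ANC_THETA_MTDNA", "MU_REFERENCE"]

MU_REFERENCE = 1.23e-8  # reference (ND2) rate, per site per year

# theta = 4 * Ne * mu with the study system's mtDNA-based effective sizes
# (in millions), for every node of the six-population tree.  This is the
# regime the study's mitochondrial genealogy exhibits -- island lineages
# monophyletic with long ancestral stems -- which is where both halves of
# the island-mainland contrast (detectable acceleration at node E,
# stochasticity-only discordance at node D) live.
THETA_MTDNA = {
    "cardinalis": 4 * 0.675e6 * MU_REFERENCE,
    "carneus": 4 * 0.104e6 * MU_REFERENCE,
    "igneus": 4 * 0.185e6 * MU_REFERENCE,
    "mariae": 4 * 0.199e6 * MU_REFERENCE,
    "saturatus": 4 * 0.049e6 * MU_REFERENCE,
    "coccineus": 4 * 0.142e6 * MU_REFERENCE,
    "D": 4 * 0.217e6 * MU_REFERENCE,
    "C": 4 * 0.189e6 * MU_REFERENCE,
    "E": 4 * 0.207e6 * MU_REFERENCE,
    "B": 4 * 0.199e6 * MU_REFERENCE,
    "A": 4 * 0.193e6 * MU_REFERENCE,
}

# retained name: the ancestral-node subset (used where only the ancestral
# regime matters)
ANC_THETA_MTDNA = {k: THETA_MTDNA[k] for k in ("D", "C", "E", "B", "A")}


def stochasticity_replicate(seed: int, accelerate: bool = False,
                            n_sims: int = 50,
                            generations: int = 20_000) -> dict:
    """One full pipeline replicate of the calibration/power experiment.

    Generates a dataset from the two-population calibration scenario
    (optionally with a five-fold mtDNA rate acceleration on the island
    lineage), fits the multilocus and mtDNA-only models, builds the
    simulation null at the multilocus estimates and returns the tested
    node's row: ``p_value``, ``delta_t_pct``, ``t_mt``, ``t_ml``.
    """
    scenario = make_calibration_scenario()
    rng = np.random.default_rng([seed, 17])
    ds = generate_dataset(
        scenario, accelerate=("island", 5.0) if accelerate else None, rng=rng)
    report = run_discordance(
        list(ds["alignments"].values()), scenario.species, scenario.priors,
        scenario.test_nodes,
        settings=McmcSettings(generations=generations,
                              burnin=generations // 5, thinning=10),
        sim=SimSettings(n_sims=n_sims, locus_length=1041,
                        generations=generations, burnin=generations // 5),
        seed=seed)
    row = report.table.iloc[0]
    return {"p_value": float(row["p_value"]),
            "delta_t_pct": float(row["delta_t_pct"]),
            "t_mt": float(row["t_mt"]), "t_ml": float(row["t_ml"])}


def replication_arm(kind: str, seed: int, n_sims: int = 50,
                    main_generations: int = 25_000,
                    null_generations: int = 30_000) -> DiscordanceReport:
    """One dataset of the six-population island-mainland replication.

    ``kind`` is ``"accelerated"`` (five-fold mtDNA acceleration on the old
    island lineage, mariae; the igneus-mariae node E is tested) or
    ``"unaccelerated"`` (very small island theta on the recent island
    lineage, saturatus; the coccineus-saturatus node D is tested).
    """
    if kind == "accelerated":
        scenario = make_cardinal_scenario(
            overrides={"theta": ANC_THETA_MTDNA})
        accelerate = ("mariae", 5.0)
        nodes = [["igneus", "mariae"]]
    elif kind == "unaccelerated":
        scenario = make_cardinal_scenario(overrides={
            "theta": {"saturatus": THETA_MTDNA["saturatus"],
                      "coccineus": THETA_MTDNA["coccineus"]},
            "tau": {"D": 0.0008},
        })
        accelerate = None
        nodes = [["coccineus", "saturatus"]]
    else:
        raise ValueError("kind must be 'accelerated' or 'unaccelerated'")
    rng = np.random.default_rng([seed, 55])
    ds = generate_dataset(scenario, accelerate=accelerate, rng=rng)
    return run_discordance(
        list(ds["alignments"].values()), scenario.species, scenario.priors,
        nodes,
        settings=McmcSettings(generations=main_generations,
                              burnin=main_generations // 5, thinning=10),
        sim=SimSettings(n_sims=n_sims, locus_length=1041,
                        generations=null_generations,
                        burnin=null_generations // 5),
        seed=seed)
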