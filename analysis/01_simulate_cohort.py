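#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the targeted-panel design: 98 lung adenocarcinomas in four driver
groups (ERBB2-Ex20mut n=19, EGFR-Ex20mut n=13, EGFR-Ex18/19/21mut n=40,
EGFR/ERBB2wt n=26) profiled on a 770-gene immune panel with 20 housekeeping,
8 negative-control and 6 positive-control probes. Hot/cold infiltration
states and per-population latent abundances are recorded as ground truth.

On top of the infiltration structure, group-specific expression effects are
planted against the wild-type group to give the downstream stages realistic
signal: a block of genes shifted in all three mutated groups (the
"shared-feature" pattern), blocks exclusive to each group, and a down-shift
of the granzyme/perforin cytotoxicity markers in the two EGFR-mutated
groups (immunologically colder tumors).

Writes results/cohort/{counts,probes,samples,truth,gene_truth,planted_effects}.tsv.
"""

from pathlib import Path

from immunopanel.synthetic import (
    GROUP_EGFR_CLASSICAL, GROUP_EGFR_EX20, GROUP_ERBB2_EX20, GROUP_WT,
    PlantedEffect, SimulationConfig, simulate_cohort, write_cohort,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 7
MUTATED = [GROUP_ERBB2_EX20, GROUP_EGFR_EX20, GROUP_EGFR_CLASSICAL]


def demo_effects() -> list[PlantedEffect]:
    effects = []
    gene_no = iter(range(1, 200))
    # up- and down-shifts shared by all three mutated groups vs wild type
    for _ in range(6):
        g = f"GENE_{next(gene_no):04d}"
        effects += [PlantedEffect(g, m, GROUP_WT, 1.3) for m in MUTATED]
    for _ in range(5):
        g = f"GENE_{next(gene_no):04d}"
        effects += [PlantedEffect(g, m, GROUP_WT, -1.3) for m in MUTATED]
    # exclusive blocks per mutated group
    for m, n_up, n_down in [(GROUP_ERBB2_EX20, 12, 10),
                            (GROUP_EGFR_EX20, 6, 5),
                            (GROUP_EGFR_CLASSICAL, 5, 6)]:
        for _ in range(n_up):
            effects.append(PlantedEffect(f"GENE_{next(gene_no):04d}", m, GROUP_WT, 1.5))
        for _ in range(n_down):
            effects.append(PlantedEffect(f"GENE_{next(gene_no):04d}", m, GROUP_WT, -1.5))
    # colder cytotoxic compartment in EGFR-mutated tumors
    for g in ("GZMA", "PRF1", "GZMB", "GNLY"):
        for m in (GROUP_EGFR_EX20, GROUP_EGFR_CLASSICAL):
            effects.append(PlantedEffect(g, m, GROUP_WT, -1.0))
    return effects


def main() -> None:
    config = SimulationConfig(seed=SEED, planted_effects=demo_effects())
    counts, probes, samples, truth = simulate_cohort(config)
    write_cohort(OUT, counts, probes, samples, truth)
    n_hot = (truth.samples["state"] == "hot").sum()
    print(f"cohort: {counts.shape[0]} probes x {counts.shape[1]} samples (seed {SEED})")
    print(samples["group"].value_counts().to_string())
    print(f"planted infiltration states: {n_hot} hot / {98 - n_hot} cold")
    print(f"planted expression effects: {len(config.planted_effects)} "
          f"on {truth.effects['gene_id'].nunique()} genes")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
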