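"""Synthetic panel cohorts with known ground truth.

The generator emulates a targeted immune expression study of a 98-sample lung
adenocarcinoma cohort split into four driver-mutation groups (19 / 13 / 40 / 26
samples), profiled on a 770-gene immuno-oncology panel with housekeeping,
negative-control and positive-control probes. Its generative model:

1. each sample draws a latent hot/cold infiltration state from its group's
   ``hot_fraction`` (hot tumors are immune-infiltrated, cold tumors depleted);
2. each of the 14 immune populations draws a latent log2 abundance
   ``Normal(state mean, sd)`` per sample;
3. a marker gene's log2 mean is its baseline plus 1.0 x its population's
   latent abundance (unit slope keeps the score scale equal to the latent
   scale); non-marker genes are baseline plus any planted contrast effects;
4. counts are negative binomial with mean ``2**log2_mean * library_factor``
   and a common dispersion (var = m + dispersion * m^2);
5. housekeeping genes see only the library factor; negative controls are
   low-mean Poisson; positive controls are a fixed ladder times the library
   factor.

Everything is driven by one master seed; per-stage independent substreams are
spawned from it with ``numpy.random.SeedSequence`` in a fixed order (states,
latents, baselines, library factors, counts, controls), so adding samples or
genes perturbs only the affected stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import panel_io
from .scores import load_marker_catalog

# The four driver groups of the study design.
GROUP_ERBB2_EX20 = "ERBB2-Ex20mut"
GROUP_EGFR_EX20 = "EGFR-Ex20mut"
GROUP_EGFR_CLASSICAL = "EGFR-Ex18/19/21mut"
GROUP_WT = "EGFR/ERBB2wt"

DEFAULT_GROUP_SIZES = {
    GROUP_ERBB2_EX20: 19,
    GROUP_EGFR_EX20: 13,
    GROUP_EGFR_CLASSICAL: 40,
    GROUP_WT: 26,
}

# Cold tumors predominate in the mutated groups (13/19, 10/13, 24/40 cold)
# while most wild-type tumors are hot (17/26): hot fractions follow.
DEFAULT_HOT_FRACTIONS = {
    GROUP_ERBB2_EX20: 6 / 19,
    GROUP_EGFR_EX20: 3 / 13,
    GROUP_EGFR_CLASSICAL: 16 / 40,
    GROUP_WT: 17 / 26,
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class InfiltrationModel:
    """Two-state (hot/cold) latent infiltration on the log2 scale.

    Defaults put the hot and cold population means 2 SD apart, matching the
    clearly bimodal infiltration structure the pipeline is meant to classify.
    """

    hot_mean: float = 2.0
    cold_mean: float = 0.0
    sd: float = 1.0
    hot_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOT_FRACTIONS)
    )


@dataclass(frozen=True)
class PlantedEffect:
    """Additive log2 shift on one gene in ``group_a``.

    The shift applies to ``group_a`` samples only, so the expected difference
    of group mean log2 expression for the contrast (group_a - group_b) equals
    ``log2_effect`` exactly; ``group_b`` records the intended contrast.
    """

    gene: str
    group_a: str
    group_b: str
    log2_effect: float


@dataclass
class SimulationConfig:
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_genes: int = 770                # endogenous probes, markers included
    n_housekeeping: int = 20
    n_neg_controls: int = 8
    n_pos_controls: int = 6
    marker_catalog: dict[str, list[str]] | None = None  # None -> packaged catalog
    infiltration: InfiltrationModel = field(default_factory=InfiltrationModel)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    dispersion: float = 0.1           # NB: var = m + dispersion * m^2
    library_size_sd: float = 0.3      # SD of log2 library factor
    baseline_log2_range: tuple[float, float] = (5.0, 10.0)
    housekeeping_log2_range: tuple[float, float] = (9.0, 11.0)
    neg_control_mean: float = 2.0
    pos_control_ladder: tuple[float, ...] = (8192, 2048, 512, 128, 32, 8)
    seed: int = 0

    def resolved_catalog(self) -> dict[str, list[str]]:
        return self.marker_catalog if self.marker_catalog is not None else load_marker_catalog()


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated cohort.

    ``samples``: per-sample group, hot/cold state, library factor and latent
    log2 abundance per population (columns ``latent:<population>``).
    ``genes``: per-gene baseline log2 mean and probe class.
    ``effects``: the planted contrast effects as a table.
    """

    samples: pd.DataFrame
    genes: pd.DataFrame
    effects: pd.DataFrame


def _validate(config: SimulationConfig) -> None:
    for g, n in config.group_sizes.items():
        if n < 2:
            raise SimulationError(f"group {g!r} has size {n}; need >= 2")
    for g, f in config.infiltration.hot_fraction.items():
        if not 0.0 <= f <= 1.0:
            raise SimulationError(f"hot_fraction for {g!r} is {f}; must be in [0, 1]")
    missing = set(config.group_sizes) - set(config.infiltration.hot_fraction)
    if missing:
        raise SimulationError(f"hot_fraction missing for group(s): {sorted(missing)}")
    if config.dispersion <= 0:
        raise SimulationError(f"dispersion must be > 0, got {config.dispersion}")
    if config.library_size_sd < 0:
        raise SimulationError("library_size_sd must be >= 0")
    for eff in config.planted_effects:
        for g in (eff.group_a, eff.group_b):
            if g not in config.group_sizes:
                raise SimulationError(f"planted effect on {eff.gene!r} references unknown group {g!r}")


def _gene_universe(config: SimulationConfig) -> tuple[list[str], list[str], pd.Series]:
    """Marker genes first (real symbols), then synthetic filler genes."""
    catalog = config.resolved_catalog()
    marker_genes: list[str] = []
    marker_pop: dict[str, str] = {}
    for pop, genes in catalog.items():
        for g in genes:
            if g in marker_pop:
                raise SimulationError(
                    f"marker {g!r} appears in both {marker_pop[g]!r} and {pop!r}; "
                    "the generator requires one population per marker"
                )
            marker_pop[g] = pop
            marker_genes.append(g)
    if config.n_genes < len(marker_genes):
        raise SimulationError(
            f"n_genes={config.n_genes} cannot accommodate the {len(marker_genes)} "
            "marker genes of the catalog"
        )
    n_filler = config.n_genes - len(marker_genes)
    filler = [f"GENE_{i:04d}" for i in range(1, n_filler + 1)]
    genes = marker_genes + filler
    population = pd.Series(
        [marker_pop.get(g, "") for g in genes], index=genes, name="population"
    )
    return genes, marker_genes, population


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate one cohort; returns (counts, probes, samples, truth)."""
    config = config if config is not None else SimulationConfig()
    _validate(config)
    catalog = config.resolved_catalog()
    populations = list(catalog)

    ss = np.random.SeedSequence(config.seed)
    rng_states, rng_latent, rng_base, rng_lib, rng_counts, rng_ctrl = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    # --- samples ----------------------------------------------------------
    sample_ids, groups = [], []
    for group, n in config.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"S{len(sample_ids) + 1:03d}")
            groups.append(group)
    n_samples = len(sample_ids)
    groups_arr = np.asarray(groups)

    hot_p = np.array([config.infiltration.hot_fraction[g] for g in groups])
    is_hot = rng_states.random(n_samples) < hot_p
    state_mean = np.where(is_hot, config.infiltration.hot_mean, config.infiltration.cold_mean)

    # latent abundances: populations x samples
    latent = rng_latent.normal(
        loc=state_mean[None, :], scale=config.infiltration.sd,
        size=(len(populations), n_samples),
    )
    latent_df = pd.DataFrame(latent, index=populations, columns=sample_ids)

    # --- genes ------------------------------------------------------------
    genes, marker_genes, marker_pop = _gene_universe(config)
    lo, hi = config.baseline_log2_range
    baseline = rng_base.uniform(lo, hi, size=len(genes))
    hk_lo, hk_hi = config.housekeeping_log2_range
    hk_genes = [f"HK_{i:02d}" for i in range(1, config.n_housekeeping + 1)]
    hk_baseline = rng_base.uniform(hk_lo, hk_hi, size=len(hk_genes))
    neg_genes = [f"NEG_{i:02d}" for i in range(1, config.n_neg_controls + 1)]
    pos_genes = [f"POS_{i:02d}" for i in range(1, config.n_pos_controls + 1)]

    # --- expected log2 means (endogenous) --------------------------------
    log2_mean = np.tile(baseline[:, None], (1, n_samples))
    pop_index = {p: i for i, p in enumerate(populations)}
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in marker_genes:
        log2_mean[gene_index[g], :] += latent[pop_index[marker_pop[g]], :]
    for eff in config.planted_effects:
        if eff.gene not in gene_index:
            raise SimulationError(f"planted effect references unknown gene {eff.gene!r}")
        log2_mean[gene_index[eff.gene], groups_arr == eff.group_a] += eff.log2_effect

    # --- library factors and counts --------------------------------------
    lib = 2.0 ** rng_lib.normal(0.0, config.library_size_sd, size=n_samples)

    def nb(mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # numpy parameterization: n successes, success prob p; mean = n(1-p)/p
        n = 1.0 / config.dispersion
        p = n / (n + mean)
        return rng.negative_binomial(n, p, size=mean.shape)

    endo_mean = (2.0 ** log2_mean) * lib[None, :]
    endo_counts = nb(endo_mean, rng_counts)
    hk_mean = (2.0 ** hk_baseline)[:, None] * lib[None, :]
    hk_counts = nb(hk_mean, rng_counts)
    neg_counts = rng_ctrl.poisson(
        config.neg_control_mean, size=(len(neg_genes), n_samples)
    )
    base_ladder = np.asarray(config.pos_control_ladder, dtype=float)
    ladder = base_ladder[np.arange(len(pos_genes)) % len(base_ladder)][:, None]
    pos_counts = rng_ctrl.poisson(ladder * lib[None, :])

    counts = pd.DataFrame(
        np.vstack([endo_counts, hk_counts, neg_counts, pos_counts]).astype(np.int64),
        index=genes + hk_genes + neg_genes + pos_genes,
        columns=sample_ids,
    )
    counts.index.name = "gene_id"
    probes = pd.DataFrame(
        {
            "probe_class": (
                ["endogenous"] * len(genes)
                + ["housekeeping"] * len(hk_genes)
                + ["negative_control"] * len(neg_genes)
                + ["positive_control"] * len(pos_genes)
            )
        },
        index=counts.index,
    )
    samples = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))

    truth_samples = pd.DataFrame(
        {
            "group": groups,
            "state": np.where(is_hot, "hot", "cold"),
            "library_factor": lib,
        },
        index=samples.index,
    )
    for pop in populations:
        truth_samples[f"latent:{pop}"] = latent_df.loc[pop].values
    truth_genes = pd.DataFrame(
        {
            "baseline_log2": np.concatenate([baseline, hk_baseline]),
            "probe_class": ["endogenous"] * len(genes) + ["housekeeping"] * len(hk_genes),
            "population": list(marker_pop.values) + [""] * len(hk_genes),
        },
        index=pd.Index(genes + hk_genes, name="gene_id"),
    )
    effects = pd.DataFrame(
        [(e.gene, e.group_a, e.group_b, e.log2_effect) for e in config.planted_effects],
        columns=["gene_id", "group_a", "group_b", "log2_effect"],
    )
    truth = SimulationTruth(samples=truth_samples, genes=truth_genes, effects=effects)
    return counts, probes, samples, truth


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """The matched null: no planted effects, hot_fraction equal across groups.

    The common hot fraction is the group-size-weighted mean of the configured
    per-group fractions, so the marginal hot/cold mix is preserved while group
    labels carry no signal.
    """
    config = config if config is not None else SimulationConfig()
    sizes = config.group_sizes
    total = sum(sizes.values())
    mean_frac = sum(
        sizes[g] * config.infiltration.hot_fraction[g] for g in sizes
    ) / total
    infiltration = replace(
        config.infiltration, hot_fraction={g: mean_frac for g in sizes}
    )
    return replace(config, planted_effects=[], infiltration=infiltration)


def simulate_null(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate a cohort in which group labels are exchangeable (pure null)."""
    return simulate_cohort(null_config(config))


def write_cohort(
    out_dir: str | Path,
    counts: pd.DataFrame,
    probes: pd.DataFrame,
    samples: pd.DataFrame,
    truth: SimulationTruth | None = None,
    rcc: bool = False,
) -> dict[str, Path]:
    """Write counts.tsv, probes.tsv, samples.tsv (+ truth tables, RCC files)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "probes": out_dir / "probes.tsv",
        "samples": out_dir / "samples.tsv",
    }
    panel_io.write_counts(counts, paths["counts"])
    panel_io.write_probes(probes, paths["probes"])
    panel_io.write_samples(samples, paths["samples"])
    if truth is not None:
        paths["truth"] = out_dir / "truth.tsv"
        truth.samples.rename_axis("sample_id").to_csv(paths["truth"], sep="\t")
        paths["gene_truth"] = out_dir / "gene_truth.tsv"
        truth.genes.to_csv(paths["gene_truth"], sep="\t")
        paths["effects"] = out_dir / "planted_effects.tsv"
        truth.effects.to_csv(paths["effects"], sep="\t", index=False)
    if rcc:
        rcc_dir = out_dir / "rcc"
        panel_io.write_rcc(counts, probes, rcc_dir)
        paths["rcc_dir"] = rcc_dir
    return paths
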