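"""End-to-end orchestration: simulate/load -> normalize -> score -> cluster
-> differential expression -> enrichment, with a machine-readable summary.

All randomness flows from one recorded master seed; rerunning a config writes
byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, panel_io, synthetic
from .cluster import association_test, contingency_table, hcluster, label_hot_cold, center_rows
from .diffexp import de_analysis, significant_sets, venn_partition
from .enrichment import enrich
from .normalization import NormalizationParams, normalize
from .scores import TOTAL_TILS, load_marker_catalog, score_matrix

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    out_dir: str | Path = "results/run"
    # input paths; all None -> simulate a synthetic cohort instead
    counts_path: str | Path | None = None
    probes_path: str | Path | None = None
    samples_path: str | Path | None = None
    markers_path: str | Path | None = None
    genesets_path: str | Path | None = None
    sim_config: synthetic.SimulationConfig | None = None
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    cluster_distance: str = "euclidean"
    cluster_linkage: str = "average"
    reference_group: str = synthetic.GROUP_WT
    fdr: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ConfigError(f"FDR must be in (0, 1), got {self.fdr}")
        for name in ("counts_path", "probes_path", "samples_path", "markers_path", "genesets_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        provided = [self.counts_path, self.probes_path, self.samples_path]
        if any(p is not None for p in provided) and not all(p is not None for p in provided):
            raise ConfigError("counts_path, probes_path and samples_path must be given together")


def _parameter_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_run_summary(summary: dict) -> None:
    """Check a run summary against the packaged schema (required keys + types)."""
    schema = json.loads(
        (importlib_resources.files("immunopanel") / "resources" / "run_summary_schema.json").read_text()
    )
    type_map = {"object": dict, "array": list, "string": str, "integer": int, "number": (int, float)}
    missing = [k for k in schema["required"] if k not in summary]
    if missing:
        raise ConfigError(f"run summary missing required key(s): {missing}")
    for key, prop in schema["properties"].items():
        if key in summary and not isinstance(summary[key], type_map[prop["type"]]):
            raise ConfigError(f"run summary key {key!r} has wrong type")


def run_all(config: RunConfig) -> dict:
    """Run every pipeline stage, write outputs under ``config.out_dir``,
    return (and write) the run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    handler = _ListHandler(warnings)
    logging.getLogger("immunopanel").addHandler(handler)
    try:
        summary = _run_stages(config, out, warnings)
    finally:
        logging.getLogger("immunopanel").removeHandler(handler)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(record.getMessage())


def _run_stages(config: RunConfig, out: Path, warnings: list[str]) -> dict:
    stages: dict[str, dict] = {}

    # --- acquire inputs ---------------------------------------------------
    if config.counts_path is not None:
        counts, probes = panel_io.read_counts(config.counts_path, config.probes_path)
        samples = panel_io.read_samples(config.samples_path)
        panel_io.validate_samples(samples, counts.columns)
    else:
        sim = config.sim_config or synthetic.SimulationConfig(seed=config.seed)
        if config.sim_config is None:
            sim.seed = config.seed
        counts, probes, samples, truth = synthetic.simulate_cohort(sim)
        synthetic.write_cohort(out, counts, probes, samples, truth)
    if config.reference_group not in set(samples["group"]):
        raise ConfigError(f"reference group {config.reference_group!r} not in sample annotation")
    stages["input"] = {"n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1])}

    # --- normalize --------------------------------------------------------
    norm = normalize(counts, probes, config.normalization)
    norm.rename_axis("gene_id").to_csv(out / "normalized.tsv", sep="\t")
    stages["normalize"] = {"n_genes": int(norm.shape[0])}

    # --- immune-cell scores ----------------------------------------------
    catalog = load_marker_catalog(config.markers_path)
    scores = score_matrix(norm, catalog)
    scores.to_csv(out / "cell_scores.tsv", sep="\t")
    stages["score"] = {"n_rows": int(scores.shape[0])}

    # --- hot/cold clustering + genotype association ----------------------
    pop_scores = scores.loc[list(catalog)]
    assign = hcluster(
        center_rows(pop_scores), axis="columns",
        distance=config.cluster_distance, linkage=config.cluster_linkage, k=2,
    )
    hot_cold = label_hot_cold(assign, scores.loc[TOTAL_TILS])
    cluster_df = pd.DataFrame({"cluster": assign.labels, "state": hot_cold})
    cluster_df.rename_axis("sample_id").to_csv(out / "clusters.tsv", sep="\t")
    table = contingency_table(hot_cold, samples["group"])
    fisher = association_test(table)
    assoc = table.copy()
    assoc.loc["p_value"] = [fisher.pvalue] + [np.nan] * (table.shape[1] - 1)
    assoc.loc["method"] = [fisher.method] + [""] * (table.shape[1] - 1)
    assoc.to_csv(out / "association.tsv", sep="\t")
    n_hot = int((hot_cold == "hot").sum())
    n_cold = int((hot_cold == "cold").sum())
    stages["cluster"] = {"n_hot": n_hot, "n_cold": n_cold, "association_method": fisher.method}

    # --- differential expression -----------------------------------------
    de = de_analysis(norm, samples, reference=config.reference_group, fdr=config.fdr)
    de.to_csv(out / "de.tsv", sep="\t")
    de_scores = de_analysis(scores, samples, reference=config.reference_group, fdr=config.fdr)
    de_scores.to_csv(out / "de_cell_scores.tsv", sep="\t")
    n_sig = int(de["sig_omnibus"].sum())
    stages["de"] = {"n_omnibus_significant": n_sig}

    pairs = [(g, config.reference_group) for g in dict.fromkeys(samples["group"])
             if g != config.reference_group]
    venn: dict[str, dict[str, int]] = {}
    for direction in ("up", "down"):
        sets = [significant_sets(de, p, direction) for p in pairs[:3]]
        while len(sets) < 3:
            sets.append(set())
        names = tuple(a for a, _ in pairs[:3]) + tuple(
            f"unused{i}" for i in range(3 - len(pairs[:3]))
        )
        cells = venn_partition(*sets[:3], names=names[:3])
        venn[direction] = {"+".join(k): len(v) for k, v in cells.items()}
        rows = [("+".join(k), len(v), ",".join(sorted(v))) for k, v in cells.items()]
        pd.DataFrame(rows, columns=["cell", "n", "genes"]).to_csv(
            out / f"venn_{direction}.tsv", sep="\t", index=False
        )

    # --- enrichment -------------------------------------------------------
    if config.genesets_path is not None:
        genesets = panel_io.read_gmt(config.genesets_path)
    else:
        genesets = panel_io.read_gmt(
            str(importlib_resources.files("immunopanel") / "resources" / "genesets.gmt")
        )
    universe = set(norm.index)
    enr_frames = []
    for a, b in pairs:
        sig = significant_sets(de, (a, b), "up") | significant_sets(de, (a, b), "down")
        res = enrich(sig, universe, genesets)
        res.insert(0, "comparison", f"{a} vs {b}")
        enr_frames.append(res)
    enr = pd.concat(enr_frames) if enr_frames else pd.DataFrame()
    enr.to_csv(out / "enrichment.tsv", sep="\t")
    stages["enrich"] = {"n_rows": int(enr.shape[0])}

    summary = {
        "package_version": __version__,
        "seed": int(config.seed),
        "parameter_hash": _parameter_hash(config),
        "stages": stages,
        "n_samples": int(counts.shape[1]),
        "n_genes": int(norm.shape[0]),
        "n_hot": n_hot,
        "n_cold": n_cold,
        "n_omnibus_significant": n_sig,
        "venn_up": venn["up"],
        "venn_down": venn["down"],
        "cluster_association_p": float(fisher.pvalue),
        "warnings": warnings,
    }
    validate_run_summary(summary)
    return summary
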