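"""Readers and writers for targeted-panel artifacts.

All tabular artifacts are plain TSV (CSV accepted for counts). Counts tables
are gene-rows x sample-columns with a header row, matching the genes x samples
orientation used for panel heatmaps. Gene symbols are matched case-sensitively
after whitespace stripping; no alias resolution is attempted.

In-memory containers are deliberately plain:

* counts matrix      -- ``pandas.DataFrame`` (int, genes x samples)
* probe annotation   -- ``pandas.DataFrame`` indexed by gene_id with a single
                        ``probe_class`` column (one of :data:`PROBE_CLASSES`)
* sample annotation  -- ``pandas.DataFrame`` indexed by sample_id with a
                        ``group`` column plus optional covariates
* gene-set catalog   -- :class:`GeneSetCatalog`
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PROBE_CLASSES = ("endogenous", "housekeeping", "positive_control", "negative_control")

#: CodeClass values of the native nCounter export mapped onto our probe classes.
RCC_CLASS_MAP = {
    "Endogenous": "endogenous",
    "Housekeeping": "housekeeping",
    "Positive": "positive_control",
    "Negative": "negative_control",
}


class PanelIOError(ValueError):
    """Malformed or inconsistent input artifact."""


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], kind: str, where: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise PanelIOError(f"duplicate {kind} id(s) in {where}: {', '.join(map(str, sorted(dups)))}")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a genes x samples counts table to int.

    Raises :class:`PanelIOError` naming the offending gene/sample for negative
    or non-numeric entries, and listing duplicate ids.
    """
    _check_unique(list(counts.index), "gene", "counts matrix")
    _check_unique(list(counts.columns), "sample", "counts matrix")
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & counts.notna()
    if bad.any().any() or counts.isna().any().any():
        mask = numeric.isna()
        gene = mask.any(axis=1).idxmax()
        sample = mask.loc[gene].idxmax()
        raise PanelIOError(
            f"non-numeric count for gene {gene!r}, sample {sample!r}: {counts.loc[gene, sample]!r}"
        )
    if (numeric < 0).any().any():
        mask = numeric < 0
        gene = mask.any(axis=1).idxmax()
        sample = mask.loc[gene].idxmax()
        raise PanelIOError(
            f"negative count for gene {gene!r}, sample {sample!r}: {numeric.loc[gene, sample]}"
        )
    return numeric.round().astype(np.int64)


def validate_probes(probes: pd.DataFrame, genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Validate a probe annotation table (index gene_id, column probe_class)."""
    if "probe_class" not in probes.columns:
        raise PanelIOError("probe annotation must have a 'probe_class' column")
    _check_unique(list(probes.index), "gene", "probe annotation")
    unknown = set(probes["probe_class"]) - set(PROBE_CLASSES)
    if unknown:
        raise PanelIOError(
            f"unknown probe_class value(s): {sorted(unknown)}; expected one of {PROBE_CLASSES}"
        )
    if genes is not None:
        missing = [g for g in genes if g not in probes.index]
        if missing:
            raise PanelIOError(
                "genes absent from probe annotation: " + ", ".join(map(str, missing[:20]))
                + ("..." if len(missing) > 20 else "")
            )
    return probes


def validate_samples(samples: pd.DataFrame, sample_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Validate a sample annotation table (index sample_id, column group)."""
    if "group" not in samples.columns:
        raise PanelIOError("sample annotation must have a 'group' column")
    _check_unique(list(samples.index), "sample", "sample annotation")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in samples.index]
        if missing:
            raise PanelIOError("samples missing from annotation: " + ", ".join(map(str, missing)))
    return samples


# ---------------------------------------------------------------------------
# counts / annotation tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, header=0, dtype={0: str})
    raw.iloc[:, 0] = raw.iloc[:, 0].astype(str).str.strip()
    raw = raw.set_index(raw.columns[0])
    raw.index.name = raw.index.name.strip() if raw.index.name else None
    raw.columns = [str(c).strip() for c in raw.columns]
    return raw


def read_counts(path: str | Path, probe_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a counts TSV/CSV plus probe annotation, with strict validation."""
    counts = validate_counts(_read_table(path))
    probes = validate_probes(_read_table(probe_path), genes=counts.index)
    return counts, probes.loc[counts.index]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_probes(path: str | Path) -> pd.DataFrame:
    return validate_probes(_read_table(path))


def write_probes(probes: pd.DataFrame, path: str | Path) -> None:
    probes.rename_axis("gene_id").to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    return validate_samples(_read_table(path))


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# RCC (Reporter Code Count, the per-sample nCounter raw format)
# ---------------------------------------------------------------------------

def _parse_rcc_sections(text: str, path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def read_rcc(paths: Sequence[str | Path]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one-sample-per-file RCC exports into a counts matrix + probe annotation.

    Sample ids come from the ``ID`` field of ``<Sample_Attributes>``, falling
    back to the file stem. Unknown CodeClass values map to endogenous with a
    warning. Files must carry identical probe sets.
    """
    if not paths:
        raise PanelIOError("read_rcc requires at least one file")
    columns: dict[str, pd.Series] = {}
    classes_ref: pd.Series | None = None
    ref_path: Path | None = None
    for p in paths:
        p = Path(p)
        sections = _parse_rcc_sections(p.read_text(), p)
        if "Code_Summary" not in sections:
            raise PanelIOError(f"RCC file {p} lacks a <Code_Summary> section")
        sample_id = p.stem
        for line in sections.get("Sample_Attributes", []):
            fields = line.split(",")
            if fields[0] == "ID" and len(fields) > 1 and fields[1].strip():
                sample_id = fields[1].strip()
        genes, cls, vals = [], [], []
        for line in sections["Code_Summary"]:
            fields = [f.strip() for f in line.split(",")]
            if fields[0] == "CodeClass":  # header row
                continue
            if len(fields) < 4:
                raise PanelIOError(f"RCC file {p}: malformed Code_Summary line {line!r}")
            code_class, name, _accession, count = fields[0], fields[1], fields[2], fields[3]
            if code_class not in RCC_CLASS_MAP:
                log.warning("RCC file %s: unknown CodeClass %r for %s; treating as endogenous",
                            p, code_class, name)
            genes.append(name)
            cls.append(RCC_CLASS_MAP.get(code_class, "endogenous"))
            vals.append(count)
        col = pd.Series(vals, index=genes, name=sample_id)
        classes = pd.Series(cls, index=genes)
        if classes_ref is None:
            classes_ref, ref_path = classes, p
        else:
            diff = set(classes_ref.index) ^ set(classes.index)
            if diff:
                raise PanelIOError(
                    f"inconsistent probe sets between {ref_path} and {p}; "
                    f"symmetric difference: {', '.join(sorted(diff))}"
                )
        if sample_id in columns:
            raise PanelIOError(f"duplicate sample id {sample_id!r} (file {p})")
        columns[sample_id] = col
    assert classes_ref is not None
    counts = pd.DataFrame({s: c.reindex(classes_ref.index) for s, c in columns.items()})
    counts = validate_counts(counts)
    probes = pd.DataFrame({"probe_class": classes_ref})
    probes.index.name = "gene_id"
    return counts, probes


_RCC_CLASS_INV = {v: k for k, v in RCC_CLASS_MAP.items()}


def write_rcc(counts: pd.DataFrame, probes: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one RCC file per sample (the inverse of :func:`read_rcc`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    validate_probes(probes, genes=counts.index)
    written = []
    for sample in counts.columns:
        lines = [
            "<Header>", "FileVersion,1.7", "SoftwareVersion,synthetic", "</Header>",
            "<Sample_Attributes>", f"ID,{sample}", "Owner,", "Comments,", "Date,",
            "GeneRLF,synthetic_panel", "</Sample_Attributes>",
            "<Lane_Attributes>", "ID,1", "FovCount,280", "FovCounted,280",
            "BindingDensity,1.0", "</Lane_Attributes>",
            "<Code_Summary>", "CodeClass,Name,Accession,Count",
        ]
        for gene in counts.index:
            cc = _RCC_CLASS_INV[probes.loc[gene, "probe_class"]]
            lines.append(f"{cc},{gene},NM_{gene},{int(counts.loc[gene, sample])}")
        lines += ["</Code_Summary>", ""]
        path = out_dir / f"{sample}.RCC"
        path.write_text("\n".join(lines))
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCatalog:
    """Ordered name -> member-gene mapping with optional per-set descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a standard GMT file (name, description, members...).

    Empty member lists are rejected; duplicate members within a set are
    deduplicated with a warning.
    """
    catalog = GeneSetCatalog()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise PanelIOError(f"{path}: GMT line {lineno} has fewer than 3 fields (no members)")
        name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if not members:
            raise PanelIOError(f"{path}: GMT line {lineno} ({name!r}) has no members")
        seen: dict[str, None] = {}
        for m in members:
            if m in seen:
                log.warning("GMT set %r: duplicate member %r deduplicated", name, m)
            seen[m] = None
        if name in catalog.sets:
            raise PanelIOError(f"{path}: duplicate gene-set name {name!r}")
        catalog.sets[name] = list(seen)
        catalog.descriptions[name] = desc
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([name, catalog.descriptions.get(name, "")] + list(members))
        for name, members in catalog.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
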