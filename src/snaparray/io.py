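"""File formats and configuration.

Tab-delimited intensity and probe tables, BED (3+ column, 0-based
half-open) regions and peaks, FASTA sequences (via Biopython), JSON fit
reports, and a single declarative YAML pipeline configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_probe_table",
    "write_probe_table",
    "PipelineConfig",
    "load_config",
]

REQUIRED_INTENSITY_COLS = ("probe_id", "sequence")


def read_intensity_table(path, replicate_prefix: str = "rep") -> pd.DataFrame:
    """Read a tab-delimited extracted- or normalized-intensity table.

    Requires columns ``probe_id`` and ``sequence`` plus at least one
    intensity column (replicate columns named ``rep*``, or a final
    ``intensity`` column); intensity values must be numeric, and malformed
    cells are reported with their line number (1-based, header is line 1).
    Annotation columns (probe class, coordinates, metadata) pass through;
    ``start``/``end`` are cast to integers when present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_INTENSITY_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    value_cols = [c for c in df.columns if c.startswith(replicate_prefix)]
    if "intensity" in df.columns:
        value_cols.append("intensity")
    if not value_cols:
        raise ValueError(f"{path}: no replicate or intensity columns found")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r}")
    for col in value_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric intensity {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = converted
    for col in ("start", "end"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df.set_index("probe_id")


def write_intensity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="probe_id")


def read_bed(path) -> pd.DataFrame:
    """BED 3+ columns; 0-based half-open intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, df.shape[1] + 1)]
    df.columns = cols
    if df.shape[1] >= 4:
        df = df.rename(columns={"col4": "name"})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: intervals must satisfy start < end")
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")


def write_probe_table(probes, path) -> None:
    """Probe library as TSV with a JSON metadata column."""
    rows = [p.to_record() for p in probes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "metadata" in df.columns:
        df["metadata"] = df["metadata"].map(
            lambda s: json.loads(s) if isinstance(s, str) else {}
        )
    return df


@dataclass
class PipelineConfig:
    """Declarative pipeline settings; CLI flags override individual fields."""

    consensus: str = "AACCGGTT"
    direct_threshold: float = 3.0
    quartile: float = 0.25
    alpha: float = 0.05
    seed: int = 0
    probe_table: str | None = None
    intensity_table: str | None = None
    regions_bed: str | None = None
    regions_fasta: str | None = None
    peaks_bed: str | None = None
    normalization_target: str = "unit_median"
    phasing_scale: str = "log"
    simulator: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.quartile <= 0.5:
            raise ValueError("quartile must be in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.direct_threshold < 0:
            raise ValueError("direct_threshold must be non-negative")


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
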