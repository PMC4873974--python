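"""File formats and pipeline configuration.

All tables are plain text: viability CSV (long format), drug panel /
expression / annotation / result TSVs, TFBS BED4 and JSON summaries.
Genomic coordinates are 0-based half-open throughout; doses are in μM and
viability is a fraction in [0, 1].  Readers are header-keyed (column
order is irrelevant), validate required columns and report malformed rows
with their file and line.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PipelineConfig",
    "read_viability", "write_viability",
    "read_combination_viability", "write_combination_viability",
    "read_drug_panel", "write_drug_panel",
    "read_expression", "write_expression",
    "read_sample_sheet", "write_sample_sheet",
    "read_gene_annotation", "write_gene_annotation",
    "read_bed", "write_bed",
    "write_table", "read_table",
    "write_json", "read_json",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serialisable to a flat JSON file."""

    seed: int = 0
    dilution_factors: tuple = (1, 2, 4, 8)
    clip_lo: float = 0.005
    clip_hi: float = 0.995
    ci_bins: dict = field(default_factory=lambda: {
        "synergism": 0.7, "moderate_synergism": 0.9,
        "nearly_additive": 1.1, "antagonism": None})
    fdr_threshold: float = 0.05
    fc_threshold: float = 2.0
    upstream: int = 5000
    downstream: int = 1000
    n_perm: int = 100_000
    noise_sd: float = 0.03
    n_drugs: int = 20
    replicates: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.clip_lo < self.clip_hi <= 1):
            raise ValueError("clip band must satisfy 0 <= lo < hi <= 1")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold out of range")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.n_perm < 1 or self.upstream < 0 or self.downstream < 0:
            raise ValueError("invalid permutation or window settings")
        self.dilution_factors = tuple(int(f) for f in self.dilution_factors)

    def ci_bins_numeric(self) -> dict:
        return {k: (np.inf if v is None else float(v))
                for k, v in self.ci_bins.items()}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_viability_values(df: pd.DataFrame, path) -> None:
    if df["viability"].isna().any():
        bad = int(df.index[df["viability"].isna()][0]) + 2  # header is line 1
        raise ValueError(f"{path}: NaN viability at line {bad}")
    if (df["viability"] < 0).any() or (df["viability"] > 1).any():
        raise ValueError(f"{path}: viability must be a fraction in [0, 1] "
                         "(percent scales are not auto-converted)")


def read_viability(path) -> pd.DataFrame:
    """Single-agent viability CSV: drug_id, dose_uM, replicate, viability."""
    df = pd.read_csv(path)
    _require_columns(df, ["drug_id", "dose_uM", "replicate", "viability"], path)
    if (df["dose_uM"] <= 0).any():
        bad = int(df.index[df["dose_uM"] <= 0][0]) + 2
        raise ValueError(f"{path}: non-positive dose at line {bad}")
    _check_viability_values(df, path)
    return df


def write_viability(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_combination_viability(path) -> pd.DataFrame:
    """Combination viability CSV: pair_id, drug1, drug2, dose1_uM, dose2_uM,
    dilution_level, replicate, viability."""
    df = pd.read_csv(path)
    _require_columns(df, ["pair_id", "drug1", "drug2", "dose1_uM", "dose2_uM",
                          "dilution_level", "replicate", "viability"], path)
    if ((df["dose1_uM"] <= 0) | (df["dose2_uM"] <= 0)).any():
        bad = int(df.index[(df["dose1_uM"] <= 0) | (df["dose2_uM"] <= 0)][0]) + 2
        raise ValueError(f"{path}: non-positive dose at line {bad}")
    _check_viability_values(df, path)
    return df


write_combination_viability = write_viability


def read_drug_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["drug_id", "target_gene", "target_class"], path)
    if df["drug_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate drug ids")
    return df


def write_drug_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples log2 matrix TSV; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing expression values are not accepted")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "group"], path)
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "chrom", "tss", "strand"], path)
    if (df["tss"] < 0).any():
        bad = int(df.index[df["tss"] < 0][0]) + 2
        raise ValueError(f"{path}: negative TSS at line {bad}")
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def write_gene_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED4 (chrom, start, end, name), 0-based half-open, no header."""
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "tf"],
                         dtype={"chrom": str, "tf": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "tf"])
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not (isinstance(row.start, (int, np.integer))
                and isinstance(row.end, (int, np.integer))):
            raise ValueError(f"{path}: non-integer coordinates at line {i}")
        if row.end <= row.start or row.start < 0:
            raise ValueError(f"{path}: invalid interval at line {i}: "
                             f"[{row.start}, {row.end})")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "tf"]].to_csv(path, sep="\t", index=False,
                                               header=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Generic result TSV (fits, CI profiles, DEG tables, enrichment)."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
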