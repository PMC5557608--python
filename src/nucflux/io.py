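"""Schema-validated TSV table input/output.

The pipeline's canonical dialect is UTF-8 TSV with '.' decimals.  Every
table has a declared schema (required columns and their kinds); loads
fail with an error naming the offending column and line rather than
propagating NaNs downstream.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_published_rate_table",
    "summarize_rate_table",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: required columns per table kind: name -> "num" | "int" | "str" | "bool"
SCHEMAS: dict[str, dict[str, str]] = {
    "expression": {
        "gene_id": "str",
        "fraction": "str",
        "replicate": "int",
        "time_min": "num",
        "fpkm": "num",
        "fpkm_spikenorm": "num",
    },
    "corrected": {
        "gene_id": "str",
        "fraction": "str",
        "replicate": "int",
        "time_min": "num",
        "abundance": "num",
    },
    "sample_reads": {
        "fraction": "str",
        "replicate": "int",
        "time_min": "num",
        "fly_mapped_reads": "num",
        "yeast_mapped_reads": "num",
    },
    "bulk": {"replicate": "int", "time_min": "num", "abundance": "num"},
    "comparison": {
        "gene_id": "str",
        "log10_x": "num",
        "log10_y": "num",
        "comparison": "str",
    },
    "features": {
        "gene_id": "str",
        "transcript_length": "num",
        "intron_length": "num",
        "utr3_length": "num",
        "utr5_length": "num",
        "cds_length": "num",
        "n_exons": "int",
        "Nu": "int",
    },
    "exclusions": {"gene_id": "str", "reason_code": "str"},
    "labels": {"gene_id": "str", "label": "str", "value": "int"},
    "chromatin_states": {"gene_id": "str", "tss_state": "str", "tts_state": "str"},
    "rates": {
        "gene_id": "str",
        "replicate": "int",
        "transcription_rate_fpkm_per_min": "num",
        "export_rate_per_min": "num",
        "decay_rate_per_min": "num",
        "turnover_rate_per_min": "num",
        "r2_nuclear": "num",
        "r2_cytoplasmic": "num",
        "retained": "bool",
    },
    "noise_model": {"log10_mean": "num", "cv": "num"},
    "truth": {
        "gene_id": "str",
        "N0": "num",
        "C0": "num",
        "W0": "num",
        "kS": "num",
        "kE": "num",
        "kD": "num",
        "kT": "num",
    },
}


def _check_schema(df: pd.DataFrame, schema: dict[str, str], where: str) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing column(s) {missing}")
    for col, kind in schema.items():
        if kind in ("num", "int"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise SchemaError(
                    f"{where}: non-numeric value in column '{col}' at line {line}"
                )
            df[col] = coerced.astype(int) if kind == "int" else coerced
        elif kind == "bool":
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return _check_schema(df, SCHEMAS[schema_name], str(path))


def write_table(df: pd.DataFrame, path: str | Path, schema_name: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema_name is not None:
        missing = [c for c in SCHEMAS[schema_name] if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {path}: missing {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_published_rate_table(path: str | Path) -> pd.DataFrame:
    """Load a published-style per-gene kinetic rate table (XLSX or TSV).

    Expected columns (case-insensitive, flexible matching): a gene
    identifier, transcription/export/decay rates, and per-fraction r².
    Returns a frame with canonical column names as in the "rates" schema.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rate table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    aliases = {
        "transcription_rate_fpkm_per_min": ("transcription", "synthesis", "ks"),
        "export_rate_per_min": ("export", "ke"),
        "decay_rate_per_min": ("decay", "degradation", "kd"),
        "r2_nuclear": ("r2_n", "r2 nuc", "r2_nuclear", "r.2.nuc"),
        "r2_cytoplasmic": ("r2_c", "r2 cyt", "r2_cytoplasmic", "r.2.cyt"),
        "gene_id": ("gene", "id", "fbgn", "symbol"),
    }
    rename = {}
    for canonical, keys in aliases.items():
        for col in df.columns:
            low = str(col).lower()
            if canonical not in rename.values() and any(k in low for k in keys):
                rename[col] = canonical
                break
    out = df.rename(columns=rename)
    missing = [c for c in aliases if c not in out.columns]
    if missing:
        raise SchemaError(
            f"{path}: could not identify column(s) {missing} in {list(df.columns)}"
        )
    return out


def summarize_rate_table(
    rates: pd.DataFrame, r2_threshold: float = 0.8
) -> dict[str, float]:
    """Medians, half-lives and retention count of a per-gene rate table.

    Rates are reported in percent per minute, half-lives in hours, as in
    the field's convention.
    """
    retained = rates[
        (rates["r2_nuclear"] > r2_threshold)
        & (rates["r2_cytoplasmic"] > r2_threshold)
    ]
    med_ke = float(retained["export_rate_per_min"].median())
    med_kd = float(retained["decay_rate_per_min"].median())
    return {
        "n_retained": int(retained["gene_id"].nunique()),
        "median_export_rate_pct_per_min": 100.0 * med_ke,
        "median_decay_rate_pct_per_min": 100.0 * med_kd,
        "export_half_life_hours": math.log(2.0) / (60.0 * med_ke),
        "decay_half_life_hours": math.log(2.0) / (60.0 * med_kd),
    }
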