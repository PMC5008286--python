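"""Validated readers and writers for the pipeline's tabular interchange formats.

All tables travel as long (tidy) TSV/CSV with the delimiter sniffed on read.
Methylation percentages are validated into [0, 100] and duplicate
(sample, locus, dmr) measurements are rejected with row numbers.  Floats are
serialized with 6 decimals so a write-read round trip is lossless at that
precision.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

__all__ = [
    "ValidationError",
    "read_methylation_table",
    "read_triad_table",
    "read_survival_table",
    "read_ct_table",
    "read_chip_table",
    "write_table",
]

METHYLATION_COLUMNS = ("sample_id", "group", "locus", "dmr", "methylation_pct")
TRIAD_COLUMNS = ("triad_id", "member", "dmr", "methylation_pct")
SURVIVAL_COLUMNS = ("sample_id", "time", "event")
CT_COLUMNS = ("sample_id", "gene", "ct")
CHIP_COLUMNS = ("region", "mark", "signal")

FLOAT_FORMAT = "%.6f"


class ValidationError(ValueError):
    """Raised when an input table fails structural or range validation."""


def _sniff_sep(path: str | Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(64 * 1024)
    if not sample.strip():
        raise ValidationError(f"{path}: file is empty")
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _check_numeric_pct(df: pd.DataFrame, col: str, path) -> None:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[values.isna() & df[col].notna()] + 2  # 1-based + header
    if len(bad):
        raise ValidationError(f"{path}: non-numeric {col} at rows {list(bad)}")
    out = df.index[(values < 0) | (values > 100)] + 2
    if len(out):
        raise ValidationError(f"{path}: {col} outside [0, 100] at rows {list(out)}")
    df[col] = values


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long methylation table.

    Requires columns (sample_id, group, locus, dmr, methylation_pct);
    optional columns (e.g. age_class) pass through.  Out-of-range or
    non-numeric methylation and duplicate (sample, locus, dmr) triples are
    hard errors naming the offending rows.
    """
    df = _read(path, METHYLATION_COLUMNS)
    _check_numeric_pct(df, "methylation_pct", path)
    dup = df.duplicated(subset=["sample_id", "locus", "dmr"], keep=False)
    if dup.any():
        rows = list(df.index[dup] + 2)
        raise ValidationError(
            f"{path}: duplicate (sample_id, locus, dmr) measurements at rows {rows}")
    return df


def read_triad_table(path: str | Path) -> pd.DataFrame:
    df = _read(path, TRIAD_COLUMNS)
    _check_numeric_pct(df, "methylation_pct", path)
    bad = set(df["member"].unique()) - {"child", "mother", "father"}
    if bad:
        raise ValidationError(f"{path}: unknown triad members {sorted(bad)}")
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = _read(path, SURVIVAL_COLUMNS)
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any() or (time <= 0).any():
        rows = list(df.index[time.isna() | (time <= 0)] + 2)
        raise ValidationError(f"{path}: non-positive or non-numeric time at rows {rows}")
    df["time"] = time
    event = pd.to_numeric(df["event"], errors="coerce")
    if not event.isin((0, 1)).all():
        rows = list(df.index[~event.isin((0, 1))] + 2)
        raise ValidationError(f"{path}: event flags must be 0/1, bad rows {rows}")
    df["event"] = event.astype(int)
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = _read(path, CT_COLUMNS)
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any() or (ct <= 0).any():
        rows = list(df.index[ct.isna() | (ct <= 0)] + 2)
        raise ValidationError(f"{path}: Ct must be positive cycles, bad rows {rows}")
    df["ct"] = ct
    return df


def read_chip_table(path: str | Path) -> pd.DataFrame:
    df = _read(path, CHIP_COLUMNS)
    sig = pd.to_numeric(df["signal"], errors="coerce")
    if sig.isna().any():
        rows = list(df.index[sig.isna()] + 2)
        raise ValidationError(f"{path}: non-numeric signal at rows {rows}")
    df["signal"] = sig
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with 6-decimal floats (round-trip safe at 6 dp)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
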