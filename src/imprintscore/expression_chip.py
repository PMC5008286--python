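"""Relative expression (delta-delta-Ct) and ChIP-qPCR enrichment normalization.

Relative expression follows the standard 2^-ddCt scheme with perfect-doubling
efficiency: dCt = Ct_gene - Ct_reference within each sample, ddCt relative to
the arithmetic-mean dCt of a calibrator sample set (so the calibrator group
has geometric-mean fold 1 by construction).

ChIP signals are normalized in any of the conventional ways: fold over the
IgG mock antibody, percent of input chromatin, or relative to total histone
H3 (itself input-scaled); the input scaling fraction is assumed applied
upstream of this module.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_stats import pearson_correlation

__all__ = [
    "relative_expression",
    "chip_enrichment",
    "log2_mean_center",
    "expression_index_association",
    "CHIP_MODES",
]

CHIP_MODES = ("fold_over_igg", "percent_input", "h3_normalized")


def relative_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_samples: Sequence[str],
    sample_col: str = "sample_id",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Fold change per gene per sample by 2^-ddCt.

    Samples without a reference-gene Ct are skipped with a warning; genes
    absent from the calibrator set are dropped (no ddCt baseline).

    Returns a long table (sample_id, gene, delta_ct, delta_delta_ct, fold).
    """
    required = {sample_col, gene_col, ct_col}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct[ct_col] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    calibrators = set(map(str, calibrator_samples))
    if not calibrators:
        raise ValueError("calibrator sample set is empty")

    wide = ct.pivot_table(index=sample_col, columns=gene_col, values=ct_col,
                          aggfunc="first")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    has_ref = wide[reference_gene].notna()
    if not has_ref.all():
        skipped = list(wide.index[~has_ref])
        warnings.warn(f"samples without reference-gene Ct skipped: {skipped}",
                      stacklevel=2)
        wide = wide[has_ref]
    present = calibrators & set(map(str, wide.index))
    if not present:
        raise ValueError("no calibrator sample has a usable reference Ct")

    dct = wide.drop(columns=[reference_gene]).sub(wide[reference_gene], axis=0)
    cal_mean = dct.loc[[s for s in wide.index if str(s) in calibrators]].mean()
    ddct = dct.sub(cal_mean, axis=1)
    fold = np.power(2.0, -ddct)

    out = (
        pd.concat(
            {"delta_ct": dct, "delta_delta_ct": ddct, "fold": fold}, axis=1
        )
        .stack(future_stack=True)
        .reset_index()
    )
    out.columns = [sample_col, gene_col, "delta_ct", "delta_delta_ct", "fold"]
    return out.dropna(subset=["fold"]).reset_index(drop=True)


def chip_enrichment(
    signal: pd.DataFrame,
    mode: str = "h3_normalized",
    region_col: str = "region",
    mark_col: str = "mark",
    signal_col: str = "signal",
    input_label: str = "input",
    igg_label: str = "IgG",
    h3_label: str = "H3",
) -> pd.DataFrame:
    """ChIP-qPCR enrichment per region and mark under one normalization mode.

    fold_over_igg:  mark / IgG
    percent_input:  100 * mark / input
    h3_normalized:  (mark / input) / (H3 / input)

    Control rows are identified by their mark label within each region; a
    missing or non-positive control raises an error naming it.
    """
    if mode not in CHIP_MODES:
        raise ValueError(f"mode must be one of {CHIP_MODES}")
    required = {region_col, mark_col, signal_col}
    missing = required - set(signal.columns)
    if missing:
        raise ValueError(f"ChIP table missing columns: {sorted(missing)}")

    controls = {"fold_over_igg": (igg_label,),
                "percent_input": (input_label,),
                "h3_normalized": (input_label, h3_label)}[mode]
    rows: list[dict] = []
    for region, sub in signal.groupby(region_col, sort=False):
        values = dict(zip(sub[mark_col], sub[signal_col]))
        for control in controls:
            if control not in values:
                raise ValueError(f"region {region!r}: control {control!r} missing")
            if not values[control] > 0:
                raise ValueError(
                    f"region {region!r}: control {control!r} must be > 0, "
                    f"got {values[control]}")
        for mark, value in values.items():
            if mark in (input_label, igg_label):
                continue
            if mode == "h3_normalized" and mark == h3_label:
                continue
            if mode == "fold_over_igg":
                enrich = value / values[igg_label]
            elif mode == "percent_input":
                enrich = 100.0 * value / values[input_label]
            else:
                enrich = (value / values[input_label]) / (values[h3_label] / values[input_label])
            rows.append({region_col: region, mark_col: mark, "mode": mode,
                         "enrichment": float(enrich)})
    return pd.DataFrame(rows)


def log2_mean_center(
    matrix: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Per-feature log2 transform followed by row-mean centering.

    Rows are features (genes), columns samples.  Values must be positive
    after adding ``pseudocount``.  Idempotent on data that is already
    log-scaled and centered in the sense that centering twice changes
    nothing.
    """
    values = matrix.to_numpy(dtype=float) + pseudocount
    if np.any(values <= 0):
        raise ValueError("non-positive values; supply a pseudocount for zeros")
    logged = np.log2(values)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def expression_index_association(
    folds: pd.DataFrame,
    scores: pd.DataFrame,
    gene_col: str = "gene",
    sample_col: str = "sample_id",
    fold_col: str = "fold",
    index_col: str = "fourteen_q_index",
) -> pd.DataFrame:
    """Per-gene association between fold change and the 14q-index.

    ``scores`` needs sample_id, the index and optionally ``group``/``call``
    columns; group means are reported per 14q-index stratum (normal,
    defect-negative, defect-positive) when calls are available, with the
    monotonicity direction across ordered strata.
    """
    merged = folds.merge(scores, on=sample_col, how="inner")
    if merged.empty:
        raise ValueError("no overlapping samples between folds and scores")

    strata: list[str] = []
    if "group" in merged.columns and "call" in merged.columns:
        def stratum(row) -> str:
            if row["group"] == "normal":
                return "normal"
            return "14q-I(+)" if row["call"] == "positive" else "14q-I(-)"
        merged["stratum"] = merged.apply(stratum, axis=1)
        strata = [s for s in ("normal", "14q-I(-)", "14q-I(+)")
                  if s in set(merged["stratum"])]

    rows: list[dict] = []
    for gene, sub in merged.groupby(gene_col, sort=False):
        if len(sub) < 3:
            continue
        r, r2 = pearson_correlation(sub[fold_col], sub[index_col])
        row = {"gene": gene, "r": r, "r_squared": r2, "n": len(sub)}
        if strata:
            means = [float(sub.loc[sub["stratum"] == s, fold_col].mean())
                     for s in strata]
            for s, m in zip(strata, means):
                row[f"mean_fold[{s}]"] = m
            diffs = np.diff(means)
            if np.all(diffs < 0):
                row["trend"] = "decreasing"
            elif np.all(diffs > 0):
                row["trend"] = "increasing"
            else:
                row["trend"] = "non-monotone"
        rows.append(row)
    if not rows:
        raise ValueError("no gene had >= 3 samples with both measurements")
    return pd.DataFrame(rows)
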