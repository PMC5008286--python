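"""Group-level cohort statistics: demethylation contrasts, correlations, tests.

The elementary statistics (Pearson r, Student/Welch t, one-way ANOVA F,
Mantel-Haenszel log-rank lives in :mod:`imprintscore.survival`) are computed
from their textbook formulas; only the t/F distribution functions are taken
from scipy.  This keeps the arithmetic of the analysis inspectable and lets
scipy/statsmodels act as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "ClassificationSummary",
    "pearson_correlation",
    "coefficient_of_determination",
    "student_t",
    "welch_t",
    "anova_oneway",
    "group_tests",
    "demethylation_extent",
    "DemethylationResult",
    "classification_summary",
    "percent_positive",
    "triad_correlation",
    "bh_adjust",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group t test or a one-way ANOVA."""

    labels: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    statistic: float
    df: tuple[float, ...]
    p_value: float
    test: str


@dataclass(frozen=True)
class ClassificationSummary:
    group: str
    n_total: int
    n_positive: int
    percent_positive: float


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation and its squared value.

    Computed as cov(x, y) / (sd(x) sd(y)) on centered data; requires equal
    lengths >= 3 and nonzero variance in both vectors.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    return r, r * r


def coefficient_of_determination(r: float) -> float:
    """R-squared of a correlation coefficient."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return r * r


def _describe(x: np.ndarray) -> tuple[int, float, float]:
    return x.size, float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0


def student_t(x, y, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Pooled-variance (Student) two-sample t test, two-sided."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size < 2 or yv.size < 2:
        raise ValueError("each group needs n >= 2")
    n1, m1, s1 = _describe(xv)
    n2, m2, s2 = _describe(yv)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se if se > 0 else 0.0
    p = 2.0 * float(stats.t.sf(abs(t), df)) if se > 0 else 1.0
    return GroupComparison(labels, (n1, n2), (m1, m2), (s1, s2), t, (float(df),), p,
                           "student_t")


def welch_t(x, y, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Welch unequal-variance two-sample t test, two-sided.

    Degrees of freedom by the Welch-Satterthwaite approximation.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size < 2 or yv.size < 2:
        raise ValueError("each group needs n >= 2")
    n1, m1, s1 = _describe(xv)
    n2, m2, s2 = _describe(yv)
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    se = math.sqrt(v1 + v2)
    if se == 0.0:
        return GroupComparison(labels, (n1, n2), (m1, m2), (s1, s2), 0.0,
                               (float(n1 + n2 - 2),), 1.0, "welch_t")
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(labels, (n1, n2), (m1, m2), (s1, s2), t, (df,), p, "welch_t")


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way fixed-effects ANOVA F test across k >= 2 groups."""
    labels = tuple(groups)
    arrays = [_as_vector(groups[g], g) for g in labels]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1 = len(arrays) - 1
    df2 = int(ns.sum()) - len(arrays)
    if ss_within == 0.0:
        f = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(f, df1, df2))
    sds = tuple(float(a.std(ddof=1)) for a in arrays)
    return GroupComparison(labels, tuple(int(n) for n in ns),
                           tuple(float(m) for m in means), sds, f,
                           (float(df1), float(df2)), p, "anova_oneway")


def group_tests(
    groups: Mapping[str, Sequence[float]], method: str = "welch"
) -> GroupComparison:
    """Two-group t test (Welch default, Student optional) or ANOVA for >= 3 groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) == 2:
        (la, xa), (lb, xb) = groups.items()
        if method == "welch":
            return welch_t(xa, xb, labels=(la, lb))
        if method == "student":
            return student_t(xa, xb, labels=(la, lb))
        raise ValueError("method must be 'welch' or 'student'")
    return anova_oneway(groups)


# ---------------------------------------------------------------------------
# demethylation vs the genome-wide surrogate

@dataclass(frozen=True)
class DemethylationResult:
    """Per-sample demethylation deltas and the locus-vs-surrogate contrast."""

    deltas: pd.DataFrame
    group_means: pd.DataFrame
    test: GroupComparison


def demethylation_extent(
    methylation: pd.DataFrame,
    normal_means: Mapping[str, float],
    locus_a: str = "14q32",
    locus_b: str = "LINE1",
    group: str | None = None,
    method: str = "welch",
) -> DemethylationResult:
    """Demethylation deltas per sample/locus and the locus-a vs locus-b test.

    The delta is ``normal_mean(locus) - sample mean(locus)`` (positive =
    demethylation; for the multi-DMR 14q32 locus the sample mean is taken
    over its DMRs).  The returned test compares the per-sample deltas of
    ``locus_a`` against ``locus_b`` across the same samples (Welch by
    default), restricted to ``group`` when given.
    """
    df = methylation
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise ValueError(f"no samples in group {group!r}")
    loci = df["locus"].unique()
    for locus in (locus_a, locus_b):
        if locus not in normal_means:
            raise ValueError(f"no normal mean provided for locus {locus!r}")
        if locus not in loci:
            raise ValueError(f"no measurements for locus {locus!r}")

    per_sample = (
        df.groupby(["sample_id", "group", "locus"], sort=False)["methylation_pct"]
        .mean()
        .reset_index()
    )
    per_sample["delta"] = per_sample["locus"].map(normal_means) - per_sample["methylation_pct"]
    per_sample = per_sample.dropna(subset=["delta"])

    group_means = (
        per_sample.groupby(["group", "locus"], sort=False)["delta"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    da = per_sample.loc[per_sample["locus"] == locus_a, "delta"].to_numpy()
    db = per_sample.loc[per_sample["locus"] == locus_b, "delta"].to_numpy()
    test = group_tests({locus_a: da, locus_b: db}, method=method)
    return DemethylationResult(per_sample, group_means, test)


# ---------------------------------------------------------------------------
# classification summaries

def percent_positive(n_positive: int, n_total: int, decimals: int = 0) -> float:
    """Percent positive with the display rounding used in cohort reports."""
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    if n_total == 0:
        raise ValueError("empty group")
    return round(100.0 * n_positive / n_total, decimals)


def classification_summary(
    calls: pd.DataFrame,
    group_col: str = "group",
    call_col: str = "call",
    decimals: int = 0,
) -> list[ClassificationSummary]:
    """Counts and percent of defect-positive calls per group.

    Full precision is a one-liner from the counts; ``decimals`` only affects
    the reported percent (nearest integer by default).  Empty groups are
    omitted with a warning.
    """
    bad = set(calls[call_col].unique()) - {"positive", "negative"}
    if bad:
        raise ValueError(f"calls must be 'positive'/'negative', found {sorted(bad)}")
    out: list[ClassificationSummary] = []
    for group, sub in calls.groupby(group_col, sort=False):
        if sub.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"group {group!r} is empty; omitted", stacklevel=2)
            continue
        n_total = int(len(sub))
        n_pos = int((sub[call_col] == "positive").sum())
        out.append(ClassificationSummary(str(group), n_total, n_pos,
                                         percent_positive(n_pos, n_total, decimals)))
    return out


# ---------------------------------------------------------------------------
# triads

def triad_correlation(triads: pd.DataFrame) -> pd.DataFrame:
    """Child-parent Pearson correlations per DMR from a long triad table.

    Expects columns (triad_id, member, dmr, methylation_pct) with members
    child/mother/father.  Triads missing any member at a DMR are excluded
    (count reported in ``n_excluded``).
    """
    required = {"triad_id", "member", "dmr", "methylation_pct"}
    missing = required - set(triads.columns)
    if missing:
        raise ValueError(f"triad table missing columns: {sorted(missing)}")
    rows: list[dict] = []
    for dmr, sub in triads.groupby("dmr", sort=False):
        wide = sub.pivot_table(index="triad_id", columns="member",
                               values="methylation_pct", aggfunc="first")
        n_before = len(wide)
        wide = wide.dropna(subset=[c for c in ("child", "mother", "father")
                                   if c in wide.columns])
        for parent in ("father", "mother"):
            if "child" not in wide.columns or parent not in wide.columns:
                continue
            r, r2 = pearson_correlation(wide["child"], wide[parent])
            rows.append({"dmr": dmr, "parent": parent, "r": r, "r_squared": r2,
                         "n": len(wide), "n_excluded": n_before - len(wide)})
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
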