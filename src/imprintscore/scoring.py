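"""Loss-of-imprinting scoring: deviation extents, the 14q-index, reference ranges.

An imprinted DMR is methylated on exactly one parental allele, so bulk
methylation of intact tissue sits near 50%.  The extent of an imprinting
defect in a sample is the absolute deviation of its DMR methylation from
that expected level, and the 14q-index is the mean extent over the three
14q32 DMRs:

    index = (|m_DMR1 - 50| + |m_DMR2 - 50| + |m_DMR3 - 50|) / 3

A sample is called defect-positive when its index strictly exceeds the
threshold (default 8.5).  Both gains and losses of methylation count as
defects, which is why the deviation is absolute.

The expected level is configurable per tissue/DMR: aged buccal epithelium,
for instance, runs higher (means near 53% at DMR-1 and 64% at DMR-2), and
mouse IG-DMR normals sit near 64% or 72-76% depending on the model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoringConfig",
    "ReferenceRange",
    "ImprintScore",
    "dmr_deviation",
    "fourteen_q_index",
    "reference_range",
    "reference_ranges_by_dmr",
    "classify_sample",
    "defect_direction",
    "score_cohort",
]

DEFAULT_EXPECTED_LEVEL = 50.0
DEFAULT_INDEX_THRESHOLD = 8.5


def _check_pct(value: float, name: str) -> None:
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be a percentage in [0, 100], got {value}")


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring parameters.

    ``expected_overrides`` maps a DMR name to a tissue-specific expected
    imprint level (e.g. buccal DMR-1 -> 53, DMR-2 -> 64); anything not
    listed uses ``expected_imprint_level``.
    """

    expected_imprint_level: float = DEFAULT_EXPECTED_LEVEL
    expected_overrides: Mapping[str, float] = field(default_factory=dict)
    index_threshold: float = DEFAULT_INDEX_THRESHOLD
    ci_level: float = 0.95
    ci_mode: str = "mean_ci"
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        _check_pct(self.expected_imprint_level, "expected_imprint_level")
        for dmr, level in self.expected_overrides.items():
            _check_pct(level, f"expected_overrides[{dmr!r}]")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie strictly between 0 and 1")
        if self.ci_mode not in ("mean_ci", "reference_interval"):
            raise ValueError("ci_mode must be 'mean_ci' or 'reference_interval'")

    def expected_for(self, dmr: str) -> float:
        return float(self.expected_overrides.get(dmr, self.expected_imprint_level))


@dataclass(frozen=True)
class ReferenceRange:
    """Normal range of one DMR plus the cohort-level index threshold."""

    mean: float
    lower: float
    upper: float
    n: int
    index_threshold: float = DEFAULT_INDEX_THRESHOLD

    def __post_init__(self) -> None:
        if not self.lower <= self.mean <= self.upper:
            raise ValueError("reference range must satisfy lower <= mean <= upper")


@dataclass(frozen=True)
class ImprintScore:
    """Per-sample imprinting-defect score.

    ``deviations`` holds the per-DMR absolute deviation extents (NaN where a
    DMR was not measured); ``complete`` is False when the index was averaged
    over fewer DMRs than requested.
    """

    sample_id: str
    deviations: Mapping[str, float]
    fourteen_q_index: float
    call: str
    directions: Mapping[str, str] = field(default_factory=dict)
    n_dmrs_used: int = 3
    complete: bool = True


def dmr_deviation(methylation: float, expected_level: float = DEFAULT_EXPECTED_LEVEL) -> float:
    """Absolute deviation of a DMR methylation value from the imprinted level."""
    _check_pct(methylation, "methylation")
    _check_pct(expected_level, "expected_level")
    return abs(methylation - expected_level)


def fourteen_q_index(
    m1: float,
    m2: float,
    m3: float,
    expected_level: float = DEFAULT_EXPECTED_LEVEL,
) -> float:
    """Mean absolute deviation of the three 14q32 DMRs from the imprinted level.

    Missing DMRs may be passed as NaN/None; the index is then the mean over
    the available DMRs (all missing is an error).  Use :func:`score_cohort`
    to keep track of completeness per sample.
    """
    values = [m for m in (m1, m2, m3) if m is not None and not math.isnan(m)]
    if not values:
        raise ValueError("all three DMR values are missing")
    return float(np.mean([dmr_deviation(m, expected_level) for m in values]))


def reference_range(
    normal_values: Sequence[float],
    ci_level: float = 0.95,
    mode: str = "mean_ci",
    index_threshold: float = DEFAULT_INDEX_THRESHOLD,
) -> ReferenceRange:
    """Normal range of a DMR from reference-tissue measurements.

    ``mean_ci`` gives the t confidence interval of the mean,
    mean +/- t_{1-(1-ci)/2, n-1} * sd / sqrt(n); ``reference_interval`` gives
    the normal-theory population interval mean +/- z * sd.  Zero variance
    degenerates to [mean, mean] with a warning.
    """
    x = np.asarray(normal_values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 normal samples for a reference range, have {x.size}")
    if np.any(~np.isfinite(x)):
        raise ValueError("normal values must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance among normal samples; degenerate reference range",
                      stacklevel=2)
        return ReferenceRange(mean, mean, mean, int(x.size), index_threshold)
    alpha = 1.0 - ci_level
    if mode == "mean_ci":
        half = stats.t.ppf(1.0 - alpha / 2.0, x.size - 1) * sd / math.sqrt(x.size)
    elif mode == "reference_interval":
        half = stats.norm.ppf(1.0 - alpha / 2.0) * sd
    else:
        raise ValueError("mode must be 'mean_ci' or 'reference_interval'")
    return ReferenceRange(mean, mean - half, mean + half, int(x.size), index_threshold)


def reference_ranges_by_dmr(
    methylation: pd.DataFrame,
    normal_group: str = "normal",
    config: ScoringConfig | None = None,
) -> dict[tuple[str, str], ReferenceRange]:
    """Reference range per (locus, dmr) from the normal group of a long table."""
    config = config or ScoringConfig()
    normals = methylation[methylation["group"] == normal_group]
    if normals.empty:
        raise ValueError(f"no samples in normal group {normal_group!r}")
    ranges: dict[tuple[str, str], ReferenceRange] = {}
    for (locus, dmr), sub in normals.groupby(["locus", "dmr"]):
        ranges[(locus, dmr)] = reference_range(
            sub["methylation_pct"].to_numpy(),
            ci_level=config.ci_level,
            mode=config.ci_mode,
            index_threshold=config.index_threshold,
        )
    return ranges


def classify_sample(
    index: float,
    threshold: float = DEFAULT_INDEX_THRESHOLD,
    strict: bool = True,
) -> str:
    """Defect call from the 14q-index: positive iff index > threshold.

    The boundary is exclusive by default (an index of exactly 8.5 is
    negative); set ``strict=False`` for an inclusive comparator in
    sensitivity analyses.
    """
    if not math.isfinite(index):
        raise ValueError("index must be finite")
    positive = index > threshold if strict else index >= threshold
    return "positive" if positive else "negative"


def defect_direction(methylation: float, range_: ReferenceRange) -> str:
    """Direction of a defect relative to a normal range: hypo/normal/hyper."""
    if methylation < range_.lower:
        return "hypo"
    if methylation > range_.upper:
        return "hyper"
    return "normal"


def score_cohort(
    methylation: pd.DataFrame,
    config: ScoringConfig | None = None,
    locus: str = "14q32",
    ranges: Mapping[tuple[str, str], ReferenceRange] | None = None,
) -> pd.DataFrame:
    """Score every sample of a long methylation table at one locus.

    Returns one row per sample: per-DMR deviations, the 14q-index, the
    positive/negative call, per-DMR direction against ``ranges`` when
    provided, and metadata (group, completeness).
    """
    config = config or ScoringConfig()
    sub = methylation[methylation["locus"] == locus]
    if sub.empty:
        raise ValueError(f"no rows for locus {locus!r}")
    dup = sub.duplicated(subset=["sample_id", "dmr"])
    if dup.any():
        raise ValueError(f"duplicate (sample, dmr) measurements at locus {locus!r}")
    dmrs = sorted(sub["dmr"].unique())

    rows: list[dict] = []
    for sid, grp in sub.groupby("sample_id", sort=False):
        values = dict(zip(grp["dmr"], grp["methylation_pct"]))
        deviations = {
            dmr: (dmr_deviation(values[dmr], config.expected_for(dmr))
                  if dmr in values and not pd.isna(values[dmr]) else float("nan"))
            for dmr in dmrs
        }
        available = [d for d in deviations.values() if not math.isnan(d)]
        if not available:
            raise ValueError(f"sample {sid!r} has no usable DMR values at {locus!r}")
        index = float(np.mean(available))
        row: dict = {
            "sample_id": sid,
            "group": grp["group"].iloc[0] if "group" in grp else "",
            "fourteen_q_index": index,
            "call": classify_sample(index, config.index_threshold, config.strict_threshold),
            "n_dmrs_used": len(available),
            "complete": len(available) == len(dmrs),
        }
        for dmr in dmrs:
            row[f"deviation_{dmr}"] = deviations[dmr]
            if ranges is not None and (locus, dmr) in ranges and dmr in values:
                row[f"direction_{dmr}"] = defect_direction(values[dmr], ranges[(locus, dmr)])
        rows.append(row)
    return pd.DataFrame(rows)
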