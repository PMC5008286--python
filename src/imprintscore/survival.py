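"""Kaplan-Meier estimation and the two-sample log-rank test, from first principles.

The product-limit estimator over distinct event times t_i with d_i events and
n_i subjects at risk is S(t) = prod_{t_i <= t} (1 - d_i / n_i); subjects
censored at an event time are still at risk for that event (events before
censorings at ties, the standard convention).  The log-rank statistic is the
Mantel-Haenszel form: chi2 = (sum O_1 - sum E_1)^2 / sum V with the
hypergeometric variance at each event time, referred to chi-square with 1 df.

Implemented directly (vectorized numpy) rather than delegated, so replicate
simulations of operating characteristics stay fast; lifelines serves as the
independent oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KaplanMeierCurve",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "stratify_by_index",
]


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Step-function survival estimate.

    ``median`` is NaN when the curve never reaches 0.5 ("not reached").
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    n_total: int
    median: float

    def survival_at(self, t) -> np.ndarray:
        """S(t) for scalar or array times (right-continuous step function)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "survival": self.survival,
        })


def _check_times(time: np.ndarray) -> None:
    if time.size == 0:
        raise ValueError("no survival records")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be positive and finite")


def km_estimate(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier curve from follow-up times and event flags (1=event, 0=censored)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_times(time)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")

    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return KaplanMeierCurve(event_times, np.array([], dtype=int),
                                np.array([], dtype=int), np.array([]),
                                int(time.size), float("nan"))

    # at risk at t: subjects with follow-up >= t (censored at t still at risk)
    n_at_risk = time.size - np.searchsorted(time, event_times, side="left")
    ev_sorted = np.sort(time[event == 1])
    n_events = (np.searchsorted(ev_sorted, event_times, side="right")
                - np.searchsorted(ev_sorted, event_times, side="left"))
    if event.all():
        # no censoring: the product telescopes to (n - cum events)/n, which
        # keeps S(t) exactly equal to 1 - ECDF(t)
        survival = (time.size - np.cumsum(n_events)) / time.size
    else:
        survival = np.cumprod(1.0 - n_events / n_at_risk)

    below = survival <= 0.5
    median = float(event_times[np.argmax(below)]) if below.any() else float("nan")
    return KaplanMeierCurve(event_times, n_at_risk.astype(int),
                            n_events.astype(int), survival, int(time.size), median)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    strata: tuple[str, str]


def logrank_test(time, event, stratum) -> LogrankResult:
    """Two-sample Mantel-Haenszel log-rank test.

    Exactly two strata are required; a stratum without any event yields a
    warning (the statistic is still defined from the pooled event times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    stratum = np.asarray(stratum)
    _check_times(time)
    labels = np.unique(stratum)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 strata, found {labels.size}")
    in_a = stratum == labels[0]
    for lab, mask in zip(labels, (in_a, ~in_a)):
        if event[mask].sum() == 0:
            warnings.warn(f"stratum {lab!r} has zero events", stacklevel=2)
    if event.sum() == 0:
        raise ValueError("no events in either stratum")

    taus = np.unique(time[event == 1])
    t_a, t_b = np.sort(time[in_a]), np.sort(time[~in_a])
    n1 = t_a.size - np.searchsorted(t_a, taus, side="left")
    n2 = t_b.size - np.searchsorted(t_b, taus, side="left")
    n = n1 + n2

    ev_a = np.sort(time[in_a & (event == 1)])
    ev_all = np.sort(time[event == 1])
    d1 = (np.searchsorted(ev_a, taus, side="right")
          - np.searchsorted(ev_a, taus, side="left"))
    d = (np.searchsorted(ev_all, taus, side="right")
         - np.searchsorted(ev_all, taus, side="left"))

    e1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n > 1, d * (n1 / n) * (n2 / n) * (n - d) / (n - 1), 0.0)
    o_minus_e = float((d1 - e1).sum())
    var = float(v.sum())
    if var == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e ** 2 / var
        p = float(stats.chi2.sf(chi2, 1))
    obs = (float(d1.sum()), float((d - d1).sum()))
    exp = (float(e1.sum()), float((d - e1).sum()))
    return LogrankResult(chi2, p, obs, exp, (str(labels[0]), str(labels[1])))


def stratify_by_index(
    scores: pd.DataFrame,
    survival: pd.DataFrame,
    mode: str = "call",
    threshold: float = 8.5,
    index_col: str = "fourteen_q_index",
) -> pd.DataFrame:
    """Join survival records to 14q-index scores and assign strata.

    Modes: ``call`` uses the existing positive/negative call, ``threshold``
    re-derives it from the index at ``threshold`` (strict), ``tertile``
    splits the index distribution into low/mid/high thirds.  Join losses on
    either side are reported as a warning; an empty intersection is an error.
    """
    if mode not in ("call", "threshold", "tertile"):
        raise ValueError("mode must be 'call', 'threshold' or 'tertile'")
    merged = survival.merge(scores, on="sample_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between survival records and scores")
    lost = (len(survival) - len(merged)) + (len(scores) - len(merged))
    if lost > 0:
        warnings.warn(f"{lost} records dropped in the survival/score join",
                      stacklevel=2)
    if mode == "call":
        if "call" not in merged.columns:
            raise ValueError("scores table has no 'call' column")
        merged["stratum"] = np.where(merged["call"] == "positive",
                                     "14q-I(+)", "14q-I(-)")
    elif mode == "threshold":
        merged["stratum"] = np.where(merged[index_col] > threshold,
                                     "14q-I(+)", "14q-I(-)")
    else:
        merged["stratum"] = pd.qcut(merged[index_col], 3,
                                    labels=["low", "mid", "high"]).astype(str)
    return merged
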