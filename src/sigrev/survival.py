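"""Survival stratification and contingency analyses.

Kaplan-Meier curves per group, the two-group log-rank test with an O/E
hazard ratio, median bifurcation into high/low expression groups, and
Pearson chi-square tests for clinical/demographic contingency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .exceptions import DegenerateInputError, InvalidConfigError

__all__ = [
    "LogRankResult",
    "km_curve",
    "logrank",
    "median_bifurcate",
    "chi_square",
]


@dataclass
class LogRankResult:
    chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    observed: tuple[float, float]
    expected: tuple[float, float]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "group"}
    if not required <= set(records.columns):
        raise InvalidConfigError(f"records need columns {sorted(required)}")
    if (records["time"] < 0).any():
        raise InvalidConfigError("negative survival time")
    return records


def km_curve(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit estimate per group.

    ``records`` columns: time, event (1 = death), group.  Returns one step
    table per group with columns time, survival.
    """
    records = _check_records(records)
    out = {}
    for level, sub in records.groupby("group", sort=False):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[str(level)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank(records: pd.DataFrame, groups: tuple[str, str] | None = None) -> LogRankResult:
    """Two-group log-rank test with O/E hazard ratio.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation; chi2 = (O1 - E1)^2 / V.  The hazard
    ratio is (O1/E1)/(O2/E2) with
    CI = exp(log HR +/- 1.96*sqrt(1/E1 + 1/E2)).  ``groups`` fixes which
    level is group 1 (numerator); default is first-appearance order.
    """
    records = _check_records(records)
    levels = list(groups) if groups is not None else list(pd.unique(records["group"]))
    if len(levels) != 2 or not set(levels) <= set(records["group"].unique()):
        raise InvalidConfigError(f"log-rank needs exactly 2 groups, got {levels}")
    g1 = records["group"] == levels[0]
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    in1 = g1.to_numpy()

    event_times = np.unique(time[event])
    o1 = e1 = e2 = v = 0.0
    o2 = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & in1).sum()
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * (n - n1) / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    if o1 == 0 or o2 == 0:
        warnings.warn("a group has zero events; hazard ratio is infinite/zero",
                      stacklevel=2)
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o1 / e1) / (o2 / e2) if e1 > 0 and e2 > 0 and o2 > 0 else np.inf
        half = 1.96 * np.sqrt(1 / e1 + 1 / e2) if e1 > 0 and e2 > 0 else np.inf
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half))) if np.isfinite(hr) \
            else (np.nan, np.nan)
    return LogRankResult(float(chi2), p, float(hr), ci,
                         observed=(float(o1), float(o2)),
                         expected=(float(e1), float(e2)))


def median_bifurcate(values: pd.Series) -> pd.Series:
    """Split samples at the median: above -> "high", at or below -> "low"."""
    values = pd.Series(values)
    if len(values) < 2:
        raise InvalidConfigError("need >=2 samples to bifurcate")
    if values.nunique() == 1:
        raise DegenerateInputError("all values identical; median split undefined")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table, (r-1)(c-1) df,
    no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise InvalidConfigError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InvalidConfigError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)
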