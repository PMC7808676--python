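"""Group-comparison statistics for per-cell measurements.

One-way ANOVA with Tukey HSD for multi-group comparisons, Fisher's exact
test alongside Pearson's chi-squared (uncorrected) for categorical scores, a
two-sample t-test on arcsine-square-root transformed proportions, and
mean/SEM summaries.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """The requested test is undefined on this data (e.g. zero variance)."""


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, p_adj


@dataclasses.dataclass(frozen=True)
class ContingencyResult:
    fisher_p: float | None  # None unless the table is 2x2
    chi2_statistic: float
    chi2_p: float
    zero_margin: bool


def anova_tukey(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA followed by Tukey's HSD on all group pairs.

    Requires >= 2 groups with n >= 2 each and nonzero pooled within-group
    variance.
    """
    names = list(groups)
    samples = [np.asarray(groups[name], dtype=float) for name in names]
    if len(samples) < 2:
        raise DegenerateDataError("need at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise DegenerateDataError("each group needs at least 2 observations")
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        raise DegenerateDataError("zero within-group variance: ANOVA undefined")
    f_statistic, p_value = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "diff": samples[i].mean() - samples[j].mean(),
                "p_adj": float(hsd.pvalue[i, j]),
            }
        )
    return AnovaResult(
        f_statistic=float(f_statistic), p_value=float(p_value), tukey=pd.DataFrame(rows)
    )


def fisher_chi2(counts: Sequence[Sequence[int]]) -> ContingencyResult:
    """Fisher's exact test (2x2 only, two-sided) and Pearson's chi-squared
    without continuity correction on an r x c contingency table.

    Tables with a zero row or column margin are flagged; the chi-squared
    fields are NaN in that case.
    """
    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    zero_margin = bool(
        np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)
    )
    fisher_p = None
    if table.shape == (2, 2):
        _, fisher_p = sps.fisher_exact(table, alternative="two-sided")
        fisher_p = float(fisher_p)
    if zero_margin:
        return ContingencyResult(fisher_p, float("nan"), float("nan"), True)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(fisher_p, float(chi2), float(p), False)


def arcsine_transform(proportions: Sequence[float]) -> np.ndarray:
    """x -> arcsin(sqrt(x)), mapping [0, 1] onto [0, pi/2]."""
    p = np.asarray(proportions, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def arcsine_prop_test(
    props_a: Sequence[float], props_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample t-test on arcsine-square-root transformed per-trial
    proportions. Returns (t, p)."""
    a = arcsine_transform(props_a)
    b = arcsine_transform(props_b)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("need at least 2 trials per arm")
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)


def summarize(values: Sequence[float], group: Sequence) -> pd.DataFrame:
    """Per-group mean, SEM (sd/sqrt(n), 0 with a flag when n == 1), and n."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(group)})
    rows = []
    for name, sub in df.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        n = v.size
        sem = float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {"group": name, "mean": float(v.mean()), "sem": sem, "n": n, "n1_flag": n == 1}
        )
    return pd.DataFrame(rows)
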