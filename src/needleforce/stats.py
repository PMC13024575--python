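"""One-way ANOVA and Tukey HSD pairwise comparisons for puncture responses.

The factorial study feeds per-trial scalar responses (peak force by
default) grouped by a single factor (speed or angle) into a standard
one-way analysis of variance, followed by Tukey's honestly-significant-
difference all-pairs test. The Tukey construction uses the studentized
range distribution (numerical quantiles via ``scipy.stats
.studentized_range``); the unequal-sample-size Tukey-Kramer form is used
throughout, which reduces to the classical balanced formula for equal n.
Each pairwise row reports meandiff (first group mean minus second group
mean), the family-wise adjusted p-value, the confidence bounds, and the
reject decision — which is always consistent with both the p-value and
whether the interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import ExperimentDataset

__all__ = ["GroupData", "AnovaResult", "TukeyRow", "anova_oneway",
           "tukey_hsd", "factorial_report", "table_report"]


@dataclass
class GroupData:
    """Labelled groups of scalar responses (e.g. peak forces in N)."""

    groups: dict  # label -> 1-D array of values

    def __post_init__(self) -> None:
        clean = {str(k): np.asarray(v, dtype=float).ravel()
                 for k, v in self.groups.items()}
        if len(clean) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in clean.items():
            if v.size < 2:
                raise ValueError(f"group {k!r} needs at least 2 values")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {k!r} contains non-finite values")
        self.groups = clean

    @property
    def labels(self):
        return list(self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return sum(v.size for v in self.groups.values())


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class TukeyRow:
    group1: str
    group2: str
    meandiff: float
    p_adj: float
    lower: float
    upper: float
    reject: bool


def anova_oneway(data: GroupData) -> AnovaResult:
    """Standard between/within variance decomposition and F test."""
    vals = list(data.groups.values())
    all_vals = np.concatenate(vals)
    grand = all_vals.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in vals)
    dfb = data.k - 1
    dfw = data.n_total - data.k
    msw = ssw / dfw
    if msw == 0.0:
        raise ZeroDivisionError(
            "zero within-group variance: F statistic undefined")
    msb = ssb / dfb
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(f_stat=float(f), p_value=p, df_between=dfb,
                       df_within=dfw, ms_between=float(msb),
                       ms_within=float(msw))


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(data: GroupData, alpha: float = 0.05,
              compute_p: bool = True):
    """All-pairs Tukey HSD (Tukey-Kramer) comparisons.

    Returns one :class:`TukeyRow` per unordered pair, k*(k-1)/2 rows, in
    label order. The pairwise standard error is
    sqrt(MS_within/2 * (1/n_i + 1/n_j)) and both the adjusted p-value and
    the CI half-width q_crit * se come from the studentized range with
    (k, df_within) parameters. ``compute_p=False`` skips the (slower)
    p-value evaluation and decides rejection from the interval alone —
    the two decisions are equivalent by construction.
    """
    an = anova_oneway(data)
    labels = data.labels
    qc = _q_crit(alpha, data.k, an.df_within)
    rows = []
    for a, b in combinations(labels, 2):
        va, vb = data.groups[a], data.groups[b]
        diff = float(va.mean() - vb.mean())
        se = float(np.sqrt(an.ms_within / 2.0
                           * (1.0 / va.size + 1.0 / vb.size)))
        half = qc * se
        lower, upper = diff - half, diff + half
        if compute_p:
            q_stat = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q_stat, data.k,
                                                   an.df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
            reject = bool(p_adj < alpha)
        else:
            p_adj = float("nan")
            reject = bool(lower > 0.0 or upper < 0.0)
        rows.append(TukeyRow(group1=str(a), group2=str(b), meandiff=diff,
                             p_adj=p_adj, lower=lower, upper=upper,
                             reject=reject))
    return rows


def _dataset_groups(dataset: ExperimentDataset, factor: str,
                    response: str = "peak_force") -> GroupData:
    col = {"speed": "speed_mm_s", "angle": "angle_deg"}.get(factor)
    if col is None:
        raise ValueError("factor must be 'speed' or 'angle'")
    resp_col = {"peak_force": "peak_force_N"}.get(response)
    if resp_col is None:
        raise ValueError(f"unknown response {response!r}")
    df = dataset.summary
    groups = {f"{factor}={lvl:g}": sub[resp_col].to_numpy()
              for lvl, sub in df.groupby(col, sort=True)}
    if len(groups) < 2:
        raise ValueError(f"dataset has a single {factor} level; "
                         "nothing to compare")
    return GroupData(groups)


def factorial_report(dataset: ExperimentDataset, factor: str,
                     response: str = "peak_force", alpha: float = 0.05):
    """ANOVA + Tukey rows for one factor of a factorial dataset.

    The response defaults to per-trial peak force. Returns
    ``(AnovaResult, list[TukeyRow])``.
    """
    data = _dataset_groups(dataset, factor, response)
    return anova_oneway(data), tukey_hsd(data, alpha=alpha)


def table_report(named_datasets, response: str = "peak_force",
                 alpha: float = 0.05) -> pd.DataFrame:
    """Combined pairwise-comparison table across tissues and factors.

    ``named_datasets`` is an iterable of (tissue_label, factor, dataset);
    the output stacks all Tukey rows with sequential comparison ids
    a_1, a_2, ... and the columns meandiff / p-adj / lower / upper /
    reject, one block per tissue x factor.
    """
    rows = []
    i = 0
    for tissue, factor, dataset in named_datasets:
        an, tukey = factorial_report(dataset, factor, response=response,
                                     alpha=alpha)
        for row in tukey:
            i += 1
            rows.append({
                "comparison": f"a_{i}", "tissue": tissue, "factor": factor,
                "group1": row.group1, "group2": row.group2,
                "meandiff": row.meandiff, "p_adj": row.p_adj,
                "lower": row.lower, "upper": row.upper,
                "reject": row.reject, "anova_F": an.f_stat,
                "anova_p": an.p_value,
            })
    return pd.DataFrame(rows)
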