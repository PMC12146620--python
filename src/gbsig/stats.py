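"""Group-comparison statistics and the behavioral preference ratio.

Methods: pooled two-sample t, Welch t, paired t, Wilcoxon signed-rank
(exact null for n ≤ 25 without ties/zeros, otherwise normal approximation
with continuity correction), one-way ANOVA, and the Tukey–Kramer post hoc
procedure (studentized-range distribution with the unequal-n correction).
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

METHODS = ("pooled_t", "welch_t", "paired_t", "wilcoxon_signed_rank",
           "anova_oneway", "tukey_kramer")


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float
    sem: float
    median: float


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float


@dataclass
class GroupComparison:
    """Result of one group comparison."""

    method: str
    statistic: float
    df: Optional[float]
    p_value: float
    groups: List[GroupSummary]
    pairwise: List[PairwiseComparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "groups": [vars(g) for g in self.groups],
            "pairwise": [vars(p) for p in self.pairwise],
        }


@dataclass
class PreferenceResult:
    """Two-bottle preference: sugar consumption over total fluid, percent."""

    sugar_ml: float
    total_ml: float
    ratio_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_percent <= 100.0:
            raise ValueError("preference ratio outside [0, 100]")


def _summaries(groups: Dict[str, np.ndarray]) -> List[GroupSummary]:
    out = []
    for name, x in groups.items():
        x = np.asarray(x, dtype=float)
        sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        out.append(GroupSummary(name=name, n=len(x), mean=float(x.mean()),
                                sd=sd, sem=sd / np.sqrt(len(x)),
                                median=float(np.median(x))))
    return out


def compare_groups(groups: Dict[str, Sequence[float]], method: str
                   ) -> GroupComparison:
    """Two-sided group comparison by the named method.

    ``groups`` maps group name → observations. Paired methods (paired t,
    Wilcoxon) require exactly two groups of equal length aligned by
    animal; ANOVA and Tukey–Kramer accept two or more groups.
    """
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    names = list(arrs)
    if method in ("pooled_t", "welch_t", "paired_t", "wilcoxon_signed_rank"):
        if len(arrs) != 2:
            raise ValueError(f"{method} needs exactly 2 groups, got {len(arrs)}")
        a, b = arrs[names[0]], arrs[names[1]]
        if method in ("paired_t", "wilcoxon_signed_rank") and len(a) != len(b):
            raise ValueError("paired methods need equal-length, "
                             "animal-aligned groups")
        if method == "pooled_t":
            if min(len(a), len(b)) < 2:
                raise ValueError("need >= 2 observations per group")
            res = st.ttest_ind(a, b, equal_var=True)
            dof = len(a) + len(b) - 2
        elif method == "welch_t":
            if min(len(a), len(b)) < 2:
                raise ValueError("need >= 2 observations per group")
            res = st.ttest_ind(a, b, equal_var=False)
            dof = float(res.df)
        elif method == "paired_t":
            if len(a) < 2:
                raise ValueError("need >= 2 pairs")
            res = st.ttest_rel(a, b)
            dof = len(a) - 1
        else:
            return _wilcoxon(a, b, _summaries(arrs))
        return GroupComparison(method=method, statistic=float(res.statistic),
                               df=float(dof), p_value=float(res.pvalue),
                               groups=_summaries(arrs))
    if method == "anova_oneway":
        if len(arrs) < 2:
            raise ValueError("ANOVA needs >= 2 groups")
        if any(len(x) < 2 for x in arrs.values()):
            raise ValueError("need >= 2 observations per group")
        res = st.f_oneway(*arrs.values())
        k = len(arrs)
        n = sum(len(x) for x in arrs.values())
        return GroupComparison(method=method, statistic=float(res.statistic),
                               df=float(k - 1), p_value=float(res.pvalue),
                               groups=_summaries(arrs))
    if method == "tukey_kramer":
        return tukey_kramer(arrs)
    raise ValueError(f"unknown method {method!r}")


def _wilcoxon(a: np.ndarray, b: np.ndarray,
              summaries: List[GroupSummary]) -> GroupComparison:
    d = a - b
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    if len(nz) <= 25 and not has_ties and len(nz) == len(d):
        mode = "exact"
    else:
        mode = "approx"
    res = st.wilcoxon(a, b, correction=True, method=mode,
                      zero_method="wilcox")
    return GroupComparison(method="wilcoxon_signed_rank",
                           statistic=float(res.statistic), df=None,
                           p_value=float(res.pvalue), groups=summaries)


def tukey_kramer(groups: Dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA F plus Tukey–Kramer pairwise p-values.

    Pairwise p-values come from the studentized-range distribution with the
    Tukey–Kramer unequal-n standard error; with two groups the procedure
    reproduces the pooled t-test's p-value.
    """
    if len(groups) < 2:
        raise ValueError("Tukey-Kramer needs >= 2 groups")
    if any(len(x) < 2 for x in groups.values()):
        raise ValueError("need >= 2 observations per group")
    names = list(groups)
    res = st.tukey_hsd(*groups.values())
    f = st.f_oneway(*groups.values())
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append(PairwiseComparison(
                group_a=names[i], group_b=names[j],
                statistic=float(res.statistic[i, j]),
                p_value=float(res.pvalue[i, j])))
    n = sum(len(x) for x in groups.values())
    return GroupComparison(method="tukey_kramer",
                           statistic=float(f.statistic),
                           df=float(len(names) - 1),
                           p_value=float(f.pvalue),
                           groups=_summaries(groups), pairwise=pairwise)


def preference_ratio(sugar_ml: float, total_ml: float) -> PreferenceResult:
    """Preference (%) = 100 × sugar consumption / total fluid consumption."""
    if total_ml <= 0:
        raise ValueError("total fluid consumption must be > 0")
    if sugar_ml < 0 or sugar_ml > total_ml:
        raise ValueError("sugar consumption must lie in [0, total]")
    return PreferenceResult(sugar_ml=sugar_ml, total_ml=total_ml,
                            ratio_percent=100.0 * sugar_ml / total_ml)


def summary_table(df: pd.DataFrame, value: str, group: str,
                  comparisons: Sequence[str] = ()) -> pd.DataFrame:
    """Tidy per-group summary (n, mean, SD, SEM, median), mean ± SD style,
    with optional appended comparison rows."""
    if group not in df.columns or value not in df.columns:
        raise ValueError("grouping or value column missing")
    if df[group].isna().any() or (df.groupby(group)[value].count() == 0).any():
        raise ValueError("empty group")
    rows = []
    grouped = {str(g): sub[value].to_numpy(dtype=float)
               for g, sub in df.groupby(group, sort=True)}
    for s in _summaries(grouped):
        rows.append({"group": s.name, "n": s.n, "mean": s.mean, "sd": s.sd,
                     "sem": s.sem, "median": s.median,
                     "mean_pm_sd": f"{s.mean:.3g} ± {s.sd:.3g}",
                     "method": "", "statistic": np.nan, "p_value": np.nan})
    for method in comparisons:
        cmp_ = compare_groups(grouped, method)
        rows.append({"group": " vs ".join(grouped), "n": sum(
            len(x) for x in grouped.values()), "mean": np.nan, "sd": np.nan,
            "sem": np.nan, "median": np.nan, "mean_pm_sd": "",
            "method": method, "statistic": cmp_.statistic,
            "p_value": cmp_.p_value})
        for pw in cmp_.pairwise:
            rows.append({"group": f"{pw.group_a} vs {pw.group_b}",
                         "n": len(grouped[pw.group_a]) + len(grouped[pw.group_b]),
                         "mean": np.nan, "sd": np.nan, "sem": np.nan,
                         "median": np.nan, "mean_pm_sd": "",
                         "method": method + "_pairwise",
                         "statistic": pw.statistic, "p_value": pw.p_value})
    return pd.DataFrame(rows)
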