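"""Thin association-statistics layer for profile tables.

Auto-selects the conventional nonparametric test: Wilcoxon rank-sum
(Mann–Whitney U, two-sided) for a numeric feature across two groups,
Kruskal–Wallis across three or more, and the χ² test (no continuity
correction by default) for two categorical variables.  Families of p
values are adjusted with Benjamini–Hochberg.  Survival is compared with
Kaplan–Meier curves and the log-rank test over a 5-year horizon:
observations beyond the horizon are administratively censored there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TESTS = ("wilcoxon", "kruskal_wallis", "chi_square", "logrank")


@dataclass
class AssociationResult:
    feature: str
    group_var: str
    test: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    n_per_group: dict[str, int] | None = None


def _check_groups(groups: pd.Series) -> list[str]:
    levels = [g for g in pd.unique(groups.dropna())]
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    return [str(g) for g in levels]


def associate(
    values: Sequence | pd.Series,
    groups: Sequence | pd.Series,
    feature: str = "value",
    group_var: str = "group",
) -> AssociationResult:
    """Test association between a per-sample feature and a grouping.

    Numeric values: two groups → Wilcoxon rank-sum (exact when the
    combined n is at most 20 and there are no ties, normal approximation
    with mid-rank tie correction otherwise); three or more groups →
    Kruskal–Wallis.  Non-numeric values → χ² on the contingency table.
    """
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True).astype(str)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    levels = sorted(set(groups.dropna()))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    numeric = pd.api.types.is_numeric_dtype(values)
    if numeric:
        keep = values.notna()
        values, groups = values[keep], groups[keep]
    n_per_group = {g: int((groups == g).sum()) for g in levels}
    for g, n in n_per_group.items():
        if n == 0:
            raise ValueError(f"group {g!r} has no observations")

    if not numeric:
        table = pd.crosstab(values, groups)
        stat, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        return AssociationResult(feature, group_var, "chi_square",
                                 float(stat), float(p), n_per_group=n_per_group)

    samples = [values[groups == g].to_numpy(dtype=float) for g in levels]
    if len(levels) == 2:
        x, y = samples
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if no_ties and len(x) + len(y) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return AssociationResult(feature, group_var, "wilcoxon",
                                 float(res.statistic), float(res.pvalue),
                                 n_per_group=n_per_group)
    res = sps.kruskal(*samples)
    return AssociationResult(feature, group_var, "kruskal_wallis",
                             float(res.statistic), float(res.pvalue),
                             n_per_group=n_per_group)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment of a family of p values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """BH-adjust one family of association results in place."""
    adj = adjust_bh([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return list(results)


def _censor_at(times: np.ndarray, events: np.ndarray, horizon: float):
    t = np.minimum(times, horizon)
    e = np.where(times > horizon, 0, events)
    return t, e


def survival_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
    horizon_months: float = 60.0,
) -> tuple[AssociationResult, dict[str, pd.DataFrame]]:
    """Kaplan–Meier curves per group and the log-rank test.

    Observations beyond ``horizon_months`` (60 = 5 years by default) are
    administratively censored at the horizon.  Returns the test result and
    a per-group KM survival table (``timeline``, ``survival``).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    groups = pd.Series(list(groups)).astype(str)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        if not (groups == g).any():
            raise ValueError(f"group {g!r} has no observations")

    t, e = _censor_at(times, events, horizon_months)
    res = multivariate_logrank_test(t, groups.to_numpy(), e)
    curves: dict[str, pd.DataFrame] = {}
    for g in levels:
        m = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=g)
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"timeline": sf.index.to_numpy(), "survival": sf[g].to_numpy()}
        )
    n_per_group = {g: int((groups == g).sum()) for g in levels}
    result = AssociationResult(
        "survival", "group", "logrank",
        float(res.test_statistic), float(res.p_value), n_per_group=n_per_group,
    )
    return result, curves


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into a tidy table."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "group_var": r.group_var,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "n_per_group": (
                    ";".join(f"{k}={v}" for k, v in (r.n_per_group or {}).items())
                ),
            }
            for r in results
        ]
    )
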