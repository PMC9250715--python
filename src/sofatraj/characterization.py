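"""Between-subphenotype comparisons: Table-1 summaries and 28-day survival.

Categorical covariates are compared with the chi-square test (no continuity
correction), falling back to Fisher's exact test for 2x2 tables with any
expected cell below 5. Continuous covariates go through a per-group
Shapiro-Wilk normality screen at alpha = 0.05: if every group passes, a
two-sample t-test (two groups) or one-way ANOVA (more) is used and the
summary is mean (SD); otherwise Mann-Whitney / Kruskal-Wallis with
median [IQR]. Survival to 28 days uses the Kaplan-Meier product-limit
estimator and the log-rank test (df = number of groups - 1); both are
delegated to lifelines.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

ALPHA_NORMALITY = 0.05


@dataclasses.dataclass
class GroupComparison:
    variable: str
    kind: str  # "categorical" | "continuous"
    summaries: dict  # group -> per-category counts (%) or a location summary
    test: str
    statistic: float
    pvalue: float

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < 0.05)


#: below this per-group size the Shapiro-Wilk screen is uninformative and
#: the nonparametric route is taken directly
MIN_N_FOR_NORMALITY_SCREEN = 12


def _groups_normal(values: pd.Series, groups: pd.Series) -> bool:
    for _, sub in values.groupby(groups, observed=True):
        sub = sub.dropna()
        if len(sub) < MIN_N_FOR_NORMALITY_SCREEN or sub.nunique() == 1:
            return False
        if stats.shapiro(sub).pvalue < ALPHA_NORMALITY:
            return False
    return True


def _compare_categorical(values: pd.Series, groups: pd.Series, name: str) -> GroupComparison:
    table = pd.crosstab(values, groups)
    summaries = {}
    for g in table.columns:
        col = table[g]
        pct = 100.0 * col / col.sum() if col.sum() else col * np.nan
        summaries[g] = {
            cat: f"{int(col[cat])} ({pct[cat]:.1f})" for cat in table.index
        }
    if table.shape[0] < 2 or table.shape[1] < 2:
        return GroupComparison(name, "categorical", summaries, "degenerate", np.nan, np.nan)
    obs = table.to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    if obs.shape == (2, 2) and (expected < 5).any():
        stat, p = stats.fisher_exact(obs)
        return GroupComparison(name, "categorical", summaries, "fisher_exact", float(stat), float(p))
    return GroupComparison(name, "categorical", summaries, "chi_square", float(chi2), float(p))


def _compare_continuous(values: pd.Series, groups: pd.Series, name: str) -> GroupComparison:
    samples = [sub.dropna().to_numpy(dtype=float) for _, sub in values.groupby(groups, observed=True)]
    keys = [g for g, _ in values.groupby(groups, observed=True)]
    if values.dropna().nunique() <= 1 or len(samples) < 2:
        return GroupComparison(name, "continuous", {}, "degenerate", np.nan, np.nan)
    normal = _groups_normal(values, groups)
    if normal:
        summaries = {
            g: f"{s.mean():.2f} ({s.std(ddof=1):.2f})" for g, s in zip(keys, samples)
        }
        if len(samples) == 2:
            res = stats.ttest_ind(*samples)
            test = "t_test"
        else:
            res = stats.f_oneway(*samples)
            test = "anova"
    else:
        summaries = {
            g: f"{np.median(s):.2f} [{np.percentile(s, 25):.2f}-{np.percentile(s, 75):.2f}]"
            for g, s in zip(keys, samples)
        }
        if len(samples) == 2:
            res = stats.mannwhitneyu(*samples, alternative="two-sided", method="auto")
            test = "mann_whitney"
        else:
            res = stats.kruskal(*samples)
            test = "kruskal_wallis"
    return GroupComparison(
        name, "continuous", summaries, test, float(res.statistic), float(res.pvalue)
    )


def summarize_groups(
    covariates: pd.DataFrame,
    assignment: pd.Series,
    variables: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """Compare each covariate across the assigned groups.

    ``assignment`` is a per-patient group label (index = patient_id) and
    must cover every covariate row used. Variable type is taken from the
    dtype: boolean/object/categorical columns are treated as categorical,
    numeric columns as continuous.
    """
    missing = set(covariates.index) - set(assignment.index)
    if missing:
        raise ValueError(f"assignment missing for {len(missing)} patients")
    groups = assignment.loc[covariates.index]
    if variables is None:
        variables = list(covariates.columns)
    out = []
    for name in variables:
        col = covariates[name]
        if col.dtype == bool or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            out.append(_compare_categorical(col, groups, name))
        else:
            out.append(_compare_continuous(col, groups, name))
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"variable": c.variable, "type": c.kind, "test": c.test,
               "statistic": c.statistic, "pvalue": c.pvalue}
        for g, s in c.summaries.items():
            row[f"group_{g}"] = s if isinstance(s, str) else "; ".join(
                f"{k}: {v}" for k, v in s.items()
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _validate_survival(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "group"}
    if not required <= set(records.columns):
        raise ValueError(f"survival records need columns {sorted(required)}")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if (records["time"] > 28).any():
        raise ValueError("survival times must be administratively censored at 28 days")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival per group.

    ``records``: DataFrame with columns time (days), event (1 = death),
    group. Returns a long frame (group, time, survival, at_risk) with the
    step function evaluated at each group's observed times (t = 0
    included, S(0) = 1).
    """
    records = _validate_survival(records)
    frames = []
    for g, sub in records.groupby("group", observed=True):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(int))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
        frames.append(
            pd.DataFrame(
                {"group": g, "time": surv.index.to_numpy(),
                 "survival": surv.to_numpy(), "at_risk": at_risk.to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def survival_at(km: pd.DataFrame, t: float) -> dict:
    """S(t) per group from a km_estimate frame (step-function evaluation)."""
    out = {}
    for g, sub in km.groupby("group", observed=True):
        sub = sub.sort_values("time")
        eligible = sub[sub["time"] <= t]
        out[g] = float(eligible["survival"].iloc[-1]) if len(eligible) else 1.0
    return out


def logrank_test(
    records: pd.DataFrame, groups: Sequence | None = None
) -> tuple[float, float, int]:
    """Log-rank test across groups; returns (chi2 statistic, p, df).

    ``groups`` optionally names the groups to compare; each must have at
    least one record. Fewer than two groups is an error.
    """
    records = _validate_survival(records)
    if groups is not None:
        for g in groups:
            if (records["group"] == g).sum() == 0:
                raise ValueError(f"group {g!r} has no records")
        records = records[records["group"].isin(list(groups))]
    n_groups = records["group"].nunique()
    if n_groups < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(
        records["time"], records["group"], records["event"].astype(int)
    )
    return float(res.test_statistic), float(res.p_value), n_groups - 1


def outcomes_to_survival(outcomes: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Join generated outcomes with group labels into survival records."""
    return pd.DataFrame(
        {
            "time": outcomes["survival_time"],
            "event": outcomes["death"].astype(int),
            "group": labels.loc[outcomes.index],
        }
    ).reset_index()
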