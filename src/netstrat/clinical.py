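"""Clinical association of molecular subtypes.

Survival is compared across subtypes with Kaplan-Meier curves and the
multi-group log-rank test, after administrative censoring at a 10-year
horizon; tumour stage/grade association uses Pearson's chi-squared test on
the subtype x category contingency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalTestResult",
    "truncate_followup",
    "kaplan_meier",
    "logrank_test",
    "chi_squared_association",
]

DAYS_PER_YEAR = 365


@dataclass
class SurvivalTestResult:
    k: int
    statistic: float
    df: int
    p_value: float
    group_sizes: dict
    group_events: dict


def truncate_followup(clin: pd.DataFrame, horizon_days: int = 3650) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``horizon_days``.

    Times strictly beyond the horizon are capped at it and their events
    recoded as censored; an event exactly at the horizon is kept.
    """
    out = clin.copy()
    beyond = out["time"] > horizon_days
    out.loc[beyond, "event"] = 0
    out.loc[beyond, "time"] = float(horizon_days)
    return out


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival, at_risk) table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
    })
    out["at_risk"] = table["at_risk"].reindex(out["time"]).to_numpy()
    return out


def _intersect(labels: pd.Series, clin: pd.DataFrame) -> pd.DataFrame:
    common = labels.index.intersection(clin.index)
    dropped = len(labels) - len(common)
    if dropped:
        logger.info("clinical: %d clustered samples lack clinical records", dropped)
    df = clin.loc[common, ["time", "event"]].copy()
    df["label"] = labels.loc[common]
    return df


def logrank_test(labels: pd.Series, clin: pd.DataFrame) -> SurvivalTestResult:
    """Multi-group log-rank test of survival differences across subtypes.

    ``labels`` is indexed by sample ID; samples without clinical records are
    excluded, empty groups are dropped, and at least two groups must remain.
    """
    df = _intersect(labels, clin)
    groups = df["label"].value_counts()
    if (groups == 0).any():
        logger.warning("logrank_test: dropping empty groups %s",
                       list(groups.index[groups == 0]))
        df = df[df["label"].isin(groups.index[groups > 0])]
    n_groups = df["label"].nunique()
    if n_groups < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    res = multivariate_logrank_test(df["time"], df["label"], df["event"])
    return SurvivalTestResult(
        k=n_groups,
        statistic=float(res.test_statistic),
        df=n_groups - 1,
        p_value=float(res.p_value),
        group_sizes=df.groupby("label")["event"].size().to_dict(),
        group_events=df.groupby("label")["event"].sum().to_dict(),
    )


def chi_squared_association(labels: pd.Series, category: pd.Series):
    """Pearson chi-squared test of subtype vs a clinical category.

    Missing categories are dropped; no continuity correction.  Returns
    ``(statistic, df, p_value, contingency_table)``.
    """
    common = labels.index.intersection(category.dropna().index)
    table = pd.crosstab(labels.loc[common], category.loc[common])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table {table.shape}; need >= 2 levels "
            "on both margins"
        )
    stat, p, df, expected = stats.chi2_contingency(table.values, correction=False)
    if (expected < 5).any():
        logger.warning(
            "chi_squared_association: %d cells have expected count < 5",
            int((expected < 5).sum()),
        )
    return float(stat), int(df), float(p), table
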