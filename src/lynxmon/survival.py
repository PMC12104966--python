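"""Kaplan-Meier survival of monitored animals with a telemetry end-status taxonomy.

Each GPS-tracking period ends in one of six states: the animal was alive when
the collar stopped (right-censored), it disappeared (fate unknown), or it died
— by suspected illegal killing, confirmed illegal killing, roadkill, or
natural causes; the first three mortality causes are grouped as human-caused.
Periods are converted to (time, event) records under a selectable policy,
survival is estimated with the product-limit (Kaplan-Meier) estimator with
Greenwood standard errors, and groups are compared with the k-sample log-rank
test.  An animal recollared years later contributes its tracking periods as
independent records.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EndStatus",
    "MORTALITY_STATUSES",
    "HUMAN_CAUSED_STATUSES",
    "CensoringPolicy",
    "SurvivalCurve",
    "to_survival_records",
    "kaplan_meier",
    "logrank_test",
]


class EndStatus(str, Enum):
    ALIVE = "alive"
    DISAPPEARED = "disappeared"
    SUSPECTED_ILLEGAL_KILLING = "suspected_illegal_killing"
    CONFIRMED_ILLEGAL_KILLING = "confirmed_illegal_killing"
    ROADKILL = "roadkill"
    NATURAL_MORTALITY = "natural_mortality"


MORTALITY_STATUSES = frozenset(
    {
        EndStatus.SUSPECTED_ILLEGAL_KILLING,
        EndStatus.CONFIRMED_ILLEGAL_KILLING,
        EndStatus.ROADKILL,
        EndStatus.NATURAL_MORTALITY,
    }
)
HUMAN_CAUSED_STATUSES = frozenset(
    {
        EndStatus.SUSPECTED_ILLEGAL_KILLING,
        EndStatus.CONFIRMED_ILLEGAL_KILLING,
        EndStatus.ROADKILL,
    }
)


class CensoringPolicy(str, Enum):
    """How end statuses map to events.

    ``DEFAULT``: disappeared excluded, every mortality cause is an event.
    ``DISAPPEARED_CENSORED``: disappeared kept as censored at last contact.
    ``HUMAN_CAUSED_ONLY``: only human-caused mortality counts as an event;
    natural deaths are censored at the death date (disappeared still excluded).
    """

    DEFAULT = "default"
    DISAPPEARED_CENSORED = "disappeared_censored"
    HUMAN_CAUSED_ONLY = "human_caused_only"


def to_survival_records(
    periods: pd.DataFrame,
    policy: CensoringPolicy | str = CensoringPolicy.DEFAULT,
) -> pd.DataFrame:
    """Convert tracking periods to (group, time_days, event) records.

    ``periods`` needs columns ``animal_id, group, start, end, end_status``.
    Distinct tracking periods of the same animal are kept as independent
    records.  Unknown status labels raise.
    """
    policy = CensoringPolicy(policy)
    statuses = periods["end_status"].map(
        lambda s: EndStatus(s) if not isinstance(s, EndStatus) else s
    )
    start = pd.to_datetime(periods["start"])
    end = pd.to_datetime(periods["end"])
    time_days = (end - start).dt.total_seconds() / 86_400.0
    if (time_days < 0).any():
        raise ValueError("tracking period ends before it starts")

    if policy is CensoringPolicy.DISAPPEARED_CENSORED:
        keep = pd.Series(True, index=periods.index)
    else:
        keep = statuses != EndStatus.DISAPPEARED

    if policy is CensoringPolicy.HUMAN_CAUSED_ONLY:
        event = statuses.isin(HUMAN_CAUSED_STATUSES)
    else:
        event = statuses.isin(MORTALITY_STATUSES)

    out = pd.DataFrame(
        {
            "animal_id": periods["animal_id"],
            "group": periods["group"],
            "time_days": time_days,
            "event": event.astype(int),
        }
    )
    return out.loc[keep].reset_index(drop=True)


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood standard errors."""

    table: pd.DataFrame          # time_days, n_risk, n_event, survival, se
    group: str | None = None

    def survival_at(self, t: float) -> float:
        """S(t): the step-function value at time t (S(0) = 1)."""
        past = self.table[self.table["time_days"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "group", self.group or "")
        out.to_csv(path, index=False)


def kaplan_meier(records: pd.DataFrame, group: str | None = None) -> SurvivalCurve:
    """Kaplan-Meier estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``records`` needs ``time_days`` and ``event`` columns.  At tied times,
    deaths are processed before censorings (the standard convention).  The
    variance follows Greenwood's formula.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    t = records["time_days"].to_numpy(float)
    e = records["event"].to_numpy(int)
    order = np.lexsort((1 - e, t))  # by time, events first at ties
    t, e = t[order], e[order]

    times = np.unique(t[e == 1])
    n_total = len(t)
    rows = []
    s = 1.0
    greenwood = 0.0
    for ti in times:
        n_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        if n_risk > d:
            greenwood += d / (n_risk * (n_risk - d))
        se = s * np.sqrt(greenwood) if s > 0 else 0.0
        rows.append(
            {"time_days": ti, "n_risk": n_risk, "n_event": d, "survival": s, "se": se}
        )
    table = pd.DataFrame(rows, columns=["time_days", "n_risk", "n_event", "survival", "se"])
    del n_total
    return SurvivalCurve(table=table, group=group)


def logrank_test(
    records: pd.DataFrame, group_column: str = "group"
) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square, df, p-value).

    Observed-minus-expected event counts are accumulated across distinct event
    times with the hypergeometric variance(-covariance) of the per-group event
    counts; the statistic is O-E against its estimated covariance on the first
    k-1 groups.
    """
    groups = sorted(records[group_column].unique())
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if records["event"].sum() == 0:
        raise ValueError("need at least one event")
    t = records["time_days"].to_numpy(float)
    e = records["event"].to_numpy(int)
    g = records[group_column].map({name: i for i, name in enumerate(groups)}).to_numpy()

    event_times = np.unique(t[e == 1])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in event_times:
        at_risk = t >= ti
        n = int(at_risk.sum())
        d = int((e[t == ti] == 1).sum())
        n_g = np.bincount(g[at_risk], minlength=k).astype(float)
        d_g = np.bincount(g[(t == ti) & (e == 1)], minlength=k).astype(float)
        exp_g = d * n_g / n
        o_minus_e += d_g - exp_g
        if n > 1:
            factor = d * (n - d) / (n - 1)
            p_g = n_g / n
            cov += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
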