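"""Lineage extinction calling, Kaplan-Meier curves, and log-rank tests.

Time is measured in transfer index (the experiment's sampling resolution).
A lineage dies at the first transfer whose 72-h pre-dilution OD600 falls
strictly below the death threshold (an OD exactly at the threshold counts
as alive); lineages alive at the final transfer are right-censored there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


def call_events(table: pd.DataFrame, threshold: float = 0.01,
                n_transfers: int | None = None) -> pd.DataFrame:
    """One survival record per lineage from a transfers table.

    Returns columns lineage_id, group (culture type), event_transfer,
    event. ``n_transfers`` defaults to the largest transfer index present.
    """
    if n_transfers is None:
        n_transfers = int(table["transfer"].max())
    rows = []
    for lid, sub in table.groupby("lineage_id", sort=False):
        sub = sub.sort_values("transfer")
        od = sub["od600"].to_numpy(dtype=float)
        dead = od < threshold
        if dead.any():
            t = int(sub["transfer"].to_numpy()[int(np.argmax(dead))])
            rows.append({"lineage_id": lid,
                         "group": sub["culture_type"].iloc[0],
                         "event_transfer": max(t, 1), "event": True})
        else:
            rows.append({"lineage_id": lid,
                         "group": sub["culture_type"].iloc[0],
                         "event_transfer": n_transfers, "event": False})
    return pd.DataFrame(rows)


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve S(t) with at-risk counts for one group."""
    if records.empty:
        raise ValueError("need at least one survival record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["event_transfer"], event_observed=records["event"])
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"]
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.iloc[:, 0].to_numpy(dtype=float),
    })
    out["at_risk"] = at_risk.reindex(surv.index).ffill().to_numpy()
    return out


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), df = 1.

    With no event in either group the statistic is 0 and p = 1.
    """
    if records_a.empty or records_b.empty:
        raise ValueError("both groups must be non-empty")
    if not records_a["event"].any() and not records_b["event"].any():
        return 0.0, 1.0
    res = _ll_logrank(records_a["event_transfer"], records_b["event_transfer"],
                      event_observed_A=records_a["event"],
                      event_observed_B=records_b["event"])
    return float(res.test_statistic), float(res.p_value)


def pairwise_logrank(records: pd.DataFrame) -> pd.DataFrame:
    """Log-rank tests for every pair of groups in a survival-record table."""
    groups = list(dict.fromkeys(records["group"]))
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            stat, p = logrank_test(records[records["group"] == a],
                                   records[records["group"] == b])
            rows.append({"group_a": a, "group_b": b,
                         "statistic": stat, "df": 1, "p": p})
    return pd.DataFrame(rows)
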