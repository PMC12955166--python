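"""Time-to-delivery comparison between predicted risk groups.

Kaplan–Meier curves of ongoing pregnancy versus gestational age at
delivery, a log-rank test between the high- and low-risk groups, and the
difference in median delivery GA.  Deliveries are all observed by default
(no censoring), in which case the product-limit estimator reduces to one
minus the empirical CDF of delivery times; a censoring flag is retained
for generality.  Estimation is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = ["KMCurve", "km_estimate", "log_rank", "median_delivery_gap", "risk_group_survival"]


@dataclass(frozen=True)
class KMCurve:
    """A fitted survival step function over distinct event weeks."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(group=self.group, time=self.times, survival=self.survival,
                 at_risk=self.at_risk)
        )


def km_estimate(event_times, censored=None, group: str = "") -> KMCurve:
    """Product-limit estimate of P(still pregnant) at each event week."""
    t = np.asarray(event_times, dtype=float)
    if t.size == 0:
        raise ValueError("no events in group")
    observed = (
        np.ones_like(t, dtype=bool)
        if censored is None
        else ~np.asarray(censored, dtype=bool)
    )
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=observed)
    distinct = np.unique(t)
    surv = kmf.survival_function_at_times(distinct).to_numpy(dtype=float)
    event_table = kmf.event_table
    at_risk = event_table["at_risk"].reindex(distinct).to_numpy(dtype=float)
    return KMCurve(group, distinct, surv, at_risk)


def log_rank(times_a, times_b, censored_a=None, censored_b=None) -> tuple[float, float]:
    """Log-rank chi-square statistic (1 df) and p-value between two groups."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups need at least one event")
    oa = np.ones_like(ta) if censored_a is None else ~np.asarray(censored_a, bool)
    ob = np.ones_like(tb) if censored_b is None else ~np.asarray(censored_b, bool)
    res = logrank_test(ta, tb, event_observed_A=oa, event_observed_B=ob)
    return float(res.test_statistic), float(res.p_value)


def median_delivery_gap(survival_input: pd.DataFrame) -> float:
    """Low-risk median delivery GA minus high-risk median, in weeks."""
    med = survival_input.groupby("risk_group")["ga_delivery_wk"].median()
    if "high" not in med.index or "low" not in med.index:
        raise ValueError("both risk groups required")
    return float(med["low"] - med["high"])


def risk_group_survival(
    samples: pd.DataFrame,
    participants: pd.DataFrame,
    threshold_model,
    score_column: str = "panel_score",
    ga_max: float = 24.0,
) -> pd.DataFrame:
    """One survival record per participant, classified by the earliest
    qualifying draw (GA at sampling <= ``ga_max``).

    Returns a frame with participant_id, ga_delivery_wk and risk_group;
    participants with no qualifying draw are omitted.
    """
    from .risk_scoring import apply_threshold

    early = samples[samples["ga_sample_wk"] <= ga_max]
    if early.empty:
        raise ValueError("no samples within the qualifying GA window")
    first = early.sort_values("ga_sample_wk").groupby("participant_id").first()
    risk = apply_threshold(first[score_column].to_numpy(dtype=float), threshold_model)
    out = participants.set_index("participant_id").loc[first.index, ["ga_delivery_wk", "group"]]
    out = out.reset_index()
    out["risk_group"] = risk
    return out
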