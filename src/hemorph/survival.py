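"""Kaplan-Meier estimation and the two-group log-rank test.

Patients within a subtype are compared by treatment intensity
(more-intensive vs less-intensive regimes). The survival function is the
product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i) over
distinct event times t_i with d_i deaths among n_i at risk; censored
patients leave the risk set after their censoring time (deaths counted
before censorings on ties). The log-rank statistic accumulates observed
minus expected deaths in group A across event times, with the
hypergeometric variance, and is referred to chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "SurvivalCurve",
    "kaplan_meier",
    "logrank_test",
    "records_to_frame",
    "frame_to_records",
]

MORE_INTENSIVE = "more-intensive"
LESS_INTENSIVE = "less-intensive"


@dataclass
class SurvivalRecord:
    """One patient's time-to-event outcome."""

    patient_id: str
    time: float  # months
    event: int  # 1 = death observed, 0 = censored
    group: str = ""  # treatment intensity
    subtype: int = 0

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class SurvivalCurve:
    """Stepwise product-limit estimate over distinct event times."""

    times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n_i at each event time
    deaths: np.ndarray  # d_i at each event time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival must be nonincreasing")

    def evaluate(self, t: float) -> float:
        """S(t); S(0) = 1."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def _arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def kaplan_meier(records: list[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit survival estimate."""
    if not records:
        raise ValueError("need at least one record")
    t, e = _arrays(records)
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    deaths = []
    s = 1.0
    for ti in event_times:
        n_i = int((t >= ti).sum())  # censored at ti still at risk (deaths first)
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        deaths.append(d_i)
    return SurvivalCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        deaths=np.array(deaths, dtype=int),
    )


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns (statistic, p). statistic = (sum_i (O_ai - E_ai))^2 / sum_i V_i
    over distinct pooled event times, with hypergeometric variance
    V_i = d_i (n_ai/n_i) (1 - n_ai/n_i) (n_i - d_i) / (n_i - 1).
    Zero total variance (e.g. all events at times with a single patient at
    risk, or one group empty of risk overlap) yields (0, 1).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event overall")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    event_times = np.unique(t[e == 1])

    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        n_a = int((ta >= ti).sum())
        n_b = int((tb >= ti).sum())
        n = n_a + n_b
        d_a = int(((ta == ti) & (ea == 1)).sum())
        d_b = int(((tb == ti) & (eb == 1)).sum())
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
            "treatment_group": [r.group for r in records],
            "subtype": [r.subtype for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(
            patient_id=str(row.patient_id),
            time=float(row.time_months),
            event=int(row.event),
            group=str(getattr(row, "treatment_group", "")),
            subtype=int(getattr(row, "subtype", 0)),
        )
        for row in df.itertuples(index=False)
    ]
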