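"""Median-split survival analysis and hazard-ratio pooling.

Patients are split at the median of the marker's expression (ties go to the
low group), compared by the log-rank test, and the per-cohort hazard ratio
is the log-rank (O-E)/V estimator — not a Cox fit — pooled on the log scale
by inverse variance with an optional DerSimonian–Laird random-effects
component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import Z95


@dataclass(frozen=True)
class HRRecord:
    """Log-rank-derived hazard ratio (high vs low) for one cohort."""

    cohort_id: str
    log_hr: float
    se: float
    ci_low: float
    ci_high: float
    O_high: float
    E_high: float
    V: float
    p: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))


def median_split(table: pd.DataFrame, expression_col: str = "expression") -> pd.DataFrame:
    """Label patients 'high'/'low' by the median of expression.

    Values strictly above the median go high; values at or below the median
    (including exact ties) go low.  Requires >= 4 patients and a non-constant
    expression column.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 patients to split")
    expr = table[expression_col].to_numpy(dtype=float)
    med = np.median(expr)
    if np.all(expr == expr[0]):
        raise ValueError("expression is constant; no median split exists")
    out = table.copy()
    out["group"] = np.where(expr > med, "high", "low")
    return out


def km_curve(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimator.

    Returns a step table with columns time, n_at_risk, n_events, survival.
    Censored observations at an event time leave the risk set after the
    events at that time are counted (events processed first).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival table")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n_at_risk = t.size
    for time in np.unique(t):
        at_this = t == time
        d = int(e[at_this].sum())
        c = int(at_this.sum()) - d
        if d > 0:
            s *= 1.0 - d / n_at_risk
            rows.append({"time": time, "n_at_risk": n_at_risk, "n_events": d, "survival": s})
        n_at_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_hr(table: pd.DataFrame, cohort_id: str = "") -> HRRecord:
    """Log-rank test and the (O-E)/V hazard-ratio estimate, high vs low.

    At each distinct event time the observed high-group events are compared
    with the hypergeometric expectation; the sums give
    log HR = (O-E)/V, se = 1/sqrt(V), chi-square = (O-E)^2/V on 1 df.
    """
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    hi = (table["group"].to_numpy() == "high").astype(int)
    if e[hi == 1].sum() < 1 or e[hi == 0].sum() < 1:
        raise ValueError("both groups need at least one event")
    O = E = V = 0.0
    for time in np.unique(t[e == 1]):
        at_risk = t >= time
        n = int(at_risk.sum())
        n1 = int((at_risk & (hi == 1)).sum())
        dead = (t == time) & (e == 1)
        d = int(dead.sum())
        d1 = int((dead & (hi == 1)).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        raise ValueError("log-rank variance is zero; no information")
    log_hr = (O - E) / V
    se = 1.0 / np.sqrt(V)
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return HRRecord(
        cohort_id, float(log_hr), float(se),
        float(np.exp(log_hr - Z95 * se)), float(np.exp(log_hr + Z95 * se)),
        O, E, V, p,
    )


def pool_hr(
    records: Sequence[HRRecord], *, model: str = "dl"
) -> dict[str, float]:
    """Inverse-variance pooling of log hazard ratios.

    Returns a dict with the pooled HR, its CI, tau^2 and k.  ``model`` picks
    the headline estimate ('dl' random effects, 'fixed' inverse variance);
    both variants are always computed.
    """
    if len(records) == 0:
        raise ValueError("cannot pool an empty set of hazard ratios")
    y = np.array([r.log_hr for r in records], dtype=float)
    v = np.array([r.se**2 for r in records], dtype=float)
    k = y.size
    w = 1.0 / v
    yf = float((w * y).sum() / w.sum())
    se_f = float(1.0 / np.sqrt(w.sum()))
    Q = float((w * (y - yf) ** 2).sum())
    if k > 1 and model == "dl":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    ws = 1.0 / (v + tau2)
    yr = float((ws * y).sum() / ws.sum())
    se_r = float(1.0 / np.sqrt(ws.sum()))
    y_hat, se_hat = (yr, se_r) if model == "dl" else (yf, se_f)
    return {
        "hr": float(np.exp(y_hat)),
        "ci_low": float(np.exp(y_hat - Z95 * se_hat)),
        "ci_high": float(np.exp(y_hat + Z95 * se_hat)),
        "log_hr": y_hat,
        "se": se_hat,
        "hr_fixed": float(np.exp(yf)),
        "tau2": tau2,
        "Q": Q,
        "k": int(k),
    }
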