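"""Kaplan-Meier estimation and the k-group log-rank (Mantel-Cox) test.

Ties between an event and a censoring at the same time follow the standard
convention: the event happens first, so the censored subject is still at
risk for it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray      # ordered distinct times with >= 1 event
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # n at risk just before each event time
    n_events: np.ndarray   # events at each time

    def at(self, t: float) -> float:
        """S(t); S(0) = 1 and the curve is right-continuous."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.n_events,
        })


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    group_ns: tuple[int, ...]


def _as_arrays(durations, events) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events)
    if d.ndim != 1 or d.shape != e.shape:
        raise ValueError("durations and events must be matched 1-d arrays")
    if d.size == 0:
        raise ValueError("empty survival input")
    if np.any(d < 0) or not np.isfinite(d).all():
        raise ValueError("durations must be finite and nonnegative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (event)")
    return d, e.astype(int)


def km_estimate(durations, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i / n_i)."""
    d, e = _as_arrays(durations, events)
    ev_times = np.unique(d[e == 1])
    if ev_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([], dtype=int), np.array([], dtype=int))
    d_sorted = np.sort(d)
    n_at_risk = d.size - np.searchsorted(d_sorted, ev_times, side="left")
    n_events = np.array([int(np.sum((d == t) & (e == 1))) for t in ev_times])
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(ev_times, surv, n_at_risk.astype(int), n_events)


def logrank_test(groups: Sequence[tuple]) -> LogrankResult:
    """Global log-rank test over k groups of (durations, events) pairs.

    Sums observed-minus-expected events over the pooled distinct event
    times with the hypergeometric variance (multiplicity-corrected); the
    statistic is z' V^{-1} z on the first k-1 groups, chi-square with
    k-1 degrees of freedom under the null.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    durs, evs = [], []
    for g in groups:
        d, e = _as_arrays(*g)
        durs.append(d)
        evs.append(e)
    k = len(groups)
    all_d = np.concatenate(durs)
    all_e = np.concatenate(evs)
    ev_times = np.unique(all_d[all_e == 1])
    if ev_times.size == 0:
        raise ValueError("no events in any group; log-rank undefined")

    T = ev_times.size
    n_g = np.empty((T, k))
    d_g = np.empty((T, k))
    for j in range(k):
        sd = np.sort(durs[j])
        n_g[:, j] = durs[j].size - np.searchsorted(sd, ev_times, side="left")
        ev_d = np.sort(durs[j][evs[j] == 1])
        d_g[:, j] = (np.searchsorted(ev_d, ev_times, side="right")
                     - np.searchsorted(ev_d, ev_times, side="left"))
    n_tot = n_g.sum(axis=1)
    d_tot = d_g.sum(axis=1)
    expected = n_g * (d_tot / n_tot)[:, None]
    z = (d_g - expected).sum(axis=0)[: k - 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    p_g = n_g / n_tot[:, None]                       # T x k
    V = -np.einsum("t,tg,th->gh", mult, p_g, p_g)
    V[np.diag_indices(k)] += mult @ p_g
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, p=p, group_ns=tuple(len(d) for d in durs))


def logrank_test_labels(durations, events, labels) -> LogrankResult:
    """Log-rank test with group membership given as a label array."""
    d, e = _as_arrays(durations, events)
    lab = np.asarray(labels)
    if lab.shape != d.shape:
        raise ValueError("labels must match durations")
    groups = [(d[lab == u], e[lab == u]) for u in np.unique(lab)]
    return logrank_test(groups)
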