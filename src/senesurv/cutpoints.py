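"""Optimal survival cutpoints by maximally selected log-rank statistics.

Two-tier search: every midpoint between consecutive distinct scores whose
split leaves both groups at least ``min_group_frac`` of the cohort is a
candidate; the selected cutoff minimizes the two-group log-rank p-value.
Three-tier search: exhaustive enumeration of ordered candidate pairs
(c1 < c2), objective the global three-group log-rank (df = 2), yielding
low / moderate / excessive tiers.

The minimum p over a search grid is selection-biased (anti-conservative),
so a permutation family-wise p-value that reruns the full search on
shuffled score-survival pairings is provided alongside the raw one.

Implementation note: because the candidate family is nested along the
score order, observed-minus-expected sums are prefix sums of per-subject
log-rank scores (martingale residuals), and at-risk counts per candidate
are prefix sums over the score-sorted at-risk indicator matrix. One such
scan costs O(T x n) for T distinct event times, which makes exhaustive
pair search and permutation re-runs cheap. Equality with brute-force
enumeration via the plain log-rank test is asserted in the test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .config import TIER_NAMES_2, TIER_NAMES_3

_NEG_INF = -np.inf


@dataclass
class CutpointResult:
    """Outcome of one cutpoint search on a score / survival pairing."""

    name: Optional[str]
    k_tiers: int
    cutoffs: tuple[float, ...]
    chi2: float
    df: int
    p_raw: float
    group_sizes: tuple[int, ...]
    min_group_frac: float
    tiers: np.ndarray = field(repr=False)       # per-subject tier labels
    p_adjusted: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "k_tiers": int(self.k_tiers),
            "cutoffs": [float(c) for c in self.cutoffs],
            "chi2": float(self.chi2),
            "df": int(self.df),
            "p_raw": float(self.p_raw),
            "p_adjusted": None if self.p_adjusted is None else float(self.p_adjusted),
            "group_sizes": [int(g) for g in self.group_sizes],
            "min_group_frac": float(self.min_group_frac),
        }


def candidate_cutoffs(scores, min_group_frac: float = 0.10) -> np.ndarray:
    """Midpoints between consecutive distinct scores with balanced splits.

    Only candidates leaving at least ``ceil(min_group_frac * n)`` subjects
    on each side survive. All-identical scores admit no candidate and
    raise.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 scores")
    change = np.nonzero(np.diff(s) > 0)[0]
    if change.size == 0:
        raise ValueError("all scores identical; no candidate cutoffs")
    g = math.ceil(min_group_frac * n)
    m = change + 1          # subjects at or below each boundary
    ok = (m >= g) & (n - m >= g)
    return ((s[change] + s[change + 1]) / 2.0)[ok]


def assign_tiers(scores, cutoffs) -> np.ndarray:
    """Tier labels from ordered cutoffs; boundaries belong to the lower tier.

    One cutoff -> low / high; two cutoffs -> low / moderate / excessive.
    """
    cuts = tuple(float(c) for c in np.atleast_1d(cutoffs))
    if len(cuts) not in (1, 2):
        raise ValueError("expected 1 or 2 cutoffs")
    if len(cuts) == 2 and not cuts[0] < cuts[1]:
        raise ValueError("cutoffs must be strictly increasing")
    s = np.asarray(scores, dtype=float)
    if len(cuts) == 1:
        return np.where(s <= cuts[0], TIER_NAMES_2[0], TIER_NAMES_2[1])
    out = np.full(s.shape, TIER_NAMES_3[2], dtype=object)
    out[s <= cuts[1]] = TIER_NAMES_3[1]
    out[s <= cuts[0]] = TIER_NAMES_3[0]
    return out.astype(str)


class _SplitScan:
    """Shared precomputation for maximally selected log-rank scans.

    Holds everything that depends only on the score multiset and the
    survival data as separate objects, so permutations of their pairing
    re-use the per-time quantities.
    """

    def __init__(self, scores, durations, events, min_group_frac: float):
        self.scores = np.asarray(scores, dtype=float)
        self.durations = np.asarray(durations, dtype=float)
        self.events = np.asarray(events, dtype=int)
        n = self.scores.size
        if not (n == self.durations.size == self.events.size):
            raise ValueError("scores and survival records must be matched")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if self.events.sum() == 0:
            raise ValueError("no events; cutpoint search undefined")
        self.n = n
        self.min_group_frac = min_group_frac
        self.g_min = math.ceil(min_group_frac * n)

        self.order = np.argsort(self.scores, kind="mergesort")
        s = self.scores[self.order]
        change = np.nonzero(np.diff(s) > 0)[0]
        if change.size == 0:
            raise ValueError("all scores identical; no candidate cutoffs")
        self.m = change + 1                                   # prefix sizes per boundary
        self.cutvals = (s[change] + s[change + 1]) / 2.0      # candidate cutoffs
        self.feasible2 = (self.m >= self.g_min) & (n - self.m >= self.g_min)

        # per-event-time quantities
        self.ev_times = np.unique(self.durations[self.events == 1])
        tms = self.ev_times
        sd = np.sort(self.durations)
        self.n_at_risk = n - np.searchsorted(sd, tms, side="left")
        ev_d = np.sort(self.durations[self.events == 1])
        self.d_tot = (np.searchsorted(ev_d, tms, side="right")
                      - np.searchsorted(ev_d, tms, side="left")).astype(float)
        nt = self.n_at_risk.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.w = np.where(nt > 1, self.d_tot * (nt - self.d_tot) / (nt - 1), 0.0)
        # per-subject log-rank scores: delta_j - Lambda(t_j)
        cumhaz = np.concatenate([[0.0], np.cumsum(self.d_tot / nt)])
        idx = np.searchsorted(tms, self.durations, side="right")
        self.lscore = self.events - cumhaz[idx]
        self.w_over_n = self.w / nt
        self.w_over_n2 = self.w / nt**2
        # at-risk indicator, times x subjects
        self.risk_mat = (self.durations[None, :] >= tms[:, None]).astype(float)

    def _prefix(self, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Prefix at-risk matrix A (T x K) and prefix O-E vector U (K,)."""
        A = np.cumsum(self.risk_mat[:, cols], axis=1)[:, self.m - 1]
        U = np.cumsum(self.lscore[cols])[self.m - 1]
        return A, U

    def scan2(self, perm: Optional[np.ndarray] = None) -> np.ndarray:
        """chi2 of the 2-group log-rank at every candidate (-inf infeasible)."""
        cols = self.order if perm is None else perm[self.order]
        A, U = self._prefix(cols)
        V = self.w_over_n @ A - self.w_over_n2 @ (A * A)
        chi2 = np.full(self.cutvals.size, _NEG_INF)
        ok = self.feasible2 & (V > 1e-12)
        chi2[ok] = U[ok] ** 2 / V[ok]
        return chi2

    def scan3(self, perm: Optional[np.ndarray] = None) -> np.ndarray:
        """chi2 of the 3-group log-rank for every ordered candidate pair.

        Entry [i, j] (i < j) is the statistic for cutoffs
        (cutvals[i], cutvals[j]); infeasible or degenerate pairs are -inf.
        """
        cols = self.order if perm is None else perm[self.order]
        A, U = self._prefix(cols)
        P = self.w_over_n @ A
        Q = A.T @ (self.w_over_n2[:, None] * A)
        dQ = np.diag(Q)
        U1 = U[:, None]
        U2 = U[None, :] - U[:, None]
        V11 = (P - dQ)[:, None]
        V22 = (P[None, :] - P[:, None]) - (dQ[None, :] - 2.0 * Q + dQ[:, None])
        V12 = -(Q - dQ[:, None])
        det = V11 * V22 - V12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = (U1**2 * V22 - 2.0 * U1 * U2 * V12 + U2**2 * V11) / det
        m = self.m
        sizes_ok = (
            (m[:, None] >= self.g_min)
            & ((m[None, :] - m[:, None]) >= self.g_min)
            & ((self.n - m[None, :]) >= self.g_min)
        )
        ok = sizes_ok & (det > 1e-12) & (V11 > 1e-12)
        return np.where(ok, chi2, _NEG_INF)

    def group_sizes3(self, i: int, j: int) -> tuple[int, int, int]:
        return (int(self.m[i]), int(self.m[j] - self.m[i]), int(self.n - self.m[j]))


def find_cutpoint_2tier(scores, durations, events,
                        min_group_frac: float = 0.10,
                        name: Optional[str] = None) -> CutpointResult:
    """Most significant two-group log-rank split over all candidate cutoffs.

    Ties in significance resolve to the smaller cutoff. The reported
    ``p_raw`` is a minimum over the search grid and therefore
    selection-biased; use :func:`permutation_adjusted_p` for a calibrated
    family-wise p-value.
    """
    scan = _SplitScan(scores, durations, events, min_group_frac)
    chi2 = scan.scan2()
    if not np.any(np.isfinite(chi2)):
        raise ValueError("no feasible candidate cutoff")
    best = int(np.argmax(chi2))     # first max = smallest cutoff on ties
    cut = float(scan.cutvals[best])
    tiers = assign_tiers(scan.scores, (cut,))
    stat = float(chi2[best])
    return CutpointResult(
        name=name, k_tiers=2, cutoffs=(cut,), chi2=stat, df=1,
        p_raw=float(stats.chi2.sf(stat, 1)),
        group_sizes=(int(scan.m[best]), int(scan.n - scan.m[best])),
        min_group_frac=min_group_frac, tiers=tiers,
    )


def find_cutpoints_3tier(scores, durations, events,
                         min_group_frac: float = 0.10,
                         name: Optional[str] = None) -> CutpointResult:
    """Most significant three-tier split over all feasible cutoff pairs.

    Objective is the global 3-group log-rank statistic (df = 2). Ties
    resolve to the pair with the largest smallest group, then the smaller
    lower cutoff, then the smaller upper cutoff.
    """
    scan = _SplitScan(scores, durations, events, min_group_frac)
    chi2 = scan.scan3()
    best = float(np.max(chi2))
    if not np.isfinite(best):
        raise ValueError("no feasible cutoff pair for a three-tier split")
    cand = np.argwhere(chi2 == best)

    def _tiebreak(ij) -> tuple:
        a, b = int(ij[0]), int(ij[1])
        return (-min(scan.group_sizes3(a, b)), scan.cutvals[a], scan.cutvals[b])

    i, j = (int(v) for v in min(cand, key=_tiebreak))
    cuts = (float(scan.cutvals[i]), float(scan.cutvals[j]))
    tiers = assign_tiers(scan.scores, cuts)
    return CutpointResult(
        name=name, k_tiers=3, cutoffs=cuts, chi2=best, df=2,
        p_raw=float(stats.chi2.sf(best, 2)),
        group_sizes=scan.group_sizes3(i, j),
        min_group_frac=min_group_frac, tiers=tiers,
    )


def permutation_adjusted_p(scores, durations, events,
                           k_tiers: int = 2,
                           B: int = 199,
                           seed: int = 0,
                           min_group_frac: float = 0.10) -> float:
    """Family-wise p-value of the selected split by permutation.

    Shuffles the pairing of survival records against scores ``B`` times,
    reruns the full cutpoint search each time, and reports
    ``(1 + #{permuted min-p <= observed min-p}) / (B + 1)`` — exact under
    the null of no score-survival association.
    """
    if B < 100:
        raise ValueError("need at least B = 100 permutations")
    if k_tiers not in (2, 3):
        raise ValueError("k_tiers must be 2 or 3")
    scan = _SplitScan(scores, durations, events, min_group_frac)
    scan_fn = scan.scan2 if k_tiers == 2 else scan.scan3
    observed = float(np.max(scan_fn()))
    if not np.isfinite(observed):
        raise ValueError("no feasible split on the observed data")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(scan.n)
        if np.max(scan_fn(perm)) >= observed:
            hits += 1
    return (1 + hits) / (B + 1)
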