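"""Kaplan-Meier estimation, log-rank testing, and the iterative percentile
cutpoint scan used to stratify cohorts by an expression score.

The scan asks, for every percentile threshold of a per-sample score from the
10th to the 90th: does splitting the cohort at that threshold separate
progression-free survival? Each split is tested with a standard two-group
log-rank statistic; splits producing duplicate sample partitions or arms
with too few events are skipped; Benjamini-Hochberg correction is applied
across the considered splits and the partition with the lowest raw p is
retained. A PFI ratio below 1 (restricted mean survival time of the
high-score arm over the low-score arm) means high scorers progress earlier.

Everything here is deterministic: same inputs, same retained partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimator",
    "logrank_test",
    "bh_adjust",
    "iterative_cutpoint_scan",
    "CutpointScan",
    "pfi_ratio",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate with restricted mean survival time.

    ``times`` are the distinct event times (ascending); ``survival`` the
    estimate just after each time (non-increasing from S(0)=1);
    ``n_at_risk`` the at-risk count just before each time. ``rmst`` is the
    area under the step curve up to ``horizon``.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    horizon: float
    rmst: float
    n: int = 0

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimator(time, event, horizon: float | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimate and its restricted mean.

    ``time`` >= 0 with ``event`` 1 for observed events, 0 for censoring.
    RMST integrates the step function from 0 to ``horizon`` (default: the
    maximum observed time).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival table")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and >= 0")
    if horizon is None:
        horizon = float(t.max())

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    surv, at_risk = [], []
    s = 1.0
    for et in ev_times:
        r = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
    surv = np.asarray(surv)
    at_risk = np.asarray(at_risk, dtype=int)

    # step-function area on [0, horizon]
    edges = np.concatenate([[0.0], np.clip(ev_times, 0.0, horizon), [horizon]])
    heights = np.concatenate([[1.0], surv])
    rmst = float(np.sum(np.maximum(np.diff(edges), 0.0) * heights))
    return KMCurve(ev_times, surv, at_risk, float(horizon), rmst, n=n)


def logrank_test(time_a, event_a, time_b, event_b) -> dict:
    """Two-group log-rank test (observed minus expected, 1 df chi-square).

    At each distinct event time the number of events in group A is compared
    with its hypergeometric expectation given the at-risk sets; the summed
    discrepancy over its variance is chi-square(1) under the null of equal
    hazards. Zero total events returns chi2=0, p=1 with ``degenerate=True``.
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")

    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    ev_times = np.unique(t[e == 1])
    if len(ev_times) == 0:
        return dict(chi2=0.0, p=1.0, degenerate=True)

    o_minus_e = 0.0
    var = 0.0
    for et in ev_times:
        at = t >= et
        n_tot = int(at.sum())
        n_a = int((at & grp_a).sum())
        dead = (t == et) & (e == 1)
        d_tot = int(dead.sum())
        d_a = int((dead & grp_a).sum())
        frac = n_a / n_tot
        o_minus_e += d_a - d_tot * frac
        if n_tot > 1:
            var += d_tot * frac * (1.0 - frac) * (n_tot - d_tot) / (n_tot - 1)
    if var <= 0:
        return dict(chi2=0.0, p=1.0, degenerate=True)
    chi2 = o_minus_e * o_minus_e / var
    return dict(chi2=float(chi2), p=float(stats.chi2.sf(chi2, 1)), degenerate=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _nearest_rank(sorted_scores: np.ndarray, pct: int) -> float:
    """Nearest-rank percentile (deterministic, no interpolation)."""
    n = len(sorted_scores)
    k = max(1, int(np.ceil(pct / 100.0 * n)))
    return float(sorted_scores[k - 1])


@dataclass
class CutpointScan:
    """Full record of an iterative percentile log-rank scan.

    ``table`` has one row per candidate percentile (threshold, group sizes,
    events per arm, chi2, p_raw, considered flag, BH q over considered rows).
    ``best`` is the considered row with the lowest raw p (ties: smallest
    percentile); None when no partition passed the filters (``empty`` set).
    """

    table: pd.DataFrame
    best: pd.Series | None = None
    empty: bool = field(default=False)


def iterative_cutpoint_scan(
    scores,
    time,
    event,
    p_min: int = 10,
    p_max: int = 90,
    min_events: int = 10,
    both_arms: bool = True,
) -> CutpointScan:
    """Scan percentile splits of a score for survival separation.

    For each percentile threshold p in [p_min, p_max] (1-percentile steps,
    nearest-rank), the high arm is samples with score strictly above the
    threshold. A split is considered only if its sample partition is new
    (identical memberships are tested once) and its arms carry enough
    events: with ``both_arms=True`` (default) both arms need >= min_events;
    ``both_arms=False`` restores the looser reading (at least one arm does).
    BH correction runs across the considered splits; the lowest raw p wins.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, time and event must align")
    order = np.sort(s)
    seen: set[bytes] = set()
    rows = []
    for pct in range(p_min, p_max + 1):
        thr = _nearest_rank(order, pct)
        high = s > thr
        n_high = int(high.sum())
        n_low = len(s) - n_high
        ev_high = int(e[high].sum())
        ev_low = int(e[~high].sum())
        key = np.packbits(high).tobytes()
        duplicate = key in seen
        if both_arms:
            enough = ev_high >= min_events and ev_low >= min_events
        else:
            enough = ev_high >= min_events or ev_low >= min_events
        considered = (not duplicate) and enough and 0 < n_high < len(s)
        chi2 = p_raw = np.nan
        if considered:
            seen.add(key)
            res = logrank_test(t[high], e[high], t[~high], e[~high])
            chi2, p_raw = res["chi2"], res["p"]
        elif not duplicate:
            seen.add(key)
        rows.append(dict(percentile=pct, threshold=thr, n_high=n_high,
                         n_low=n_low, events_high=ev_high, events_low=ev_low,
                         chi2=chi2, p_raw=p_raw, considered=considered,
                         duplicate=duplicate))
    table = pd.DataFrame(rows)
    mask = table["considered"].to_numpy()
    table["q"] = np.nan
    if mask.any():
        table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p_raw"].to_numpy())
        cons = table[mask]
        best = cons.sort_values(["p_raw", "percentile"], kind="mergesort").iloc[0]
        return CutpointScan(table, best=best, empty=False)
    return CutpointScan(table, best=None, empty=True)


def pfi_ratio(high: KMCurve, low: KMCurve) -> dict:
    """Ratio of restricted mean survival times, high over low.

    Both curves must share the restriction horizon. A ratio below 1 means
    the high-score arm progresses earlier. A zero low-arm RMST is undefined
    and flagged instead of raising.
    """
    if not np.isclose(high.horizon, low.horizon):
        raise ValueError("curves must share a common horizon")
    if low.rmst == 0:
        return dict(ratio=np.nan, undefined=True,
                    rmst_high=high.rmst, rmst_low=low.rmst)
    return dict(ratio=high.rmst / low.rmst, undefined=False,
                rmst_high=high.rmst, rmst_low=low.rmst)
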