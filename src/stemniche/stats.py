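"""Biomarker statistics: Mann-Whitney, ROC-AUC, log-rank, two-group hazard
ratio, and maximally selected rank cutpoints."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U of the first group with a two-sided p.

    Exact (full enumeration, tie-safe) when both groups have at most 8
    values; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group must be non-empty")
    u = _u_statistic(a, b)
    if len(a) <= 8 and len(b) <= 8:
        p = _exact_p(a, b, u)
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return u, p


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: #(a > b) + 0.5 #(a == b) over all pairs."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    pooled = np.concatenate([a, b])
    n1 = len(a)
    mean_u = len(a) * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = comb(len(pooled), n1)
    hits = 0
    idx = np.arange(len(pooled))
    for chosen in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def roc_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the rank/U formula."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return _u_statistic(pos, neg) / (len(pos) * len(neg))


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed: tuple      # (O1, O2)
    expected: tuple      # (E1, E2)
    variance: float


def _oe_table(time1, event1, time2, event2) -> LogrankResult:
    t1 = np.asarray(time1, dtype=float)
    t2 = np.asarray(time2, dtype=float)
    e1 = np.asarray(event1, dtype=int)
    e2 = np.asarray(event2, dtype=int)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o1 = float(e1.sum())
    o2 = float(e2.sum())
    exp1 = exp2 = var = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        n = n1 + n2
        d = float(((t1 == t) & (e1 == 1)).sum() + ((t2 == t) & (e2 == 1)).sum())
        if n == 0:
            continue
        exp1 += d * n1 / n
        exp2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValueError("log-rank variance is zero")
    chi2 = (o1 - exp1) ** 2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return LogrankResult(
        chi2=float(chi2), p=p, observed=(o1, o2), expected=(exp1, exp2), variance=float(var)
    )


def logrank(time1, event1, time2, event2) -> LogrankResult:
    """Two-group log-rank test by O-E accumulation over event times."""
    res = _oe_table(time1, event1, time2, event2)
    if res.observed[0] < 1 or res.observed[1] < 1:
        raise ValueError("both groups need at least 1 event")
    return res


def hazard_ratio(time1, event1, time2, event2, conf: float = 0.95) -> dict:
    """Pike estimator HR = (O1/E1)/(O2/E2) with a log-scale CI using the
    log-rank variance: se(log HR) ~ 1/sqrt(V)."""
    res = _oe_table(time1, event1, time2, event2)
    o1, o2 = res.observed
    e1, e2 = res.expected
    if e1 == 0 or e2 == 0:
        raise ValueError("expected event count is zero")
    hr = (o1 / e1) / (o2 / e2)
    z = sps.norm.ppf(0.5 + conf / 2.0)
    se = 1.0 / np.sqrt(res.variance)
    return {
        "hr": float(hr),
        "ci_low": float(np.exp(np.log(hr) - z * se)),
        "ci_high": float(np.exp(np.log(hr) + z * se)),
        "logrank": res,
    }


def maxstat_cutoff(
    table: pd.DataFrame,
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> tuple[float, float]:
    """Maximally selected rank cutpoint for a survival biomarker.

    Evaluates the standardized log-rank statistic z = (O1 - E1)/sqrt(V) at
    every candidate cut between the ``q_low`` and ``q_high`` biomarker
    quantiles and returns (cutoff, max |z|). The downstream Kaplan-Meier
    log-rank p at this cutoff is NOT adjusted for the cutpoint selection;
    treat it as descriptive.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 subjects")
    if table["event"].sum() < 5:
        raise ValueError("need at least 5 events")
    x = table["biomarker"].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("biomarker is constant")
    lo, hi = np.quantile(x, [q_low, q_high])
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    best_cut, best_stat = None, -np.inf
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    for c in candidates:
        high = x > c
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        try:
            res = _oe_table(time[high], event[high], time[~high], event[~high])
        except ValueError:
            continue
        z = abs(res.observed[0] - res.expected[0]) / np.sqrt(res.variance)
        if z > best_stat:
            best_stat, best_cut = z, float(c)
    if best_cut is None:
        raise ValueError("no valid cutpoint in the quantile window")
    return best_cut, float(best_stat)
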