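"""Kaplan-Meier estimation and log-rank comparison of survival between
extreme-PRS strata.

Samples are split at the empirical 10% and 90% score quantiles into
low / middle / high genetic-risk groups; by default only the two
extreme groups enter the log-rank test. The log-rank statistic is
computed directly (pooled-tie hypergeometric variance) so per-group
observed and expected event counts are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats as sps

__all__ = [
    "KMCurve",
    "LogrankResult",
    "stratify_by_prs_quantiles",
    "km_estimate",
    "logrank_test",
]


def stratify_by_prs_quantiles(
    scores, q_low: float = 0.10, q_high: float = 0.90
) -> np.ndarray:
    """Label samples low / middle / high by empirical score quantiles.

    Quantiles are linear-interpolation order statistics (NumPy's
    default, "type 7"). Low means score <= the q_low quantile, high
    means score >= the q_high quantile.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 10:
        raise ValueError("need at least 10 samples to stratify by deciles")
    if not (0 < q_low < q_high < 1):
        raise ValueError("require 0 < q_low < q_high < 1")
    lo = np.quantile(scores, q_low)
    hi = np.quantile(scores, q_high)
    if lo == hi:
        raise ValueError("degenerate quantiles (scores tied); cannot stratify")
    labels = np.full(scores.shape, "middle", dtype=object)
    labels[scores <= lo] = "low"
    labels[scores >= hi] = "high"
    return labels


@dataclass
class KMCurve:
    event_times: np.ndarray  # sorted distinct times with >= 1 event
    survival_probs: np.ndarray  # product-limit S(t) at those times
    at_risk: np.ndarray  # risk-set size just before each time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise ValueError("survival probabilities must be nonincreasing")
        if self.survival_probs.size and self.survival_probs[0] > 1.0 + 1e-12:
            raise ValueError("survival probability above 1")


def km_estimate(times, event_flags) -> KMCurve:
    """Product-limit estimator ``S(t) = prod_{t_i <= t} (1 - d_i/n_i)``.

    Censored-only times do not appear in the curve (they only shrink the
    risk set). Samples with unknown vital status must be removed before
    calling.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    with_events = tab[tab["observed"] > 0]
    event_times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(
        event_times=event_times,
        survival_probs=surv,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float
    n_groups: int
    observed: dict
    expected: dict

    def __post_init__(self) -> None:
        if self.chi2 < -1e-12:
            raise ValueError("negative chi-square")
        if not 0 < self.p <= 1:
            raise ValueError("p outside (0, 1]")
        if abs(sum(self.observed.values()) - sum(self.expected.values())) > 1e-8:
            raise ValueError("total expected events != total observed events")


def logrank_test(times, event_flags, group_labels, groups=None) -> LogrankResult:
    """K-sample log-rank test with pooled-tie hypergeometric variance.

    ``groups`` restricts the comparison (default: all labels present);
    the pipeline passes ("low", "high") to compare the extreme PRS
    strata only. Chi-square has ``len(groups) - 1`` degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    labels = np.asarray(group_labels, dtype=object)
    if groups is None:
        groups = sorted(set(labels.tolist()))
    else:
        groups = list(groups)
    keep = np.isin(labels, groups)
    times, events, labels = times[keep], events[keep], labels[keep]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if not np.any(labels == g):
            raise ValueError(f"group {g!r} is empty")
    if not events.any():
        raise ValueError("no events observed; log-rank undefined")

    k = len(groups)
    gidx = np.array([groups.index(g) for g in labels])
    event_times = np.unique(times[events])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int((events & (times == t)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[events & (times == t)], minlength=k).astype(float)
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            var += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[:-1]
    V = var[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(V) @ diff)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return LogrankResult(
        chi2=chi2,
        p=max(p, 5e-324),
        n_groups=k,
        observed={g: float(o) for g, o in zip(groups, observed)},
        expected={g: float(e) for g, e in zip(groups, expected)},
    )
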