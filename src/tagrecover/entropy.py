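"""Relative-entropy characterization of dive-profile recovery.

Diving behaviour is summarized hour by hour as a probability vector over
three target-depth categories (Shallow, Medium, Deep); by default each
dive contributes its duration, so P_t(x) is the share of dive-seconds in
hour t spent in category-x dives.  A reference ("baseline") distribution Q
is formed from the hours of an a-priori normal region t > tN as a weighted
average of hourly distributions, where the weighting counters the thinning
of the animal sample as tags drop off: between consecutive drop points the
hourly distributions are averaged, and the segment means are combined with
weights proportional to the number of animals still transmitting before
each drop point.

The divergence between P_t and Q is the Jensen-Shannon relative entropy in
log base 2, which is symmetric, always finite, and bounded in [0, 1].  To
decide which divergences are "typical of baseline", a region of recovery
(RoR) is built from the normal-region hours by leave-one-out
cross-validation: for each hour t' the reference is recomputed without t'
and J(P_t' || Q_-t') collected; the RoR is the empirical central 95% band
of these values.  Hours are then labelled +1 (inside the RoR) or -1
(outside); the label series feeds the breakpoint estimator in
:mod:`tagrecover.changepoint`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CATEGORIES

__all__ = [
    "HourlyDistribution",
    "DropSchedule",
    "ReferenceDistribution",
    "EntropySeries",
    "RoR",
    "hourly_distributions",
    "build_schedule",
    "reference_distribution",
    "kl_divergence",
    "js_divergence",
    "entropy_series",
    "region_of_recovery",
    "pooled_region_of_recovery",
    "label_series",
]

_LN2 = np.log(2.0)


@dataclass
class HourlyDistribution:
    """Dive-profile composition of one hour [hour, hour+1) since release."""

    hour: int
    p: np.ndarray
    n_dives: int
    total_dive_seconds: float
    n_animals: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(CATEGORIES),):
            raise ValueError(f"p must have one entry per category {CATEGORIES}")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must be a probability vector")


@dataclass
class DropSchedule:
    """Tag drop points inside the normal region and their weights.

    ``drops`` are the distinct record-end hours beyond ``t_n`` (the last
    one is the maximum record duration); ``n_active[i]`` counts animals
    still transmitting before ``drops[i]``; ``weights`` are n_i / sum(n).
    """

    t_n: float
    drops: np.ndarray
    n_active: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.drops = np.asarray(self.drops, dtype=float)
        self.n_active = np.asarray(self.n_active, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.drops) <= 0):
            raise ValueError("drop points must be strictly increasing")
        if np.any(np.diff(self.n_active) > 0):
            raise ValueError("active counts must be nonincreasing")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to one")

    @property
    def segments(self) -> list[tuple[float, float]]:
        """Half-open hour segments (t_{i-1}, t_i] partitioning (t_n, t_M]."""
        lo = np.concatenate([[self.t_n], self.drops[:-1]])
        return list(zip(lo, self.drops))


@dataclass
class ReferenceDistribution:
    """Drop-weighted long-term average distribution Q."""

    q: np.ndarray
    schedule: DropSchedule
    excluded_hour: int | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < 0) or abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError("q must be a probability vector")


@dataclass
class EntropySeries:
    """Hourly Jensen-Shannon divergences from the reference distribution."""

    hours: np.ndarray
    values: np.ndarray
    group: str = "all"

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.hours.shape != self.values.shape:
            raise ValueError("hours and values must align")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("Jensen-Shannon divergences must lie in [0, 1]")


@dataclass
class RoR:
    """Region of recovery: central band of leave-one-out divergences."""

    lo: float
    hi: float
    level: float
    source_hours: np.ndarray
    t_upper: float
    loo_values: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo <= self.hi <= 1.0:
            raise ValueError("RoR bounds must satisfy 0 <= lo <= hi <= 1")


# ---------------------------------------------------------------------------
# hourly distributions and the reference


def hourly_distributions(
    dives: pd.DataFrame, weighting: str = "duration"
) -> list[HourlyDistribution]:
    """Pool a group's dives into per-hour category distributions.

    A dive belongs to the hour its start falls in.  With
    ``weighting='duration'`` (default) each dive contributes its duration
    in seconds; with ``'count'`` each dive counts once.  Hours with no
    dives yield no distribution.
    """
    if weighting not in ("duration", "count"):
        raise ValueError("weighting must be 'duration' or 'count'")
    if dives.empty:
        return []
    df = dives.copy()
    df["hour"] = np.floor(df["start_h"]).astype(np.int64)
    w = df["duration_s"].to_numpy(float) if weighting == "duration" else np.ones(len(df))
    df["_w"] = w
    out = []
    for hour, sub in df.groupby("hour", sort=True):
        totals = np.array(
            [sub.loc[sub["category"] == c, "_w"].sum() for c in CATEGORIES]
        )
        out.append(
            HourlyDistribution(
                hour=int(hour),
                p=totals / totals.sum(),
                n_dives=len(sub),
                total_dive_seconds=float(sub["duration_s"].sum()),
                n_animals=sub["animal_id"].nunique(),
            )
        )
    return out


def hourly_duration_profiles(
    dives: pd.DataFrame,
    duration_edges_s: tuple[float, ...] = (0.0, 120.0, 300.0, 600.0, 1200.0, np.inf),
) -> pd.DataFrame:
    """Joint category x duration-bin composition per hour (display only).

    A finer alphabet than the 3-category vector, intended for
    heatmap-style inspection of how dive durations shift over time; the
    divergence machinery always works on the 3-category distributions.
    Returns a long frame (hour, category, duration_bin, share) where the
    duration-weighted shares sum to 1 within each hour.
    """
    if dives.empty:
        return pd.DataFrame(columns=["hour", "category", "duration_bin", "share"])
    df = dives.copy()
    df["hour"] = np.floor(df["start_h"]).astype(np.int64)
    edges = np.asarray(duration_edges_s, dtype=float)
    labels = [f"{lo:g}-{hi:g}s" for lo, hi in zip(edges[:-1], edges[1:])]
    df["duration_bin"] = pd.cut(df["duration_s"], bins=edges, labels=labels, right=False)
    out = (
        df.groupby(["hour", "category", "duration_bin"], observed=True)["duration_s"]
        .sum()
        .rename("share")
        .reset_index()
    )
    totals = out.groupby("hour")["share"].transform("sum")
    out["share"] = out["share"] / totals
    return out


def build_schedule(record_ends_h, t_n: float) -> DropSchedule:
    """Drop points and weights from per-animal record-end hours.

    Drop points are the distinct record ends beyond ``t_n``; the weight of
    the segment ending at drop i is proportional to the number of animals
    whose records reach at least that drop point.
    """
    ends = np.asarray(list(record_ends_h), dtype=float)
    if ends.size == 0:
        raise ValueError("no record ends supplied")
    drops = np.unique(ends[ends > t_n])
    if drops.size == 0:
        raise ValueError(
            f"no record extends beyond t_n={t_n}; the normal region is empty"
        )
    n_active = np.array([(ends >= d).sum() for d in drops])
    return DropSchedule(t_n, drops, n_active, n_active / n_active.sum())


def reference_distribution(
    hourly: list[HourlyDistribution],
    schedule: DropSchedule,
    excluded_hour: int | None = None,
) -> ReferenceDistribution:
    """Weighted long-term average Q over the normal region.

    Q = sum_i w_i * mean of P_t over hours t in (t_{i-1}, t_i] (half-open;
    integer hour t means the interval [t, t+1)).  Hours absent from
    ``hourly`` — and the optional ``excluded_hour`` for leave-one-out use —
    are dropped from their segment mean with a renormalized divisor; a
    segment left with no hours has its weight redistributed proportionally
    over the remaining segments (with a warning).
    """
    by_hour = {h.hour: h.p for h in hourly}
    means, weights = [], []
    empty = 0
    for (lo, hi), w in zip(schedule.segments, schedule.weights):
        ps = [
            p for t, p in by_hour.items()
            if lo < t <= hi and t != excluded_hour
        ]
        if not ps:
            empty += 1
            continue
        means.append(np.mean(ps, axis=0))
        weights.append(w)
    if not means:
        raise ValueError("no hourly distributions available in the normal region")
    if empty:
        warnings.warn(
            f"{empty} drop-schedule segment(s) had no hourly distributions; "
            "their weight was redistributed proportionally", stacklevel=2,
        )
    weights = np.asarray(weights) / np.sum(weights)
    q = np.einsum("i,ij->j", weights, np.asarray(means))
    return ReferenceDistribution(q / q.sum(), schedule, excluded_hour)


# ---------------------------------------------------------------------------
# divergences


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence in bits, sum p log2(p/q).

    0 log 0 contributes nothing; any p(x) > 0 where q(x) = 0 makes the
    divergence infinite.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must share an alphabet")
    for v in (p, q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("inputs must be probability vectors")
    support = p > 0
    if np.any(q[support] == 0):
        return np.inf
    return float(np.sum(p[support] * np.log(p[support] / q[support])) / _LN2)


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits: always finite, symmetric, in [0, 1].

    J(p, q) = K(p, m)/2 + K(q, m)/2 with m the equal mixture of p and q.
    The base-2 logarithm pins the maximum (disjoint supports) at exactly 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    j = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    return float(min(max(j, 0.0), 1.0))


def entropy_series(
    hourly: list[HourlyDistribution],
    reference: ReferenceDistribution,
    group: str = "all",
) -> EntropySeries:
    """J(P_t || Q) for every available hour."""
    hours = np.array([h.hour for h in hourly], dtype=int)
    values = np.array([js_divergence(h.p, reference.q) for h in hourly])
    order = np.argsort(hours)
    return EntropySeries(hours[order], values[order], group=group)


# ---------------------------------------------------------------------------
# region of recovery and labels


def leave_one_out_divergences(
    hourly: list[HourlyDistribution],
    schedule: DropSchedule,
    t_upper: float,
) -> tuple[np.ndarray, np.ndarray]:
    """J(P_t' || Q_-t') for normal-region hours t' in (t_n, t_upper]."""
    if t_upper <= schedule.t_n:
        raise ValueError("t_upper must exceed the normal-region threshold")
    by_hour = {h.hour: h for h in hourly}
    hours = sorted(t for t in by_hour if schedule.t_n < t <= t_upper)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-hour segments vanish under LOO
        for t in hours:
            q_loo = reference_distribution(hourly, schedule, excluded_hour=t)
            vals.append(js_divergence(by_hour[t].p, q_loo.q))
    return np.asarray(hours, dtype=int), np.asarray(vals)


def _band(loo: np.ndarray, hours: np.ndarray, t_upper: float, level: float) -> RoR:
    lo, hi = np.quantile(loo, [(1 - level) / 2, 1 - (1 - level) / 2])
    return RoR(float(lo), float(hi), level, hours, t_upper, loo)


def region_of_recovery(
    hourly: list[HourlyDistribution],
    schedule: DropSchedule,
    t_upper: float,
    level: float = 0.95,
) -> RoR:
    """Empirical central band of the leave-one-out divergences.

    ``t_upper`` should sit at one of the first drop points so the set of
    animals underlying P_t is stable over the band's source hours.  The
    band is the (2.5%, 97.5%) empirical quantile pair at the default level,
    closed at both endpoints.
    """
    hours, loo = leave_one_out_divergences(hourly, schedule, t_upper)
    if hours.size < 10:
        warnings.warn(
            f"only {hours.size} normal-region hours feed the RoR; the band "
            "may be unstable", stacklevel=2,
        )
    return _band(loo, hours, t_upper, level)


def pooled_region_of_recovery(
    per_group: list[tuple[list[HourlyDistribution], DropSchedule]],
    t_upper: float,
    level: float = 0.95,
) -> RoR:
    """RoR from the combined leave-one-out divergences of several groups.

    Used when comparing subgroups: the band assumes the groups share a
    baseline distribution inside the normal region, so their divergences
    are pooled before taking quantiles.
    """
    all_hours, all_loo = [], []
    for hourly, schedule in per_group:
        hours, loo = leave_one_out_divergences(hourly, schedule, t_upper)
        all_hours.append(hours)
        all_loo.append(loo)
    return _band(np.concatenate(all_loo), np.concatenate(all_hours), t_upper, level)


def label_series(series: EntropySeries, ror: RoR) -> pd.DataFrame:
    """±1 labels: +1 when lo <= J(t) <= hi (closed interval), else -1.

    Hours without a distribution carry no label (they are simply absent
    from ``series``).  Returns a frame with columns hour, J, label.
    """
    inside = (series.values >= ror.lo) & (series.values <= ror.hi)
    return pd.DataFrame(
        {
            "hour": series.hours,
            "J": series.values,
            "label": np.where(inside, 1, -1).astype(int),
        }
    )
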