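"""Cluster-based permutation inference over time-resolved statistics.

The same engine serves two consumers: sliding-window decoding accuracy
(one-sided, upper tail) and single-channel vocal-vs-nonvocal t-statistic
series (two-sided, signed tails).  The procedure:

1. For each label permutation, recompute the statistic series; per window,
   the critical value is the upper ``1 - alpha`` percentile of that window's
   null (split ``alpha/2`` per signed tail when two-sided).
2. Observed clusters are maximal runs of windows exceeding their critical
   value; the cluster mass is the sum of the statistic values inside the run.
3. Each permutation contributes its maximum absolute cluster mass (0 when no
   window is suprathreshold); a cluster's p-value is the fraction of null
   maxima at or above its absolute mass.

Small instances can be tested exactly by exhaustive enumeration of label
assignments instead of random shuffles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd


@dataclass
class TimeStatSeries:
    """A statistic evaluated on a regular grid of time windows."""

    values: np.ndarray
    window_centers_ms: np.ndarray
    kind: Literal["accuracy", "tstat"] = "tstat"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_centers_ms = np.asarray(self.window_centers_ms, dtype=float)
        if self.values.shape != self.window_centers_ms.shape:
            raise ValueError("values and window centers must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic series contains non-finite values")
        if len(self.window_centers_ms) > 1:
            steps = np.diff(self.window_centers_ms)
            if not np.allclose(steps, steps[0]):
                raise ValueError("window spacing must be constant")


@dataclass
class Cluster:
    start: int          # first window index in the run
    end: int            # last window index (inclusive)
    mass: float
    p: float
    start_ms: float | None = None
    end_ms: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    critical_high: np.ndarray
    critical_low: np.ndarray | None
    n_permutations: int
    null_max_masses: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start_window": c.start,
                    "end_window": c.end,
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "mass": c.mass,
                    "p": c.p,
                }
                for c in self.clusters
            ],
            columns=["start_window", "end_window", "start_ms", "end_ms", "mass", "p"],
        )


def bh_fdr(p: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up false-discovery-rate control.

    Returns a boolean rejection vector at level ``alpha`` and the adjusted
    p-values (monotone after sorting, capped at 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("p-value vector is empty")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adjusted_sorted
    return adjusted <= alpha, adjusted


def _find_clusters(values: np.ndarray, mask: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of True in ``mask``; mass = sum of values within the run."""
    clusters = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            clusters.append((i, j, float(values[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return clusters


def _clusters_for_series(values, crit_high, crit_low, tail):
    out = _find_clusters(values, values > crit_high)
    if tail == "two":
        out += _find_clusters(values, values < crit_low)
    return out


def permutation_cluster_test(
    series_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    data: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    window_alpha: float = 0.05,
    seed: int | None = 0,
    tail: Literal["greater", "two"] = "two",
    window_centers_ms: np.ndarray | None = None,
    exhaustive: bool = False,
    max_exhaustive: int = 20000,
) -> ClusterResult:
    """Run the cluster permutation test for ``series_fn`` applied to labelled data.

    Parameters
    ----------
    series_fn
        Maps ``(data, labels)`` to a 1-D statistic series over windows.
    labels
        Boolean class labels, one per observation (row of ``data``); both
        classes must be present.
    exhaustive
        Enumerate all distinct label assignments instead of random shuffles
        (only feasible for ≤ ~10 observations).  The observed assignment is
        part of the enumeration, so p-values are exact.
    """
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    k = int(labels.sum())
    if k == 0 or k == n:
        raise ValueError("both label classes must be present")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    observed = np.asarray(series_fn(data, labels), dtype=float)
    n_windows = observed.size

    if exhaustive:
        from math import comb

        if comb(n, k) > max_exhaustive:
            raise ValueError(f"exhaustive enumeration infeasible for C({n},{k}) assignments")
        perms = []
        for idx in itertools.combinations(range(n), k):
            lab = np.zeros(n, dtype=bool)
            lab[list(idx)] = True
            perms.append(lab)
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(labels) for _ in range(n_perm)]

    null = np.empty((len(perms), n_windows))
    for i, lab in enumerate(perms):
        null[i] = series_fn(data, lab)

    if tail == "greater":
        crit_high = np.quantile(null, 1.0 - window_alpha, axis=0)
        crit_low = None
        crit_low_arr = np.full(n_windows, -np.inf)
    elif tail == "two":
        crit_high = np.quantile(null, 1.0 - window_alpha / 2.0, axis=0)
        crit_low = np.quantile(null, window_alpha / 2.0, axis=0)
        crit_low_arr = crit_low
    else:
        raise ValueError(f"unknown tail {tail!r}")

    null_max = np.zeros(len(perms))
    for i in range(len(perms)):
        cl = _clusters_for_series(null[i], crit_high, crit_low_arr, tail)
        if cl:
            null_max[i] = max(abs(mass) for _, _, mass in cl)

    clusters = []
    for start, end, mass in _clusters_for_series(observed, crit_high, crit_low_arr, tail):
        p = float(np.mean(null_max >= abs(mass)))
        c = Cluster(start=start, end=end, mass=mass, p=p)
        if window_centers_ms is not None:
            c.start_ms = float(window_centers_ms[start])
            c.end_ms = float(window_centers_ms[end])
        clusters.append(c)

    return ClusterResult(
        clusters=clusters,
        critical_high=crit_high,
        critical_low=crit_low,
        n_permutations=len(perms),
        null_max_masses=null_max,
    )


def sum_cluster_mass(result: ClusterResult, p_threshold: float = 0.001) -> float:
    """Sum of absolute masses over significant clusters (0 when none).

    Summing all significant clusters, rather than taking the largest one,
    credits channels whose vocal/nonvocal difference comes in several bursts.
    """
    return float(sum(abs(c.mass) for c in result.clusters if c.p < p_threshold))


def sliding_tstats(
    data: np.ndarray,
    labels: np.ndarray,
    window_centers_ms: np.ndarray | None = None,
) -> TimeStatSeries:
    """Two-sample pooled-variance t-statistic at every time point.

    ``data`` is trials × time for a single channel; ``labels`` marks vocal
    trials.  The sign convention is vocal minus nonvocal, so swapping labels
    negates the series.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if data.ndim != 2 or data.shape[0] != labels.size:
        raise ValueError("data must be trials × time with one label per trial")
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least 2 trials")
    t = tstat_series(data, labels)
    if window_centers_ms is None:
        window_centers_ms = np.arange(data.shape[1], dtype=float)
    return TimeStatSeries(values=t, window_centers_ms=window_centers_ms, kind="tstat")


def tstat_series(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t (class True minus class False)."""
    labels = np.asarray(labels, dtype=bool)
    a, b = data[labels], data[~labels]
    n1, n0 = a.shape[0], b.shape[0]
    m1, m0 = a.mean(axis=0), b.mean(axis=0)
    ss1 = ((a - m1) ** 2).sum(axis=0)
    ss0 = ((b - m0) ** 2).sum(axis=0)
    sp2 = (ss1 + ss0) / (n1 + n0 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    return np.where(denom == 0, 0.0, t)
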