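"""Single-cell domain boundary detection on spatial distance matrices.

For each locus of a trace's (interpolated) distance matrix two contrast
ratios are computed from pooled medians of short column segments flanking
the diagonal:

* start-of-domain strength  L/R — median distance in the three columns
  left of the locus (each extending 10 elements below the diagonal)
  divided by the median in the three columns from the locus rightward;
* end-of-domain strength    B/T — the analogous ratio above the diagonal,
  with B pooling the three columns right of the locus and T the three
  columns up to and including it.

A domain start (end) is called where the start (end) strength is a local
maximum above a threshold.  Aggregating calls over traces gives per-locus
boundary probabilities and the per-trace boundary frequency; an F-test on
the across-locus variance of two probability profiles quantifies which
profile is more uniform (Xi-like boundaries are spread out, Xa-like
boundaries pile up at the ensemble TAD boundary).

Strengths are ratios of medians, hence invariant to global rescaling of
distances.  Loci whose contributing pool is empty on either side (the
first/last loci of the region) have undefined strength, reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .core import DistanceMatrix, TraceSet, compute_distance_matrix, filter_by_min_observed

__all__ = [
    "BoundaryProfile",
    "BoundaryCalls",
    "BoundaryStats",
    "BoundaryAnalysis",
    "boundary_strengths",
    "call_boundaries",
    "boundary_probability_profile",
    "boundary_frequency",
    "uniformity_ftest",
    "compare_conditions",
    "DEFAULT_CALL_THRESHOLD",
    "MIN_LOCI_BOUNDARY",
]

DEFAULT_CALL_THRESHOLD = 1.2
MIN_LOCI_BOUNDARY = 23


@dataclass
class BoundaryProfile:
    """Per-locus start/end boundary strengths of one matrix (NaN = undefined)."""

    start_strength: np.ndarray
    end_strength: np.ndarray
    window: int = 10
    n_cols: int = 3


@dataclass
class BoundaryCalls:
    """Called boundary loci of one trace."""

    start_loci: list[int]
    end_loci: list[int]
    threshold: float

    @property
    def n_calls(self) -> int:
        return len(self.start_loci) + len(self.end_loci)


@dataclass
class BoundaryStats:
    """Per-locus boundary probabilities aggregated over traces.

    Both probabilities are indexed by the domain *transition* a call
    supports, labelled with the start-of-domain locus: a start call at
    locus i and an end call at locus i-1 (the last locus of the previous
    domain) both support a transition at i.  This alignment makes the
    averaged ``boundary_prob`` single-peaked at a domain transition
    instead of splitting its mass between two adjacent loci.
    """

    start_prob: np.ndarray
    end_prob: np.ndarray
    n_traces: int

    @property
    def boundary_prob(self) -> np.ndarray:
        return (self.start_prob + self.end_prob) / 2.0


def _column_below(values: np.ndarray, j: int, window: int) -> np.ndarray:
    """Elements of column j extending ``window`` rows below the diagonal."""
    n = values.shape[0]
    return values[j + 1 : min(j + 1 + window, n), j]


def _column_above(values: np.ndarray, j: int, window: int) -> np.ndarray:
    """Elements of column j extending ``window`` rows above the diagonal."""
    return values[max(j - window, 0) : j, j]


def _pooled_median(values: np.ndarray, cols: range, window: int, below: bool) -> float:
    pool = []
    n = values.shape[0]
    for j in cols:
        if 0 <= j < n:
            seg = _column_below(values, j, window) if below else _column_above(values, j, window)
            pool.append(seg)
    if not pool:
        return np.nan
    flat = np.concatenate(pool)
    return float(np.median(flat)) if flat.size else np.nan


def boundary_strengths(
    matrix: DistanceMatrix | np.ndarray, window: int = 10, n_cols: int = 3
) -> BoundaryProfile:
    """Start (L/R) and end (B/T) boundary strengths for every locus.

    For locus i (0-based) the pools are medians over all contributing
    elements of up to ``n_cols`` columns, each clipped to the matrix:

    * L: below-diagonal elements of columns i-3 .. i-1
    * R: below-diagonal elements of columns i   .. i+2
    * T: above-diagonal elements of columns i-2 .. i
    * B: above-diagonal elements of columns i+1 .. i+3
    """
    values = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix, float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("matrix must be at least 2x2")
    start = np.full(n, np.nan)
    end = np.full(n, np.nan)
    for i in range(n):
        L = _pooled_median(values, range(i - n_cols, i), window, below=True)
        R = _pooled_median(values, range(i, i + n_cols), window, below=True)
        T = _pooled_median(values, range(i - n_cols + 1, i + 1), window, below=False)
        B = _pooled_median(values, range(i + 1, i + n_cols + 1), window, below=False)
        if np.isfinite(L) and np.isfinite(R) and R > 0:
            start[i] = L / R
        if np.isfinite(B) and np.isfinite(T) and T > 0:
            end[i] = B / T
    return BoundaryProfile(start, end, window=window, n_cols=n_cols)


def _local_maxima(strength: np.ndarray, threshold: float) -> list[int]:
    """Strict local maxima over defined neighbors, at or above threshold.

    Operates on the subsequence of defined (finite) values.  A plateau of
    equal values qualifies only if strictly greater than both flanking
    defined values; the leftmost plateau index is called.  A plateau
    spanning the whole defined subsequence yields no call.
    """
    defined = np.flatnonzero(np.isfinite(strength))
    vals = strength[defined]
    calls: list[int] = []
    m = vals.size
    i = 0
    while i < m:
        j = i
        while j + 1 < m and vals[j + 1] == vals[i]:
            j += 1
        left_ok = i > 0 and vals[i] > vals[i - 1]
        right_ok = j < m - 1 and vals[j] > vals[j + 1]
        has_left = i > 0
        has_right = j < m - 1
        if (has_left or has_right) and (left_ok or not has_left) and (right_ok or not has_right):
            if vals[i] >= threshold:
                calls.append(int(defined[i]))
        i = j + 1
    return calls


def call_boundaries(profile: BoundaryProfile, threshold: float = DEFAULT_CALL_THRESHOLD) -> BoundaryCalls:
    """Call start/end boundaries as thresholded local maxima, independently."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return BoundaryCalls(
        start_loci=_local_maxima(profile.start_strength, threshold),
        end_loci=_local_maxima(profile.end_strength, threshold),
        threshold=threshold,
    )


class BoundaryAnalysis(BaseEstimator):
    """Boundary statistics over a set of traces, sklearn-style.

    ``fit`` filters traces to at least ``min_loci`` detected loci,
    interpolates, computes per-trace strength profiles and boundary
    calls, and aggregates per-locus probabilities and the boundary
    frequency (mean boundary calls per trace).

    Attributes (after fit): ``profiles_``, ``calls_``, ``stats_``,
    ``frequency_``, ``frequency_sd_``, ``n_traces_``.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_CALL_THRESHOLD,
        window: int = 10,
        n_cols: int = 3,
        min_loci: int = MIN_LOCI_BOUNDARY,
    ):
        self.threshold = threshold
        self.window = window
        self.n_cols = n_cols
        self.min_loci = min_loci

    def fit(self, trace_set: TraceSet, y=None):
        kept = filter_by_min_observed(trace_set, self.min_loci)
        if len(kept) == 0:
            raise ValueError(
                f"no traces with >= {self.min_loci} observed loci ({len(trace_set)} supplied)"
            )
        n = kept.region.n_loci
        self.profiles_ = []
        self.calls_ = []
        start_counts = np.zeros(n)
        end_counts = np.zeros(n)
        per_trace_calls = []
        for t in kept:
            dm = compute_distance_matrix(t, use_interpolation=True)
            prof = boundary_strengths(dm, window=self.window, n_cols=self.n_cols)
            calls = call_boundaries(prof, self.threshold)
            self.profiles_.append(prof)
            self.calls_.append(calls)
            start_counts[calls.start_loci] += 1
            # an end call at locus j marks the last locus of a domain; the
            # transition it supports is at start-of-domain locus j+1
            end_counts[[j + 1 for j in calls.end_loci if j + 1 < n]] += 1
            per_trace_calls.append(calls.n_calls)
        m = len(kept)
        self.n_traces_ = m
        self.stats_ = BoundaryStats(start_counts / m, end_counts / m, m)
        counts = np.asarray(per_trace_calls, float)
        self.frequency_ = float(counts.mean())
        self.frequency_sd_ = float(counts.std(ddof=1)) if m > 1 else 0.0
        return self


def boundary_probability_profile(
    trace_set: TraceSet, threshold: float = DEFAULT_CALL_THRESHOLD, **kwargs
) -> BoundaryStats:
    """Per-locus start/end/combined boundary probabilities over traces."""
    return BoundaryAnalysis(threshold=threshold, **kwargs).fit(trace_set).stats_


def boundary_frequency(
    trace_set: TraceSet, threshold: float = DEFAULT_CALL_THRESHOLD, **kwargs
) -> tuple[float, float, pd.DataFrame]:
    """Mean (and sd of) boundary calls per trace, plus a per-condition table."""
    ba = BoundaryAnalysis(threshold=threshold, **kwargs).fit(trace_set)
    kept = filter_by_min_observed(trace_set, ba.min_loci)
    rows = []
    df = pd.DataFrame(
        {
            "condition": [t.condition for t in kept],
            "n_calls": [c.n_calls for c in ba.calls_],
        }
    )
    for cond, g in df.groupby("condition", sort=True):
        rows.append(
            {
                "condition": cond,
                "n_traces": len(g),
                "frequency": g["n_calls"].mean(),
                "sd": g["n_calls"].std(ddof=1) if len(g) > 1 else 0.0,
            }
        )
    return ba.frequency_, ba.frequency_sd_, pd.DataFrame(rows)


def uniformity_ftest(stats_a: BoundaryStats, stats_b: BoundaryStats) -> tuple[float, float]:
    """Variance-ratio F-test comparing uniformity of two boundary profiles.

    F = var(profile A across loci) / var(profile B across loci), with a
    two-sided p from F(n_loci-1, n_loci-1).  F < 1 means profile A is the
    more uniform (flatter) of the two.
    """
    a = stats_a.boundary_prob
    b = stats_b.boundary_prob
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same loci")
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if var_b == 0:
        raise ValueError("zero variance in denominator profile")
    f = var_a / var_b
    df_ = a.size - 1
    cdf = stats.f.cdf(f, df_, df_)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return f, min(p, 1.0)


def compare_conditions(
    groups: dict[str, np.ndarray], reference: str | None = None
) -> pd.DataFrame:
    """Pairwise Welch t-tests with Benjamini–Hochberg FDR correction.

    ``groups`` maps a condition label to its per-trace values (boundary
    frequencies or strengths).  With ``reference`` each other group is
    tested against it; otherwise all pairs are tested.  Adjustment is
    applied across the whole comparison family.
    """
    labels = list(groups)
    if reference is not None:
        pairs = [(reference, other) for other in labels if other != reference]
    else:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(
            np.asarray(groups[a], float), np.asarray(groups[b], float), equal_var=False
        )
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
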