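"""Radius-of-gyration compaction analysis.

The radius of gyration of a trace,

    Rg = sqrt( (1/N) * sum_i |r_i - r_c|^2 ),

with r_c the centroid of the N detected loci, measures the size of the
spatial volume the trace occupies.  Only detected loci enter the
computation (N is the number of observed loci, not the number of targeted
segments), and traces below a minimum detection count are excluded: 25 of
28 loci for the fine-scale regions, 35 for large-scale whole-chromosome
traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromatinTrace, TraceSet

__all__ = [
    "RgRecord",
    "radius_of_gyration",
    "rg_table",
    "box_summary",
    "compare_rg",
    "MIN_LOCI_RG_FINE",
    "MIN_LOCI_RG_LARGE",
]

MIN_LOCI_RG_FINE = 25
MIN_LOCI_RG_LARGE = 35


@dataclass(frozen=True)
class RgRecord:
    trace_id: str
    allele: str
    rg_nm: float
    n_used: int


def radius_of_gyration(trace: ChromatinTrace, min_loci: int = MIN_LOCI_RG_FINE) -> RgRecord:
    """Rg over the trace's observed loci; raises if below ``min_loci``."""
    n_obs = trace.n_observed
    if n_obs < min_loci:
        raise ValueError(
            f"trace {trace.trace_id}: {n_obs} observed loci < min_loci {min_loci}"
        )
    pts = trace.coords[trace.observed]
    centroid = pts.mean(axis=0)
    rg = float(np.sqrt(np.sum((pts - centroid) ** 2) / n_obs))
    return RgRecord(trace.trace_id, trace.allele, rg, n_obs)


def rg_table(trace_set: TraceSet, min_loci: int = MIN_LOCI_RG_FINE) -> tuple[pd.DataFrame, int]:
    """Per-trace Rg table over qualifying traces, plus the excluded count."""
    records, excluded = [], 0
    for t in trace_set:
        if t.n_observed < min_loci:
            excluded += 1
            continue
        records.append(radius_of_gyration(t, min_loci))
    df = pd.DataFrame(
        [{"trace_id": r.trace_id, "allele": r.allele, "rg_nm": r.rg_nm, "n_used": r.n_used} for r in records],
        columns=["trace_id", "allele", "rg_nm", "n_used"],
    )
    return df, excluded


def box_summary(values: np.ndarray) -> dict:
    """Box-plot summary with outliers beyond 1.5x the interquartile range.

    Returns quartiles, median, the non-outlier extrema (whiskers) and the
    outlying values themselves.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inliers = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_lo": float(inliers.min()),
        "whisker_hi": float(inliers.max()),
        "outliers": np.sort(x[(x < lo_fence) | (x > hi_fence)]),
        "n": int(x.size),
    }


def compare_rg(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Welch two-sided t-test plus box summaries for two Rg groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "summary_a": box_summary(a),
        "summary_b": box_summary(b),
    }
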