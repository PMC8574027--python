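"""Population-level structure: mean distance matrices, Hi-C binning and the
distance–contact power law.

The population-mean spatial distance matrix is the imaging counterpart of
an ensemble Hi-C contact map over the same region.  Hi-C counts at their
native resolution (5 kb) are summed into the tracing resolution (30 kb),
and contact frequency is regressed against mean distance in log-log
space, where a power law  freq = C * d^(-k)  is a straight line with
slope -k.  Chromatin-tracing studies consistently report k near 4 with a
log-log correlation near -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .boundaries import BoundaryProfile, boundary_strengths
from .core import GenomicRegion, TraceSet

__all__ = [
    "EnsembleComparison",
    "mean_distance_matrix",
    "bin_hic_counts",
    "PowerLawRegression",
    "powerlaw_fit",
    "ensemble_boundary",
]


@dataclass
class EnsembleComparison:
    mean_dist: np.ndarray
    hic: np.ndarray
    exponent_k: float
    prefactor: float
    pearson_r: float
    n_pairs: int


def mean_distance_matrix(trace_set: TraceSet) -> tuple[np.ndarray, np.ndarray]:
    """Entrywise mean distance over traces in which both loci were detected.

    Interpolated coordinates are excluded so that missing data cannot bias
    entries toward smoother traces.  Entries with no supporting trace are
    NaN; the per-entry support count is returned alongside.
    """
    n = trace_set.region.n_loci
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for t in trace_set:
        d = np.linalg.norm(t.coords[:, None, :] - t.coords[None, :, :], axis=-1)
        ok = t.observed[:, None] & t.observed[None, :]
        total[ok] += d[ok]
        count += ok.astype(int)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def bin_hic_counts(
    contacts: pd.DataFrame, region: GenomicRegion, source_bin: int = 5_000
) -> tuple[np.ndarray, int]:
    """Sum native-resolution Hi-C counts into the region's tracing bins.

    ``contacts`` has columns bin1_start, bin2_start, count with bin starts
    in assembly coordinates at ``source_bin`` resolution.  Records whose
    bin start falls outside the region (half-open) are dropped; the
    dropped count is returned.  The output matrix is symmetric.
    """
    if region.bin_size % source_bin != 0:
        raise ValueError(
            f"target bin {region.bin_size} not divisible by source bin {source_bin}"
        )
    n = region.n_loci
    counts = np.zeros((n, n))
    dropped = 0
    b1 = contacts["bin1_start"].to_numpy()
    b2 = contacts["bin2_start"].to_numpy()
    c = contacts["count"].to_numpy()
    i = np.floor_divide(b1 - region.start, region.bin_size)
    j = np.floor_divide(b2 - region.start, region.bin_size)
    inside = (b1 >= region.start) & (b1 < region.end) & (b2 >= region.start) & (b2 < region.end)
    dropped = int((~inside).sum())
    for bi, bj, cc in zip(i[inside], j[inside], c[inside]):
        lo, hi = (bi, bj) if bi <= bj else (bj, bi)
        counts[lo, hi] += cc
    counts = counts + counts.T - np.diag(np.diag(counts))
    return counts, dropped


class PowerLawRegression(BaseEstimator, RegressorMixin):
    """Least-squares power law  freq = prefactor * dist^(-exponent).

    Fitted in log-log space, where the model is linear; the Pearson
    correlation of the same log-log pairs is reported so the fit quality
    is directly comparable with published distance-vs-contact panels.

    Attributes (after fit): ``exponent_``, ``prefactor_``, ``pearson_r_``,
    ``n_pairs_``.
    """

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(d) & np.isfinite(f) & (d > 0) & (f > 0)
        if ok.sum() < 3:
            raise ValueError(f"need >= 3 valid (dist, freq) pairs, have {int(ok.sum())}")
        logd, logf = np.log(d[ok]), np.log(f[ok])
        slope, intercept = np.polyfit(logd, logf, 1)
        self.exponent_ = float(-slope)
        self.prefactor_ = float(np.exp(intercept))
        if np.ptp(logd) == 0 or np.ptp(logf) == 0:
            self.pearson_r_ = 0.0
        else:
            self.pearson_r_ = float(stats.pearsonr(logd, logf)[0])
        self.n_pairs_ = int(ok.sum())
        return self

    def predict(self, X):
        d = np.asarray(X, dtype=float)
        return self.prefactor_ * d ** (-self.exponent_)


def powerlaw_fit(mean_dist: np.ndarray, hic: np.ndarray) -> EnsembleComparison:
    """Fit the distance–contact power law on off-diagonal matrix entries.

    Uses strict-upper-triangle entries where the mean distance is defined
    and positive and the Hi-C count is positive (zero counts are excluded
    rather than pseudocounted).
    """
    mean_dist = np.asarray(mean_dist, dtype=float)
    hic = np.asarray(hic, dtype=float)
    iu = np.triu_indices_from(mean_dist, k=1)
    reg = PowerLawRegression().fit(mean_dist[iu], hic[iu])
    return EnsembleComparison(
        mean_dist=mean_dist,
        hic=hic,
        exponent_k=reg.exponent_,
        prefactor=reg.prefactor_,
        pearson_r=reg.pearson_r_,
        n_pairs=reg.n_pairs_,
    )


def ensemble_boundary(mean_dist: np.ndarray, **kwargs) -> tuple[int | None, BoundaryProfile]:
    """Locate the ensemble TAD boundary on a mean distance matrix.

    The boundary is the interior locus maximizing the start-of-domain
    strength of the mean matrix, provided that maximum exceeds 1 (a
    strength of 1 is a featureless matrix); returns ``(None, profile)``
    otherwise.
    """
    profile = boundary_strengths(np.asarray(mean_dist, dtype=float), **kwargs)
    s = profile.start_strength
    if not np.any(np.isfinite(s)) or np.nanmax(s) <= 1.0:
        return None, profile
    return int(np.nanargmax(s)), profile
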