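"""Core data model for chromatin-tracing analysis.

A chromatin trace is the ordered set of 3-D localizations (in nm) of the
consecutive genomic segments of one chromosome copy, as reconstructed by
multiplexed sequential DNA FISH.  Individual segments ("loci") can be
missing when a spot was not detected; downstream analyses either
interpolate the missing coordinates or restrict themselves to observed
loci, depending on the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GenomicRegion",
    "ChromatinTrace",
    "DistanceMatrix",
    "TraceSet",
    "partition_region",
    "interpolate_trace",
    "compute_distance_matrix",
    "filter_by_min_observed",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval tiled by equally sized segments.

    Coordinates are 0-based half-open base pairs; ``bin_size`` is the
    segment length (30 kb for the traced X-chromosome regions, giving
    28 segments per 840-kb region).
    """

    chrom: str
    start: int
    end: int
    bin_size: int
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if (self.end - self.start) % self.bin_size != 0:
            raise ValueError(
                f"region span {self.end - self.start} is not divisible by "
                f"bin_size {self.bin_size}; refusing to truncate"
            )

    @property
    def n_loci(self) -> int:
        return (self.end - self.start) // self.bin_size

    def locus_starts(self) -> np.ndarray:
        """Start coordinate of each segment, 5' to 3'."""
        return self.start + self.bin_size * np.arange(self.n_loci)

    def locus_interval(self, index: int) -> tuple[int, int]:
        """Half-open [start, end) of segment ``index`` (0-based)."""
        if not 0 <= index < self.n_loci:
            raise IndexError(f"locus index {index} outside [0, {self.n_loci})")
        s = self.start + index * self.bin_size
        return s, s + self.bin_size


def partition_region(
    chrom: str, start: int, end: int, bin_size: int, assembly: str = ""
) -> GenomicRegion:
    """Partition ``[start, end)`` into consecutive ``bin_size`` segments."""
    return GenomicRegion(chrom, start, end, bin_size, assembly)


ALLELES = ("Xa", "Xi", "unknown")


@dataclass
class ChromatinTrace:
    """One chromosome copy's ordered 3-D trace.

    ``coords`` has shape (n_loci, 3) in nm; entries at unobserved loci are
    NaN unless the trace has been interpolated.  ``observed`` records which
    loci were actually detected and is never changed by interpolation.
    """

    trace_id: str
    coords: np.ndarray
    observed: np.ndarray
    cell_id: str = ""
    allele: str = "unknown"
    condition: str = "control"
    marker_intensity: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_loci, 3)")
        if self.observed.shape != (self.coords.shape[0],):
            raise ValueError("observed mask length must match coords")
        if self.allele not in ALLELES:
            raise ValueError(f"allele must be one of {ALLELES}")
        if not np.all(np.isfinite(self.coords[self.observed])):
            raise ValueError("coords must be finite at observed loci")

    @property
    def n_loci(self) -> int:
        return self.coords.shape[0]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distance matrix of one trace (nm).

    ``interpolated[i, j]`` is True when the entry involves at least one
    locus whose coordinates were interpolated rather than observed.
    """

    values: np.ndarray
    interpolated: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if self.values.shape != self.interpolated.shape:
            raise ValueError("values and interpolated must have the same shape")
        n, m = self.values.shape
        if n != m:
            raise ValueError("distance matrix must be square")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]


@dataclass
class TraceSet:
    """A collection of traces over one genomic region."""

    region: GenomicRegion
    traces: list[ChromatinTrace] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        n = self.region.n_loci
        for t in self.traces:
            if t.n_loci != n:
                raise ValueError(
                    f"trace {t.trace_id} has {t.n_loci} loci, region has {n}"
                )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def subset(self, predicate) -> "TraceSet":
        return TraceSet(self.region, [t for t in self.traces if predicate(t)], self.provenance)

    def by_allele(self, allele: str) -> "TraceSet":
        return self.subset(lambda t: t.allele == allele)

    def by_condition(self, condition: str) -> "TraceSet":
        return self.subset(lambda t: t.condition == condition)


def interpolate_trace(trace: ChromatinTrace) -> ChromatinTrace:
    """Fill missing loci by per-axis linear interpolation in genomic index.

    Interior gaps are linearly interpolated between the nearest observed
    flanking loci; runs of missing loci at either end are filled with the
    nearest observed coordinate (constant extrapolation).  The observed
    mask is unchanged, so interpolated loci stay identifiable.
    """
    if trace.n_observed < 2:
        raise ValueError(
            f"trace {trace.trace_id}: need >=2 observed loci to interpolate, "
            f"have {trace.n_observed}"
        )
    if trace.n_observed == trace.n_loci:
        return replace(trace, coords=trace.coords.copy(), observed=trace.observed.copy())
    idx = np.arange(trace.n_loci)
    obs = trace.observed
    coords = trace.coords.copy()
    for axis in range(3):
        # np.interp holds endpoint values constant outside the observed span
        coords[~obs, axis] = np.interp(idx[~obs], idx[obs], trace.coords[obs, axis])
    return replace(trace, coords=coords, observed=obs.copy())


def compute_distance_matrix(
    trace: ChromatinTrace, use_interpolation: bool = True
) -> DistanceMatrix:
    """Pairwise Euclidean distances between the trace's loci.

    With ``use_interpolation`` missing loci are filled first and every
    entry touching a filled locus is flagged; without it those entries are
    NaN (and likewise flagged).
    """
    if use_interpolation:
        t = interpolate_trace(trace)
        values = squareform(pdist(t.coords))
    else:
        values = squareform(pdist(trace.coords))
        # pdist propagates NaN from missing coords
    missing = ~trace.observed
    flagged = missing[:, None] | missing[None, :]
    np.fill_diagonal(flagged, False)
    return DistanceMatrix(values, flagged)


def filter_by_min_observed(trace_set: TraceSet, k: int) -> TraceSet:
    """Keep traces with at least ``k`` detected loci, preserving order.

    The boundary analyses use k=23 of 28 loci; radius-of-gyration uses
    k=25 (fine scale) or k=35 (large scale).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    return trace_set.subset(lambda t: t.n_observed >= k)
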