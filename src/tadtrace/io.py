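"""Plain-text I/O: trace tables (TSV), region BED, Hi-C contact lists.

Trace table schema (tab-delimited, header required)::

    trace_id  cell_id  allele  condition  locus_index  x_nm  y_nm  z_nm

One row per detected locus; absent rows denote missing loci.  An optional
``marker_intensity`` column carries the per-trace XIST/mH2A1 signal used
for Xa/Xi classification (repeated on every row of a trace).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ALLELES, ChromatinTrace, GenomicRegion, TraceSet

__all__ = [
    "read_trace_table",
    "write_trace_table",
    "read_region_bed",
    "write_region_bed",
    "read_hic_contacts",
]

_COLUMNS = ["trace_id", "cell_id", "allele", "condition", "locus_index", "x_nm", "y_nm", "z_nm"]


def read_trace_table(path, region: GenomicRegion) -> TraceSet:
    """Read a trace TSV into a :class:`TraceSet` over ``region``."""
    df = pd.read_csv(
        path, sep="\t", dtype={"trace_id": str, "cell_id": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trace table missing columns: {missing_cols}")
    for c in ("x_nm", "y_nm", "z_nm"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"non-numeric values in column {c}")
    n = region.n_loci
    if (df["locus_index"] < 0).any() or (df["locus_index"] >= n).any():
        bad = df.loc[(df["locus_index"] < 0) | (df["locus_index"] >= n), "locus_index"]
        raise ValueError(f"locus_index out of range [0, {n}): {sorted(set(bad))}")
    if df.duplicated(subset=["trace_id", "locus_index"]).any():
        dups = df[df.duplicated(subset=["trace_id", "locus_index"], keep=False)]
        raise ValueError(
            "duplicate (trace_id, locus_index) rows: "
            + ", ".join(map(str, dups[["trace_id", "locus_index"]].values[:5]))
        )
    has_marker = "marker_intensity" in df.columns
    traces = []
    for trace_id, g in df.groupby("trace_id", sort=False):
        coords = np.full((n, 3), np.nan)
        observed = np.zeros(n, dtype=bool)
        li = g["locus_index"].to_numpy()
        coords[li] = g[["x_nm", "y_nm", "z_nm"]].to_numpy()
        observed[li] = True
        first = g.iloc[0]
        marker = None
        if has_marker and pd.notna(first["marker_intensity"]):
            marker = float(first["marker_intensity"])
        traces.append(
            ChromatinTrace(
                trace_id=str(trace_id),
                coords=coords,
                observed=observed,
                cell_id=str(first["cell_id"]),
                allele=str(first["allele"]),
                condition=str(first["condition"]),
                marker_intensity=marker,
            )
        )
    return TraceSet(region, traces, provenance=f"read from {path}")


def write_trace_table(trace_set: TraceSet, path) -> None:
    """Write a :class:`TraceSet` as a trace TSV (observed loci only).

    Coordinates are written with repr-level precision so that a
    write/read round trip reproduces them exactly.
    """
    any_marker = any(t.marker_intensity is not None for t in trace_set)
    rows = []
    for t in trace_set:
        for i in np.flatnonzero(t.observed):
            row = {
                "trace_id": t.trace_id,
                "cell_id": t.cell_id,
                "allele": t.allele,
                "condition": t.condition,
                "locus_index": int(i),
                "x_nm": repr(float(t.coords[i, 0])),
                "y_nm": repr(float(t.coords[i, 1])),
                "z_nm": repr(float(t.coords[i, 2])),
            }
            if any_marker:
                row["marker_intensity"] = (
                    "" if t.marker_intensity is None else repr(float(t.marker_intensity))
                )
            rows.append(row)
    cols = _COLUMNS + (["marker_intensity"] if any_marker else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_region_bed(path, bin_size: int, assembly: str = "") -> GenomicRegion:
    """Read the first record of a 3-column BED (0-based half-open)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            return GenomicRegion(parts[0], int(parts[1]), int(parts[2]), bin_size, assembly)
    raise ValueError(f"no records in BED file {path}")


def write_region_bed(region: GenomicRegion, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{region.chrom}\t{region.start}\t{region.end}\n")


def read_hic_contacts(path) -> pd.DataFrame:
    """Read a 3-column Hi-C contact list: bin1_start, bin2_start, count.

    Coordinates are assembly base pairs (bin start positions at the native
    resolution, e.g. 5 kb); counts are non-negative.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["bin1_start", "bin2_start", "count"],
        comment="#",
    )
    if df["count"].lt(0).any():
        raise ValueError("negative Hi-C counts")
    return df
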