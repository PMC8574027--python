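"""Shared fixtures: small hand-built traces and seeded synthetic sets."""

import numpy as np
import pytest

from tadtrace import GenomicRegion, SyntheticConfig, TraceSet, generate_trace_set
from tadtrace.core import ChromatinTrace


def make_trace(coords, observed=None, **kwargs):
    coords = np.asarray(coords, dtype=float)
    if observed is None:
        observed = np.ones(len(coords), dtype=bool)
    kwargs.setdefault("trace_id", "t0")
    return ChromatinTrace(coords=coords, observed=np.asarray(observed, bool), **kwargs)


def two_block_matrix(n=28, split=14, within=100.0, between=1000.0, grade=2.0):
    """Distance matrix of two blocks [0, split) and [split, n).

    ``grade`` adds a small |i-j| ramp so strength maxima are unique.
    """
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same = (i < split) == (j < split)
            m[i, j] = (within if same else between) + grade * abs(i - j)
    return m


@pytest.fixture(scope="session")
def region28():
    return GenomicRegion("chrX", 76_800_000, 77_640_000, 30_000, assembly="hg18")


@pytest.fixture(scope="session")
def xa_like_set():
    """Xa-like ensemble: preferred boundary at locus 14 in 70% of copies."""
    cfg = SyntheticConfig(
        n_traces=500, boundary_model="preferred", preferred_boundary=14,
        preferred_prob=0.7, seed=11,
    )
    ts, plans = generate_trace_set(cfg)
    return ts, plans, cfg


@pytest.fixture(scope="session")
def xi_like_set():
    """Xi-like ensemble: boundaries uniformly placed along the region."""
    cfg = SyntheticConfig(n_traces=500, boundary_model="uniform", seed=1011)
    ts, plans = generate_trace_set(cfg)
    return ts, plans, cfg


@pytest.fixture(scope="session")
def domain_set():
    """Default-configuration synthetic set used for cooperativity checks."""
    cfg = SyntheticConfig(n_traces=500, seed=3)
    ts, plans = generate_trace_set(cfg)
    return ts, plans, cfg


@pytest.fixture(scope="session")
def archetype_sets():
    """Two conformational archetypes (distinct planted boundary positions)."""
    cfg_a = SyntheticConfig(
        n_traces=200, boundary_model="preferred", preferred_boundary=9,
        preferred_prob=1.0, n_domains_range=(2, 2), seed=5,
    )
    cfg_b = SyntheticConfig(
        n_traces=200, boundary_model="preferred", preferred_boundary=19,
        preferred_prob=1.0, n_domains_range=(2, 2), seed=6,
    )
    ts_a, _ = generate_trace_set(cfg_a)
    ts_b, _ = generate_trace_set(cfg_b)
    from dataclasses import replace

    traces = [replace(t, trace_id=f"a_{t.trace_id}") for t in ts_a] + [
        replace(t, trace_id=f"b_{t.trace_id}") for t in ts_b
    ]
    merged = TraceSet(ts_a.region, traces)
    archetype = np.array([0] * len(ts_a) + [1] * len(ts_b))
    return merged, archetype
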