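"""Synthetic chromatin-trace generator with planted single-cell domains.

Emulates the phenomenology the analyses consume: each simulated chromosome
copy carries its own partition of the 28-locus region into a few compact
domains, domains are mutually displaced in space, localizations carry
Gaussian error, and loci drop out at a fixed detection efficiency.  Two
boundary-placement regimes mirror the two X-chromosome states:

* ``uniform`` — boundary positions drawn uniformly along the region
  (Xi-like: boundaries spread out, no preferred ensemble boundary);
* ``preferred`` — with probability ``preferred_prob`` one boundary sits at
  a fixed locus (Xa-like: single-cell boundaries pile up at the ensemble
  TAD boundary).

The polymer model is a hierarchical random walk (domain centers on a
coarse walk, loci on a fine walk recentred on their domain), not a
mechanistic loop-extrusion or binder simulation; it reproduces the
distance-matrix block structure the statistics operate on, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ChromatinTrace, GenomicRegion, TraceSet

__all__ = [
    "SyntheticConfig",
    "DomainPlan",
    "sample_domain_plan",
    "generate_trace",
    "generate_trace_set",
    "generate_intensities",
    "generate_pseudo_hic",
]


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults describe a 28-locus, 840-kb-like region with 1–4 domains per
    copy (single-cell domain number varies from copy to copy, and that
    variability is what couples contacts within a trace), ~50-nm
    intra-domain bond length, ~800-nm displacement between domain
    centers, 50-nm localization error, and 95% per-locus detection
    efficiency — magnitudes matching reported chromatin-tracing data at
    30-kb resolution.
    """

    n_traces: int = 500
    n_loci: int = 28
    boundary_model: str = "preferred"  # "preferred" (Xa-like) or "uniform" (Xi-like)
    preferred_boundary: int = 14
    preferred_prob: float = 0.7
    n_domains_range: tuple[int, int] = (1, 4)
    intra_step_nm: float = 50.0
    domain_sep_nm: float = 800.0
    loc_error_nm: float = 50.0
    detection_eff: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        for name in ("preferred_prob", "detection_eff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("intra_step_nm", "domain_sep_nm", "loc_error_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.n_domains_range
        if not 1 <= lo <= hi:
            raise ValueError("n_domains_range must satisfy 1 <= min <= max")
        if self.boundary_model not in ("uniform", "preferred"):
            raise ValueError("boundary_model must be 'uniform' or 'preferred'")
        if self.boundary_model == "preferred" and not 1 <= self.preferred_boundary <= self.n_loci - 1:
            raise ValueError("preferred_boundary must be in [1, n_loci-1]")


@dataclass(frozen=True)
class DomainPlan:
    """Planted domain partition of one trace.

    ``boundaries`` are start-of-domain locus indices, strictly increasing
    within [1, n_loci-1]; an empty tuple means a single domain.
    """

    boundaries: tuple[int, ...]
    n_loci: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(not 1 <= x <= self.n_loci - 1 for x in b):
            raise ValueError("boundaries must lie in [1, n_loci-1]")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_domains(self) -> int:
        return len(self.boundaries) + 1

    def domain_of(self) -> np.ndarray:
        """Domain label of every locus."""
        labels = np.zeros(self.n_loci, dtype=int)
        for b in self.boundaries:
            labels[b:] += 1
        return labels


def sample_domain_plan(config: SyntheticConfig, rng: np.random.Generator) -> DomainPlan:
    """Draw a per-trace domain partition under the configured regime."""
    lo, hi = config.n_domains_range
    n_domains = int(rng.integers(lo, hi + 1))
    n_boundaries = n_domains - 1
    positions = np.arange(1, config.n_loci)
    if n_boundaries > positions.size:
        raise ValueError(
            f"{n_domains} domains need {n_boundaries} boundaries but only "
            f"{positions.size} positions exist"
        )
    if n_boundaries == 0:
        return DomainPlan((), config.n_loci)
    chosen: list[int] = []
    if config.boundary_model == "preferred" and rng.random() < config.preferred_prob:
        chosen.append(config.preferred_boundary)
    remaining = [p for p in positions if p not in chosen]
    extra = n_boundaries - len(chosen)
    if extra > 0:
        chosen.extend(rng.choice(remaining, size=extra, replace=False).tolist())
    return DomainPlan(tuple(sorted(int(c) for c in chosen[:n_boundaries])), config.n_loci)


def generate_trace(
    plan: DomainPlan,
    config: SyntheticConfig,
    rng: np.random.Generator,
    trace_id: str = "t0",
    **trace_kwargs,
) -> ChromatinTrace:
    """Realize one trace from a domain plan.

    Draw order is fixed (domain centers, then intra-domain walks, then
    localization noise, then dropout) so that a given RNG state always
    yields the same trace.
    """
    labels = plan.domain_of()
    n_dom = plan.n_domains
    # domain centers: 3-D walk with step length ~ N(domain_sep_nm, domain_sep_nm/4)
    centers = np.zeros((n_dom, 3))
    for d in range(1, n_dom):
        length = abs(rng.normal(config.domain_sep_nm, config.domain_sep_nm / 4))
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        centers[d] = centers[d - 1] + length * direction
    # intra-domain random walks, recentred on the domain center
    coords = np.zeros((plan.n_loci, 3))
    for d in range(n_dom):
        loci = np.flatnonzero(labels == d)
        steps = rng.normal(0.0, config.intra_step_nm / np.sqrt(3), size=(loci.size, 3))
        walk = np.cumsum(steps, axis=0)
        coords[loci] = centers[d] + walk - walk.mean(axis=0)
    coords = coords + rng.normal(0.0, config.loc_error_nm, size=coords.shape)
    observed = rng.random(plan.n_loci) < config.detection_eff
    out = np.where(observed[:, None], coords, np.nan)
    return ChromatinTrace(trace_id=trace_id, coords=out, observed=observed, **trace_kwargs)


def generate_trace_set(
    config: SyntheticConfig,
    region: GenomicRegion | None = None,
    condition: str = "control",
) -> tuple[TraceSet, list[DomainPlan]]:
    """Generate ``config.n_traces`` traces plus their ground-truth plans.

    A single RNG stream seeded from ``config.seed`` is consumed in a fixed
    per-trace order, so the first k traces are identical regardless of
    ``n_traces``.
    """
    if region is None:
        region = GenomicRegion(
            "chrX", 0, 30_000 * config.n_loci, 30_000, assembly="synthetic"
        )
    if region.n_loci != config.n_loci:
        raise ValueError("region n_loci must match config.n_loci")
    rng = np.random.default_rng(config.seed)
    traces, plans = [], []
    for i in range(config.n_traces):
        plan = sample_domain_plan(config, rng)
        trace = generate_trace(
            plan, config, rng,
            trace_id=f"sim{i:05d}", cell_id=f"cell{i // 2:05d}", condition=condition,
        )
        traces.append(trace)
        plans.append(plan)
    ts = TraceSet(region, traces, provenance=f"synthetic(seed={config.seed})")
    return ts, plans


def generate_intensities(
    trace_set: TraceSet,
    rng: np.random.Generator,
    xi_fraction: float = 0.5,
    mode_lo: float = 100.0,
    mode_hi: float = 1000.0,
    sd: float = 50.0,
) -> tuple[TraceSet, dict[str, str]]:
    """Attach bimodal marker intensities with hidden Xa/Xi ground truth.

    Each trace is Xi with probability ``xi_fraction`` and draws its
    intensity from the corresponding Gaussian mode, truncated at 0.
    Returns the new set (alleles left ``"unknown"``) and the hidden
    trace_id -> allele map for scoring.
    """
    traces, truth = [], {}
    for t in trace_set:
        is_xi = rng.random() < xi_fraction
        mean = mode_hi if is_xi else mode_lo
        intensity = max(0.0, float(rng.normal(mean, sd)))
        truth[t.trace_id] = "Xi" if is_xi else "Xa"
        traces.append(replace(t, marker_intensity=intensity))
    return TraceSet(trace_set.region, traces, trace_set.provenance), truth


def generate_pseudo_hic(trace_set: TraceSet, contact_threshold_nm: float = 200.0) -> np.ndarray:
    """Contact-count matrix from traces: pairs within threshold, both observed.

    ``count[i, j]`` is the number of traces in which loci i and j are both
    detected and within ``contact_threshold_nm``; the diagonal counts
    traces in which the locus is detected.
    """
    n = trace_set.region.n_loci
    counts = np.zeros((n, n), dtype=int)
    for t in trace_set:
        obs = t.observed
        d = np.linalg.norm(t.coords[:, None, :] - t.coords[None, :, :], axis=-1)
        pair_ok = obs[:, None] & obs[None, :]
        contact = pair_ok & (d <= contact_threshold_nm)
        np.fill_diagonal(contact, False)
        counts += contact.astype(int)
        counts[np.diag_indices(n)] += obs.astype(int)
    return counts
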