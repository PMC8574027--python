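# tadtrace

Analysis of **chromatin tracing** data — 3-D coordinates of consecutive
30-kb genomic segments in single chromosome copies, measured by
multiplexed sequential DNA FISH — focused on **TAD-like single-cell
domains**: self-interacting chromatin domains that are visible in a
single copy's spatial distance matrix but whose boundary positions vary
from copy to copy.  The package is written for spatial-genomics analysts
comparing domain structure between chromosome populations (for example
active vs. inactive X chromosomes, or drug-perturbed vs. control cells).

## What it computes

Given per-trace locus coordinates (TSV), `tadtrace` provides:

* **Boundary statistics** — per-locus start/end boundary strengths from
  pooled medians of distance-matrix columns (start L/R, end B/T over
  three 10-element columns flanking the diagonal), boundary calls at
  thresholded local maxima, per-locus boundary probabilities, boundary
  frequency (mean calls per trace), a variance-ratio F-test for profile
  uniformity, and Welch t-tests with Benjamini–Hochberg FDR for
  condition comparisons.
* **Triplet cooperativity** — for every ordered locus triplet A<B<C the
  unconditional contact probability P(BC) and the conditional
  probabilities P(BC|AB), P(BC|¬AB) at a 200-nm contact threshold.
* **Compaction** — radius of gyration
  Rg = √(Σᵢ‖rᵢ−r_c‖²/N) over detected loci, with box summaries
  (1.5×IQR outlier fences) and group comparisons.
* **Ensemble structures** — population mean distance matrices, 5-kb→30-kb
  Hi-C binning, the distance–contact power law freq ∝ d⁻ᵏ fitted in
  log-log space, and ensemble TAD boundary localization.
* **Conformational clustering** — Louvain–Jaccard clustering of traces on
  their pairwise-distance profiles, cluster composition tables, and
  t-SNE display embedding.
* **Synthetic data** — a seeded generator of trace sets with planted
  domain partitions, marker intensities and pseudo-Hi-C, used as ground
  truth throughout the test suite.

See `docs/methods.md` for the full model and parameter description.

## Worked example

```python
import numpy as np
import tadtrace as tt

# Xa-like synthetic population: 500 copies of a 28-locus region whose
# main domain boundary sits at locus 14 in 70% of copies
cfg = tt.SyntheticConfig(n_traces=500, boundary_model="preferred",
                         preferred_boundary=14, preferred_prob=0.7, seed=11)
traces, plans = tt.generate_trace_set(cfg)

stats = tt.boundary_probability_profile(traces)          # >=23-locus filter,
print(int(np.argmax(stats.boundary_prob)))               # interpolation inside
# 14    <- boundary probability peaks at the planted boundary

freq, sd, by_condition = tt.boundary_frequency(traces)
print(round(freq, 2), round(sd, 2))
# 6.37 1.35    <- boundary calls per trace at the default 1.2 threshold

# Xi-like population: boundaries spread uniformly along the region
xi, _ = tt.generate_trace_set(tt.SyntheticConfig(n_traces=500,
                                                 boundary_model="uniform",
                                                 seed=1011))
F, p = tt.uniformity_ftest(tt.boundary_probability_profile(xi), stats)
print(round(F, 2), f"{p:.1e}")
# 0.32 4.4e-03    <- F < 1: the Xi-like profile is the more uniform one

mean_dist, support = tt.mean_distance_matrix(traces)
print(tt.ensemble_boundary(mean_dist)[0])
# 14    <- the ensemble boundary matches the preferred single-cell boundary
```

The same stages are available from the command line:

```sh
tadtrace simulate --n-traces 500 --seed 11 --out-dir sim/
tadtrace boundaries --traces sim/traces.tsv --group-by allele --out-dir out/
tadtrace full-pipeline --traces sim/traces.tsv --out-dir out/
```

Every run writes a `manifest.json` echoing the resolved configuration.

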