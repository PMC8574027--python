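"""Triplet conditional-contact analysis of chromatin interaction cooperativity.

Two loci are "in contact" when their spatial distance is at or below a
threshold (200 nm by default).  For every ordered triplet A < B < C of
loci (5' to 3'), three probabilities are compared across traces:

* P(BC)       — fraction of traces with a B–C contact, among traces with
  both B and C detected;
* P(BC | AB)  — the same fraction among traces with A, B, C detected and
  an A–B contact;
* P(BC | ¬AB) — among traces with A, B, C detected and no A–B contact.

Cooperativity of domain-forming interactions shows as P(BC|AB) sitting
systematically above P(BC), which in turn sits above P(BC|¬AB).  Only
detected loci enter the analysis; no interpolated coordinates are used,
so on incomplete data the three probabilities have different denominators
(the unconditional one does not require A detected).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ChromatinTrace, TraceSet

__all__ = [
    "binary_contacts",
    "triplet_probabilities",
    "triplet_probabilities_from_contacts",
    "shuffled_contact_null",
    "cooperativity_summary",
    "DEFAULT_CONTACT_NM",
]

DEFAULT_CONTACT_NM = 200.0


def binary_contacts(trace: ChromatinTrace, threshold_nm: float = DEFAULT_CONTACT_NM) -> np.ndarray:
    """Contact matrix of one trace: 1/0 where both loci observed, NaN otherwise.

    The diagonal is 1 wherever the locus is observed (zero self-distance).
    """
    d = np.linalg.norm(trace.coords[:, None, :] - trace.coords[None, :, :], axis=-1)
    out = np.full_like(d, np.nan)
    pair_ok = trace.observed[:, None] & trace.observed[None, :]
    with np.errstate(invalid="ignore"):
        out[pair_ok] = (d[pair_ok] <= threshold_nm).astype(float)
    return out


def triplet_probabilities(
    trace_set: TraceSet, threshold_nm: float = DEFAULT_CONTACT_NM
) -> pd.DataFrame:
    """Unconditional and conditional B–C contact probabilities per triplet.

    Returns one row per ordered triplet (a < b < c) with columns
    ``p_bc``, ``p_bc_given_ab``, ``p_bc_given_not_ab`` and the supporting
    counts (``n_bc_den``: traces with B,C detected; ``n_ab`` / ``n_not_ab``:
    traces with A,B,C detected and A–B contact / no contact).  Empty
    conditioning sets give NaN, never 0.
    """
    if len(trace_set) == 0:
        raise ValueError("empty trace set")
    contact = np.stack([binary_contacts(t, threshold_nm) for t in trace_set])  # (T, n, n)
    return triplet_probabilities_from_contacts(contact, threshold_nm)


def triplet_probabilities_from_contacts(
    contact: np.ndarray, threshold_nm: float = DEFAULT_CONTACT_NM
) -> pd.DataFrame:
    """Triplet table from a stacked (n_traces, n, n) contact array.

    Entries are 1/0 for contact/no-contact and NaN where either locus was
    undetected, as produced by :func:`binary_contacts`.
    """
    n = contact.shape[1]
    rows = []
    for a in range(n - 2):
        for b in range(a + 1, n - 1):
            ab = contact[:, a, b]  # (T,)
            for c in range(b + 1, n):
                bc = contact[:, b, c]
                det_bc = ~np.isnan(bc)
                n_bc_den = int(det_bc.sum())
                p_bc = float(bc[det_bc].mean()) if n_bc_den else np.nan
                trip = det_bc & ~np.isnan(ab)
                with_ab = trip & (ab == 1.0)
                without_ab = trip & (ab == 0.0)
                n_ab = int(with_ab.sum())
                n_not = int(without_ab.sum())
                rows.append(
                    {
                        "a": a,
                        "b": b,
                        "c": c,
                        "p_bc": p_bc,
                        "p_bc_given_ab": float(bc[with_ab].mean()) if n_ab else np.nan,
                        "p_bc_given_not_ab": float(bc[without_ab].mean()) if n_not else np.nan,
                        "n_bc_den": n_bc_den,
                        "n_bc": int(np.nansum(bc[det_bc])),
                        "n_ab": n_ab,
                        "n_not_ab": n_not,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["threshold_nm"] = threshold_nm
    return out


def shuffled_contact_null(
    contact: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independence null: permute each locus pair's contacts across traces.

    Every pair (i, j) keeps its marginal contact frequency, but the
    pairing of contacts within a trace is destroyed, so conditional and
    unconditional B–C probabilities coincide in expectation.  (Permuting
    locus *coordinates* across traces is not an independence null: two
    contacts sharing locus B remain coupled through B's position and the
    source trace's overall compaction.)
    """
    out = contact.copy()
    n = contact.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            perm = rng.permutation(contact.shape[0])
            out[:, i, j] = contact[perm, i, j]
            out[:, j, i] = out[:, i, j]
    return out


def cooperativity_summary(table: pd.DataFrame) -> dict:
    """Order triplets by unconditional probability and summarize cooperativity.

    Returns the three probability series sorted ascending by ``p_bc``
    (the display convention for the triplet-index plots) plus the
    fractions of triplets, among those where both terms are defined, with
    P(BC|AB) > P(BC) and with P(BC) > P(BC|¬AB).
    """
    ordered = table.sort_values("p_bc", kind="mergesort").reset_index(drop=True)
    both_ab = ordered["p_bc_given_ab"].notna() & ordered["p_bc"].notna()
    both_not = ordered["p_bc_given_not_ab"].notna() & ordered["p_bc"].notna()
    frac_ab = (
        float((ordered.loc[both_ab, "p_bc_given_ab"] > ordered.loc[both_ab, "p_bc"]).mean())
        if both_ab.any()
        else np.nan
    )
    frac_not = (
        float((ordered.loc[both_not, "p_bc"] > ordered.loc[both_not, "p_bc_given_not_ab"]).mean())
        if both_not.any()
        else np.nan
    )
    return {
        "ordered": ordered,
        "p_bc": ordered["p_bc"].to_numpy(),
        "p_bc_given_ab": ordered["p_bc_given_ab"].to_numpy(),
        "p_bc_given_not_ab": ordered["p_bc_given_not_ab"].to_numpy(),
        "frac_conditional_above_unconditional": frac_ab,
        "frac_unconditional_above_not_ab": frac_not,
    }
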