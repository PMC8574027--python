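"""Boundary strengths, calls, probabilities, F-test and condition comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from tadtrace import (
    boundary_frequency,
    boundary_probability_profile,
    boundary_strengths,
    call_boundaries,
    compare_conditions,
    uniformity_ftest,
)
from tadtrace.boundaries import BoundaryAnalysis, BoundaryProfile, BoundaryStats
from tadtrace.core import TraceSet

from conftest import make_trace, two_block_matrix


def oracle_strengths(m, window=10, n_cols=3):
    """Element-by-element re-implementation of the pooled-median definitions.

    Written with explicit loops and python lists, independent of the
    package's vectorized code path.
    """
    import statistics

    n = len(m)
    start = [float("nan")] * n
    end = [float("nan")] * n
    for i in range(n):

        def below(cols):
            pool = []
            for j in cols:
                if 0 <= j < n:
                    for r in range(j + 1, j + 1 + window):
                        if r < n:
                            pool.append(m[r][j])
            return pool

        def above(cols):
            pool = []
            for j in cols:
                if 0 <= j < n:
                    for r in range(j - window, j):
                        if r >= 0:
                            pool.append(m[r][j])
            return pool

        L = below(range(i - n_cols, i))
        R = below(range(i, i + n_cols))
        T = above(range(i - n_cols + 1, i + 1))
        B = above(range(i + 1, i + n_cols + 1))
        if L and R:
            start[i] = statistics.median(L) / statistics.median(R)
        if T and B:
            end[i] = statistics.median(B) / statistics.median(T)
    return np.array(start), np.array(end)


def random_symmetric_matrix(rng, n=28):
    a = rng.uniform(10, 2000, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestBoundaryStrengths:
    def test_constant_matrix_all_strengths_one(self):
        m = np.full((28, 28), 500.0)
        np.fill_diagonal(m, 0)
        prof = boundary_strengths(m)
        defined = np.isfinite(prof.start_strength)
        assert np.allclose(prof.start_strength[defined], 1.0)
        defined_e = np.isfinite(prof.end_strength)
        assert np.allclose(prof.end_strength[defined_e], 1.0)

    def test_edge_loci_undefined(self):
        m = random_symmetric_matrix(np.random.default_rng(0))
        prof = boundary_strengths(m)
        assert np.isnan(prof.start_strength[0])  # no columns left of locus 0
        assert np.isnan(prof.end_strength[-1])  # no columns right of last locus

    def test_two_block_matrix_peaks_at_split(self):
        m = two_block_matrix()
        prof = boundary_strengths(m)
        assert np.nanargmax(prof.start_strength) == 14
        assert np.nanargmax(prof.end_strength) == 13
        exp_start, exp_end = oracle_strengths(m.tolist())
        np.testing.assert_allclose(prof.start_strength, exp_start, equal_nan=True)
        np.testing.assert_allclose(prof.end_strength, exp_end, equal_nan=True)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_literal_oracle(self, seed):
        m = random_symmetric_matrix(np.random.default_rng(seed))
        prof = boundary_strengths(m)
        exp_start, exp_end = oracle_strengths(m.tolist())
        np.testing.assert_allclose(prof.start_strength, exp_start, equal_nan=True)
        np.testing.assert_allclose(prof.end_strength, exp_end, equal_nan=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_mirror_symmetry(self, seed):
        m = random_symmetric_matrix(np.random.default_rng(100 + seed))
        rev = m[::-1, ::-1]
        prof = boundary_strengths(m)
        prof_rev = boundary_strengths(rev)
        np.testing.assert_allclose(
            prof_rev.start_strength, prof.end_strength[::-1], equal_nan=True
        )
        np.testing.assert_allclose(
            prof_rev.end_strength, prof.start_strength[::-1], equal_nan=True
        )

    def test_scale_invariance(self):
        m = random_symmetric_matrix(np.random.default_rng(5))
        p1 = boundary_strengths(m)
        p2 = boundary_strengths(m * 7.3)
        np.testing.assert_allclose(p1.start_strength, p2.start_strength, equal_nan=True)
        np.testing.assert_allclose(p1.end_strength, p2.end_strength, equal_nan=True)


class TestCallBoundaries:
    def _profile(self, start, end=None):
        start = np.asarray(start, float)
        end = start.copy() if end is None else np.asarray(end, float)
        return BoundaryProfile(start, end)

    def test_single_peak(self):
        calls = call_boundaries(self._profile([1, 1, 3, 1, 1]), threshold=2.0)
        assert calls.start_loci == [2]

    def test_flat_profile_no_calls(self):
        calls = call_boundaries(self._profile([2.0] * 8), threshold=0.5)
        assert calls.start_loci == [] and calls.end_loci == []

    def test_below_threshold_not_called(self):
        calls = call_boundaries(self._profile([1, 1, 1.5, 1, 1]), threshold=2.0)
        assert calls.start_loci == []

    def test_plateau_leftmost_wins(self):
        calls = call_boundaries(self._profile([1, 3, 3, 1, 1]), threshold=2.0)
        assert calls.start_loci == [1]

    def test_nan_neighbors_skipped(self):
        calls = call_boundaries(
            self._profile([np.nan, 1, 3, np.nan, 1]), threshold=2.0
        )
        assert calls.start_loci == [2]

    def test_two_block_single_start_call(self):
        prof = boundary_strengths(two_block_matrix())
        calls = call_boundaries(prof, threshold=2.0)
        assert calls.start_loci == [14]
        assert calls.end_loci == [13]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_boundaries(self._profile([1, 2, 1]), threshold=0.0)


def _block_trace(split, trace_id, rng, sep=900.0, spread=5.0):
    """Trace with two tight domains split at ``split``."""
    coords = rng.normal(0, spread, size=(28, 3))
    coords[split:] += np.array([sep, 0, 0])
    return make_trace(coords, trace_id=trace_id)


class TestBoundaryStats:
    def test_call_fraction(self, region28):
        rng = np.random.default_rng(0)
        traces = [_block_trace(14, "a", rng), make_trace(rng.normal(0, 30, (28, 3)), trace_id="b")]
        st = boundary_probability_profile(TraceSet(region28, traces), threshold=2.0)
        assert st.start_prob[14] == pytest.approx(0.5)

    def test_probabilities_in_unit_interval_and_identity(self, xa_like_set):
        ba = BoundaryAnalysis().fit(xa_like_set[0])
        st = ba.stats_
        assert ((st.start_prob >= 0) & (st.start_prob <= 1)).all()
        assert np.allclose(st.boundary_prob, (st.start_prob + st.end_prob) / 2)
        # counting identity: summed start probability = mean start calls/trace
        mean_start_calls = np.mean([len(c.start_loci) for c in ba.calls_])
        assert st.start_prob.sum() == pytest.approx(mean_start_calls)

    def test_recovery_argmax_at_planted_boundary(self, xa_like_set):
        st = boundary_probability_profile(xa_like_set[0])
        assert int(np.argmax(st.boundary_prob)) == 14

    def test_empty_set_rejected(self, region28):
        with pytest.raises(ValueError):
            boundary_probability_profile(TraceSet(region28, []))


class TestBoundaryFrequency:
    def test_mean_over_traces(self, region28):
        # deterministic two-domain trace: one start and one end call
        coords = np.zeros((28, 3))
        coords[:, 0] = 2.0 * np.arange(28)
        coords[14:, 0] += 900
        t1 = make_trace(coords, trace_id="a")
        freq, sd, table = boundary_frequency(TraceSet(region28, [t1]), threshold=5.0)
        assert freq == pytest.approx(2.0)

    def test_equals_mean_of_per_trace_calls(self, xa_like_set):
        ba = BoundaryAnalysis().fit(xa_like_set[0])
        freq, _, _ = boundary_frequency(xa_like_set[0])
        assert freq == pytest.approx(np.mean([c.n_calls for c in ba.calls_]))

    def test_single_domain_high_threshold_near_zero(self):
        from tadtrace import SyntheticConfig, generate_trace_set

        cfg = SyntheticConfig(n_traces=50, n_domains_range=(1, 1), seed=21)
        ts, _ = generate_trace_set(cfg)
        freq, _, _ = boundary_frequency(ts, threshold=3.0)
        assert freq < 0.5

    def test_invariant_under_reordering(self, xa_like_set):
        ts = xa_like_set[0]
        rev = TraceSet(ts.region, list(ts.traces)[::-1])
        f1, _, _ = boundary_frequency(ts)
        f2, _, _ = boundary_frequency(rev)
        assert f1 == pytest.approx(f2)


class TestUniformityFTest:
    def _stats(self, prob):
        prob = np.asarray(prob, float)
        return BoundaryStats(prob, prob, n_traces=100)

    def test_identical_profiles(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 28)
        f, pval = uniformity_ftest(self._stats(p), self._stats(p))
        assert f == pytest.approx(1.0)
        assert pval == pytest.approx(1.0)

    def test_known_variance_ratio_against_distribution_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 28)
        base = (base - base.mean()) / base.std(ddof=1)
        a = 0.5 + 0.2 * base * 2  # variance 4 * 0.04
        b = 0.5 + 0.2 * base      # variance 0.04
        f, pval = uniformity_ftest(self._stats(a), self._stats(b))
        assert f == pytest.approx(4.0)
        expected = 2 * min(sps.f.cdf(4.0, 27, 27), sps.f.sf(4.0, 27, 27))
        assert pval == pytest.approx(expected)

    def test_swap_inverts_f_preserves_p(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 1, 28), rng.uniform(0, 1, 28)
        f1, p1 = uniformity_ftest(self._stats(a), self._stats(b))
        f2, p2 = uniformity_ftest(self._stats(b), self._stats(a))
        assert f1 == pytest.approx(1 / f2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            uniformity_ftest(self._stats(np.ones(28)), self._stats(np.ones(28)))

    def test_xi_more_uniform_than_xa(self, xa_like_set, xi_like_set):
        xa = boundary_probability_profile(xa_like_set[0])
        xi = boundary_probability_profile(xi_like_set[0])
        f, p = uniformity_ftest(xi, xa)
        assert f < 1
        assert p < 0.05


class TestCompareConditions:
    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        out = compare_conditions({"a": x, "b": x.copy()})
        assert out["p_adj"].iloc[0] > 0.9

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        groups = {
            "control": rng.normal(0, 1, 100),
            "shifted": rng.normal(10, 1, 100),
            "same": rng.normal(0, 1, 100),
        }
        out = compare_conditions(groups, reference="control")
        row = out[out["group_b"] == "shifted"].iloc[0]
        assert row["p_adj"] < 1e-3

    def test_bh_adjustment_matches_hand_computation(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 40) for i in range(4)}
        out = compare_conditions(groups)
        # independent step-up BH on the reported raw p-values
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * m / (rank + 1))
            adj[idx] = running
        np.testing.assert_allclose(out["p_adj"].to_numpy(), adj, rtol=1e-12)
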