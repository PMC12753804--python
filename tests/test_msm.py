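"""MSM estimator oracles: clustering, counting, reversible MLE, timescales,
CK test, PCCA+, MFPTs and pathway decomposition."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from translokit.msm import (CountMatrix, TransitionMatrix, ck_test,
                            count_matrix, decompose_pathway,
                            estimate_reversible_T, implied_timescales,
                            kmeans_cluster, markov_mfpt, mfpt_and_rates,
                            pcca_coarse_grain, select_n_macrostates,
                            stationary_distribution)


class TestKMeans:
    def test_two_clear_clusters(self):
        Y = np.array([0.0, 0.1, 10.0, 10.1])
        m = kmeans_cluster(Y, 2, seed=0)
        centers = np.sort(m.centers.ravel())
        assert np.allclose(centers, [0.05, 10.05])

    def test_k_equals_n_gives_zero_variance(self, rng):
        Y = rng.normal(size=(8, 2))
        m = kmeans_cluster(Y, 8, seed=0)
        assert np.allclose(np.sort(m.centers, axis=0),
                           np.sort(Y, axis=0))

    def test_seeded_determinism(self, rng):
        Y = rng.normal(size=(500, 3))
        a = kmeans_cluster(Y, 10, seed=7)
        b = kmeans_cluster(Y, 10, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 1)), 5, seed=0)


class TestCountMatrix:
    def test_hand_counted_example(self):
        c = count_matrix([0, 1, 0, 1], 1)
        assert np.array_equal(c.C, [[0, 2], [1, 0]])

    def test_lag_longer_than_sequence(self):
        with pytest.raises(ValueError):
            count_matrix([0, 1], 5)

    def test_multiple_trajectories_are_additive(self):
        a, b = [0, 1, 1, 0], [1, 1, 0, 0]
        combined = count_matrix([a, b], 1).C
        assert np.array_equal(combined,
                              count_matrix(a, 1).C + count_matrix(b, 1).C)


class TestReversibleEstimation:
    def test_symmetric_counts_closed_form(self):
        C = np.array([[90, 10], [10, 90]])
        tm = estimate_reversible_T(C)
        assert np.allclose(tm.T, [[0.9, 0.1], [0.1, 0.9]], atol=1e-10)
        assert np.allclose(tm.pi, [0.5, 0.5], atol=1e-10)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_detailed_balance_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(1, 50, size=(5, 5))
        tm = estimate_reversible_T(C)
        flux = tm.pi[:, None] * tm.T
        assert np.max(np.abs(flux - flux.T)) < 1e-8
        assert np.allclose(tm.T.sum(1), 1.0, atol=1e-10)

    def test_disconnected_blocks_trimmed(self, caplog):
        C = np.zeros((4, 4), dtype=int)
        C[:2, :2] = [[5, 5], [5, 5]]
        C[2:, 2:] = [[50, 50], [50, 50]]
        with caplog.at_level("WARNING"):
            tm = estimate_reversible_T(C)
        assert list(tm.active) == [2, 3]
        assert "trimming" in caplog.text

    def test_pi_is_left_eigenvector(self):
        rng = np.random.default_rng(0)
        tm = estimate_reversible_T(rng.integers(1, 30, size=(6, 6)))
        assert np.allclose(tm.pi @ tm.T, tm.pi, atol=1e-9)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        tm = TransitionMatrix(T=T, pi=np.array([0.5, 0.5]))
        its = implied_timescales(tm, lag=1, dt_seconds=1.0)
        assert its.timescales[0] == pytest.approx(-1 / np.log(0.9), rel=1e-12)

    def test_identity_reports_infinite(self):
        tm = TransitionMatrix(T=np.eye(2), pi=np.array([0.5, 0.5]))
        its = implied_timescales(tm, 1, 1.0)
        assert np.isinf(its.timescales[0])

    def test_linear_scaling_with_dt(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        tm = TransitionMatrix(T=T, pi=np.array([0.5, 0.5]))
        t1 = implied_timescales(tm, 3, 1e-6).timescales[0]
        t2 = implied_timescales(tm, 3, 2e-6).timescales[0]
        assert t2 == pytest.approx(2 * t1)

    def test_negative_eigenvalue_undefined(self):
        T = np.array([[0.1, 0.9], [0.9, 0.1]])
        tm = TransitionMatrix(T=T, pi=np.array([0.5, 0.5]))
        its = implied_timescales(tm, 1, 1.0)
        assert np.isnan(its.timescales[0])


class TestMacrostateSelection:
    def test_documented_gap_example(self):
        its = _fake_its([100, 90, 80, 1, 0.9])
        assert select_n_macrostates(its, 5) == 4

    def test_all_equal_ties_to_two(self):
        assert select_n_macrostates(_fake_its([5, 5, 5, 5]), 4) == 2

    def test_single_dominant_timescale(self):
        assert select_n_macrostates(_fake_its([10, 0.1, 0.09]), 3) == 2


def _fake_its(timescales):
    from translokit.msm import ImpliedTimescales
    ts = np.asarray(timescales, dtype=float)
    return ImpliedTimescales(eigenvalues=np.exp(-1 / ts), timescales=ts,
                             lag=1, dt_seconds=1.0)


def _metastable_4state(intra=0.495, inter=0.005):
    T = np.full((4, 4), inter)
    for blk in ((0, 1), (2, 3)):
        for i in blk:
            for j in blk:
                T[i, j] = intra
    T /= T.sum(1, keepdims=True)
    return TransitionMatrix(T=T, pi=stationary_distribution(T))


class TestPCCA:
    def test_two_block_chain_matches_bruteforce_partition(self):
        tm = _metastable_4state()
        mm = pcca_coarse_grain(tm, 2)
        got = frozenset(frozenset(np.where(mm.crisp == c)[0].tolist())
                        for c in range(2))
        # brute force: the 2-partition maximizing the metastability
        # (trace of the π-weighted coarse transition matrix)
        best, best_tr = None, -np.inf
        for size in (1, 2):
            for A in combinations(range(4), size):
                B = tuple(sorted(set(range(4)) - set(A)))
                tr = 0.0
                for part in (A, B):
                    w = tm.pi[list(part)]
                    w = w / w.sum()
                    tr += float(w @ tm.T[np.ix_(part, part)].sum(1))
                if tr > best_tr:
                    best_tr, best = tr, frozenset({frozenset(A), frozenset(B)})
        assert got == best

    def test_memberships_are_a_partition_of_unity(self):
        tm = _metastable_4state()
        mm = pcca_coarse_grain(tm, 2)
        assert np.allclose(mm.chi.sum(1), 1.0, atol=1e-10)
        assert np.all(mm.chi >= 0) and np.all(mm.chi <= 1 + 1e-12)
        assert np.allclose(mm.coarse_T.sum(1), 1.0, atol=1e-10)

    def test_m_equals_k_recovers_identity(self):
        tm = _metastable_4state(intra=0.4, inter=0.1)
        mm = pcca_coarse_grain(tm, 4)
        assert sorted(mm.crisp.tolist()) == [0, 1, 2, 3]

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            pcca_coarse_grain(_metastable_4state(), 1)

    def test_coarse_weights_match_pi_mass(self):
        tm = _metastable_4state()
        mm = pcca_coarse_grain(tm, 2)
        for c in range(2):
            members = np.where(mm.crisp == c)[0]
            assert mm.weights[c] == pytest.approx(tm.pi[members].sum(),
                                                  abs=0.02)


class TestMFPT:
    def test_two_state_geometric(self):
        T = np.array([[0.9, 0.1], [0.0, 1.0]])
        m = markov_mfpt(T, [1], step_seconds=1.0)
        assert m[0] == pytest.approx(10.0)
        assert m[1] == 0.0

    def test_three_state_chain_vs_monte_carlo(self, rng):
        T = np.array([[0.8, 0.2, 0.0],
                      [0.1, 0.7, 0.2],
                      [0.0, 0.3, 0.7]])
        analytic = markov_mfpt(T, [2], 1.0)[0]
        # Monte-Carlo first-passage oracle
        n_walkers = 40_000
        state = np.zeros(n_walkers, dtype=int)
        steps = np.zeros(n_walkers)
        alive = np.ones(n_walkers, dtype=bool)
        cum = np.cumsum(T, axis=1)
        for _ in range(2000):
            if not alive.any():
                break
            u = rng.random(alive.sum())
            state[alive] = (u[:, None] > cum[state[alive]]).sum(1)
            steps[alive] += 1
            alive &= state != 2
        assert steps.mean() == pytest.approx(analytic, rel=0.02)

    def test_macrostate_aggregation_diagonal_zero(self):
        tm = _metastable_4state()
        mm = pcca_coarse_grain(tm, 2)
        res = mfpt_and_rates(mm, lag=1, dt_seconds=1.0)
        assert np.all(np.diag(res.mfpt) == 0)
        off = res.mfpt[~np.eye(2, dtype=bool)]
        assert np.all(off > 0)
        assert np.allclose(res.rates[~np.eye(2, dtype=bool)], 1 / off)


class TestPathway:
    def test_two_state_chain_has_no_traps(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        p = decompose_pathway(T, 0, 1)
        assert p.on_path == [0, 1] and p.traps == []

    def test_hand_built_graph_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        T = rng.random((5, 5)) + 0.01
        T /= T.sum(1, keepdims=True)
        got = decompose_pathway(T, 0, 4)
        # brute force over all simple paths, maximizing the probability product
        import itertools
        best, best_p = None, -1.0
        for r in range(0, 4):
            for mid in itertools.permutations([1, 2, 3], r):
                path = [0, *mid, 4]
                p = np.prod([T[a, b] for a, b in zip(path, path[1:])])
                if p > best_p:
                    best_p, best = p, path
        assert got.on_path == best

    def test_unreachable_sink_errors(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="unreachable"):
            decompose_pathway(T, 0, 1)

    def test_source_equals_sink_rejected(self):
        with pytest.raises(ValueError):
            decompose_pathway(np.eye(2), 1, 1)


class TestCKTest:
    def test_markovian_data_passes(self, rng):
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        labels = _sample_chain(T, 100_000, rng)
        tm = estimate_reversible_T(count_matrix(labels, 1).C)
        dev = ck_test(tm, labels, 1, [1, 2, 5])
        assert dev[1] == 0.0
        assert dev[2] < 0.02 and dev[5] < 0.03

    def test_non_markovian_flagged(self):
        # deterministic period-3 pattern projected on two symbols
        labels = np.tile([0, 0, 1], 4000)
        tm = estimate_reversible_T(count_matrix(labels, 1).C)
        dev = ck_test(tm, labels, 1, [2])
        assert dev[2] > 0.15


def _sample_chain(T, n, rng):
    cum = np.cumsum(T, axis=1)
    s = np.zeros(n, dtype=int)
    for t in range(1, n):
        s[t] = np.searchsorted(cum[s[t - 1]], rng.random())
    return s


class TestPermutationEquivariance:
    def test_timescales_invariant_under_relabeling(self, rng):
        C = rng.integers(1, 40, size=(6, 6))
        perm = rng.permutation(6)
        Cp = C[np.ix_(perm, perm)]
        t1 = implied_timescales(estimate_reversible_T(C), 1, 1.0).timescales
        t2 = implied_timescales(estimate_reversible_T(Cp), 1, 1.0).timescales
        assert np.allclose(t1, t2, rtol=1e-8, equal_nan=True)
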