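"""Explicit-duration HSMM: trellis, EM and decoding against enumeration."""

import numpy as np
import pytest
from scipy.stats import chisquare

from gazehsmm import hsmm
from gazehsmm.hmm import HMMParams, hmm_decode, hmm_loglik
from oracles import hsmm_enumerate, random_hsmm_params


def uniform_params(N=2, M=2, D=3):
    A = (np.ones((N, N)) - np.eye(N)) / max(N - 1, 1)
    return hsmm.HSMMParams(
        pi=np.full(N, 1 / N),
        A=A,
        B=np.full((N, M), 1 / M),
        P=np.full((N, D), 1 / D),
    )


def random_instance(rng, feasible=True):
    N = int(rng.integers(1, 4))
    M = int(rng.integers(1, 4))
    D = int(rng.integers(1, 5))
    T = int(rng.integers(1, 9))
    if feasible and N == 1:
        T = min(T, D)  # single state must complete in one segment
    params = random_hsmm_params(rng, N, M, D)
    obs = rng.integers(0, M, size=T)
    return params, obs


class TestValidate:
    def test_uniform_params_pass(self):
        hsmm.validate_params(uniform_params())

    def test_bad_row_sum_raises(self):
        p = uniform_params()
        p.A = p.A * 0.8
        with pytest.raises(ValueError, match="row"):
            hsmm.validate_params(p)

    def test_nonzero_diagonal_raises(self):
        p = uniform_params(N=2)
        p.A = np.array([[0.5, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            hsmm.validate_params(p)

    def test_negative_entry_raises(self):
        p = uniform_params()
        p.pi = np.array([1.5, -0.5])
        with pytest.raises(ValueError, match="negative"):
            hsmm.validate_params(p)

    def test_random_dirichlet_params_always_pass(self, rng):
        for _ in range(50):
            p = random_hsmm_params(
                rng, int(rng.integers(1, 5)), int(rng.integers(1, 5)), int(rng.integers(1, 6))
            )
            hsmm.validate_params(p)


class TestForward:
    def test_single_state_forced_duration(self, rng):
        # N=1, duration mass entirely on T: loglik = sum_t log b(o_t)
        T = 5
        B = np.array([[0.7, 0.3]])
        P = np.zeros((1, T))
        P[0, T - 1] = 1.0
        params = hsmm.HSMMParams(pi=[1.0], A=np.zeros((1, 1)), B=B, P=P)
        obs = rng.integers(0, 2, size=T)
        _, ll = hsmm.forward(params, hsmm.ObservationSequence(obs))
        assert ll == pytest.approx(np.log(B[0, obs]).sum(), abs=1e-12)

    def test_duration_one_reduces_to_hmm(self, rng):
        for _ in range(10):
            params = random_hsmm_params(rng, 3, 3, 1)
            obs = rng.integers(0, 3, size=8)
            seq = hsmm.ObservationSequence(obs)
            _, ll = hsmm.forward(params, seq)
            ll_hmm = hmm_loglik(HMMParams(params.pi, params.A, params.B), seq)
            assert ll == pytest.approx(ll_hmm, abs=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            params, obs = random_instance(rng)
            ll_true, _, _, _ = hsmm_enumerate(params, obs)
            _, ll = hsmm.forward(params, hsmm.ObservationSequence(obs))
            assert ll == pytest.approx(ll_true, abs=1e-9)

    def test_impossible_sequence_reports_neg_inf(self):
        params = uniform_params(N=1, M=2, D=2)  # single state, D=2
        obs = np.zeros(5, dtype=int)  # needs one segment of length 5
        _, ll = hsmm.forward(params, hsmm.ObservationSequence(obs))
        assert ll == -np.inf


class TestBackward:
    def test_t1_initialization_is_one(self):
        params = uniform_params()
        beta = hsmm.backward(params, hsmm.ObservationSequence([0]))
        assert np.allclose(beta[0], 0.0)  # log domain

    def test_alpha_beta_identity_every_t(self, rng):
        for _ in range(15):
            params, obs = random_instance(rng)
            seq = hsmm.ObservationSequence(obs)
            alpha, ll = hsmm.forward(params, seq)
            if not np.isfinite(ll):
                continue
            beta = hsmm.backward(params, seq)
            for t in range(len(obs)):
                v = np.logaddexp.reduce((alpha[t] + beta[t]).ravel())
                assert v == pytest.approx(ll, abs=1e-9)


class TestPosteriors:
    def test_rows_sum_to_one(self, rng):
        params, obs = random_instance(rng)
        post = hsmm.posteriors(params, hsmm.ObservationSequence(obs))
        assert np.allclose(post.r.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert np.all(post.r >= -1e-12) and np.all(post.r <= 1 + 1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(20):
            params, obs = random_instance(rng)
            _, r_true, _, _ = hsmm_enumerate(params, obs)
            post = hsmm.posteriors(params, hsmm.ObservationSequence(obs))
            assert np.abs(post.r - r_true).max() < 1e-9

    def test_xi_zero_on_diagonal(self, rng):
        params, obs = random_instance(rng)
        post = hsmm.posteriors(params, hsmm.ObservationSequence(obs))
        idx = np.arange(params.N)
        assert np.all(post.xi[:, idx, idx, :] == 0)

    def test_symmetric_states_have_equal_posteriors(self):
        params = uniform_params(N=2, M=2, D=3)  # fully symmetric in the states
        post = hsmm.posteriors(params, hsmm.ObservationSequence([0, 1, 0, 1]))
        occ = post.r.sum(axis=2)
        assert np.allclose(occ[:, 0], occ[:, 1], atol=1e-12)

    def test_impossible_sequence_raises(self):
        params = uniform_params(N=1, M=2, D=2)
        with pytest.raises(ValueError, match="impossible"):
            hsmm.posteriors(params, hsmm.ObservationSequence(np.zeros(5, dtype=int)))


class TestEM:
    def test_near_fixed_point_at_truth(self, rng):
        truth = random_hsmm_params(rng, 2, 3, 4)
        obs_set, _ = hsmm.simulate(truth, T=60, n_sequences=30, seed=5)
        _, trace = hsmm.em_fit(truth, obs_set, tol=1e-9, max_iter=4)
        assert trace[-1] - trace[0] < 10 * abs(trace[0]) * 1e-3

    def test_monotone_loglik(self, rng):
        truth = random_hsmm_params(rng, 3, 3, 4)
        obs_set, _ = hsmm.simulate(truth, T=40, n_sequences=8, seed=2)
        start = random_hsmm_params(rng, 3, 3, 4)
        _, trace = hsmm.em_fit(start, obs_set, tol=-np.inf, max_iter=15)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_single_state_mstep_degenerates_emission(self):
        params = uniform_params(N=1, M=3, D=4)
        obs = hsmm.ObservationSequence(np.full(4, 2))
        fitted, _ = hsmm.em_fit(params, [obs], max_iter=3)
        assert fitted.B[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_mstep_preserves_normalizations(self, rng):
        truth = random_hsmm_params(rng, 3, 4, 5)
        obs_set, _ = hsmm.simulate(truth, T=50, n_sequences=5, seed=3)
        fitted, _ = hsmm.em_fit(random_hsmm_params(rng, 3, 4, 5), obs_set, max_iter=5)
        hsmm.validate_params(fitted)  # raises on any violated constraint


class TestViterbi:
    def test_single_state_single_segment(self):
        params = uniform_params(N=1, M=2, D=6)
        path, score = hsmm.viterbi(params, hsmm.ObservationSequence([0, 1, 0]))
        assert path.segments == [(0, 0, 3)]
        assert np.all(path.states == 0)

    def test_attains_enumerated_maximum(self, rng):
        for _ in range(25):
            params, obs = random_instance(rng)
            ll_true, _, best, argmax = hsmm_enumerate(params, obs)
            path, score = hsmm.viterbi(params, hsmm.ObservationSequence(obs))
            if not np.isfinite(best):
                assert score == -np.inf
                continue
            assert score == pytest.approx(best, abs=1e-9)
            assert tuple(path.states) in argmax
            _, ll = hsmm.forward(params, hsmm.ObservationSequence(obs))
            assert score <= ll + 1e-9

    def test_duration_one_equals_hmm_viterbi(self, rng):
        for _ in range(10):
            params = random_hsmm_params(rng, 3, 3, 1)
            obs = rng.integers(0, 3, size=8)
            seq = hsmm.ObservationSequence(obs)
            path, score = hsmm.viterbi(params, seq)
            hpath, hscore = hmm_decode(HMMParams(params.pi, params.A, params.B), seq)
            assert score == pytest.approx(hscore, abs=1e-12)
            assert np.array_equal(path.states, hpath)

    def test_segments_tile_sequence(self, rng):
        params, obs = random_instance(rng)
        path, score = hsmm.viterbi(params, hsmm.ObservationSequence(obs))
        if np.isfinite(score):
            covered = sum(d for _, _, d in path.segments)
            assert covered == len(obs)
            assert all(
                a[0] != b[0] for a, b in zip(path.segments, path.segments[1:])
            )


class TestSimulate:
    def test_point_mass_params_deterministic(self):
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        P = np.zeros((2, 3))
        P[:, 2] = 1.0  # all durations 3
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        params = hsmm.HSMMParams(pi=[1.0, 0.0], A=A, B=B, P=P)
        seq, path = hsmm.simulate(params, T=12, seed=0)
        assert np.array_equal(seq.obs, [0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1])

    def test_reproducible_given_seed(self):
        params = uniform_params(N=3, M=4, D=5)
        a, _ = hsmm.simulate(params, T=50, seed=123)
        b, _ = hsmm.simulate(params, T=50, seed=123)
        assert np.array_equal(a.obs, b.obs)

    def test_duration_histogram_matches_pmf(self, rng):
        params = random_hsmm_params(rng, 2, 2, 5)
        obs_set, paths = hsmm.simulate(params, T=60, n_sequences=600, seed=11)
        for state in range(2):
            durations = [
                d
                for path in paths
                for (s, start, d) in path.segments[:-1]  # last may be truncated
                if s == state
            ]
            counts = np.bincount(durations, minlength=6)[1:6]
            expected = params.P[state] * counts.sum()
            keep = expected > 5
            _, pval = chisquare(counts[keep], expected[keep] * counts[keep].sum() / expected[keep].sum())
            assert pval > 1e-4

    def test_emission_frequencies_match_rows(self, rng):
        params = random_hsmm_params(rng, 2, 3, 4)
        obs_set, paths = hsmm.simulate(params, T=80, n_sequences=300, seed=13)
        for state in range(2):
            symbols = np.concatenate(
                [
                    seq.obs[path.states == state]
                    for seq, path in zip(obs_set, paths)
                ]
            )
            freq = np.bincount(symbols, minlength=3) / symbols.size
            assert np.abs(freq - params.B[state]).max() < 0.02


def test_discretized_normal_durations_mean_close_to_parameter():
    P = hsmm.discretized_normal_durations([10.0, 20.0], [2.0, 3.0], 60)
    d = np.arange(1, 61)
    means = P @ d
    assert means == pytest.approx([10.0, 20.0], abs=0.05)


def test_choose_max_duration_percentile():
    assert hsmm.choose_max_duration(range(1, 101), q=0.99) == 100
    assert hsmm.choose_max_duration(range(1, 101), q=0.99, cap=50) == 50
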