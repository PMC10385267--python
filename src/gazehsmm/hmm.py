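"""Discrete-emission hidden Markov model baseline.

Implements scaled forward/backward, Baum–Welch estimation and Viterbi
decoding natively so that the HSMM-vs-HMM comparison is self-contained.
Self-transitions are allowed (state dwell times are implicitly geometric),
which is exactly the restriction the explicit-duration model lifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .hsmm import ObservationSequence

__all__ = ["HMMParams", "validate_hmm_params", "hmm_loglik", "hmm_fit", "hmm_decode"]

_NEG = -np.inf


@dataclass
class HMMParams:
    """pi (N,), A (N, N) with self-transitions allowed, B (N, M)."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)

    @property
    def N(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    def to_dict(self) -> dict:
        return {
            "kind": "hmm",
            "N": self.N,
            "M": self.M,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(np.array(d["pi"], float), np.array(d["A"], float), np.array(d["B"], float))


def validate_hmm_params(params: HMMParams, tol: float = 1e-9) -> HMMParams:
    pi, A, B = params.pi, params.A, params.B
    N = pi.shape[0]
    if A.shape != (N, N) or B.shape[0] != N:
        raise ValueError("inconsistent HMM parameter shapes")
    for name, arr in (("pi", pi), ("A", A), ("B", B)):
        if np.any(arr < -tol):
            raise ValueError(f"{name} has negative entries")
    if abs(pi.sum() - 1.0) > tol:
        raise ValueError("pi must sum to 1")
    for name, arr in (("A", A), ("B", B)):
        if np.any(np.abs(arr.sum(axis=1) - 1.0) > tol):
            raise ValueError(f"rows of {name} must sum to 1")
    pi = np.clip(pi, 0, None)
    A = np.clip(A, 0, None)
    B = np.clip(B, 0, None)
    return replace(
        params,
        pi=pi / pi.sum(),
        A=A / A.sum(axis=1, keepdims=True),
        B=B / B.sum(axis=1, keepdims=True),
    )


def _scaled_forward(params: HMMParams, obs: np.ndarray):
    T, N = obs.size, params.N
    alpha = np.zeros((T, N))
    scale = np.zeros(T)
    a = params.pi * params.B[:, obs[0]]
    scale[0] = a.sum()
    if scale[0] == 0:
        return None, None, _NEG
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.A) * params.B[:, obs[t]]
        scale[t] = a.sum()
        if scale[t] == 0:
            return None, None, _NEG
        alpha[t] = a / scale[t]
    return alpha, scale, float(np.log(scale).sum())


def _scaled_backward(params: HMMParams, obs: np.ndarray, scale: np.ndarray):
    T, N = obs.size, params.N
    beta = np.zeros((T, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (params.A @ (params.B[:, obs[t + 1]] * beta[t + 1])) / scale[t + 1]
    return beta


def hmm_loglik(params: HMMParams, seq: ObservationSequence) -> float:
    """Log P(O | lambda) by the scaled forward recursion (-inf if impossible)."""
    obs = seq.obs
    if obs.max() >= params.M:
        raise ValueError("observation codes out of range")
    _, _, ll = _scaled_forward(params, obs)
    return ll


def hmm_fit(
    params0: HMMParams,
    obs_set: list[ObservationSequence],
    tol: float = 1e-6,
    max_iter: int = 100,
    emission_floor: float = 1e-10,
):
    """Classical Baum–Welch over pooled sequences; returns (params, trace)."""
    if not obs_set:
        raise ValueError("obs_set must be non-empty")
    params = validate_hmm_params(params0)
    trace: list[float] = []
    for _ in range(max_iter):
        N, M = params.N, params.M
        pi_num = np.zeros(N)
        A_num = np.zeros((N, N))
        B_num = np.zeros((N, M))
        total_ll = 0.0
        for seq in obs_set:
            obs = seq.obs
            alpha, scale, ll = _scaled_forward(params, obs)
            if not np.isfinite(ll):
                raise ValueError("observation impossible under model during EM")
            total_ll += ll
            beta = _scaled_backward(params, obs, scale)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            pi_num += gamma[0]
            np.add.at(B_num.T, obs, gamma)
            T = obs.size
            if T > 1:
                emitted = params.B[:, obs[1:]].T * beta[1:]  # (T-1, N)
                xi = alpha[:-1, :, None] * params.A[None] * emitted[:, None, :]
                xi /= scale[1:, None, None]
                A_num += xi.sum(axis=0)
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        A_sum = A_num.sum(axis=1, keepdims=True)
        dead_A = A_sum[:, 0] <= 0
        if np.any(dead_A):
            A_num[dead_A] = 1.0
            A_sum = A_num.sum(axis=1, keepdims=True)
        B_sum = B_num.sum(axis=1, keepdims=True)
        if np.any(B_sum[:, 0] <= 0):
            warnings.warn("emission row(s) lost support; flooring")
        B_num = np.maximum(B_num, emission_floor)
        params = replace(
            params,
            pi=pi_num / pi_num.sum(),
            A=A_num / A_sum,
            B=B_num / B_num.sum(axis=1, keepdims=True),
        )
    return params, trace


def hmm_decode(params: HMMParams, seq: ObservationSequence):
    """Viterbi path and its log joint probability.

    Ties are broken front-to-back toward the smallest state index, giving the
    lexicographically smallest optimal path.
    """
    obs = seq.obs
    if obs.max() >= params.M:
        raise ValueError("observation codes out of range")
    T, N = obs.size, params.N
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
        logB = np.log(params.B)
    # W[t, j]: best log prob of o_t..o_T given state j at t
    W = np.zeros((T, N))
    nxt = np.zeros((T, N), dtype=np.int64)
    W[T - 1] = logB[:, obs[T - 1]]
    nxt[T - 1] = -1
    for t in range(T - 2, -1, -1):
        vals = logA + W[t + 1][None, :]
        best = vals.max(axis=1)
        nxt[t] = vals.argmax(axis=1)
        W[t] = logB[:, obs[t]] + best
    start = logpi + W[0]
    score = float(start.max())
    if not np.isfinite(score):
        return np.zeros(0, dtype=np.int64), _NEG
    path = np.empty(T, dtype=np.int64)
    path[0] = start.argmax()
    for t in range(1, T):
        path[t] = nxt[t - 1, path[t - 1]]
    return path, score
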