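"""Explicit-duration hidden semi-Markov model (HSMM) with discrete emissions.

Model
-----
A sequence of *macro-states* is generated by a first-order Markov chain with
zero self-transition probability.  On entering state ``i`` the chain draws a
residence duration ``d`` from a per-state duration pmf ``P_i(d)``
(``1 <= d <= D``), emits ``d`` observations i.i.d. from the categorical
emission row ``b_i(.)`` (one observation per time step of residence), and then
jumps to a different state ``j`` with probability ``a_ij``.  The final segment
must complete exactly at ``T`` for the likelihood (no right-censoring); a
censored variant is selectable where noted.

The duration variable ``tau_t`` exposed in the trellis arrays is the *elapsed*
residence time of the segment active at ``t`` (the time the system has been
resident in its current state up to and including ``t``).  At ``t = T`` the
forward variable is restricted to segments completing exactly at ``T``, so
``sum_{i,d} alpha_T(i,d) = P(O | lambda)`` while ``beta_T(i,d) = 1``.

All trellis computations are carried out in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "HSMMParams",
    "ObservationSequence",
    "TrellisPosteriors",
    "DecodedPath",
    "validate_params",
    "discretized_normal_durations",
    "choose_max_duration",
    "forward",
    "backward",
    "posteriors",
    "em_fit",
    "viterbi",
    "simulate",
]

_NEG = -np.inf


def logsumexp(a, axis=None):
    """Lean log-sum-exp (scipy-compatible for the uses here, -inf safe)."""
    a = np.asarray(a, dtype=float)
    if axis is None:
        a = a.ravel()
        axis = 0
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - m_safe), axis=axis)) + np.squeeze(m_safe, axis=axis)
    m_red = np.squeeze(m, axis=axis)
    out = np.where(np.isfinite(m_red), out, m_red)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class HSMMParams:
    """Full parameter set ``lambda = (pi, A, B, P)``.

    Attributes
    ----------
    pi : (N,) initial macro-state probabilities.
    A : (N, N) macro-state transition matrix, zero diagonal.
    B : (N, M) emission matrix over the observation alphabet.
    P : (N, D) duration pmf per state, support ``d = 1..D``.
    state_labels : optional state names (e.g. ``["HP", "MP", "LP"]``).
    duration_family : ``"table"`` (free pmf rows) or ``"discretized_normal"``
        (rows kept in the family of normals discretized over ``1..D``).
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    P: np.ndarray
    state_labels: list[str] | None = None
    duration_family: str = "table"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.P = np.asarray(self.P, dtype=float)

    @property
    def N(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    @property
    def D(self) -> int:
        return self.P.shape[1]

    def to_dict(self) -> dict:
        return {
            "kind": "hsmm",
            "N": self.N,
            "M": self.M,
            "D": self.D,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "P": self.P.tolist(),
            "labels": self.state_labels,
            "duration_family": self.duration_family,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSMMParams":
        return cls(
            pi=np.array(d["pi"], float),
            A=np.array(d["A"], float),
            B=np.array(d["B"], float),
            P=np.array(d["P"], float),
            state_labels=d.get("labels"),
            duration_family=d.get("duration_family", "table"),
        )


@dataclass(frozen=True)
class ObservationSequence:
    """Integer-coded observation sequence ``o_1 .. o_T`` over ``[0, M)``."""

    obs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.obs, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("observation sequence must be 1-D and non-empty")
        object.__setattr__(self, "obs", arr)

    @property
    def T(self) -> int:
        return int(self.obs.size)

    @classmethod
    def from_symbols(cls, symbols, alphabet) -> "ObservationSequence":
        index = {s: k for k, s in enumerate(alphabet)}
        try:
            codes = [index[s] for s in symbols]
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} not in alphabet") from exc
        return cls(np.array(codes, dtype=np.int64))


@dataclass
class TrellisPosteriors:
    """Forward/backward trellis and posterior arrays for one sequence.

    ``alpha`` and ``beta`` are stored in log domain with shape (T, N, D);
    ``r`` (state/elapsed-duration posteriors) and ``xi`` (segment-end
    transition posteriors, shape (T-1, N, N, D), zero on the state diagonal)
    are probabilities.  ``sum_{i,d} r[t, i, d] == 1`` for every ``t``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    r: np.ndarray
    xi: np.ndarray
    loglik: float


@dataclass
class DecodedPath:
    """A macro-state segmentation of ``[0, T)``.

    ``segments`` is a list of ``(state, start, duration)`` tiles covering the
    sequence exactly with no two consecutive segments in the same state;
    ``states`` is the per-step state vector consistent with the tiles.
    """

    states: np.ndarray
    segments: list[tuple[int, int, int]]

    @property
    def T(self) -> int:
        return int(self.states.size)

    def dwell_steps(self, n_states: int) -> np.ndarray:
        """Total decoded time steps spent in each state."""
        out = np.zeros(n_states)
        for s, _, d in self.segments:
            out[s] += d
        return out


# ---------------------------------------------------------------------------
# validation and duration families
# ---------------------------------------------------------------------------


def validate_params(params: HSMMParams, tol: float = 1e-9) -> HSMMParams:
    """Check the stochasticity constraints and return a renormalized copy.

    Rows whose sums deviate from 1 by more than ``tol`` raise; rows within
    tolerance are renormalized exactly.  The transition diagonal must be zero
    (macro-state transitions change state).
    """
    pi, A, B, P = params.pi, params.A, params.B, params.P
    N = pi.shape[0]
    if A.shape != (N, N):
        raise ValueError(f"A must be ({N},{N}), got {A.shape}")
    if B.ndim != 2 or B.shape[0] != N:
        raise ValueError(f"B must have {N} rows")
    if P.ndim != 2 or P.shape[0] != N:
        raise ValueError(f"P must have {N} rows")
    for name, arr in (("pi", pi), ("A", A), ("B", B), ("P", P)):
        if np.any(arr < -tol):
            raise ValueError(f"{name} has negative entries")
    if np.any(np.abs(np.diag(A)) > tol):
        raise ValueError("A must have a zero diagonal (a_ii = 0)")
    if abs(pi.sum() - 1.0) > tol:
        raise ValueError(f"pi sums to {pi.sum():.6g}, expected 1")
    # N = 1: no macro-transition exists, A is the 1x1 zero matrix
    rows_to_check = (("B", B), ("P", P)) if N == 1 else (("A", A), ("B", B), ("P", P))
    for name, arr in rows_to_check:
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 1.0) > tol
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(f"row {i} of {name} sums to {sums[i]:.6g}, expected 1")
    pi = np.clip(pi, 0.0, None)
    A = np.clip(A, 0.0, None)
    np.fill_diagonal(A, 0.0)
    B = np.clip(B, 0.0, None)
    P = np.clip(P, 0.0, None)
    out = replace(
        params,
        pi=pi / pi.sum(),
        A=A if N == 1 else A / A.sum(axis=1, keepdims=True),
        B=B / B.sum(axis=1, keepdims=True),
        P=P / P.sum(axis=1, keepdims=True),
    )
    return out


def discretized_normal_durations(means, sds, D: int) -> np.ndarray:
    """Duration pmf rows from per-state normal (mean, sd), discretized on 1..D.

    Each integer duration ``d`` receives the normal mass over
    ``(d - 0.5, d + 0.5]``; rows are renormalized over the support.
    """
    means = np.atleast_1d(np.asarray(means, float))
    sds = np.atleast_1d(np.asarray(sds, float))
    if np.any(sds <= 0):
        raise ValueError("duration sds must be positive")
    d = np.arange(1, D + 1)
    upper = norm.cdf(d[None, :] + 0.5, loc=means[:, None], scale=sds[:, None])
    lower = norm.cdf(d[None, :] - 0.5, loc=means[:, None], scale=sds[:, None])
    pmf = upper - lower
    total = pmf.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("discretized normal has no mass on 1..D")
    return pmf / total


def choose_max_duration(run_lengths, q: float = 0.99, cap: int = 200) -> int:
    """Upper duration bound D: the q-quantile of observed run lengths, capped."""
    arr = np.asarray(list(run_lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("no run lengths supplied")
    return int(min(cap, max(1, np.ceil(np.quantile(arr, q)))))


# ---------------------------------------------------------------------------
# trellis internals
# ---------------------------------------------------------------------------


def _check_obs(params: HSMMParams, seq: ObservationSequence) -> np.ndarray:
    obs = seq.obs
    if obs.min() < 0 or obs.max() >= params.M:
        raise ValueError("observation codes out of range for emission alphabet")
    return obs


def _log_tables(params: HSMMParams, obs: np.ndarray):
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
        logB = np.log(params.B)
        logP = np.log(params.P)
        # survival S_i(d) = P(duration >= d)
        surv = np.cumsum(params.P[:, ::-1], axis=1)[:, ::-1]
        logS = np.log(np.clip(surv, 0.0, None))
    np.fill_diagonal(logA, _NEG)
    T = obs.size
    C = np.zeros((params.N, T + 1))
    C[:, 1:] = np.cumsum(logB[:, obs], axis=1)
    return logpi, logA, logB, logP, logS, C


def _forward_pass(params, obs, logpi, logA, logP, C):
    """Segment-end forward recursion.

    Returns ``log_ent[s, i]`` (log prob of the prefix ending with an entry
    into state ``i`` at time ``s``), ``log_endseg[t, i, d]`` (log prob of the
    prefix with a duration-``d`` segment of state ``i`` ending at ``t``),
    ``log_fend[t, i] = logsumexp_d log_endseg`` and the log-likelihood.
    """
    T, N, D = obs.size, params.N, params.D
    log_ent = np.full((T, N), _NEG)
    log_ent[0] = logpi
    log_endseg = np.full((T, N, D), _NEG)
    log_fend = np.full((T, N), _NEG)
    for t in range(T):
        dmax = min(D, t + 1)
        ds = np.arange(1, dmax + 1)
        emis = C[:, t + 1][:, None] - C[:, t + 1 - ds]  # (N, dmax)
        ent = log_ent[t + 1 - ds, :].T  # (N, dmax)
        log_endseg[t, :, :dmax] = ent + logP[:, :dmax] + emis
        log_fend[t] = logsumexp(log_endseg[t, :, :dmax], axis=1)
        if t + 1 < T:
            log_ent[t + 1] = logsumexp(log_fend[t][:, None] + logA, axis=0)
    loglik = float(logsumexp(log_fend[T - 1]))
    return log_ent, log_endseg, log_fend, loglik


def _backward_pass(params, obs, logA, logP, C):
    """Entry-conditioned backward recursion.

    Returns ``log_bent[s, j]`` (log prob of ``o_s..o_T`` with exact completion
    given entry into ``j`` at ``s``) and ``log_xend[t, i]`` (log prob of the
    suffix after a segment of ``i`` ends at ``t``; zero at ``t = T-1``).
    """
    T, N, D = obs.size, params.N, params.D
    log_bent = np.full((T, N), _NEG)
    log_xend = np.full((T, N), _NEG)
    for s in range(T - 1, -1, -1):
        if s == T - 1:
            log_xend[s] = 0.0
        else:
            log_xend[s] = logsumexp(logA + log_bent[s + 1][None, :], axis=1)
        dmax = min(D, T - s)
        ds = np.arange(1, dmax + 1)
        emis = C[:, s + ds] - C[:, s][:, None]  # (N, dmax)
        ends = s + ds - 1
        log_bent[s] = logsumexp(logP[:, :dmax] + emis + log_xend[ends, :].T, axis=1)
    return log_bent, log_xend


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def forward(params: HSMMParams, seq: ObservationSequence):
    """Forward variables ``alpha_t(i, d)`` (log domain) and the log-likelihood.

    ``alpha_t(i, d) = P(o_1..o_t, q_t = s_i, tau_t = d | lambda)`` with
    ``tau_t`` the elapsed residence time; at ``t = T`` the array is restricted
    to segments completing exactly at ``T``, so summing ``exp(alpha_T)`` over
    all ``(i, d)`` yields ``P(O | lambda)``.  A zero-probability sequence
    yields ``loglik = -inf`` (no exception).
    """
    obs = _check_obs(params, seq)
    logpi, logA, logB, logP, logS, C = _log_tables(params, obs)
    log_ent, log_endseg, _, loglik = _forward_pass(params, obs, logpi, logA, logP, C)
    T, N, D = obs.size, params.N, params.D
    alpha = np.full((T, N, D), _NEG)
    for t in range(T):
        dmax = min(D, t + 1)
        ds = np.arange(1, dmax + 1)
        emis = C[:, t + 1][:, None] - C[:, t + 1 - ds]
        ent = log_ent[t + 1 - ds, :].T
        G = logP[:, :dmax] if t == T - 1 else logS[:, :dmax]
        alpha[t, :, :dmax] = ent + emis + G
    return alpha, loglik


def backward(params: HSMMParams, seq: ObservationSequence) -> np.ndarray:
    """Backward variables ``beta_t(i, d)`` in log domain.

    ``beta_T(i, d) = 1`` for all states and durations; for ``t < T`` the value
    conditions on elapsed residence ``d`` at ``t`` and accounts for the exact
    completion of the final segment.  Together with :func:`forward`,
    ``logsumexp(alpha_t + beta_t)`` equals the log-likelihood for every ``t``.
    """
    obs = _check_obs(params, seq)
    logpi, logA, logB, logP, logS, C = _log_tables(params, obs)
    _, log_xend = _backward_pass(params, obs, logA, logP, C)
    T, N, D = obs.size, params.N, params.D
    beta = np.full((T, N, D), _NEG)
    beta[T - 1] = 0.0
    d_idx = np.arange(D)
    for t in range(T - 2, -1, -1):
        mmax = min(D - 1, T - 1 - t)
        ms = np.arange(mmax + 1)
        # residual emission + continuation term for each extra residence m
        cx = (C[:, t + 1 + ms] - C[:, t + 1][:, None]) + log_xend[t + ms, :].T  # (N, m)
        tot = d_idx[None, :, None] + ms[None, None, :]  # total-duration index d+m
        valid = tot < D
        logPd = np.where(valid, logP[np.arange(params.N)[:, None, None], np.minimum(tot, D - 1)], _NEG)
        vals = logPd + cx[:, None, :]
        num = logsumexp(vals, axis=2)
        ok = np.isfinite(logS)
        beta[t] = np.where(ok, num - np.where(ok, logS, 0.0), _NEG)
    return beta


def posteriors(params: HSMMParams, seq: ObservationSequence) -> TrellisPosteriors:
    """Full posterior trellis: ``alpha``, ``beta``, ``r`` and ``xi``.

    ``r_t(i, d) = P(q_t = s_i, tau_t = d | O, lambda)`` sums to one over
    ``(i, d)`` at every ``t``; ``xi_t(i, j, d)`` is the posterior probability
    that a duration-``d`` segment of ``i`` ends at ``t`` and the chain moves
    to ``j != i``.  Raises if the sequence has zero probability.
    """
    obs = _check_obs(params, seq)
    logpi, logA, logB, logP, logS, C = _log_tables(params, obs)
    log_ent, log_endseg, log_fend, loglik = _forward_pass(params, obs, logpi, logA, logP, C)
    if not np.isfinite(loglik):
        raise ValueError("observation impossible under model")
    log_bent, log_xend = _backward_pass(params, obs, logA, logP, C)
    alpha, _ = forward(params, seq)
    beta = backward(params, seq)
    with np.errstate(invalid="ignore"):
        r = np.exp(alpha + beta - loglik)
    r[~np.isfinite(alpha)] = 0.0
    T, N, D = obs.size, params.N, params.D
    if T > 1:
        logxi = (
            log_endseg[: T - 1, :, None, :]
            + logA[None, :, :, None]
            + log_bent[1:, None, :, None]
            - loglik
        )
        xi = np.exp(logxi)
    else:
        xi = np.zeros((0, N, N, D))
    return TrellisPosteriors(alpha=alpha, beta=beta, r=r, xi=xi, loglik=loglik)


def _scaled_forward(params, obs):
    """Scaled linear-domain forward pass.

    Maintains ``w_t(i, d)``, the joint probability that state ``i`` is active
    at ``t`` with elapsed residence ``d`` and the segment survives at least
    ``d`` steps, normalized by the running scale product ``Q_t``.  Returns
    per-step scales ``c``, segment-end arrays ``endseg_hat = EndSeg / Q_t``
    and ``fend_hat``, and the log-likelihood (``-inf`` if impossible).
    """
    T, N, D = obs.size, params.N, params.D
    b = params.B[:, obs]  # (N, T)
    c = np.zeros(T)
    endseg_hat = np.zeros((T, N, D))
    fend_hat = np.zeros((T, N))
    w = np.zeros((N, D))
    ent = params.pi
    for t in range(T):
        raw = np.zeros((N, D))
        raw[:, 0] = ent * b[:, t]
        if t > 0:
            raw[:, 1:] = w[:, :-1] * b[:, t][:, None]
        c_t = raw.sum()
        if c_t <= 0.0:
            return None, None, None, _NEG
        w = raw / c_t
        c[t] = c_t
        endseg_hat[t] = w * params.P
        fend_hat[t] = endseg_hat[t].sum(axis=1)
        ent = fend_hat[t] @ params.A
    tail = fend_hat[T - 1].sum()
    if tail <= 0.0:
        return None, None, None, _NEG
    loglik = float(np.log(c).sum() + np.log(tail))
    return c, endseg_hat, fend_hat, loglik


def _scaled_backward(params, obs, c):
    """Scaled backward pass matched to :func:`_scaled_forward`'s scales.

    Returns ``bent_hat[s, j] = Bent[s, j] / prod_{u>=s} c_u`` and
    ``xend_hat[t, i] = Xend[t, i] / prod_{u>t} c_u``.
    """
    T, N, D = obs.size, params.N, params.D
    b = params.B[:, obs]
    bent_hat = np.zeros((T, N))
    xend_hat = np.zeros((T, N))
    v = np.zeros((N, D))
    for s in range(T - 1, -1, -1):
        if s == T - 1:
            xend_hat[s] = 1.0
        else:
            xend_hat[s] = params.A @ bent_hat[s + 1]
        bb = b[:, s] / c[s]
        v_new = np.empty((N, D))
        v_new[:, 0] = bb * xend_hat[s]
        v_new[:, 1:] = bb[:, None] * v[:, :-1]
        v = v_new
        bent_hat[s] = (params.P * v).sum(axis=1)
    return bent_hat, xend_hat


def _sequence_stats(params, obs):
    """E-step sufficient statistics for one sequence (exact EM).

    Returns (loglik, pi_stat, A_stat, B_stat, P_stat) where the stats are the
    posterior-expected counts: initial-state occupancy, macro transitions,
    emission occupancy per symbol and one count per (state, total-duration)
    segment.
    """
    T, N, D = obs.size, params.N, params.D
    c, endseg_hat, fend_hat, loglik = _scaled_forward(params, obs)
    if not np.isfinite(loglik):
        raise ValueError("observation impossible under model during EM")
    bent_hat, xend_hat = _scaled_backward(params, obs, c)
    tail = fend_hat[T - 1].sum()

    # posterior segment counts U[t, i, d]: duration-d segment of i ends at t
    U = endseg_hat * xend_hat[:, :, None] / tail  # (T, N, D)
    P_stat = U.sum(axis=0)

    # per-step state occupancy via interval accumulation of segment posteriors
    diff = np.zeros((T + 1, N))
    ts = np.arange(T)
    ds = np.arange(1, D + 1)
    starts = ts[:, None] - ds[None, :] + 1  # (T, D)
    mask = starts >= 0
    flat_starts = starts[mask]
    for i in range(N):
        np.add.at(diff[:, i], flat_starts, U[:, i, :][mask])
    diff[1 : T + 1] -= U.sum(axis=2)
    gamma = np.cumsum(diff[:T], axis=0)  # (T, N), gamma[t, i] = P(q_t = i | O)

    pi_stat = gamma[0].copy()
    B_stat = np.zeros((params.M, N))
    np.add.at(B_stat, obs, gamma)
    if T > 1:
        A_stat = (fend_hat[: T - 1].T @ bent_hat[1:]) * params.A / tail
    else:
        A_stat = np.zeros((N, N))
    return loglik, pi_stat, A_stat, B_stat.T, P_stat


def em_fit(
    params0: HSMMParams,
    obs_set: list[ObservationSequence],
    tol: float = 1e-6,
    max_iter: int = 100,
    emission_floor: float = 1e-10,
    update: tuple[str, ...] = ("pi", "A", "B", "P"),
):
    """Baum–Welch (EM) estimation of the HSMM, pooled over sequences.

    Each iteration computes the exact posterior sufficient statistics
    (initial-state occupancies, macro-transition counts, emission occupancies
    and per-segment duration counts) and re-estimates pi, A, B and the
    duration pmf by row normalization.  The log-likelihood trace recorded at
    each E-step is non-decreasing up to floating point.  Emission rows that
    lose all posterior support are floored at ``emission_floor`` and
    renormalized, with a warning.

    Returns ``(fitted_params, loglik_trace)``.
    """
    if not obs_set:
        raise ValueError("obs_set must be non-empty")
    params = validate_params(params0)
    trace: list[float] = []
    for _ in range(max_iter):
        obs_list = [_check_obs(params, s) for s in obs_set]
        N, M, D = params.N, params.M, params.D
        pi_num = np.zeros(N)
        A_num = np.zeros((N, N))
        B_num = np.zeros((N, M))
        P_num = np.zeros((N, D))
        total_ll = 0.0
        for obs in obs_list:
            ll, pi_s, A_s, B_s, P_s = _sequence_stats(params, obs)
            total_ll += ll
            pi_num += pi_s
            A_num += A_s
            B_num += B_s
            P_num += P_s
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break

        def _rows(num, floor, name):
            sums = num.sum(axis=1, keepdims=True)
            dead = sums[:, 0] <= 0
            if np.any(dead):
                warnings.warn(f"{name} row(s) {np.where(dead)[0].tolist()} lost support; flooring")
                num = num + floor
                sums = num.sum(axis=1, keepdims=True)
            elif floor > 0:
                num = np.maximum(num, floor)
                sums = num.sum(axis=1, keepdims=True)
            return num / sums

        new = {}
        if "pi" in update:
            new["pi"] = pi_num / pi_num.sum()
        if "A" in update and N > 1:
            np.fill_diagonal(A_num, 0.0)
            new["A"] = _rows(A_num, 0.0 if A_num.sum() else emission_floor, "transition")
            np.fill_diagonal(new["A"], 0.0)
            new["A"] /= new["A"].sum(axis=1, keepdims=True)
        if "B" in update:
            new["B"] = _rows(B_num, emission_floor, "emission")
        if "P" in update:
            if params.duration_family == "discretized_normal":
                d = np.arange(1, D + 1)
                w = P_num / P_num.sum(axis=1, keepdims=True)
                means = (w * d).sum(axis=1)
                var = (w * d**2).sum(axis=1) - means**2
                sds = np.sqrt(np.maximum(var, 0.25))
                new["P"] = discretized_normal_durations(means, sds, D)
            else:
                new["P"] = _rows(P_num, emission_floor, "duration")
        params = replace(params, **new)
    return params, trace


def viterbi(params: HSMMParams, seq: ObservationSequence):
    """Duration-aware Viterbi decoding.

    Returns the maximum-probability macro-state segmentation and its log joint
    probability (which never exceeds the forward log-likelihood).  Exact score
    ties are broken deterministically front-to-back: smallest initial state,
    then smallest segment duration, then smallest successor state.  A
    zero-probability sequence returns an empty path with score ``-inf``.
    """
    obs = _check_obs(params, seq)
    logpi, logA, logB, logP, logS, C = _log_tables(params, obs)
    T, N, D = obs.size, params.N, params.D
    # W[s, j]: best log prob of o_s..o_T given entry into j at s (exact end at T)
    W = np.full((T, N), _NEG)
    bestd = np.zeros((T, N), dtype=np.int64)
    Xv = np.full((T, N), _NEG)
    Xk = np.zeros((T, N), dtype=np.int64)
    for s in range(T - 1, -1, -1):
        if s == T - 1:
            Xv[s] = 0.0
            Xk[s] = -1
        else:
            vals = logA + W[s + 1][None, :]
            Xv[s] = vals.max(axis=1)
            Xk[s] = vals.argmax(axis=1)  # first (smallest) argmax
        dmax = min(D, T - s)
        ds = np.arange(1, dmax + 1)
        emis = C[:, s + ds] - C[:, s][:, None]
        ends = s + ds - 1
        scores = logP[:, :dmax] + emis + Xv[ends, :].T
        W[s] = scores.max(axis=1)
        bestd[s] = scores.argmax(axis=1) + 1
    start_scores = logpi + W[0]
    total = float(start_scores.max())
    if not np.isfinite(total):
        return DecodedPath(states=np.zeros(0, dtype=np.int64), segments=[]), _NEG
    j = int(start_scores.argmax())
    segments: list[tuple[int, int, int]] = []
    s = 0
    while s < T:
        d = int(bestd[s, j])
        segments.append((j, s, d))
        e = s + d - 1
        if e == T - 1:
            break
        j = int(Xk[e, j])
        s = e + 1
    states = np.empty(T, dtype=np.int64)
    for st, start, d in segments:
        states[start : start + d] = st
    return DecodedPath(states=states, segments=segments), total


def simulate(
    params: HSMMParams,
    T: int | None = None,
    n_sequences: int | None = None,
    seed: int | np.random.Generator = 0,
):
    """Sample observation sequences and their true macro-state paths.

    Draws the initial state from ``pi``, a duration from ``P_i(.)``, ``d``
    i.i.d. emissions from ``b_i(.)``, then the next macro-state from
    ``a_i.``; the final segment is truncated at ``T``.  With ``n_sequences``
    set, returns lists; otherwise a single ``(ObservationSequence,
    DecodedPath)`` pair.  Fully reproducible given the seed.
    """
    params = validate_params(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if T is None:
        raise ValueError("T must be given")

    def _one() -> tuple[ObservationSequence, DecodedPath]:
        durations = np.arange(1, params.D + 1)
        obs = np.empty(T, dtype=np.int64)
        states = np.empty(T, dtype=np.int64)
        segments: list[tuple[int, int, int]] = []
        t = 0
        state = int(rng.choice(params.N, p=params.pi))
        while t < T:
            d = int(rng.choice(durations, p=params.P[state]))
            d_eff = min(d, T - t)
            obs[t : t + d_eff] = rng.choice(params.M, size=d_eff, p=params.B[state])
            states[t : t + d_eff] = state
            segments.append((state, t, d_eff))
            t += d_eff
            if t < T:
                state = int(rng.choice(params.N, p=params.A[state]))
        return ObservationSequence(obs), DecodedPath(states=states, segments=segments)

    if n_sequences is None:
        return _one()
    pairs = [_one() for _ in range(n_sequences)]
    return [p[0] for p in pairs], [p[1] for p in pairs]
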