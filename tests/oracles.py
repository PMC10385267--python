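"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's recursions: likelihoods and posteriors
are obtained by exhaustively enumerating macro-state segmentations, pattern
supports by enumerating candidate patterns and scanning for constrained
embeddings, fixations by a direct run-length scan.  They are only feasible at
tiny problem sizes, which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np

from gazehsmm import hsmm
from gazehsmm.cspade import MiningConstraints, SequenceDatabase


# ---------------------------------------------------------------------------
# HSMM enumeration
# ---------------------------------------------------------------------------


def compositions(T: int, D: int):
    """All ordered compositions of T into parts of size 1..D."""
    if T == 0:
        yield ()
        return
    for d in range(1, min(D, T) + 1):
        for rest in compositions(T - d, D):
            yield (d,) + rest


def hsmm_enumerate(params: hsmm.HSMMParams, obs: np.ndarray):
    """Exhaustive HSMM quantities for one observation sequence.

    Returns ``(loglik, r, best_logp, argmax_paths)`` where ``r[t, i, d]`` is
    the posterior of state ``i`` with elapsed residence ``d`` at ``t``
    (matching the package's trellis convention) and ``argmax_paths`` is the
    set of per-step state tuples attaining the maximum joint probability.
    """
    T, N, D = len(obs), params.N, params.D
    total = 0.0
    r = np.zeros((T, N, D))
    best_logp = -np.inf
    argmax: list[tuple[int, ...]] = []
    for comp in compositions(T, D):
        for states in itertools.product(range(N), repeat=len(comp)):
            if any(a == b for a, b in zip(states, states[1:])):
                continue
            p = params.pi[states[0]]
            t = 0
            for s, d in zip(states, comp):
                p *= params.P[s, d - 1]
                for u in range(d):
                    p *= params.B[s, obs[t + u]]
                t += d
            for a, b in zip(states, states[1:]):
                p *= params.A[a, b]
            if p <= 0.0:
                continue
            total += p
            t = 0
            path = []
            for s, d in zip(states, comp):
                for u in range(d):
                    r[t + u, s, u] += p
                path += [s] * d
                t += d
            logp = np.log(p)
            if logp > best_logp + 1e-12:
                best_logp = logp
                argmax = [tuple(path)]
            elif abs(logp - best_logp) <= 1e-12:
                argmax.append(tuple(path))
    if total > 0.0:
        return np.log(total), r / total, best_logp, set(argmax)
    return -np.inf, r, -np.inf, set()


def hmm_enumerate(pi, A, B, obs):
    """Exhaustive HMM loglik and argmax paths (tiny T only)."""
    T, N = len(obs), len(pi)
    total = 0.0
    best_logp = -np.inf
    argmax: list[tuple[int, ...]] = []
    for states in itertools.product(range(N), repeat=T):
        p = pi[states[0]] * B[states[0], obs[0]]
        for t in range(1, T):
            p *= A[states[t - 1], states[t]] * B[states[t], obs[t]]
        if p <= 0.0:
            continue
        total += p
        logp = np.log(p)
        if logp > best_logp + 1e-12:
            best_logp = logp
            argmax = [states]
        elif abs(logp - best_logp) <= 1e-12:
            argmax.append(states)
    ll = np.log(total) if total > 0 else -np.inf
    return ll, best_logp, set(argmax)


def random_hsmm_params(rng, N, M, D) -> hsmm.HSMMParams:
    pi = rng.dirichlet(np.ones(N))
    A = np.zeros((N, N))
    if N > 1:
        for i in range(N):
            others = [j for j in range(N) if j != i]
            A[i, others] = rng.dirichlet(np.ones(N - 1))
    return hsmm.HSMMParams(
        pi=pi,
        A=A,
        B=rng.dirichlet(np.ones(M), size=N),
        P=rng.dirichlet(np.ones(D), size=N),
    )


# ---------------------------------------------------------------------------
# pattern mining
# ---------------------------------------------------------------------------


def embeds(events, pattern, constraints: MiningConstraints) -> bool:
    """Whether the pattern occurs in one event list under the constraints."""

    def search(idx: int, first: int | None, last: int | None) -> bool:
        if idx == len(pattern):
            return True
        for eid, item in events:
            if item != pattern[idx]:
                continue
            if last is not None and not constraints.gap_ok(last, eid):
                continue
            if first is not None and not constraints.span_ok(first, eid):
                continue
            if search(idx + 1, eid if first is None else first, eid):
                return True
        return False

    return search(0, None, None)


def brute_force_patterns(
    db: SequenceDatabase, constraints: MiningConstraints
) -> dict[tuple[str, ...], int]:
    """All frequent patterns with supports, by candidate enumeration."""
    alphabet = db.alphabet
    maxl = constraints.maxl or max(len(e) for _, e in db.sequences)
    min_sup = constraints.abs_min_sup(len(db))
    out: dict[tuple[str, ...], int] = {}

    def grow(prefix: tuple[str, ...]) -> None:
        if len(prefix) >= maxl:
            return
        for sym in alphabet:
            cand = prefix + (sym,)
            sup = sum(
                1 for _, events in db.sequences if embeds(events, cand, constraints)
            )
            if sup >= min_sup:
                out[cand] = sup
                grow(cand)

    grow(())
    return {
        k: v for k, v in out.items() if len(k) >= constraints.min_len_report
    }


def random_database(rng, max_sequences=8, max_events=10, alphabet_size=4):
    alphabet = [chr(ord("A") + k) for k in range(alphabet_size)]
    n = int(rng.integers(2, max_sequences + 1))
    named = {
        f"S{k}": [
            alphabet[int(i)]
            for i in rng.integers(0, alphabet_size, size=int(rng.integers(1, max_events + 1)))
        ]
        for k in range(n)
    }
    return SequenceDatabase.from_symbol_lists(named)


# ---------------------------------------------------------------------------
# fixation detection
# ---------------------------------------------------------------------------


def rle_fixations(samples, config, min_fix_ms):
    """Plain run-length scan over assigned AOI labels (reference detector)."""
    kept = []
    for s in samples:
        if not s.valid:
            continue
        if config.screen is not None:
            w, h = config.screen
            if not (0 <= s.x < w and 0 <= s.y < h):
                continue
        kept.append((s.timestamp_ms, config.assign(s.x, s.y)))
    out = []
    i = 0
    while i < len(kept):
        j = i
        while j + 1 < len(kept) and kept[j + 1][1] == kept[i][1]:
            j += 1
        label = kept[i][1]
        dur = kept[j][0] - kept[i][0]
        if label is not None and dur >= min_fix_ms:
            out.append((label, kept[i][0], dur))
        i = j + 1
    return out
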