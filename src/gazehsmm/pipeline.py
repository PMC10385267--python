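"""End-to-end perceptual-state recognition and evaluation.

A single 3-state explicit-duration HSMM is trained on labeled AOI sequences;
the hidden states are the perceptual classes themselves (HP / MP / LP: high,
moderate, low perception).  Training seeds the emission rows from the
per-class empirical symbol distributions (supervised initialization) and
refines all parameters by EM.  A sequence is classified by duration-aware
Viterbi decoding followed by label aggregation over the decoded segments.

Evaluation follows the confusion-count convention: for a class, ``N1`` is the
number of correctly identified samples, ``N2`` the samples misassigned into
it, and ``N3`` its members assigned elsewhere, giving precision
``P = N1/(N1+N2)``, recall ``R = N1/(N1+N3)`` and the F-value
``F = (beta^2+1) P R / (beta^2 P + R)`` (percentages, ``beta = 1`` by
default).  Pooled figures micro-average the counts across classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import hsmm
from .preprocess import AOISequence

__all__ = [
    "StateLabel",
    "EvalReport",
    "ClassCounts",
    "FittedStateModel",
    "prf_from_counts",
    "evaluate",
    "fit_state_model",
    "classify_sequence",
    "state_duration_means",
]


class StateLabel(str, Enum):
    """Perceptual level of the pilot: high, moderate or low perception."""

    HP = "HP"
    MP = "MP"
    LP = "LP"


@dataclass(frozen=True)
class ClassCounts:
    """Confusion counts and P/R/F (percent) for one class."""

    n1: int
    n2: int
    n3: int
    precision: float
    recall: float
    f_value: float


@dataclass
class EvalReport:
    """Pooled (micro-averaged) and per-class precision/recall/F (percent)."""

    n1: int
    n2: int
    n3: int
    precision: float
    recall: float
    f_value: float
    beta: float
    per_class: dict[str, ClassCounts]


def prf_from_counts(n1: int, n2: int, n3: int, beta: float = 1.0):
    """Precision, recall and F-value (percent) from confusion counts."""
    if min(n1, n2, n3) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * n1 / (n1 + n2) if n1 + n2 else 0.0
    r = 100.0 * n1 / (n1 + n3) if n1 + n3 else 0.0
    denom = beta**2 * p + r
    f = (beta**2 + 1) * p * r / denom if denom else 0.0
    return p, r, f


def evaluate(pred, truth, beta: float = 1.0) -> EvalReport:
    """Micro-averaged and per-class P/R/F from predicted and true labels."""
    pred = [getattr(x, "value", x) for x in pred]
    truth = [getattr(x, "value", x) for x in truth]
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    classes = sorted(set(truth) | set(pred))
    per_class: dict[str, ClassCounts] = {}
    n1 = n2 = n3 = 0
    for c in classes:
        c1 = sum(1 for p, t in zip(pred, truth) if p == t == c)
        c2 = sum(1 for p, t in zip(pred, truth) if p == c and t != c)
        c3 = sum(1 for p, t in zip(pred, truth) if t == c and p != c)
        pc, rc, fc = prf_from_counts(c1, c2, c3, beta)
        per_class[c] = ClassCounts(c1, c2, c3, pc, rc, fc)
        n1, n2, n3 = n1 + c1, n2 + c2, n3 + c3
    p, r, f = prf_from_counts(n1, n2, n3, beta)
    return EvalReport(
        n1=n1, n2=n2, n3=n3, precision=p, recall=r, f_value=f, beta=beta,
        per_class=per_class,
    )


@dataclass
class FittedStateModel:
    """A fitted HSMM together with its alphabet and state-label bijection."""

    params: hsmm.HSMMParams
    alphabet: list[str]
    state_labels: list[str]

    def encode(self, seq: AOISequence) -> hsmm.ObservationSequence:
        index = {s: k for k, s in enumerate(self.alphabet)}
        unknown = [s for s in seq.symbols if s not in index]
        if unknown:
            raise ValueError(f"symbol {unknown[0]!r} not in model alphabet")
        return hsmm.ObservationSequence(
            np.array([index[s] for s in seq.symbols], dtype=np.int64)
        )


def fit_state_model(
    train: list[AOISequence],
    labels: dict[str, str],
    alphabet: list[str] | None = None,
    classes: list[str] = ("HP", "MP", "LP"),
    max_duration: int = 40,
    tol: float = 1e-4,
    max_iter: int = 5,
    seed: int = 0,
) -> FittedStateModel:
    """Supervised-init + EM fit of the 3-state perceptual model.

    ``labels`` maps seq_id to a class name; every class in ``classes`` must be
    present in the training data.  Emission rows are initialized from the
    per-class empirical symbol distributions (add-one smoothed), durations
    from a broad discretized normal, transitions uniform off-diagonal; EM then
    refines all parameters jointly.  State ``k`` corresponds to
    ``classes[k]`` throughout.

    Refinement is deliberately brief (``max_iter=5`` by default): the class
    semantics of the states are carried only by the supervised
    initialization, and prolonged unsupervised EM optimizes marginal
    likelihood at the expense of that anchoring, diffusing the emission rows
    toward each other.  Early stopping acts as the regularizer keeping states
    aligned with their classes; raise ``max_iter`` only when the labels are
    plentiful and the classes strongly separated.
    """
    if not train:
        raise ValueError("training set is empty")
    classes = list(classes)
    present = {labels[s.seq_id] for s in train}
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"class(es) absent from training data: {missing}")
    if alphabet is None:
        alphabet = sorted({sym for s in train for sym in s.symbols})
    sym_index = {s: k for k, s in enumerate(alphabet)}
    N, M, D = len(classes), len(alphabet), max_duration

    B0 = np.ones((N, M))  # add-one smoothing
    counts = np.zeros(N)
    for s in train:
        k = classes.index(labels[s.seq_id])
        counts[k] += 1
        for sym in s.symbols:
            B0[k, sym_index[sym]] += 1
    B0 /= B0.sum(axis=1, keepdims=True)
    pi0 = counts / counts.sum()
    A0 = (np.ones((N, N)) - np.eye(N)) / (N - 1)
    P0 = hsmm.discretized_normal_durations(
        np.full(N, D / 3.0), np.full(N, D / 4.0), D
    )
    params0 = hsmm.HSMMParams(
        pi=pi0, A=A0, B=B0, P=P0, state_labels=classes,
        duration_family="table",
    )
    obs_set = []
    for s in train:
        obs_set.append(
            hsmm.ObservationSequence(
                np.array([sym_index[sym] for sym in s.symbols], dtype=np.int64)
            )
        )
    fitted, _ = hsmm.em_fit(params0, obs_set, tol=tol, max_iter=max_iter)
    fitted.state_labels = classes
    return FittedStateModel(params=fitted, alphabet=list(alphabet), state_labels=classes)


def classify_sequence(
    model: FittedStateModel, seq: AOISequence, method: str = "modal"
):
    """Viterbi-decode a sequence and aggregate the path to one class label.

    ``method``: ``"modal"`` (duration-weighted modal decoded state, the
    default), ``"final"`` (state of the last decoded segment) or
    ``"posterior-mean"`` (state with the largest mean posterior occupancy).
    Ties go to the lowest state index.  Returns ``(label, decoded_path)``.
    """
    obs = model.encode(seq)
    path, _ = hsmm.viterbi(model.params, obs)
    if method == "modal":
        weights = path.dwell_steps(model.params.N)
        k = int(np.argmax(weights))
    elif method == "final":
        k = int(path.segments[-1][0])
    elif method == "posterior-mean":
        post = hsmm.posteriors(model.params, obs)
        occ = post.r.sum(axis=2).mean(axis=0)
        k = int(np.argmax(occ))
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return model.state_labels[k], path


def state_duration_means(params: hsmm.HSMMParams) -> np.ndarray:
    """Mean residence duration per state: sum_d d * P_i(d) (time steps)."""
    d = np.arange(1, params.D + 1)
    return params.P @ d
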