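"""Synthetic gaze and AOI-sequence generation for testing and simulation.

Emulates the acquisition setting of a cockpit eye-tracking study: a 100 Hz
gaze stream over six instrument AOIs (A..F) laid out on a 1920x1080 screen,
driven by a ground-truth 3-state explicit-duration HSMM whose states are the
perceptual classes HP / MP / LP.  Two layers are generated:

* symbol layer — labeled AOI sequences drawn from the ground-truth model
  (class-conditional by forcing the initial state), with per-step dwell
  durations;
* raw-gaze layer — sample streams placed inside the dictated AOI rectangle
  with isotropic Gaussian jitter and i.i.d. dropout, the inverse of the
  preprocessing step.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hsmm
from .preprocess import PHASES, AOIConfig, AOIRect, AOISequence, GazeSample

__all__ = [
    "Scenario",
    "default_aoi_config",
    "default_ground_truth",
    "generate_labeled_dataset",
    "generate_gaze_stream",
]


def default_aoi_config(screen=(1920.0, 1080.0)) -> AOIConfig:
    """Six 300x300 px instrument AOIs in a 3x2 grid, labels A..F."""
    w, h = screen
    labels = ["A", "B", "C", "D", "E", "F"]
    rects = []
    size = 300.0
    x_gap = (w - 3 * size) / 4
    y_gap = (h - 2 * size) / 3
    k = 0
    for row in range(2):
        for col in range(3):
            x0 = x_gap + col * (size + x_gap)
            y0 = y_gap + row * (size + y_gap)
            rects.append(AOIRect(labels[k], x0, y0, x0 + size, y0 + size))
            k += 1
    return AOIConfig(aois=rects, screen=screen)


def default_ground_truth(D: int = 40) -> hsmm.HSMMParams:
    """Ground-truth 3-state model over the six AOIs.

    Emission rows are well separated (each perceptual level concentrates its
    scanning on different instruments); residence durations are discretized
    normals with means 8 / 12 / 18 steps for HP / MP / LP — higher perception
    levels correspond to shorter, more agile dwells.
    """
    B = np.array(
        [
            [0.02, 0.10, 0.08, 0.55, 0.15, 0.10],  # HP: attitude-led scan
            [0.10, 0.45, 0.25, 0.08, 0.07, 0.05],  # MP: airspeed/altimeter
            [0.50, 0.08, 0.07, 0.05, 0.10, 0.20],  # LP: low-value instruments
        ]
    )
    A = np.array(
        [
            [0.0, 0.7, 0.3],
            [0.5, 0.0, 0.5],
            [0.3, 0.7, 0.0],
        ]
    )
    P = hsmm.discretized_normal_durations([8.0, 12.0, 18.0], [2.0, 3.0, 4.0], D)
    return hsmm.HSMMParams(
        pi=np.full(3, 1 / 3),
        A=A,
        B=B,
        P=P,
        state_labels=["HP", "MP", "LP"],
        duration_family="table",
    )


@dataclass
class Scenario:
    """Study conditions for the synthetic generators.

    ``dwell_range_ms`` is the uniform range of per-observation-step dwell
    times used when rendering symbol sequences as gaze streams (all above the
    200 ms fixation threshold); jitter and dropout set the raw-gaze noise.
    """

    seed: int
    screen: tuple[float, float] = (1920.0, 1080.0)
    aoi_config: AOIConfig = field(default_factory=default_aoi_config)
    params: hsmm.HSMMParams = field(default_factory=default_ground_truth)
    rate_hz: float = 100.0
    dropout_p: float = 0.02
    jitter_sd_px: float = 3.0
    n_sequences: int = 90
    t_range: tuple[int, int] = (120, 240)
    dwell_range_ms: tuple[float, float] = (300.0, 800.0)


def class_conditional_params(
    base: hsmm.HSMMParams,
    c: int,
    return_prob: float = 0.8,
    dwell_boost: float = 2.5,
) -> hsmm.HSMMParams:
    """Per-class ground truth: the base model conditioned on perceptual class c.

    A pilot whose perceptual level is class ``c`` starts in state ``c``,
    returns to it with probability ``return_prob`` after every excursion, and
    resides in it ``dwell_boost`` times longer than the base model says, so
    the class state dominates the generated path.  Emissions are untouched —
    class separation comes from where the gaze dwells, not from new symbols.
    """
    N = base.N
    pi = np.eye(N)[c]
    A = base.A.copy()
    for i in range(N):
        if i == c:
            continue
        others = [j for j in range(N) if j not in (i, c)]
        A[i, c] = return_prob
        rest = base.A[i, others]
        rest_total = rest.sum()
        if others:
            A[i, others] = (
                (1 - return_prob) * rest / rest_total
                if rest_total > 0
                else (1 - return_prob) / len(others)
            )
    d = np.arange(1, base.D + 1)
    means = base.P @ d
    var = base.P @ d**2 - means**2
    means = means.copy()
    means[c] = min(base.D * 0.75, means[c] * dwell_boost)
    P = hsmm.discretized_normal_durations(
        means, np.sqrt(np.maximum(var, 1.0)), base.D
    )
    return hsmm.HSMMParams(
        pi=pi, A=A, B=base.B, P=P, state_labels=base.state_labels
    )


def generate_labeled_dataset(scenario: Scenario):
    """Class-conditional labeled AOI sequences from the per-class ground truths.

    Sequences cycle through the three classes; each class's sequences are
    drawn from :func:`class_conditional_params` of the scenario model, and the
    ground-truth label is the duration-weighted modal true state of the
    generated path (which is the conditioning class almost always).  Each
    merged symbol's dwell (ms) is the sum of uniform per-step dwells.
    Returns ``(sequences, labels, paths)`` where ``labels`` maps seq_id to
    class name and ``paths`` holds the true state paths of the *unmerged*
    step sequences.
    """
    rng = np.random.default_rng(scenario.seed)
    params = hsmm.validate_params(scenario.params)
    classes = params.state_labels or [str(i) for i in range(params.N)]
    alphabet = scenario.aoi_config.labels
    if len(alphabet) != params.M:
        raise ValueError("AOI config and emission alphabet sizes differ")
    sequences: list[AOISequence] = []
    labels: dict[str, str] = {}
    paths: list[hsmm.DecodedPath] = []
    lo, hi = scenario.t_range
    per_class = [
        hsmm.validate_params(class_conditional_params(params, c))
        for c in range(params.N)
    ]
    for n in range(scenario.n_sequences):
        c = n % params.N
        T = int(rng.integers(lo, hi + 1))
        obs, path = hsmm.simulate(per_class[c], T=T, seed=rng)
        label = classes[int(np.argmax(path.dwell_steps(params.N)))]
        step_dwells = rng.uniform(*scenario.dwell_range_ms, size=T)
        symbols: list[str] = []
        dwells: list[float] = []
        for t, o in enumerate(obs.obs):
            sym = alphabet[int(o)]
            if symbols and symbols[-1] == sym:
                dwells[-1] += step_dwells[t]
            else:
                symbols.append(sym)
                dwells.append(step_dwells[t])
        seq_id = f"seq{n:04d}"
        sequences.append(
            AOISequence(
                seq_id=seq_id,
                symbols=symbols,
                dwells_ms=[float(d) for d in dwells],
                phase=PHASES[n % len(PHASES)],
            )
        )
        labels[seq_id] = label
        paths.append(path)
    return sequences, labels, paths


def generate_gaze_stream(
    scenario: Scenario, aoi_sequence: AOISequence, rng=None
) -> list[GazeSample]:
    """Render an AOI sequence as a raw 100 Hz gaze stream with noise.

    Samples are placed at the AOI rectangle center plus isotropic Gaussian
    jitter, spanning each dwell exactly (first to last sample timestamps
    ``dwell_ms`` apart), with i.i.d. dropout marking samples invalid.  Errors
    if a dwell is shorter than one sample period.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    period = 1000.0 / scenario.rate_hz
    rect_by_label = {a.label: a for a in scenario.aoi_config.aois}
    samples: list[GazeSample] = []
    t = 0.0
    for sym, dwell in zip(aoi_sequence.symbols, aoi_sequence.dwells_ms):
        if dwell < period:
            raise ValueError(
                f"dwell {dwell} ms shorter than one sample period ({period} ms)"
            )
        rect = rect_by_label[sym]
        cx = (rect.x_min + rect.x_max) / 2
        cy = (rect.y_min + rect.y_max) / 2
        n = int(dwell // period) + 1
        for k in range(n):
            x = cx + rng.normal(0.0, scenario.jitter_sd_px)
            y = cy + rng.normal(0.0, scenario.jitter_sd_px)
            valid = bool(rng.random() >= scenario.dropout_p)
            samples.append(GazeSample(timestamp_ms=t + k * period, x=x, y=y, valid=valid))
        t += dwell + period
    return samples
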