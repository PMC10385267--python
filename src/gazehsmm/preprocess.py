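"""Raw gaze samples -> AOI fixations -> compressed AOI symbol sequences.

The instrument panel is partitioned into rectangular areas of interest (AOIs,
labels A..F by default: configuration indicator, airspeed indicator,
altimeter, attitude director, horizontal situation indicator and vertical
velocity indicator).  A fixation is a maximal run of consecutive valid gaze
samples inside one AOI rectangle lasting at least a minimum duration (200 ms
by default).  Consecutive fixations on the same AOI are merged, yielding the
symbol sequences consumed by the pattern miner and the state models.

Per-AOI dwell thresholds can alternatively be derived from non-dwell-time
statistics as ``threshold = mean + sd`` of the observed non-dwell intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GazeSample",
    "AOIRect",
    "AOIConfig",
    "AOIStats",
    "AOIFixation",
    "AOISequence",
    "compute_dwell_threshold",
    "detect_fixations",
    "build_aoi_sequence",
    "aoi_dwell_shares",
    "aoi_non_dwell_times",
    "visual_behavior_database",
]

PHASES = ("Upwind", "Crosswind", "Downwind", "Base", "Final")


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: screen pixel position at a timestamp (ms).

    ``valid=False`` marks null / lost-track samples; coordinates use a
    top-left pixel origin.
    """

    timestamp_ms: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class AOIRect:
    """A labeled half-open screen rectangle [x_min, x_max) x [y_min, y_max)."""

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass
class AOIConfig:
    """Ordered AOI rectangles; overlaps resolved first-match-wins.

    ``screen`` (width, height) defines the valid sample area; samples outside
    it are treated as outliers and dropped.
    """

    aois: list[AOIRect]
    screen: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        labels = [a.label for a in self.aois]
        if len(set(labels)) != len(labels):
            raise ValueError("AOI labels must be unique")
        for a in self.aois:
            if a.x_max <= a.x_min or a.y_max <= a.y_min:
                raise ValueError(f"AOI {a.label!r} has non-positive area")

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.aois]

    def assign(self, x: float, y: float) -> str | None:
        for a in self.aois:
            if a.contains(x, y):
                return a.label
        return None

    def to_dict(self) -> dict:
        return {
            "screen": list(self.screen) if self.screen else None,
            "aois": [
                {"label": a.label, "rect": [a.x_min, a.y_min, a.x_max, a.y_max]}
                for a in self.aois
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AOIConfig":
        return cls(
            aois=[AOIRect(a["label"], *a["rect"]) for a in d["aois"]],
            screen=tuple(d["screen"]) if d.get("screen") else None,
        )


@dataclass(frozen=True)
class AOIStats:
    """Non-dwell-time statistics for one AOI (seconds).

    ``threshold_s`` is exactly ``mean_ndt_s + std_ndt_s``.
    """

    label: str
    mean_ndt_s: float
    std_ndt_s: float
    threshold_s: float


@dataclass(frozen=True)
class AOIFixation:
    """One dwell on an AOI: label, onset (ms) and duration (ms)."""

    aoi_label: str
    onset_ms: float
    duration_ms: float


@dataclass
class AOISequence:
    """Merged AOI symbol sequence with per-symbol dwell durations (ms)."""

    seq_id: str
    symbols: list[str]
    dwells_ms: list[float]
    phase: str | None = None

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("empty sequence")
        if len(self.symbols) != len(self.dwells_ms):
            raise ValueError("symbols and dwells length mismatch")
        if any(d <= 0 for d in self.dwells_ms):
            raise ValueError("dwells must be positive")
        if any(a == b for a, b in zip(self.symbols, self.symbols[1:])):
            raise ValueError("consecutive duplicate symbols (sequence not merged)")

    def __len__(self) -> int:
        return len(self.symbols)


def compute_dwell_threshold(
    non_dwell_times_s, label: str = "", ddof: int = 0
) -> AOIStats:
    """Per-AOI dwell threshold from non-dwell intervals: mean + sd (seconds).

    The standard deviation is the population one (``ddof=0``) by default.
    """
    arr = np.asarray(list(non_dwell_times_s), dtype=float)
    if arr.size == 0:
        raise ValueError("no non-dwell observations")
    if np.any(arr < 0):
        raise ValueError("non-dwell times must be >= 0")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=ddof))
    return AOIStats(label=label, mean_ndt_s=mu, std_ndt_s=sigma, threshold_s=mu + sigma)


def detect_fixations(
    samples, config: AOIConfig, min_fix_ms: float = 200.0
) -> list[AOIFixation]:
    """Detect AOI fixations as qualifying runs of same-AOI samples.

    Invalid samples and samples outside the configured screen bounds are
    dropped; a maximal run of consecutive retained samples falling inside the
    same AOI rectangle becomes a fixation if its span (last minus first
    timestamp) is at least ``min_fix_ms``.  Samples outside every AOI break
    runs and produce no fixation.
    """
    if not config.aois:
        raise ValueError("AOI config is empty")
    seq = list(samples)
    ts = [s.timestamp_ms for s in seq]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("timestamps must be strictly increasing")
    kept = [s for s in seq if s.valid]
    if config.screen is not None:
        w, h = config.screen
        kept = [s for s in kept if 0 <= s.x < w and 0 <= s.y < h]
    fixations: list[AOIFixation] = []
    run_label: str | None = None
    run_start = run_end = 0.0
    for s in kept:
        label = config.assign(s.x, s.y)
        if label == run_label and label is not None:
            run_end = s.timestamp_ms
            continue
        if run_label is not None and run_end - run_start >= min_fix_ms:
            fixations.append(AOIFixation(run_label, run_start, run_end - run_start))
        run_label = label
        run_start = run_end = s.timestamp_ms
    if run_label is not None and run_end - run_start >= min_fix_ms:
        fixations.append(AOIFixation(run_label, run_start, run_end - run_start))
    return fixations


def build_aoi_sequence(
    fixations: list[AOIFixation], seq_id: str, phase: str | None = None
) -> AOISequence:
    """Merge consecutive same-AOI fixations into one compressed symbol sequence."""
    if not fixations:
        raise ValueError("empty sequence")
    onsets = [f.onset_ms for f in fixations]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("fixations must be time-ordered")
    symbols: list[str] = []
    dwells: list[float] = []
    for f in fixations:
        if symbols and symbols[-1] == f.aoi_label:
            dwells[-1] += f.duration_ms
        else:
            symbols.append(f.aoi_label)
            dwells.append(f.duration_ms)
    return AOISequence(seq_id=seq_id, symbols=symbols, dwells_ms=dwells, phase=phase)


def aoi_dwell_shares(sequences: list[AOISequence]) -> pd.DataFrame:
    """Share of total dwell time spent on each AOI, per flight phase.

    Returns a tidy frame (phase, aoi_label, share); shares within a phase sum
    to one.  Every sequence must carry a phase.
    """
    if any(s.phase is None for s in sequences):
        raise ValueError("all sequences must have a phase set")
    rows = [
        {"phase": s.phase, "aoi_label": sym, "dwell_ms": dw}
        for s in sequences
        for sym, dw in zip(s.symbols, s.dwells_ms)
    ]
    df = pd.DataFrame(rows)
    totals = df.groupby("phase")["dwell_ms"].transform("sum")
    df["share"] = df["dwell_ms"] / totals
    out = (
        df.groupby(["phase", "aoi_label"], as_index=False)["share"]
        .sum()
        .sort_values(["phase", "aoi_label"], ignore_index=True)
    )
    return out


def aoi_non_dwell_times(fixations: list[AOIFixation]) -> dict[str, list[float]]:
    """Non-dwell intervals per AOI: gaps between successive fixations on it (s)."""
    by_label: dict[str, list[AOIFixation]] = {}
    for f in fixations:
        by_label.setdefault(f.aoi_label, []).append(f)
    out: dict[str, list[float]] = {}
    for label, fs in by_label.items():
        fs = sorted(fs, key=lambda f: f.onset_ms)
        gaps = [
            (b.onset_ms - (a.onset_ms + a.duration_ms)) / 1000.0
            for a, b in zip(fs, fs[1:])
        ]
        out[label] = [g for g in gaps if g >= 0]
    return out


def visual_behavior_database(fixations: list[AOIFixation]) -> pd.DataFrame:
    """Per-AOI table of mean non-dwell time, its sd and the dwell threshold (s)."""
    stats = []
    for label, gaps in sorted(aoi_non_dwell_times(fixations).items()):
        if gaps:
            st = compute_dwell_threshold(gaps, label=label)
            stats.append(
                {
                    "aoi_label": label,
                    "mean_ndt_s": st.mean_ndt_s,
                    "std_ndt_s": st.std_ndt_s,
                    "threshold_s": st.threshold_s,
                }
            )
    return pd.DataFrame(stats)
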