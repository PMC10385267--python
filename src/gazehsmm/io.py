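"""Plain-text readers/writers for the tool's external formats.

* gaze CSV: header ``timestamp_ms,x,y,valid``, one row per sample;
* AOI config JSON: ``{"screen": [w, h], "aois": [{"label", "rect"}...]}``;
* AOI sequence TSV: ``seq_id<TAB>phase<TAB>A:550,C:400,...`` (label:dwell_ms),
  phase ``-`` when unset;
* patterns TSV: ``pattern<TAB>support<TAB>length`` with ``-``-joined items;
* model JSON: HSMM or HMM parameter sets keyed by ``"kind"``;
* labels TSV: ``seq_id<TAB>label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .hmm import HMMParams
from .hsmm import HSMMParams
from .preprocess import AOIConfig, AOISequence, GazeSample

__all__ = [
    "read_gaze_csv",
    "write_gaze_csv",
    "read_aoi_config",
    "write_aoi_config",
    "read_sequences_tsv",
    "write_sequences_tsv",
    "write_patterns_tsv",
    "read_model_json",
    "write_model_json",
    "read_labels_tsv",
    "write_labels_tsv",
]


def read_gaze_csv(path) -> list[GazeSample]:
    df = pd.read_csv(path)
    return [
        GazeSample(
            timestamp_ms=float(r.timestamp_ms),
            x=float(r.x),
            y=float(r.y),
            valid=bool(int(r.valid)),
        )
        for r in df.itertuples()
    ]


def write_gaze_csv(samples: list[GazeSample], path) -> None:
    pd.DataFrame(
        {
            "timestamp_ms": [s.timestamp_ms for s in samples],
            "x": [s.x for s in samples],
            "y": [s.y for s in samples],
            "valid": [int(s.valid) for s in samples],
        }
    ).to_csv(path, index=False)


def read_aoi_config(path) -> AOIConfig:
    return AOIConfig.from_dict(json.loads(Path(path).read_text()))


def write_aoi_config(config: AOIConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def read_sequences_tsv(path) -> list[AOISequence]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        seq_id, phase, body = line.split("\t")
        symbols, dwells = [], []
        for part in body.split(","):
            label, dwell = part.split(":")
            symbols.append(label)
            dwells.append(float(dwell))
        out.append(
            AOISequence(
                seq_id=seq_id,
                symbols=symbols,
                dwells_ms=dwells,
                phase=None if phase == "-" else phase,
            )
        )
    return out


def write_sequences_tsv(sequences: list[AOISequence], path) -> None:
    lines = []
    for s in sequences:
        body = ",".join(f"{sym}:{dw:g}" for sym, dw in zip(s.symbols, s.dwells_ms))
        lines.append(f"{s.seq_id}\t{s.phase or '-'}\t{body}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_patterns_tsv(patterns, path) -> None:
    lines = [f"{'-'.join(p.items)}\t{p.support}\t{p.length}" for p in patterns]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_json(path) -> HSMMParams | HMMParams:
    d = json.loads(Path(path).read_text())
    if d.get("kind", "hsmm") == "hmm":
        return HMMParams.from_dict(d)
    return HSMMParams.from_dict(d)


def write_model_json(params: HSMMParams | HMMParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_labels_tsv(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            seq_id, label = line.split("\t")
            out[seq_id] = label
    return out


def write_labels_tsv(labels: dict[str, str], path) -> None:
    Path(path).write_text(
        "\n".join(f"{k}\t{v}" for k, v in labels.items()) + "\n"
    )
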