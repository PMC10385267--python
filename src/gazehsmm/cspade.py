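"""Constrained sequential-pattern mining (cSPADE) over AOI sequence databases.

Patterns are ordered subsequences of single AOI symbols; support is the
number of distinct sequences containing at least one occurrence that honors
the gap constraints (event-index gap between consecutive pattern items in
``[min_gap, max_gap]``) and the window constraint (total event-index span).
Candidate growth follows the vertical ID-list scheme: supports of length-1
and length-2 patterns come from a horizontal scan of the database, longer
patterns are grown depth-first by temporally joining the ID-list of a
``k``-pattern with the ID-lists of the frequent 2-sequences starting at its
last item, pruning infrequent patterns at every step.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

__all__ = [
    "SequenceDatabase",
    "MiningConstraints",
    "Pattern",
    "count_support",
    "temporal_join",
    "mine_frequent",
]

# An occurrence is (sid, first_eid, last_eid): one constraint-satisfying
# embedding of the pattern, keyed by the eids of its first and last items.
# Occurrence lists are kept dominated: for each (sid, last_eid) only the
# embedding with the largest first_eid is stored — it has the smallest span,
# so it subsumes the others for every support, gap and window decision.
Occurrence = tuple[str, int, int]


def _dominate(occurrences) -> list[Occurrence]:
    best: dict[tuple[str, int], int] = {}
    for sid, first, last in occurrences:
        key = (sid, last)
        if key not in best or first > best[key]:
            best[key] = first
    return sorted((sid, first, last) for (sid, last), first in best.items())


@dataclass
class SequenceDatabase:
    """Sequences of (eid, item) events with optional per-sequence class labels.

    Event ids must be strictly increasing within each sequence.
    """

    sequences: list[tuple[str, list[tuple[int, str]]]]
    classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        sids = [sid for sid, _ in self.sequences]
        if len(set(sids)) != len(sids):
            raise ValueError("sequence ids must be unique")
        for sid, events in self.sequences:
            eids = [e for e, _ in events]
            if any(b <= a for a, b in zip(eids, eids[1:])):
                raise ValueError(f"eids not strictly increasing in {sid!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def alphabet(self) -> list[str]:
        items = {it for _, events in self.sequences for _, it in events}
        return sorted(items)

    @classmethod
    def from_symbol_lists(cls, named_lists, classes=None) -> "SequenceDatabase":
        """Build from {sid: [symbol, ...]}; eids are 1-based positions."""
        seqs = [
            (sid, [(i + 1, sym) for i, sym in enumerate(symbols)])
            for sid, symbols in named_lists.items()
        ]
        return cls(sequences=seqs, classes=classes)

    @classmethod
    def from_aoi_sequences(cls, aoi_sequences, use_phase_as_class: bool = True):
        """Build from AOISequence objects; eids are 1-based symbol positions."""
        named = {s.seq_id: list(s.symbols) for s in aoi_sequences}
        classes = None
        if use_phase_as_class and all(s.phase is not None for s in aoi_sequences):
            classes = {s.seq_id: s.phase for s in aoi_sequences}
        return cls.from_symbol_lists(named, classes=classes)


@dataclass(frozen=True)
class MiningConstraints:
    """Gap/window/length constraints and the minimum support.

    ``min_sup`` is an absolute sequence count when >= 1, else a fraction of
    the database size (rounded up).  Gaps are event-index differences between
    consecutive pattern items; ``window`` bounds the eid span of the whole
    occurrence.  ``maxw`` (items per element) is retained for fidelity to the
    general algorithm but fixed to 1: gaze events are atomic.
    ``min_len_report`` filters the returned patterns only; mining always
    starts from length 1.
    """

    min_sup: float = 2
    min_gap: int = 1
    max_gap: int | None = None
    window: int | None = None
    maxl: int | None = None
    maxw: int = 1
    min_len_report: int = 1
    per_class_min_sup: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.min_sup <= 0:
            raise ValueError("min_sup must be positive")
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1")
        if self.max_gap is not None and self.max_gap < self.min_gap:
            raise ValueError("max_gap must be >= min_gap")
        if self.maxl is not None and self.maxl < 1:
            raise ValueError("maxl must be >= 1")
        if self.maxw != 1:
            raise ValueError("only single-item elements are supported (maxw = 1)")

    def abs_min_sup(self, n_sequences: int) -> int:
        if self.min_sup < 1:
            return max(1, math.ceil(self.min_sup * n_sequences))
        return int(self.min_sup)

    def gap_ok(self, prev_eid: int, next_eid: int) -> bool:
        gap = next_eid - prev_eid
        if gap < self.min_gap:
            return False
        return self.max_gap is None or gap <= self.max_gap

    def span_ok(self, first_eid: int, last_eid: int) -> bool:
        return self.window is None or last_eid - first_eid <= self.window


@dataclass(frozen=True)
class Pattern:
    """A mined pattern: ordered items, sequence-level support and ID-list.

    ``idlist`` holds (sid, eid-of-last-item) for every distinct occurrence
    endpoint; ``support`` equals the number of distinct sids in it.
    """

    items: tuple[str, ...]
    support: int
    idlist: tuple[tuple[str, int], ...]

    @property
    def length(self) -> int:
        return len(self.items)


def _occurrences_of(
    events: list[tuple[int, str]],
    pattern: tuple[str, ...],
    constraints: MiningConstraints,
) -> list[tuple[int, int]]:
    """All (first_eid, last_eid) embeddings of ``pattern`` in one sequence."""
    # frontier of partial embeddings: (first_eid, eid_of_last_matched_item),
    # dominated to the max first_eid per last_eid
    frontier = [(eid, eid) for eid, item in events if item == pattern[0]]
    for sym in pattern[1:]:
        positions = [eid for eid, item in events if item == sym]
        nxt: dict[int, int] = {}
        for first, last in frontier:
            for eid in positions:
                if constraints.gap_ok(last, eid) and constraints.span_ok(first, eid):
                    if eid not in nxt or first > nxt[eid]:
                        nxt[eid] = first
        frontier = sorted((first, last) for last, first in nxt.items())
        if not frontier:
            return []
    return frontier


def count_support(
    db: SequenceDatabase,
    pattern,
    constraints: MiningConstraints | None = None,
) -> int:
    """Number of distinct sequences containing the pattern under the constraints."""
    pattern = tuple(pattern)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    constraints = constraints or MiningConstraints(min_sup=1)
    return sum(
        1
        for _, events in db.sequences
        if _occurrences_of(events, pattern, constraints)
    )


def temporal_join(
    parent_occurrences: list[Occurrence],
    item_occurrences: list[Occurrence],
    constraints: MiningConstraints,
) -> list[Occurrence]:
    """Extend a pattern's occurrence list by the positions of one more item.

    ``item_occurrences`` supplies candidate positions of the appended item via
    their last eids.  Every output occurrence extends a parent occurrence with
    an eid gap in ``[min_gap, max_gap]`` and a total span within ``window``;
    the result is dominated (max first eid per endpoint).
    """
    by_sid: dict[str, list[int]] = {}
    for sid, _, last in item_occurrences:
        by_sid.setdefault(sid, []).append(last)
    for positions in by_sid.values():
        positions.sort()
    out: dict[tuple[str, int], int] = {}
    for sid, first, last in parent_occurrences:
        positions = by_sid.get(sid)
        if not positions:
            continue
        lo = bisect_left(positions, last + constraints.min_gap)
        hi_eid = last + constraints.max_gap if constraints.max_gap is not None else None
        for eid in positions[lo:]:
            if hi_eid is not None and eid > hi_eid:
                break
            if constraints.span_ok(first, eid):
                key = (sid, eid)
                if key not in out or first > out[key]:
                    out[key] = first
    return sorted((sid, first, eid) for (sid, eid), first in out.items())


def _support_of(occurrences: list[Occurrence]) -> int:
    return len({sid for sid, _, _ in occurrences})


def _frequent_enough(
    occurrences: list[Occurrence],
    db: SequenceDatabase,
    constraints: MiningConstraints,
    min_sup_abs: int,
) -> bool:
    if _support_of(occurrences) >= min_sup_abs:
        return True
    if constraints.per_class_min_sup and db.classes:
        per_class: dict[str, set[str]] = {}
        for sid, _, _ in occurrences:
            cls = db.classes.get(sid)
            if cls is not None:
                per_class.setdefault(cls, set()).add(sid)
        class_sizes: dict[str, int] = {}
        for sid, _ in db.sequences:
            cls = db.classes.get(sid)
            if cls is not None:
                class_sizes[cls] = class_sizes.get(cls, 0) + 1
        for cls, thresh in constraints.per_class_min_sup.items():
            n_cls = class_sizes.get(cls, 0)
            need = max(1, math.ceil(thresh * n_cls)) if thresh < 1 else int(thresh)
            if len(per_class.get(cls, ())) >= need:
                return True
    return False


def mine_frequent(
    db: SequenceDatabase, constraints: MiningConstraints
) -> list[Pattern]:
    """All frequent patterns under the constraints, with supports and ID-lists.

    Output is sorted by (length desc, support desc, items lexicographic) and
    filtered to ``min_len_report``.  A ``min_sup`` exceeding the database size
    yields an empty result.
    """
    if len(db) == 0:
        raise ValueError("database must be non-empty")
    min_sup_abs = constraints.abs_min_sup(len(db))
    maxl = constraints.maxl or max(
        (len(events) for _, events in db.sequences), default=1
    )

    # length 1: horizontal scan
    atom_occs: dict[str, list[Occurrence]] = {}
    for sid, events in db.sequences:
        for eid, item in events:
            atom_occs.setdefault(item, []).append((sid, eid, eid))
    frequent: dict[tuple[str, ...], list[Occurrence]] = {}
    f1 = {
        item: occs
        for item, occs in atom_occs.items()
        if _frequent_enough(occs, db, constraints, min_sup_abs)
    }
    for item, occs in f1.items():
        frequent[(item,)] = occs
    if maxl >= 2:
        # length 2: horizontal scan over item pairs of frequent atoms
        f2: dict[tuple[str, str], list[Occurrence]] = {}
        for x in f1:
            for y in f1:
                occs = [
                    (sid, first, last)
                    for sid, events in db.sequences
                    for first, last in _occurrences_of(events, (x, y), constraints)
                ]
                if _frequent_enough(occs, db, constraints, min_sup_abs):
                    f2[(x, y)] = occs
        for pair, occs in f2.items():
            frequent[pair] = occs

        # length >= 3: depth-first ID-list joins with the frequent 2-sequences
        ext_by_last: dict[str, list[tuple[str, list[Occurrence]]]] = {}
        for (x, y), occs in f2.items():
            ext_by_last.setdefault(x, []).append((y, occs))

        def grow(items: tuple[str, ...], occs: list[Occurrence]) -> None:
            if len(items) >= maxl:
                return
            for y, occs2 in ext_by_last.get(items[-1], ()):
                child = temporal_join(occs, occs2, constraints)
                if _frequent_enough(child, db, constraints, min_sup_abs):
                    key = items + (y,)
                    frequent[key] = child
                    grow(key, child)

        for pair, occs in sorted(f2.items()):
            grow(pair, occs)

    patterns = [
        Pattern(
            items=items,
            support=_support_of(occs),
            idlist=tuple(sorted({(sid, last) for sid, _, last in occs})),
        )
        for items, occs in frequent.items()
        if len(items) >= constraints.min_len_report
    ]
    patterns.sort(key=lambda p: (-p.length, -p.support, p.items))
    return patterns
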