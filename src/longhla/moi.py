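"""Mismatch-in-the-Overlapped-Interval (MOI) alignment comparison.

Two candidate alignments of the *same read* are compared only within the
read interval both alignments cover.  Differences are counted as events:
a maximal run of substitution columns is one event, and a contiguous gap
(insertion or deletion run) of at least ``min_gap`` bases is one event —
shorter gaps are ignored as likely sequencing artifacts.  Fewer events in
the shared interval wins.  In ``high_error`` tie mode (for noisier reads,
e.g. Nanopore R10) a difference of at most one event also counts as a
tie, deliberately creating more ties so that downstream stages keep both
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .aligner import Alignment, parse_cigar

DEFAULT_MIN_GAP = 3


@dataclass(frozen=True)
class DiffEvent:
    """One alignment difference: a substitution run or a contiguous gap.

    ``read_interval`` is on the read (zero-width for deletions, which
    consume no read bases); ``target_interval`` is on the target (zero-
    width for insertions).  ``length`` is the run length in bases.
    """

    kind: str  # "substitution" | "gap"
    read_interval: tuple[int, int]
    target_interval: tuple[int, int]
    length: int


class Outcome(str, Enum):
    FIRST_BETTER = "first_better"
    SECOND_BETTER = "second_better"
    TIE = "tie"

    def mirrored(self) -> "Outcome":
        if self is Outcome.FIRST_BETTER:
            return Outcome.SECOND_BETTER
        if self is Outcome.SECOND_BETTER:
            return Outcome.FIRST_BETTER
        return Outcome.TIE


@dataclass(frozen=True)
class MoiVerdict:
    outcome: Outcome
    diff_counts: tuple[int, int]


def difference_events(aln: Alignment, min_gap: int = DEFAULT_MIN_GAP) -> list[DiffEvent]:
    """Extract difference events from an extended-CIGAR alignment.

    Consecutive ``X`` runs coalesce into one substitution event per
    maximal run (adjacent X runs in the CIGAR are merged); each maximal
    ``I`` or ``D`` run of length >= ``min_gap`` is one gap event; shorter
    indel runs are dropped.
    """
    if aln.cigar is None:
        raise ValueError("difference_events requires an alignment with a cigar")
    events: list[DiffEvent] = []
    q, t = aln.query_interval[0], aln.target_interval[0]
    # merge adjacent runs of the same op (a parser may emit e.g. 1X1X)
    runs: list[tuple[int, str]] = []
    for n, op in parse_cigar(aln.cigar):
        if runs and runs[-1][1] == op:
            runs[-1] = (runs[-1][0] + n, op)
        else:
            runs.append((n, op))
    for n, op in runs:
        if op == "=":
            q += n
            t += n
        elif op == "X":
            events.append(DiffEvent("substitution", (q, q + n), (t, t + n), n))
            q += n
            t += n
        elif op == "I":
            if n >= min_gap:
                events.append(DiffEvent("gap", (q, q + n), (t, t), n))
            q += n
        elif op == "D":
            if n >= min_gap:
                events.append(DiffEvent("gap", (q, q), (t, t + n), n))
            t += n
    return events


def _flip_interval(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - iv[1], length - iv[0])


def _overlaps(ev_iv: tuple[int, int], window: tuple[int, int]) -> bool:
    s, e = ev_iv
    ws, we = window
    if s == e:  # zero-width (deletion): count if inside or touching the window
        return ws <= s <= we
    return max(s, ws) < min(e, we)


def count_events_in_window(
    events: list[DiffEvent], window: tuple[int, int], *, flip_length: Optional[int] = None
) -> int:
    """Events whose read interval intersects ``window`` (read coordinates).

    ``flip_length``: if given, event intervals are mirrored to the
    opposite strand frame of a read of that length before the test.
    """
    n = 0
    for ev in events:
        iv = ev.read_interval
        if flip_length is not None:
            iv = _flip_interval(iv, flip_length)
        if _overlaps(iv, window):
            n += 1
    return n


def moi_compare(
    aln_a: Alignment,
    aln_b: Alignment,
    tie_mode: str = "strict",
    min_gap: int = DEFAULT_MIN_GAP,
    events_a: Optional[list[DiffEvent]] = None,
    events_b: Optional[list[DiffEvent]] = None,
) -> MoiVerdict:
    """Decide which of two alignments of one read is better.

    The comparison window is the intersection of the two read intervals,
    expressed in the frame of ``aln_a`` (if strands differ, ``aln_b``'s
    coordinates are mirrored first).  Pre-computed event lists may be
    passed to avoid re-parsing CIGARs in hot loops.
    """
    if aln_a.query_id != aln_b.query_id:
        raise ValueError("moi_compare requires two alignments of the same read")
    if tie_mode not in ("strict", "high_error"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    ivb = aln_b.query_interval
    flip = None
    if aln_a.strand != aln_b.strand:
        length = aln_a.query_length or aln_b.query_length
        ivb = _flip_interval(ivb, length)
        flip = length
    lo = max(aln_a.query_interval[0], ivb[0])
    hi = min(aln_a.query_interval[1], ivb[1])
    if lo >= hi:
        return MoiVerdict(Outcome.TIE, (0, 0))
    window = (lo, hi)
    if events_a is None:
        events_a = difference_events(aln_a, min_gap)
    if events_b is None:
        events_b = difference_events(aln_b, min_gap)
    ca = count_events_in_window(events_a, window)
    cb = count_events_in_window(events_b, window, flip_length=flip)
    if tie_mode == "high_error" and abs(ca - cb) <= 1:
        return MoiVerdict(Outcome.TIE, (ca, cb))
    if ca < cb:
        return MoiVerdict(Outcome.FIRST_BETTER, (ca, cb))
    if cb < ca:
        return MoiVerdict(Outcome.SECOND_BETTER, (ca, cb))
    return MoiVerdict(Outcome.TIE, (ca, cb))
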