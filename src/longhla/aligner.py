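"""Pairwise alignment layer shared by every pipeline stage.

All alignments are computed under unit edit costs (match 0, mismatch /
insertion / deletion 1) with the edlib bit-vector engine.  Two modes are
exposed:

``global``
    end-to-end alignment of both sequences (edit distance).
``semi_global``
    the query must align end-to-end but may land anywhere inside the
    target (gaps at the target's flanks are free) — the natural mode for
    placing a read inside a full-length allele sequence.

CIGAR strings are extended CIGAR over ``= X I D`` where ``I`` consumes
query bases and ``D`` consumes target bases.  Intervals are 0-based
half-open.  Strand ``-`` means the query was reverse-complemented before
alignment; all recorded coordinates then refer to the reverse-complemented
query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

QUERY_OPS = frozenset("=XI")
TARGET_OPS = frozenset("=XD")
EDIT_OPS = frozenset("XID")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) runs.

    Raises ``ValueError`` on an ambiguous ``M`` op: the whole package
    requires extended CIGAR with match/mismatch distinguished.
    """
    runs = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed cigar: {cigar!r}")
        n, op = int(m.group(1)), m.group(2)
        if op == "M":
            raise ValueError("ambiguous 'M' op: extended CIGAR (=/X) required")
        runs.append((n, op))
        pos = m.end()
    if pos != len(cigar):
        raise ValueError(f"malformed cigar: {cigar!r}")
    return runs


def cigar_edit_count(cigar: str) -> int:
    """Total edited bases (X + I + D) in an extended CIGAR."""
    return sum(n for n, op in parse_cigar(cigar) if op in EDIT_OPS)


def cigar_consumed(cigar: str) -> tuple[int, int]:
    """(query bases, target bases) consumed by a CIGAR."""
    q = t = 0
    for n, op in parse_cigar(cigar):
        if op in QUERY_OPS:
            q += n
        if op in TARGET_OPS:
            t += n
    return q, t


@dataclass
class Alignment:
    """One query-to-target alignment with interval-anchored extended CIGAR.

    ``cigar`` may be ``None`` for screening alignments computed without
    traceback (edit count and intervals are still valid).
    """

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    cigar: Optional[str]
    edit_count: int
    strand: str = "+"
    query_length: int = 0  # full (original) query length, for strand flips

    def __post_init__(self) -> None:
        if self.cigar is not None:
            q, t = cigar_consumed(self.cigar)
            qw = self.query_interval[1] - self.query_interval[0]
            tw = self.target_interval[1] - self.target_interval[0]
            if (q, t) != (qw, tw):
                raise ValueError(
                    f"cigar consumes ({q},{t}) but intervals span ({qw},{tw})"
                )

    @property
    def matched_bases(self) -> int:
        if self.cigar is None:
            raise ValueError("alignment has no cigar")
        return sum(n for n, op in parse_cigar(self.cigar) if op == "=")

    def columns(self) -> Iterator[tuple[str, int, int]]:
        """Yield (op, query_pos, target_pos) per alignment column.

        For ``I`` the target position is the next target base; for ``D``
        the query position is the next query base.
        """
        if self.cigar is None:
            raise ValueError("alignment has no cigar")
        q, t = self.query_interval[0], self.target_interval[0]
        for n, op in parse_cigar(self.cigar):
            for _ in range(n):
                yield op, q, t
                if op in QUERY_OPS:
                    q += 1
                if op in TARGET_OPS:
                    t += 1


def _expand_result(
    res: dict,
    query: str,
    target: str,
    mode: str,
    query_id: str,
    target_id: str,
    strand: str,
) -> Alignment:
    start, end = res["locations"][0]
    start = 0 if start is None else start
    return Alignment(
        query_id=query_id,
        target_id=target_id,
        query_interval=(0, len(query)),
        target_interval=(start, end + 1),
        cigar=res.get("cigar"),
        edit_count=res["editDistance"],
        strand=strand,
        query_length=len(query),
    )


_EDLIB_MODE = {"global": "NW", "semi_global": "HW"}


def align_pair(
    query: str,
    target: str,
    mode: str = "global",
    *,
    query_id: str = "query",
    target_id: str = "target",
    max_edits: int = -1,
    with_path: bool = True,
    strand: str = "+",
) -> Optional[Alignment]:
    """Optimal unit-cost alignment of ``query`` against ``target``.

    Returns ``None`` when ``max_edits`` >= 0 and no alignment within that
    many edits exists (banded screening).
    """
    if not query or not target:
        raise ValueError("align_pair requires non-empty sequences")
    res = edlib.align(
        query,
        target,
        mode=_EDLIB_MODE[mode],
        task="path" if with_path else "locations",
        k=max_edits,
    )
    if res["editDistance"] < 0:
        return None
    return _expand_result(res, query, target, mode, query_id, target_id, strand)


_TRIM_MATCH_SCORE = 1
_TRIM_EDIT_SCORE = -2


def trim_alignment(aln: Alignment) -> Optional[Alignment]:
    """Soft-clip noisy alignment ends, keeping the best-scoring segment.

    A read extending past its target (e.g. flanking genomic sequence
    around a gene-length allele) is force-aligned by semi-global modes
    into dense mismatch/indel tails.  This trims the alignment to the
    maximum-scoring contiguous run segment (+1 per matched base, -2 per
    edited base, Kadane over CIGAR runs), the classic fit-alignment
    recovery.  Returns ``None`` when no positive-scoring segment exists
    (the alignment is all noise).
    """
    if aln.cigar is None:
        raise ValueError("trim_alignment requires a cigar")
    runs = parse_cigar(aln.cigar)
    scores = [
        n * (_TRIM_MATCH_SCORE if op == "=" else _TRIM_EDIT_SCORE)
        for n, op in runs
    ]
    best_sum = 0
    best = None  # (start_run, end_run) half-open
    cur_sum = 0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur_sum <= 0:
            cur_sum = 0
            cur_start = i
        cur_sum += s
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    if best is None:
        return None
    i, j = best
    if i == 0 and j == len(runs):
        return aln
    dq = sum(n for n, op in runs[:i] if op in QUERY_OPS)
    dt = sum(n for n, op in runs[:i] if op in TARGET_OPS)
    kept = runs[i:j]
    qspan = sum(n for n, op in kept if op in QUERY_OPS)
    tspan = sum(n for n, op in kept if op in TARGET_OPS)
    qs = aln.query_interval[0] + dq
    ts = aln.target_interval[0] + dt
    return Alignment(
        query_id=aln.query_id,
        target_id=aln.target_id,
        query_interval=(qs, qs + qspan),
        target_interval=(ts, ts + tspan),
        cigar="".join(f"{n}{op}" for n, op in kept),
        edit_count=sum(n for n, op in kept if op in EDIT_OPS),
        strand=aln.strand,
        query_length=aln.query_length,
    )


def align_read(
    read: str,
    target: str,
    *,
    read_id: str = "read",
    target_id: str = "target",
    max_edits: int = -1,
    with_path: bool = True,
) -> Optional[Alignment]:
    """Semi-global alignment of a read on its better strand.

    Both orientations are screened by edit distance; the better one is
    realigned with traceback when requested.  On a tie the forward strand
    wins.  Coordinates of a ``-`` alignment refer to the
    reverse-complemented read.
    """
    if not read:
        return None
    fwd = edlib.align(read, target, mode="HW", task="locations", k=max_edits)
    rc = reverse_complement(read)
    rev = edlib.align(rc, target, mode="HW", task="locations", k=max_edits)
    df, dr = fwd["editDistance"], rev["editDistance"]
    if df < 0 and dr < 0:
        return None
    if dr < 0 or (df >= 0 and df <= dr):
        seq, strand, res = read, "+", fwd
    else:
        seq, strand, res = rc, "-", rev
    if with_path:
        res = edlib.align(seq, target, mode="HW", task="path", k=max_edits)
    return _expand_result(res, seq, target, "semi_global", read_id, target_id, strand)


def map_read(
    read: str,
    references: Sequence,
    max_hits: int = 50,
    *,
    read_id: str = "read",
    max_edit_fraction: Optional[float] = None,
    with_path: bool = True,
) -> list[Alignment]:
    """Map a read against a panel of allele records, both strands.

    Hits are ranked by ascending edit rate (edits / aligned target span),
    ties broken by target id; at most ``max_hits`` are returned.
    ``references`` are objects with ``allele_id`` and ``sequence``
    attributes (see :mod:`longhla.allele_db`).
    """
    if not read:
        return []
    k = -1
    if max_edit_fraction is not None:
        k = max(1, int(max_edit_fraction * len(read)))
    hits = []
    for ref in references:
        aln = align_read(
            read,
            ref.sequence,
            read_id=read_id,
            target_id=ref.allele_id,
            max_edits=k,
            with_path=with_path,
        )
        if aln is not None:
            hits.append(aln)
    hits.sort(
        key=lambda a: (
            a.edit_count / max(1, a.target_interval[1] - a.target_interval[0]),
            a.target_id,
        )
    )
    return hits[:max_hits]


def reconstruct_pair(aln: Alignment, query: str, target: str) -> tuple[str, str]:
    """Rebuild the two gapped rows of an alignment (CIGAR round-trip check)."""
    qrow, trow = [], []
    for op, q, t in aln.columns():
        qrow.append(query[q] if op in QUERY_OPS else "-")
        trow.append(target[t] if op in TARGET_OPS else "-")
    return "".join(qrow), "".join(trow)
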