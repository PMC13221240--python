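"""Full-field allele name assignment for consensus sequences.

A consensus is scored against every full-length allele of its gene with a
weighted penalty: 9999 per exonic difference event and 1 per intronic
event, where an event is a maximal substitution run or a contiguous gap
of any size (no small-gap forgiveness here — a real 1-bp exonic indel
must cost the full exonic weight).  The heavy exon weight makes any
candidate differing in an exon lose to any candidate that differs only
in introns, regardless of how many intronic differences the latter has
(up to 9998 of them).

Name assignment:

1. exact — some full-length allele aligns with zero events (penalty 0);
2. partial-CDS fallback — no perfect genomic match, but some allele
   (including exon-only partial records) has a coding sequence identical
   to the consensus CDS;
3. novel — reported as the closest full-length allele plus the extended
   CIGAR of the global alignment against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .aligner import align_pair
from .allele_db import AlleleDatabase, AlleleRecord, coding_sequence
from .consensus import HaplotypeConsensus
from .moi import DiffEvent, difference_events

logger = logging.getLogger(__name__)

DEFAULT_EXON_WEIGHT = 9999
DEFAULT_INTRON_WEIGHT = 1


@dataclass(frozen=True)
class PenaltyConfig:
    exon_weight: int = DEFAULT_EXON_WEIGHT
    intron_weight: int = DEFAULT_INTRON_WEIGHT

    def __post_init__(self) -> None:
        if not self.exon_weight > self.intron_weight > 0:
            raise ValueError("require exon_weight > intron_weight > 0")


@dataclass
class AlleleCall:
    """One haplotype's typing call."""

    allele_name: str
    status: str  # "exact" | "partial_cds" | "novel" | "no_call"
    penalty: int
    novel_cigar: Optional[str]
    consensus_id: str


@dataclass
class TypingResult:
    gene: str
    calls: tuple[AlleleCall, AlleleCall]


def _event_is_exonic(ev: DiffEvent, exons: list[tuple[int, int]]) -> bool:
    # zero-width target interval (insertion): exonic if it touches an exon,
    # boundary positions included — exon-affecting changes are never
    # discounted to intronic
    s, e = ev.target_interval
    for xs, xe in exons:
        if s == e:
            if xs <= s <= xe:
                return True
        elif max(s, xs) < min(e, xe):
            return True
    return False


def penalty_events(
    consensus_seq: str, candidate: AlleleRecord
) -> tuple[list[DiffEvent], int, str]:
    """Difference events of consensus vs candidate, exonic count, cigar."""
    aln = align_pair(consensus_seq, candidate.sequence, "global")
    events = difference_events(aln, min_gap=1)
    exonic = sum(1 for ev in events if _event_is_exonic(ev, candidate.exons))
    return events, exonic, aln.cigar


def penalty_score(
    consensus: HaplotypeConsensus | str,
    candidate: AlleleRecord,
    cfg: PenaltyConfig = PenaltyConfig(),
) -> int:
    """Weighted exon/intron penalty of a consensus against one candidate."""
    if candidate.is_partial:
        raise ValueError(
            f"{candidate.allele_id} is partial; use the coding-sequence path"
        )
    seq = consensus if isinstance(consensus, str) else consensus.sequence
    events, exonic, _ = penalty_events(seq, candidate)
    intronic = len(events) - exonic
    return cfg.exon_weight * exonic + cfg.intron_weight * intronic


def type_allele(
    consensus: HaplotypeConsensus,
    db: AlleleDatabase,
    cfg: PenaltyConfig = PenaltyConfig(),
    consensus_id: str = "consensus",
) -> AlleleCall:
    """Assign an allele name to one haplotype consensus."""
    gene = consensus.gene
    full = db.by_gene(gene, full_length_only=True)
    if not full:
        raise ValueError(f"gene {gene} absent from database")
    best: Optional[tuple[int, int, str]] = None  # (penalty, exonic, name)
    best_cigar = ""
    for cand in full:
        events, exonic, cigar = penalty_events(consensus.sequence, cand)
        intronic = len(events) - exonic
        pen = cfg.exon_weight * exonic + cfg.intron_weight * intronic
        key = (pen, exonic, cand.name)
        if best is None or key < best:
            best = key
            best_cigar = cigar
    penalty, _, name = best
    if penalty == 0:
        return AlleleCall(name, "exact", 0, None, consensus_id)
    cons_cds = consensus.coding_sequence
    # partial (exon-only) records are applied only through a perfect CDS
    # match; a full-length allele with equal CDS but imperfect genomic
    # sequence means the consensus is a novel variant of that allele
    for cand in sorted(db.by_gene(gene), key=lambda a: a.name):
        if cand.is_partial and coding_sequence(cand) == cons_cds:
            return AlleleCall(cand.name, "partial_cds", penalty, None, consensus_id)
    return AlleleCall(name, "novel", penalty, best_cigar, consensus_id)


def type_pair(
    consensus_1: HaplotypeConsensus,
    consensus_2: HaplotypeConsensus,
    db: AlleleDatabase,
    cfg: PenaltyConfig = PenaltyConfig(),
    sample: str = "sample",
) -> TypingResult:
    gene = consensus_1.gene
    c1 = type_allele(consensus_1, db, cfg, f"{sample}|{gene}|hap1")
    c2 = type_allele(consensus_2, db, cfg, f"{sample}|{gene}|hap2")
    return TypingResult(gene=gene, calls=(c1, c2))
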