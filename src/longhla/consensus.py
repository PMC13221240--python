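"""Read phasing, pileup variant calling, and consensus construction.

Reads are phased onto the two template alleles by MOI comparison (ties go
to both haplotypes).  Per haplotype, a per-column pileup over the phased
reads' alignments yields candidate variants; only *major* variants —
supported by at least three reads and by more than half of the covering
reads — are kept, and applied to the template to produce the consensus
allele sequence.  Indels are left-aligned before pileup aggregation so
equivalent placements stack onto one candidate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .aligner import Alignment, align_pair, parse_cigar
from .allele_db import AlleleRecord
from .extraction import GeneRead, GeneReadSet
from .moi import Outcome, moi_compare
from .template import GeneSupport, TemplatePair

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_AF = 0.5
#: variant evidence this close to a read's own alignment boundary is
#: ignored (soft-clip junction artifacts misalign consistently across
#: reads sharing flanking sequence); the read still counts toward depth
DEFAULT_EDGE_MASK = 25
QV_CAP = 60.0


@dataclass
class Variant:
    """One major variant on a template allele (0-based coordinates).

    ``ref``/``alt`` are the replaced/replacement strings: a SNV has both
    of length 1, a deletion has empty ``alt``, an insertion empty ``ref``
    (the insertion lands *before* ``position``).
    """

    template_allele_id: str
    position: int
    ref: str
    alt: str
    kind: str  # "snv" | "ins" | "del"
    support: int
    depth: int

    @property
    def af(self) -> float:
        return self.support / self.depth if self.depth else 0.0

    @property
    def span(self) -> tuple[int, int]:
        return (self.position, self.position + len(self.ref))

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class HaplotypeConsensus:
    gene: str
    template_allele_id: str
    sequence: str
    features: list[tuple[str, int, int]]  # lifted onto the consensus
    applied_variants: list[Variant]
    phased_read_ids: set[str]
    mean_depth: float

    @property
    def exons(self) -> list[tuple[int, int]]:
        return [(s, e) for kind, s, e in self.features if kind == "exon"]

    @property
    def coding_sequence(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)


def phase_reads(
    gene_reads: GeneReadSet,
    pair: TemplatePair,
    support: GeneSupport,
    tie_mode: str = "strict",
    min_gap: int = 3,
) -> tuple[list[GeneRead], list[GeneRead]]:
    """Assign each read to one or both template haplotypes via MOI.

    Ties place the read on both haplotypes; a forced-homozygous pair
    receives every read on both (identical) haplotypes.  Reads aligning
    to neither template are dropped with a log entry.
    """
    reads_1: list[GeneRead] = []
    reads_2: list[GeneRead] = []
    id1, id2 = pair.allele_1.allele_id, pair.allele_2.allele_id
    for read in gene_reads.reads:
        a1 = support.alignments.get((read.read_id, id1))
        a2 = support.alignments.get((read.read_id, id2))
        if a1 is None and a2 is None:
            logger.debug("read %s aligns to neither template; dropped", read.read_id)
            continue
        if pair.is_homozygous:
            reads_1.append(read)
            reads_2.append(read)
            continue
        if a1 is None:
            reads_2.append(read)
            continue
        if a2 is None:
            reads_1.append(read)
            continue
        verdict = moi_compare(
            a1, a2, tie_mode, min_gap,
            events_a=support.events.get((read.read_id, id1)),
            events_b=support.events.get((read.read_id, id2)),
        )
        if verdict.outcome is Outcome.FIRST_BETTER:
            reads_1.append(read)
        elif verdict.outcome is Outcome.SECOND_BETTER:
            reads_2.append(read)
        else:
            reads_1.append(read)
            reads_2.append(read)
    return reads_1, reads_2


def _left_normalize(seq: str, pos: int, allele: str) -> tuple[int, str]:
    """Shift an indel to its lowest equivalent template coordinate.

    For a deletion, ``allele`` is the deleted template substring at
    ``pos``; for an insertion, the inserted bases placed before ``pos``.
    """
    # rotating one step keeps a deletion's content equal to the template
    # substring at the new position, so the shift is always consistent
    while pos > 0 and allele and seq[pos - 1] == allele[-1]:
        allele = seq[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


def call_variants(
    reads: list[GeneRead],
    template: AlleleRecord,
    support: GeneSupport,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_af: float = DEFAULT_MIN_AF,
    edge_mask: int = DEFAULT_EDGE_MASK,
) -> list[Variant]:
    """Pileup caller over reads phased to one template haplotype.

    Emits a variant when its read support is at least ``min_support``
    and its allele fraction among covering reads exceeds ``min_af``.
    Overlapping candidates are resolved by highest support, then
    leftmost position.  Alignments are taken from the support cache
    (computed during template selection).
    """
    L = len(template.sequence)
    depth = np.zeros(L + 1, dtype=np.int32)
    snv: dict[tuple[int, str], int] = {}
    ins: dict[tuple[int, str], int] = {}
    dele: dict[tuple[int, str], int] = {}
    n_cov = 0
    for read in reads:
        aln = support.alignments.get((read.read_id, template.allele_id))
        if aln is None:
            continue
        n_cov += 1
        ts, te = aln.target_interval
        depth[ts:te] += 1
        lo, hi = ts + edge_mask, te - edge_mask
        q, t = aln.query_interval[0], aln.target_interval[0]
        for n, op in parse_cigar(aln.cigar):
            if op == "=":
                q += n
                t += n
            elif op == "X":
                for i in range(n):
                    if lo <= t + i < hi:
                        key = (t + i, read.sequence[q + i])
                        snv[key] = snv.get(key, 0) + 1
                q += n
                t += n
            elif op == "I":
                if lo <= t < hi:
                    p, a = _left_normalize(template.sequence, t, read.sequence[q : q + n])
                    ins[(p, a)] = ins.get((p, a), 0) + 1
                q += n
            elif op == "D":
                if lo <= t < hi:
                    p, a = _left_normalize(template.sequence, t, template.sequence[t : t + n])
                    dele[(p, a)] = dele.get((p, a), 0) + 1
                t += n
    candidates: list[Variant] = []
    for (pos, base), sup in snv.items():
        candidates.append(
            Variant(template.allele_id, pos, template.sequence[pos], base,
                    "snv", sup, int(depth[pos]))
        )
    for (pos, seq), sup in ins.items():
        d = int(depth[pos]) if pos < L else int(depth[L - 1])
        candidates.append(
            Variant(template.allele_id, pos, "", seq, "ins", sup, d)
        )
    for (pos, seq), sup in dele.items():
        candidates.append(
            Variant(template.allele_id, pos, seq, "", "del", sup, int(depth[pos]))
        )
    passed = [
        v for v in candidates if v.support >= min_support and v.af > min_af
    ]
    # resolve overlaps: highest support wins, then leftmost
    passed.sort(key=lambda v: (-v.support, v.position, v.kind, v.alt))
    accepted: list[Variant] = []
    for v in passed:
        s, e = v.span
        clash = False
        for w in accepted:
            ws, we = w.span
            if s == e and ws < s < we:
                clash = True
            elif ws == we and s < ws < e:
                clash = True
            elif s == e and ws == we and s == ws:
                clash = True
            elif max(s, ws) < min(e, we):
                clash = True
            if clash:
                break
        if not clash:
            accepted.append(v)
    accepted.sort(key=lambda v: (v.position, v.kind))
    if n_cov and not np.all(depth[:L] > 0):
        gaps = int(np.sum(depth[:L] == 0))
        logger.info(
            "%s: %d template bases without read coverage", template.allele_id, gaps
        )
    return accepted


def _lift(pos: int, variants: list[Variant]) -> int:
    """Map a template coordinate through applied variants to the consensus."""
    off = 0
    for v in variants:
        s, e = v.span
        if e <= pos and not (s == e == pos):
            off += v.delta
        elif s < pos < e:  # inside a deletion: collapse to its start
            return s + off
        else:
            break
    return pos + off


def apply_variants(
    template: AlleleRecord, variants: list[Variant], gene: Optional[str] = None,
    phased_read_ids: Optional[set[str]] = None, mean_depth: float = 0.0,
) -> HaplotypeConsensus:
    """Apply non-overlapping variants to the template, lifting features.

    Variants are applied right-to-left so earlier coordinates stay
    valid; exon/intron intervals are carried through the indel offsets
    for downstream coding-sequence work.
    """
    ordered = sorted(variants, key=lambda v: v.position)
    for a, b in zip(ordered, ordered[1:]):
        if max(a.span[0], b.span[0]) < min(a.span[1], b.span[1]):
            raise ValueError("overlapping variants cannot be applied")
    seq = template.sequence
    out = list(seq)
    for v in reversed(ordered):
        s, e = v.span
        if seq[s:e] != v.ref:
            raise ValueError(
                f"ref mismatch at {v.position}: template has {seq[s:e]!r}, "
                f"variant claims {v.ref!r}"
            )
        out[s:e] = list(v.alt)
    lifted = [
        (kind, _lift(s, ordered), _lift(e, ordered))
        for kind, s, e in template.features
    ]
    lifted = [(k, s, e) for k, s, e in lifted if e > s]
    return HaplotypeConsensus(
        gene=gene or template.gene,
        template_allele_id=template.allele_id,
        sequence="".join(out),
        features=lifted,
        applied_variants=ordered,
        phased_read_ids=phased_read_ids or set(),
        mean_depth=mean_depth,
    )


def consensus_qv(consensus: str, truth: str) -> tuple[int, float]:
    """Edit distance and quality value of a consensus against truth.

    QV = -10 log10(edits / alignment columns), capped at 60 when the
    sequences are identical.
    """
    if not consensus or not truth:
        raise ValueError("consensus_qv requires non-empty sequences")
    aln = align_pair(consensus, truth, "global")
    edits = aln.edit_count
    columns = sum(n for n, _ in parse_cigar(aln.cigar))
    if edits == 0:
        return 0, QV_CAP
    return edits, min(QV_CAP, -10.0 * math.log10(edits / columns))


def aggregate_qv(pairs: Iterable[tuple[int, int]]) -> float:
    """Pooled QV over (edits, columns) pairs: -10 log10(sum e / sum cols)."""
    e = sum(p[0] for p in pairs)
    c = sum(p[1] for p in pairs)
    if c == 0:
        raise ValueError("no aligned columns")
    if e == 0:
        return QV_CAP
    return min(QV_CAP, -10.0 * math.log10(e / c))


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Covering reads">\n'
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
)
VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def format_vcf_records(variants: list[Variant], template: AlleleRecord) -> str:
    """VCF body lines (1-based, indels anchored on the preceding base)."""
    lines = []
    for v in variants:
        if v.kind == "snv":
            pos1, ref, alt = v.position + 1, v.ref, v.alt
        elif v.kind == "ins":
            anchor = v.position - 1 if v.position > 0 else 0
            base = template.sequence[anchor]
            pos1, ref, alt = anchor + 1, base, base + v.alt
        else:
            anchor = v.position - 1 if v.position > 0 else 0
            base = template.sequence[anchor]
            pos1, ref, alt = anchor + 1, base + v.ref, base
        lines.append(
            f"{v.template_allele_id}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t"
            f"SUPPORT={v.support};DP={v.depth};AF={v.af:.3f}\n"
        )
    return "".join(lines)


def write_vcf(variants: list[Variant], template: AlleleRecord, path) -> None:
    """Minimal VCF: template allele as contig, 1-based anchored records."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"##contig=<ID={template.allele_id},length={len(template.sequence)}>\n")
        fh.write(VCF_COLUMNS)
        fh.write(format_vcf_records(variants, template))
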