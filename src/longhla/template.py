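"""Diploid template allele pair selection from read support.

Every informative read of a gene is aligned to all full-length alleles of
that gene; among the alleles covering the same read, only those that
never lose a pairwise MOI comparison (the undominated set) count as
supported by that read.  Per allele a three-metric support tuple

    S(A) = (n, c, m)

accumulates: ``n`` unique supporting reads, ``c`` fractional read
coverage (a read supporting k alleles contributes 1/k to each), and
``m`` matched base pairs (divided by k the same way).  Pair scores add
elementwise, S(A,B) = S(A) + S(B); distinct pairs are ranked
lexicographically on (c, n, m) descending and the winner becomes the
template pair.  If one member's coverage is more than four times smaller
than the other's, that member is dropped and the genotype is forced
homozygous on the stronger allele.

Coverage leads the ranking because ``n`` double-counts reads that tie
between near-identical alleles: a pair of siblings differing by one
hard-to-observe base collects every shared read in both members' ``n``
and would outrank the true genotype, whereas the fractional division
built into ``c`` (and ``m``) neutralizes exactly that inflation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .aligner import Alignment, align_pair, trim_alignment
from .allele_db import AlleleRecord
from .extraction import GeneReadSet
from .moi import DiffEvent, Outcome, difference_events, moi_compare

logger = logging.getLogger(__name__)

DEFAULT_TOP_K_HIFI = 15
DEFAULT_TOP_K_R10 = 30
DEFAULT_HOMO_RATIO = 4.0
DEFAULT_SUPPORT_EDIT_FRACTION = 0.15


@dataclass
class SupportTuple:
    n: int = 0
    c: float = 0.0
    m: float = 0.0

    def add(self, other: "SupportTuple") -> "SupportTuple":
        return SupportTuple(self.n + other.n, self.c + other.c, self.m + other.m)

    def key(self) -> tuple[float, int, float]:
        """Ranking key: coverage first, then read count, then matched bases."""
        return (self.c, self.n, self.m)


@dataclass
class GeneSupport:
    """Read-support bookkeeping for one gene."""

    gene: str
    pool: dict[str, SupportTuple]
    read_support: dict[str, list[str]]  # read_id -> supported allele_ids
    alignments: dict[tuple[str, str], Alignment]  # (read_id, allele_id) -> aln
    events: dict[tuple[str, str], list[DiffEvent]]
    alleles: dict[str, AlleleRecord]


@dataclass
class TemplatePair:
    gene: str
    allele_1: AlleleRecord
    allele_2: AlleleRecord
    score_1: SupportTuple
    score_2: SupportTuple
    forced_homozygous: bool = False

    @property
    def pair_score(self) -> SupportTuple:
        return self.score_1.add(self.score_2)

    @property
    def is_homozygous(self) -> bool:
        return self.allele_1.allele_id == self.allele_2.allele_id


def build_support(
    gene_reads: GeneReadSet,
    gene_alleles: list[AlleleRecord],
    *,
    tie_mode: str = "strict",
    min_gap: int = 3,
    max_edit_fraction: float = DEFAULT_SUPPORT_EDIT_FRACTION,
) -> GeneSupport:
    """Align reads to the gene's full-length alleles and accumulate support.

    Reads arrive pre-oriented (extraction stores them in anchor frame),
    so alignment runs on the forward strand only.  Alignments and their
    difference events are cached for reuse during phasing and variant
    calling.
    """
    candidates = [a for a in gene_alleles if not a.is_partial]
    pool = {a.allele_id: SupportTuple() for a in candidates}
    read_support: dict[str, list[str]] = {}
    aln_cache: dict[tuple[str, str], Alignment] = {}
    ev_cache: dict[tuple[str, str], list[DiffEvent]] = {}
    for read in gene_reads.reads:
        k_band = max(1, int(max_edit_fraction * len(read.sequence)))
        alns: list[Alignment] = []
        for allele in candidates:
            aln = align_pair(
                read.sequence,
                allele.sequence,
                "semi_global",
                query_id=read.read_id,
                target_id=allele.allele_id,
                max_edits=k_band,
            )
            if aln is None:
                continue
            aln = trim_alignment(aln)  # clip flank carried past the allele
            if aln is None:
                continue
            alns.append(aln)
            aln_cache[(read.read_id, allele.allele_id)] = aln
            ev_cache[(read.read_id, allele.allele_id)] = difference_events(aln, min_gap)
        if not alns:
            continue
        # undominated set: never losing a pairwise MOI comparison
        losers: set[str] = set()
        for a, b in combinations(alns, 2):
            verdict = moi_compare(
                a, b, tie_mode, min_gap,
                events_a=ev_cache[(read.read_id, a.target_id)],
                events_b=ev_cache[(read.read_id, b.target_id)],
            )
            if verdict.outcome is Outcome.FIRST_BETTER:
                losers.add(b.target_id)
            elif verdict.outcome is Outcome.SECOND_BETTER:
                losers.add(a.target_id)
        supported = sorted(a.target_id for a in alns if a.target_id not in losers)
        if not supported:
            continue
        k = len(supported)
        for allele_id in supported:
            t = pool[allele_id]
            t.n += 1
            t.c += 1.0 / k
            t.m += aln_cache[(read.read_id, allele_id)].matched_bases / k
        read_support[read.read_id] = supported
    if not any(t.n for t in pool.values()):
        warnings.warn(f"gene {gene_reads.gene}: no read supports any allele")
    return GeneSupport(
        gene=gene_reads.gene,
        pool=pool,
        read_support=read_support,
        alignments=aln_cache,
        events=ev_cache,
        alleles={a.allele_id: a for a in candidates},
    )


def select_template_pair(
    support: GeneSupport,
    top_k: int = DEFAULT_TOP_K_HIFI,
    homo_ratio: float = DEFAULT_HOMO_RATIO,
) -> Optional[TemplatePair]:
    """Pick the best-supported allele pair for one gene.

    Candidates are pruned to the ``top_k`` alleles with highest coverage
    ``c`` (ties by ``m`` then allele_id); all distinct pairs are ranked
    by their summed tuple compared lexicographically on (c, n, m)
    descending.  After ranking, the four-fold coverage rule may force the
    pair homozygous.  Returns ``None`` when nothing is supported.
    """
    supported = [aid for aid, t in support.pool.items() if t.n > 0]
    if not supported:
        return None
    ranked = sorted(
        supported,
        key=lambda aid: (-support.pool[aid].c, -support.pool[aid].m, aid),
    )[:top_k]
    if len(ranked) == 1:
        aid = ranked[0]
        allele = support.alleles[aid]
        return TemplatePair(
            gene=support.gene, allele_1=allele, allele_2=allele,
            score_1=support.pool[aid], score_2=support.pool[aid],
            forced_homozygous=True,
        )
    best: Optional[tuple] = None
    best_pair: Optional[tuple[str, str]] = None
    for a, b in combinations(ranked, 2):
        s = support.pool[a].add(support.pool[b])
        key = s.key()
        a1, a2 = sorted((a, b))
        if best is None or key > best or (key == best and (a1, a2) < best_pair):
            best = key
            best_pair = (a1, a2)
    a1, a2 = best_pair
    t1, t2 = support.pool[a1], support.pool[a2]
    forced = False
    # four-fold rule: strictly smaller than a quarter of the other's coverage
    if min(t1.c, t2.c) * homo_ratio < max(t1.c, t2.c):
        keep = a1 if t1.c >= t2.c else a2
        a1 = a2 = keep
        t1 = t2 = support.pool[keep]
        forced = True
    return TemplatePair(
        gene=support.gene,
        allele_1=support.alleles[a1],
        allele_2=support.alleles[a2],
        score_1=t1,
        score_2=t2,
        forced_homozygous=forced,
    )


def write_template_report(pairs: dict[str, Optional[TemplatePair]], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tallele_1\tallele_2\tn1\tc1\tm1\tn2\tc2\tm2\tforced_homozygous\n"
        )
        for gene in sorted(pairs):
            p = pairs[gene]
            if p is None:
                fh.write(f"{gene}\tno_call\tno_call\t0\t0\t0\t0\t0\t0\t0\n")
                continue
            fh.write(
                f"{gene}\t{p.allele_1.name}\t{p.allele_2.name}\t"
                f"{p.score_1.n}\t{p.score_1.c:.3f}\t{p.score_1.m:.1f}\t"
                f"{p.score_2.n}\t{p.score_2.c:.3f}\t{p.score_2.m:.1f}\t"
                f"{int(p.forced_homozygous)}\n"
            )
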