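"""Informative read extraction against the anchor allele panel.

A raw read is screened against every anchor (targeted-gene representatives
plus paralog decoys) on both strands.  Mappings whose mismatch rate is
more than ``ratio`` times the read's best rate are discarded — this is
what routes paralog-derived reads to their decoy anchor and out of the
targeted sets.  A surviving mapping to a targeted anchor makes the read
informative for that anchor's gene when it covers at least 40% of the
anchor length or at least 200 bases touching either anchor end.  A read
may be informative for several genes; each gene pipeline then resolves
ownership during template selection.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .aligner import Alignment, align_read, reverse_complement, trim_alignment
from .allele_db import AlleleDatabase, AlleleRecord, AnchorSet

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_THRESHOLD = 0.40
DEFAULT_END_ANCHOR_BASES = 200
DEFAULT_MISMATCH_RATIO = 10.0
DEFAULT_MISMATCH_FLOOR = 0.001
DEFAULT_MAX_EDIT_FRACTION = 0.25


@dataclass
class ReadMapping:
    """One read-to-anchor screening alignment with extraction metrics."""

    read_id: str
    allele_id: str
    gene: str
    alignment: Alignment
    mismatch_rate: float
    anchor_coverage_fraction: float
    end_anchored_bases: int


@dataclass
class GeneRead:
    read_id: str
    sequence: str  # oriented to the anchor '+' frame (reverse-complemented if needed)
    strand: str  # orientation applied relative to the input read
    mappings: list[ReadMapping] = field(default_factory=list)


@dataclass
class GeneReadSet:
    gene: str
    reads: list[GeneRead] = field(default_factory=list)


def make_mapping(read_id: str, anchor: AlleleRecord, aln: Alignment) -> ReadMapping:
    ts, te = aln.target_interval
    span = te - ts
    alen = len(anchor.sequence)
    end_bases = span if (ts == 0 or te == alen) else 0
    return ReadMapping(
        read_id=read_id,
        allele_id=anchor.allele_id,
        gene=anchor.gene,
        alignment=aln,
        mismatch_rate=aln.edit_count / max(1, span),
        anchor_coverage_fraction=span / alen,
        end_anchored_bases=end_bases,
    )


def is_informative(
    mapping: ReadMapping,
    anchor: AlleleRecord,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    end_anchor_bases: int = DEFAULT_END_ANCHOR_BASES,
) -> bool:
    """Anchor-overlap rule: >=40% of anchor length, or >=200 bp from one end.

    Both thresholds are inclusive.
    """
    return (
        mapping.anchor_coverage_fraction >= coverage_threshold
        or mapping.end_anchored_bases >= end_anchor_bases
    )


def filter_by_mismatch_ratio(
    mappings: list[ReadMapping],
    ratio: float = DEFAULT_MISMATCH_RATIO,
    floor: float = DEFAULT_MISMATCH_FLOOR,
) -> list[ReadMapping]:
    """Drop mappings whose mismatch rate exceeds ``ratio`` x the read's best.

    The reference rate is floored at ``floor`` so that a perfect best
    mapping (rate 0) does not annihilate near-perfect co-mappings needed
    for heterozygote support.  At least one mapping always survives.
    """
    if not mappings:
        raise ValueError("filter_by_mismatch_ratio requires a non-empty list")
    r_min = max(min(m.mismatch_rate for m in mappings), floor)
    return [m for m in mappings if m.mismatch_rate <= ratio * r_min]


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzip FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def extract_informative_reads(
    reads: Iterable[tuple[str, str]],
    anchors: AnchorSet,
    db: AlleleDatabase,
    *,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    end_anchor_bases: int = DEFAULT_END_ANCHOR_BASES,
    mismatch_ratio: float = DEFAULT_MISMATCH_RATIO,
    mismatch_floor: float = DEFAULT_MISMATCH_FLOOR,
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
) -> dict[str, GeneReadSet]:
    """Partition a read stream into per-gene informative read sets.

    Returns a dict keyed by targeted gene symbol (every targeted gene
    present in the database gets an entry, possibly empty).  Each
    retained read is stored oriented to its best anchor's forward frame
    so downstream allele alignments can run single-stranded.
    """
    anchor_by_id = {a.allele_id: a for a in anchors.anchors}
    targeted = {a.allele_id for a, t in zip(anchors.anchors, anchors.target_flags) if t}
    sets: dict[str, GeneReadSet] = {
        g: GeneReadSet(gene=g) for g in db.targeted_genes if g in db.genes
    }
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        if not seq:
            continue
        mappings: list[ReadMapping] = []
        for anchor in anchors.anchors:
            aln = align_read(
                seq,
                anchor.sequence,
                read_id=read_id,
                target_id=anchor.allele_id,
                max_edits=max(1, int(max_edit_fraction * len(seq))),
            )
            if aln is None:
                continue
            # soft-clip flanking sequence the read carries beyond the anchor
            aln = trim_alignment(aln)
            if aln is not None:
                mappings.append(make_mapping(read_id, anchor, aln))
        if not mappings:
            continue
        kept = filter_by_mismatch_ratio(mappings, mismatch_ratio, mismatch_floor)
        per_gene: dict[str, list[ReadMapping]] = {}
        for m in kept:
            if m.allele_id not in targeted:
                continue
            if is_informative(m, anchor_by_id[m.allele_id], coverage_threshold, end_anchor_bases):
                per_gene.setdefault(m.gene, []).append(m)
        for gene, ms in per_gene.items():
            if gene not in sets:
                continue
            best = min(ms, key=lambda m: m.mismatch_rate)
            strand = best.alignment.strand
            oriented = seq if strand == "+" else reverse_complement(seq)
            sets[gene].reads.append(
                GeneRead(read_id=read_id, sequence=oriented, strand=strand, mappings=ms)
            )
    if n_reads == 0:
        warnings.warn("empty read input: no informative reads extracted")
    return sets


def write_extraction_report(sets: dict[str, GeneReadSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene\tbest_anchor\tmismatch_rate\trule\n")
        for gene in sorted(sets):
            for r in sets[gene].reads:
                best = min(r.mappings, key=lambda m: m.mismatch_rate)
                rule = (
                    "coverage"
                    if best.anchor_coverage_fraction >= DEFAULT_COVERAGE_THRESHOLD
                    else "end_anchor"
                )
                fh.write(
                    f"{r.read_id}\t{gene}\t{best.allele_id}\t"
                    f"{best.mismatch_rate:.5f}\t{rule}\n"
                )
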