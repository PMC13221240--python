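"""Reference allele database: parsing, validation, CDS, anchor clustering.

The database is a multi-FASTA of full-length (or exon-only partial) allele
sequences plus a structure sidecar: a BED-dialect TSV with one row per
feature, ``allele_id  start  end  kind`` in 0-based half-open coordinates
on the allele's own sequence.  Allele names follow the four-field
nomenclature ``GENE*f1:f2:f3:f4`` (1-4 fields, optional trailing
expression suffix letter); the gene symbol is everything before ``*``.

Anchor alleles are cluster representatives obtained by greedy incremental
clustering at a global-identity cutoff, per gene; anchors of non-targeted
genes act as paralog decoys during read extraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .aligner import align_pair, parse_cigar

logger = logging.getLogger(__name__)

#: the six classical genes targeted by default on a real database
DEFAULT_TARGETED_GENES = ("A", "B", "C", "DRB1", "DQA1", "DQB1")

FEATURE_KINDS = ("exon", "intron", "utr")


@dataclass
class AlleleRecord:
    """One reference allele: sequence plus exon/intron structure."""

    allele_id: str
    name: str
    sequence: str
    features: list[tuple[str, int, int]]
    is_partial: bool = False

    @property
    def gene(self) -> str:
        return self.name.split("*", 1)[0]

    @property
    def exons(self) -> list[tuple[int, int]]:
        return [(s, e) for kind, s, e in self.features if kind == "exon"]

    def validate(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError(f"{self.allele_id}: invalid sequence alphabet")
        if "*" not in self.name:
            raise ValueError(f"{self.allele_id}: name {self.name!r} lacks gene symbol")
        if not self.features:
            raise ValueError(f"{self.allele_id}: no structure rows")
        prev_end = 0
        for kind, s, e in self.features:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"{self.allele_id}: unknown feature kind {kind!r}")
            if not (0 <= s < e <= len(seq)):
                raise ValueError(
                    f"{self.allele_id}: feature [{s},{e}) outside sequence "
                    f"bounds [0,{len(seq)})"
                )
            if s < prev_end:
                raise ValueError(f"{self.allele_id}: overlapping/unsorted features")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.allele_id}: no exon feature")
        if not self.is_partial:
            covered = sum(e - s for _, s, e in self.features)
            if covered != len(seq):
                raise ValueError(
                    f"{self.allele_id}: features do not tile non-partial sequence"
                )

    def name_fields(self) -> list[str]:
        """Numeric name fields after the gene symbol (suffix stripped)."""
        return split_fields(self.name)


def split_fields(name: str) -> list[str]:
    body = name.split("*", 1)[1]
    fields = body.split(":")
    fields[-1] = fields[-1].rstrip("NLSCAQ")  # expression suffixes
    return fields


def truncate_name(name: str, n_fields: int) -> str:
    """``GENE*f1:...`` truncated to at most ``n_fields`` fields, no suffix."""
    gene = name.split("*", 1)[0]
    return gene + "*" + ":".join(split_fields(name)[:n_fields])


def complement_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Sorted complement of non-overlapping intervals within [0, length)."""
    out = []
    pos = 0
    for s, e in sorted(intervals):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


@dataclass
class AlleleDatabase:
    alleles: dict[str, AlleleRecord]
    targeted_genes: tuple[str, ...] = DEFAULT_TARGETED_GENES

    @property
    def genes(self) -> set[str]:
        return {a.gene for a in self.alleles.values()}

    def by_gene(self, gene: str, *, full_length_only: bool = False) -> list[AlleleRecord]:
        out = [a for a in self.alleles.values() if a.gene == gene]
        if full_length_only:
            out = [a for a in out if not a.is_partial]
        out.sort(key=lambda a: a.allele_id)
        return out

    def validate(self) -> None:
        names = {}
        for a in self.alleles.values():
            a.validate()
            if a.name in names:
                raise ValueError(f"duplicate allele name {a.name!r}")
            names[a.name] = a.allele_id
        for gene in self.targeted_genes:
            if gene in self.genes and not self.by_gene(gene, full_length_only=True):
                raise ValueError(f"targeted gene {gene} has no full-length allele")


def parse_allele_fasta(
    fasta_path: str | Path,
    structure_path: str | Path,
    targeted_genes: Iterable[str] = DEFAULT_TARGETED_GENES,
) -> AlleleDatabase:
    """Load the allele FASTA + structure sidecar into a validated database.

    FASTA headers carry ``allele_id name [partial]``.  Records whose
    structure rows are exon-only but do not tile the sequence get introns
    inferred as the complement intervals (full-length record with sparse
    annotation); records flagged ``partial`` keep exon-only features.
    """
    rows: dict[str, list[tuple[str, int, int]]] = {}
    with open(structure_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{structure_path}:{lineno}: expected 4 columns")
            allele_id, start, end, kind = parts
            rows.setdefault(allele_id, []).append((kind, int(start), int(end)))

    alleles: dict[str, AlleleRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tokens = rec.description.split()
        allele_id = tokens[0]
        if len(tokens) < 2:
            raise ValueError(f"{allele_id}: FASTA header lacks allele name")
        name = tokens[1]
        is_partial = "partial" in tokens[2:]
        if allele_id not in rows:
            raise ValueError(f"{allele_id}: no structure rows in sidecar")
        feats = sorted(rows[allele_id], key=lambda f: f[1])
        seq = str(rec.seq).upper()
        if not is_partial:
            covered = sum(e - s for _, s, e in feats)
            if covered < len(seq) and all(k == "exon" for k, _, _ in feats):
                exon_ivs = [(s, e) for _, s, e in feats]
                feats = sorted(
                    feats + [("intron", s, e) for s, e in complement_intervals(exon_ivs, len(seq))],
                    key=lambda f: f[1],
                )
        alleles[allele_id] = AlleleRecord(
            allele_id=allele_id, name=name, sequence=seq,
            features=feats, is_partial=is_partial,
        )
    db = AlleleDatabase(alleles=alleles, targeted_genes=tuple(targeted_genes))
    db.validate()
    return db


def coding_sequence(allele: AlleleRecord) -> str:
    """Concatenation of exon subsequences in feature order."""
    return "".join(allele.sequence[s:e] for s, e in allele.exons)


@dataclass
class AnchorSet:
    """Cluster representatives used to fish informative reads from WGS data."""

    anchors: list[AlleleRecord]
    target_flags: list[bool]
    identity_cutoff: float
    cluster_sizes: list[int] = field(default_factory=list)

    @property
    def targeted_anchors(self) -> list[AlleleRecord]:
        return [a for a, t in zip(self.anchors, self.target_flags) if t]

    def write(self, fasta_path: str | Path, manifest_path: str | Path) -> None:
        with open(fasta_path, "w") as fa:
            for a in self.anchors:
                fa.write(f">{a.allele_id} {a.name}\n{a.sequence}\n")
        with open(manifest_path, "w") as mf:
            mf.write("anchor_id\tgene\ttargeted\tcluster_size\n")
            for a, t, n in zip(self.anchors, self.target_flags, self.cluster_sizes):
                mf.write(f"{a.allele_id}\t{a.gene}\t{int(t)}\t{n}\n")


def global_identity(a: str, b: str) -> float:
    """matches / alignment columns under unit-cost global alignment."""
    aln = align_pair(a, b, "global")
    columns = sum(n for n, _ in parse_cigar(aln.cigar))
    return aln.matched_bases / columns


def build_anchor_set(db: AlleleDatabase, identity_cutoff: float = 0.95) -> AnchorSet:
    """Greedy incremental clustering per gene; representatives become anchors.

    Full-length alleles are visited in length-descending (then allele_id)
    order; each joins the first-founded cluster whose representative it
    matches at >= ``identity_cutoff`` global identity, else founds a new
    cluster.  Genes with only partial alleles are excluded with a warning.
    """
    if not 0.5 < identity_cutoff <= 1.0:
        raise ValueError("identity_cutoff must be in (0.5, 1]")
    anchors: list[AlleleRecord] = []
    flags: list[bool] = []
    sizes: list[int] = []
    for gene in sorted(db.genes):
        members = db.by_gene(gene, full_length_only=True)
        if not members:
            warnings.warn(f"gene {gene} has only partial alleles; no anchors built")
            continue
        members.sort(key=lambda a: (-len(a.sequence), a.allele_id))
        reps: list[AlleleRecord] = []
        counts: list[int] = []
        for allele in members:
            placed = False
            for i, rep in enumerate(reps):
                if global_identity(allele.sequence, rep.sequence) >= identity_cutoff:
                    counts[i] += 1
                    placed = True
                    break
            if not placed:
                reps.append(allele)
                counts.append(1)
        targeted = gene in db.targeted_genes
        anchors.extend(reps)
        flags.extend([targeted] * len(reps))
        sizes.extend(counts)
    return AnchorSet(
        anchors=anchors, target_flags=flags,
        identity_cutoff=identity_cutoff, cluster_sizes=sizes,
    )
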