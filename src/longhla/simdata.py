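"""Synthetic allele databases and diploid long-read samples with known truth.

The generator emulates the structure of a curated HLA allele database at
desk scale: several targeted genes, each with an exon/intron partition
and a family of alleles organized by the four-field nomenclature, plus
paralog decoy genes at larger divergence.  Field semantics drive where
mutations are planted so field-resolution evaluation is meaningful:

* field-2 groups are founded by mutations across the whole gene
  (exonic and intronic) at the within-gene divergence rate;
* field-3 variants differ from their field-2 founder by 1-2 exonic
  substitutions;
* field-4 variants differ by 1-3 intronic substitutions.

Reads are drawn per haplotype from the allele embedded in random flank
sequence, on either strand, with independent per-base substitution and
indel errors; the R10 profile scales indel rates by homopolymer run
length (runs >= 4) to reproduce the characteristic homopolymer failure
mode of nanopore data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .aligner import reverse_complement
from .allele_db import AlleleDatabase, AlleleRecord

BASES = "ACGT"

#: per-base error rates by profile: (substitution, insertion+deletion)
ERROR_PROFILES = {
    "hifi": {"sub": 0.002, "indel": 0.002, "homopolymer_boost": False},
    "r10": {"sub": 0.01, "indel": 0.02, "homopolymer_boost": True},
    "exact": {"sub": 0.0, "indel": 0.0, "homopolymer_boost": False},
}


@dataclass
class SimConfig:
    """Study conditions for database generation and read simulation."""

    n_genes_target: int = 6
    n_decoy_genes: int = 2
    alleles_per_gene: int = 20
    gene_length_range: tuple[int, int] = (3000, 6000)
    exon_count_range: tuple[int, int] = (4, 8)
    within_gene_divergence: float = 0.03
    between_paralog_divergence: float = 0.10
    #: decoy alleles sit beyond the anchor clustering radius of each other,
    #: so each founds its own cluster and absorbs its reads at pure-error
    #: mismatch rates (paralog families are diverse in real databases)
    decoy_within_divergence: float = 0.06
    partial_fraction: float = 0.1
    depth_per_haplotype: float = 30.0
    read_length_mean: int = 4000
    flank_length: int = 300
    error_profile: str = "hifi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_gene_divergence >= self.between_paralog_divergence:
            raise ValueError(
                "within-gene divergence must stay below paralog divergence "
                "or genes would blur together"
            )
        if self.error_profile not in ERROR_PROFILES:
            raise ValueError(f"unknown error profile {self.error_profile!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mutate_subs(
    rng: np.random.Generator, seq: str, positions: np.ndarray
) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def _partition_gene(
    rng: np.random.Generator, length: int, n_exons: int
) -> list[tuple[str, int, int]]:
    """Exon/intron partition tiling [0, length), alternating from intron."""
    # exons take roughly 40% of the gene
    exon_total = int(0.4 * length)
    exon_lens = rng.multinomial(exon_total - 60 * n_exons, [1 / n_exons] * n_exons) + 60
    intron_total = length - int(exon_lens.sum())
    n_introns = n_exons + 1
    intron_lens = rng.multinomial(intron_total - 50 * n_introns, [1 / n_introns] * n_introns) + 50
    feats = []
    pos = 0
    for i in range(n_exons):
        s = pos + int(intron_lens[i])
        e = s + int(exon_lens[i])
        feats.append(("intron", pos, s))
        feats.append(("exon", s, e))
        pos = e
    feats.append(("intron", pos, length))
    return feats


@dataclass
class TruthDB:
    db: AlleleDatabase
    #: gene -> allele name -> allele_id
    names: dict[str, dict[str, str]]


def _pick_positions(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    count: int,
    used: set[int],
) -> list[int]:
    """Distinct positions inside the given intervals, avoiding ``used``."""
    pool = np.concatenate([np.arange(s, e) for s, e in intervals])
    pool = np.array([p for p in pool if p not in used])
    count = min(count, len(pool))
    picks = rng.choice(pool, size=count, replace=False)
    used.update(int(p) for p in picks)
    return [int(p) for p in picks]


def generate_allele_db(cfg: SimConfig) -> TruthDB:
    """Build a synthetic multi-gene allele database with known relationships."""
    rng = np.random.default_rng(cfg.seed)
    alleles: dict[str, AlleleRecord] = {}
    names: dict[str, dict[str, str]] = {}
    counter = 0

    def add(name: str, seq: str, feats, partial: bool) -> AlleleRecord:
        nonlocal counter
        counter += 1
        rec = AlleleRecord(
            allele_id=f"SYN{counter:05d}", name=name, sequence=seq,
            features=[tuple(f) for f in feats], is_partial=partial,
        )
        alleles[rec.allele_id] = rec
        return rec

    target_genes = [f"G{i + 1}" for i in range(cfg.n_genes_target)]
    decoy_genes = [f"P{i + 1}" for i in range(cfg.n_decoy_genes)]
    ancestors: dict[str, tuple[str, list]] = {}

    for gene in target_genes:
        length = int(rng.integers(*cfg.gene_length_range))
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        feats = _partition_gene(rng, length, n_exons)
        ancestral = _random_seq(rng, length)
        ancestors[gene] = (ancestral, feats)
        exon_ivs = [(s, e) for k, s, e in feats if k == "exon"]
        intron_ivs = [(s, e) for k, s, e in feats if k == "intron"]
        names[gene] = {}

        # field-2 founders, each mutated across the whole gene
        n_f2 = max(1, cfg.alleles_per_gene // 5)
        remaining = cfg.alleles_per_gene
        made: list[tuple[str, str]] = []  # (name, sequence)
        for f2 in range(1, n_f2 + 1):
            if remaining <= 0:
                break
            if f2 == 1:
                seq = ancestral
            else:
                n_mut = max(2, int(cfg.within_gene_divergence * length))
                pos = rng.choice(length, size=n_mut, replace=False)
                seq = _mutate_subs(rng, ancestral, pos)
            name = f"{gene}*01:{f2:02d}:01:01"
            made.append((name, seq))
            remaining -= 1
        # derive field-3 / field-4 variants from random existing alleles
        f3_counter = {n: 1 for n, _ in made}
        used_positions: dict[str, set[int]] = {n: set() for n, _ in made}
        attempts = 0
        while remaining > 0:
            attempts += 1
            if attempts > 50 * cfg.alleles_per_gene:
                raise RuntimeError(
                    f"gene {gene}: could not place enough distinct alleles; "
                    "raise gene length or lower alleles_per_gene"
                )
            base_name, base_seq = made[int(rng.integers(len(made)))]
            parts = base_name.split("*")[1].split(":")
            used = used_positions.setdefault(base_name, set())
            if rng.random() < 0.5:
                # new field-3: 1-2 exonic substitutions
                k = int(rng.integers(1, 3))
                pos = _pick_positions(rng, exon_ivs, k, used)
                f3 = int(parts[2]) + f3_counter.get(base_name, 1)
                f3_counter[base_name] = f3_counter.get(base_name, 1) + 1
                name = f"{gene}*{parts[0]}:{parts[1]}:{f3:02d}:01"
            else:
                # new field-4: 1-3 intronic substitutions
                k = int(rng.integers(1, 4))
                pos = _pick_positions(rng, intron_ivs, k, used)
                f4 = int(parts[3]) + 1
                name = f"{gene}*{parts[0]}:{parts[1]}:{parts[2]}:{f4:02d}"
                while any(n == name for n, _ in made):
                    f4 += 1
                    name = f"{gene}*{parts[0]}:{parts[1]}:{parts[2]}:{f4:02d}"
            if not pos or any(n == name for n, _ in made):
                continue
            seq = _mutate_subs(rng, base_seq, np.array(pos))
            made.append((name, seq))
            remaining -= 1
        # emit records; a fraction of non-founder alleles become partial
        for i, (name, seq) in enumerate(made):
            partial = i > 0 and rng.random() < cfg.partial_fraction
            if partial:
                cds = "".join(seq[s:e] for s, e in exon_ivs)
                pfeats = []
                off = 0
                for s, e in exon_ivs:
                    pfeats.append(("exon", off, off + (e - s)))
                    off += e - s
                rec = add(name, cds, pfeats, True)
            else:
                rec = add(name, seq, feats, False)
            names[gene][name] = rec.allele_id

    for j, gene in enumerate(decoy_genes):
        src_gene = target_genes[j % len(target_genes)]
        ancestral, feats = ancestors[src_gene]
        length = len(ancestral)
        n_mut = max(2, int(cfg.between_paralog_divergence * length))
        pos = rng.choice(length, size=n_mut, replace=False)
        seq = _mutate_subs(rng, ancestral, pos)
        names[gene] = {}
        for k in range(1, max(2, cfg.alleles_per_gene // 5) + 1):
            if k == 1:
                dseq = seq
            else:
                n2 = max(2, int(cfg.decoy_within_divergence * length))
                dpos = rng.choice(length, size=n2, replace=False)
                dseq = _mutate_subs(rng, seq, dpos)
            name = f"{gene}*01:{k:02d}:01:01"
            rec = add(name, dseq, feats, False)
            names[gene][name] = rec.allele_id

    db = AlleleDatabase(alleles=alleles, targeted_genes=tuple(target_genes))
    db.validate()
    return TruthDB(db=db, names=names)


def write_db(truth: TruthDB, fasta_path: str | Path, structure_path: str | Path) -> None:
    with open(fasta_path, "w") as fa, open(structure_path, "w") as st:
        for aid in sorted(truth.db.alleles):
            rec = truth.db.alleles[aid]
            tag = " partial" if rec.is_partial else ""
            fa.write(f">{rec.allele_id} {rec.name}{tag}\n{rec.sequence}\n")
            for kind, s, e in rec.features:
                st.write(f"{rec.allele_id}\t{s}\t{e}\t{kind}\n")


# ---------------------------------------------------------------------------
# read simulation

_HOMOPOLYMER_MIN_RUN = 4


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run each base belongs to."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(arr) == 0:
        return np.zeros(0, dtype=np.int32)
    boundaries = np.flatnonzero(np.diff(arr) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(arr)]])
    out = np.empty(len(arr), dtype=np.int32)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def _inject_errors(
    rng: np.random.Generator, seq: str, profile: dict
) -> str:
    sub, indel = profile["sub"], profile["indel"]
    if sub == 0 and indel == 0:
        return seq
    n = len(seq)
    indel_rate = np.full(n, indel)
    if profile["homopolymer_boost"]:
        runs = _run_lengths(seq)
        boost = runs >= _HOMOPOLYMER_MIN_RUN
        indel_rate[boost] = np.minimum(0.5, indel * runs[boost])
    out = []
    u_sub = rng.random(n)
    u_ind = rng.random(n)
    u_kind = rng.random(n)
    for i, base in enumerate(seq):
        if u_ind[i] < indel_rate[i]:
            if u_kind[i] < 0.5:
                out.append(base + rng.choice(list(BASES)))  # insertion after
            # else: deletion — emit nothing
            continue
        if u_sub[i] < sub:
            out.append(rng.choice([b for b in BASES if b != base]))
        else:
            out.append(base)
    return "".join(out)


@dataclass
class SimulatedReads:
    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth_rows: list[dict]  # read_id, gene, hap, allele_name, start, end, strand
    #: (gene, hap) -> the flanked haplotype sequence reads were drawn from
    contexts: dict[tuple[str, int], str] = field(default_factory=dict)


def simulate_reads(
    truth: TruthDB,
    genotype: dict[str, tuple[str, str]],
    cfg: SimConfig,
    *,
    rng: Optional[np.random.Generator] = None,
    haplotype_overrides: Optional[dict[tuple[str, int], str]] = None,
) -> SimulatedReads:
    """Simulate diploid reads for a genotype (gene -> pair of allele names).

    ``haplotype_overrides`` maps (gene, hap index) to an explicit
    haplotype sequence, used to plant novel variants absent from the
    database.  Reads are embedded in per-haplotype random flank so they
    can start upstream of the gene, drawn on either strand.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if cfg.depth_per_haplotype <= 0:
        raise ValueError("depth must be positive")
    profile = ERROR_PROFILES[cfg.error_profile]
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    contexts: dict[tuple[str, int], str] = {}
    rid = 0
    for gene in sorted(genotype):
        pair = genotype[gene]
        for hap, allele_name in enumerate(pair, start=1):
            if haplotype_overrides and (gene, hap) in haplotype_overrides:
                hap_seq = haplotype_overrides[(gene, hap)]
            else:
                rec = truth.db.alleles[truth.names[gene][allele_name]]
                if rec.is_partial:
                    raise ValueError(f"cannot simulate from partial allele {allele_name}")
                hap_seq = rec.sequence
            ctx = (
                _random_seq(rng, cfg.flank_length)
                + hap_seq
                + _random_seq(rng, cfg.flank_length)
            )
            contexts[(gene, hap)] = ctx
            n_reads = int(np.ceil(cfg.depth_per_haplotype * len(ctx) / cfg.read_length_mean))
            for _ in range(n_reads):
                length = int(rng.normal(cfg.read_length_mean, 0.1 * cfg.read_length_mean))
                length = max(500, min(length, len(ctx)))
                start = int(rng.integers(0, len(ctx) - length + 1))
                fragment = ctx[start : start + length]
                observed = _inject_errors(rng, fragment, profile)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    observed = reverse_complement(observed)
                rid += 1
                read_id = f"sim_{gene}_h{hap}_{rid:06d}"
                reads.append((read_id, observed))
                rows.append(
                    dict(
                        read_id=read_id, gene=gene, hap=hap,
                        allele_name=allele_name, start=start,
                        end=start + length, strand=strand,
                    )
                )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return SimulatedReads(reads=reads, truth_rows=rows, contexts=contexts)


def write_fastq(sim: SimulatedReads, path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq in sim.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(sim: SimulatedReads, genotype: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#genotype\t" + ";".join(
            f"{g}={a1}/{a2}" for g, (a1, a2) in sorted(genotype.items())
        ) + "\n")
        fh.write("read_id\tgene\thap\tallele_name\tstart\tend\tstrand\n")
        for r in sim.truth_rows:
            fh.write(
                f"{r['read_id']}\t{r['gene']}\t{r['hap']}\t{r['allele_name']}\t"
                f"{r['start']}\t{r['end']}\t{r['strand']}\n"
            )


def random_genotype(
    truth: TruthDB,
    rng: np.random.Generator,
    *,
    homozygous: bool = False,
    genes: Optional[list[str]] = None,
) -> dict[str, tuple[str, str]]:
    """Draw a diploid genotype from the database's full-length alleles."""
    genotype = {}
    for gene in genes or truth.db.targeted_genes:
        pool = sorted(
            n for n, aid in truth.names[gene].items()
            if not truth.db.alleles[aid].is_partial
        )
        if homozygous or len(pool) == 1:
            a = pool[int(rng.integers(len(pool)))]
            genotype[gene] = (a, a)
        else:
            i, j = rng.choice(len(pool), size=2, replace=False)
            genotype[gene] = (pool[int(i)], pool[int(j)])
    return genotype
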