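"""Seeded simulation studies used by the acceptance checks and benchmarks.

Each study generates a synthetic allele database and diploid samples
with known truth, runs the full typing pipeline, and returns summary
metrics.  Problem sizes are deliberately modest (single-CPU, minutes):
gene lengths around 3 kb and a handful of samples per study, which is
enough coverage-wise (30x per haplotype) for the method's thresholds to
operate as designed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .allele_db import build_anchor_set, truncate_name
from .pipeline import RunConfig, consensus_metrics, evaluate, run_sample
from .simdata import (
    SimConfig,
    TruthDB,
    generate_allele_db,
    random_genotype,
    simulate_reads,
)

#: study-scale conditions: 3 kb genes and 3 kb reads keep single reads
#: spanning most of a gene, as HiFi reads do for real HLA loci
STUDY_DB = dict(
    gene_length_range=(2800, 3400),
    exon_count_range=(4, 6),
    read_length_mean=3000,
    depth_per_haplotype=30.0,
)


def _truth_sequences(truth: TruthDB, genotype: dict) -> dict:
    out = {}
    for gene, (a1, a2) in genotype.items():
        out[gene] = tuple(
            truth.db.alleles[truth.names[gene][a]].sequence for a in (a1, a2)
        )
    return out


def typing_recovery_study(
    seed: int,
    n_samples: int = 20,
    *,
    n_genes: int = 6,
    alleles_per_gene: int = 20,
    error_profile: str = "hifi",
    preset: str = "hifi",
    depth: float = 30.0,
    homozygous: bool = False,
    tie_mode: Optional[str] = None,
    sim_overrides: Optional[dict] = None,
) -> dict:
    """End-to-end diploid typing recovery with truth alleles in the database.

    Returns field-resolution accuracies, consensus perfect-match
    fraction and aggregate QV, plus forced-homozygosity bookkeeping.
    """
    cfg_kwargs = dict(
        STUDY_DB,
        n_genes_target=n_genes,
        n_decoy_genes=2,
        alleles_per_gene=alleles_per_gene,
        error_profile=error_profile,
        depth_per_haplotype=depth,
        seed=seed,
    )
    if sim_overrides:
        cfg_kwargs.update(sim_overrides)
    sim_cfg = SimConfig(**cfg_kwargs)
    truth = generate_allele_db(sim_cfg)
    run_cfg = RunConfig(preset=preset, seed=seed)
    if tie_mode is not None:
        run_cfg.tie_mode = tie_mode
    anchors = build_anchor_set(truth.db, run_cfg.anchor_identity_cutoff)
    reports = []
    truths = {}
    truth_seqs = {}
    rng = np.random.default_rng(seed + 101)
    for i in range(n_samples):
        genotype = random_genotype(truth, rng, homozygous=homozygous)
        sim = simulate_reads(truth, genotype, sim_cfg, rng=rng)
        name = f"s{i:03d}"
        rep = run_sample(sim.reads, truth.db, run_cfg, anchors=anchors, sample=name)
        reports.append(rep)
        truths[name] = genotype
        truth_seqs[name] = _truth_sequences(truth, genotype)
    acc = evaluate(reports, truths)
    overall = acc[acc.gene == "overall"].iloc[0]
    cons = consensus_metrics(reports, truth_seqs)
    forced = sum(
        1
        for rep in reports
        for out in rep.genes.values()
        if out.template is not None and out.template.forced_homozygous
    )
    correct_homozygous = 0
    n_gene_calls = 0
    for rep in reports:
        for gene, pair in truths[rep.sample].items():
            n_gene_calls += 1
            out = rep.genes[gene]
            if out.result is None:
                continue
            c1, c2 = (c.allele_name for c in out.result.calls)
            if pair[0] == pair[1] and c1 == c2 == pair[0]:
                correct_homozygous += 1
    return dict(
        field_accuracy={d: float(overall[f"field{d}_accuracy"]) for d in range(1, 5)},
        n_alleles=int(overall["n_alleles"]),
        consensus=cons,
        forced_homozygous_count=forced,
        n_gene_calls=n_gene_calls,
        correct_homozygous_calls=correct_homozygous,
        per_gene=acc.to_dict(orient="records"),
    )


def _plant_mutations(
    rng: np.random.Generator,
    sequence: str,
    intervals: list[tuple[int, int]],
    k: int,
    min_spacing: int = 15,
) -> tuple[str, int]:
    """Plant k non-adjacent substitutions inside the given intervals.

    Positions keep ``min_spacing`` bases apart and avoid homopolymer
    runs so each plant stays one distinct difference event.
    """
    # stay clear of gene ends: pileup evidence near alignment boundaries
    # is masked, so terminal variants are not recoverable by design
    lo, hi = 100, len(sequence) - 100
    candidates = []
    for s, e in intervals:
        candidates.extend(range(max(s + 2, lo), min(e - 2, hi)))
    rng.shuffle(candidates)
    chosen: list[int] = []
    for p in candidates:
        if len(chosen) >= k:
            break
        if any(abs(p - q) < min_spacing for q in chosen):
            continue
        if sequence[p - 1] == sequence[p] or sequence[p] == sequence[p + 1]:
            continue
        chosen.append(p)
    out = list(sequence)
    for p in chosen:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out), len(chosen)


def novel_allele_study(
    seed: int,
    n_samples: int = 20,
    *,
    n_genes: int = 2,
    alleles_per_gene: int = 10,
    intronic_only: bool = True,
) -> dict:
    """Plant 1-3 mutations absent from the database and type the samples.

    Checks that typing reports status ``novel`` with a CIGAR whose
    difference-event count equals the planted count, and (for intronic
    plants) that the first three name fields stay those of the base
    allele.
    """
    sim_cfg = SimConfig(
        **STUDY_DB,
        n_genes_target=n_genes,
        n_decoy_genes=1,
        alleles_per_gene=alleles_per_gene,
        partial_fraction=0.0,
        error_profile="hifi",
        seed=seed,
    )
    truth = generate_allele_db(sim_cfg)
    run_cfg = RunConfig(preset="hifi", seed=seed)
    anchors = build_anchor_set(truth.db, run_cfg.anchor_identity_cutoff)
    rng = np.random.default_rng(seed + 202)
    n_alleles = 0
    n_novel_with_correct_cigar = 0
    n_novel_status = 0
    field3_stable = 0
    field3_total = 0
    for i in range(n_samples):
        genotype = random_genotype(truth, rng)
        overrides = {}
        planted: dict[tuple[str, int], int] = {}
        base_names: dict[tuple[str, int], str] = {}
        for gene, pair in genotype.items():
            for hap, allele_name in enumerate(pair, start=1):
                rec = truth.db.alleles[truth.names[gene][allele_name]]
                ivs = (
                    [(s, e) for k_, s, e in rec.features if k_ == "intron"]
                    if intronic_only
                    else [(s, e) for _, s, e in rec.features]
                )
                k = int(rng.integers(1, 4))
                mutated, k_actual = _plant_mutations(rng, rec.sequence, ivs, k)
                if k_actual == 0 or any(
                    mutated == a.sequence for a in truth.db.alleles.values()
                ):
                    continue
                overrides[(gene, hap)] = mutated
                planted[(gene, hap)] = k_actual
                base_names[(gene, hap)] = allele_name
        if not overrides:
            continue
        sim = simulate_reads(
            truth, genotype, sim_cfg, rng=rng, haplotype_overrides=overrides
        )
        rep = run_sample(
            sim.reads, truth.db, run_cfg, anchors=anchors, sample=f"nv{i:03d}"
        )
        for gene, pair in genotype.items():
            out = rep.genes[gene]
            if out.result is None:
                n_alleles += sum(1 for h in (1, 2) if (gene, h) in planted)
                continue
            gene_planted = [(h, planted[(gene, h)]) for h in (1, 2) if (gene, h) in planted]
            if not gene_planted:
                continue
            # match calls to haplotypes by consensus sequence
            for hap, k in gene_planted:
                n_alleles += 1
                target_seq = overrides[(gene, hap)]
                best_call = None
                for call, cons in zip(out.result.calls, out.consensus):
                    if cons is not None and cons.sequence == target_seq:
                        best_call = call
                        break
                if best_call is None:
                    continue
                if best_call.status == "novel":
                    n_novel_status += 1
                    from .moi import difference_events
                    from .aligner import Alignment, cigar_consumed

                    cigar = best_call.novel_cigar
                    q, t = cigar_consumed(cigar)
                    aln = Alignment(
                        "c", "t", (0, q), (0, t), cigar,
                        edit_count=0, query_length=q,
                    )
                    n_events = len(difference_events(aln, min_gap=1))
                    if n_events == k:
                        n_novel_with_correct_cigar += 1
                if intronic_only:
                    field3_total += 1
                    base = base_names[(gene, hap)]
                    if truncate_name(best_call.allele_name, 3) == truncate_name(base, 3):
                        field3_stable += 1
    return dict(
        n_planted_alleles=n_alleles,
        novel_status_fraction=n_novel_status / n_alleles if n_alleles else 0.0,
        correct_cigar_fraction=(
            n_novel_with_correct_cigar / n_alleles if n_alleles else 0.0
        ),
        field3_stable=field3_stable,
        field3_total=field3_total,
    )


def homozygote_study(seed: int, n_samples: int = 10) -> dict:
    """Homozygous-genotype recovery and exercise of the 4x forcing rule."""
    res = typing_recovery_study(
        seed,
        n_samples,
        n_genes=3,
        alleles_per_gene=12,
        homozygous=True,
    )
    return dict(
        n_gene_calls=res["n_gene_calls"],
        correct_homozygous_calls=res["correct_homozygous_calls"],
        forced_homozygous_count=res["forced_homozygous_count"],
        field_accuracy=res["field_accuracy"],
    )


def tie_mode_study(seed: int, n_seeds: int = 10) -> dict:
    """Paired comparison of strict vs high-error tie mode on R10-like reads."""
    acc = {"strict": [], "high_error": []}
    field4 = {"strict": [], "high_error": []}
    for i in range(n_seeds):
        for mode in ("strict", "high_error"):
            res = typing_recovery_study(
                seed + i,
                n_samples=1,
                n_genes=2,
                alleles_per_gene=10,
                error_profile="r10",
                preset="r10",
                tie_mode=mode,
            )
            f = res["field_accuracy"]
            acc[mode].append((f[1] + f[2] + f[3]) / 3)
            field4[mode].append(f[4])
    return dict(
        mean_field13_strict=float(np.mean(acc["strict"])),
        mean_field13_high_error=float(np.mean(acc["high_error"])),
        mean_field4_strict=float(np.mean(field4["strict"])),
        mean_field4_high_error=float(np.mean(field4["high_error"])),
        n_seeds=n_seeds,
    )
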