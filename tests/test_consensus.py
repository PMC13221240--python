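import numpy as np
import pytest

from longhla.aligner import align_pair
from longhla.allele_db import AlleleRecord, coding_sequence
from longhla.consensus import (
    HaplotypeConsensus,
    Variant,
    aggregate_qv,
    apply_variants,
    call_variants,
    consensus_qv,
    phase_reads,
    write_vcf,
)
from longhla.extraction import GeneRead, GeneReadSet
from longhla.moi import difference_events
from longhla.template import TemplatePair, build_support

from conftest import mutate, random_dna


def _rec(aid, seq, features=None):
    return AlleleRecord(aid, f"GX*{aid}", seq, features or [("exon", 0, len(seq))], False)


def _gene_reads(seqs, prefix="r"):
    return GeneReadSet(
        "GX", [GeneRead(f"{prefix}{i}", s, "+") for i, s in enumerate(seqs)]
    )


def _setup(template_seqs, read_seqs):
    alleles = [_rec(f"t{i}", s) for i, s in enumerate(template_seqs)]
    reads = _gene_reads(read_seqs)
    support = build_support(reads, alleles)
    return alleles, reads, support


class TestPhaseReads:
    def test_discriminating_snv_separates_haplotypes(self):
        rng = np.random.default_rng(0)
        t1 = random_dna(rng, 1500)
        t2 = mutate(rng, t1, rng.choice(1500, size=8, replace=False))
        reads_h1 = [t1[i : i + 900] for i in (0, 300, 600)]
        reads_h2 = [t2[i : i + 900] for i in (0, 300, 600)]
        alleles, reads, support = _setup([t1, t2], reads_h1 + reads_h2)
        pair = TemplatePair("GX", alleles[0], alleles[1],
                            support.pool["t0"], support.pool["t1"])
        r1, r2 = phase_reads(reads, pair, support)
        assert sorted(r.read_id for r in r1) == ["r0", "r1", "r2"]
        assert sorted(r.read_id for r in r2) == ["r3", "r4", "r5"]

    def test_read_from_identical_region_goes_to_both(self):
        rng = np.random.default_rng(1)
        t1 = random_dna(rng, 1500)
        t2 = t1[:1200] + mutate(rng, t1[1200:], [10, 50])  # differ only after 1200
        shared = t1[0:900]
        alleles, reads, support = _setup([t1, t2], [shared])
        pair = TemplatePair("GX", alleles[0], alleles[1],
                            support.pool["t0"], support.pool["t1"])
        r1, r2 = phase_reads(reads, pair, support)
        assert [r.read_id for r in r1] == ["r0"]
        assert [r.read_id for r in r2] == ["r0"]

    def test_forced_homozygous_duplicates_read_sets(self):
        rng = np.random.default_rng(2)
        t1 = random_dna(rng, 1500)
        alleles, reads, support = _setup([t1], [t1[0:900], t1[400:1300]])
        pair = TemplatePair("GX", alleles[0], alleles[0],
                            support.pool["t0"], support.pool["t0"],
                            forced_homozygous=True)
        r1, r2 = phase_reads(reads, pair, support)
        assert [r.read_id for r in r1] == [r.read_id for r in r2]


class TestCallVariants:
    def _pileup_case(self, n_alt, n_ref, edit):
        rng = np.random.default_rng(3)
        template_seq = random_dna(rng, 1200)
        alt_seq = edit(template_seq)
        reads = [alt_seq for _ in range(n_alt)] + [template_seq for _ in range(n_ref)]
        alleles, gr, support = _setup([template_seq], reads)
        hap_reads = gr.reads
        return call_variants(hap_reads, alleles[0], support), template_seq

    def test_all_reads_identical_to_template_no_variants(self):
        variants, _ = self._pileup_case(0, 20, lambda s: s)
        assert variants == []

    def test_majority_snv_called(self):
        def put_snv(s):
            return s[:600] + ("T" if s[600] != "T" else "G") + s[601:]

        variants, tmpl = self._pileup_case(12, 8, put_snv)
        assert len(variants) == 1
        v = variants[0]
        assert v.kind == "snv" and v.position == 600
        assert v.support == 12 and v.depth == 20
        assert v.af == pytest.approx(0.6)

    def test_insufficient_support_not_called(self):
        variants, _ = self._pileup_case(
            2, 1, lambda s: s[:600] + "ACGT" + s[600:]
        )
        assert variants == []  # support 2 < 3 even though af > 0.5

    def test_minority_fraction_not_called(self):
        def put_snv(s):
            return s[:600] + ("T" if s[600] != "T" else "G") + s[601:]

        variants, _ = self._pileup_case(9, 11, put_snv)  # af 0.45
        assert variants == []

    def test_majority_deletion_called_and_left_aligned(self):
        rng = np.random.default_rng(4)
        tmpl = random_dna(rng, 500) + "CAAAAG" + random_dna(rng, 500)
        deleted = tmpl[:503] + tmpl[505:]  # drop two A's inside the run
        alleles, gr, support = _setup([tmpl], [deleted] * 5 + [tmpl] * 2)
        variants = call_variants(gr.reads, alleles[0], support)
        assert len(variants) == 1
        v = variants[0]
        assert v.kind == "del" and v.ref == "AA"
        assert v.position == 501  # left-aligned to the start of the A-run

    def test_edge_evidence_masked(self):
        rng = np.random.default_rng(5)
        tmpl = random_dna(rng, 1200)
        # SNV 10 bp from the template start: inside every read's edge zone
        alt = ("T" if tmpl[10] != "T" else "G")
        mutated = tmpl[:10] + alt + tmpl[11:]
        alleles, gr, support = _setup([tmpl], [mutated] * 8)
        assert call_variants(gr.reads, alleles[0], support) == []


class TestApplyVariants:
    def _template(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 900)
        feats = [
            ("intron", 0, 200), ("exon", 200, 400),
            ("intron", 400, 600), ("exon", 600, 800), ("intron", 800, 900),
        ]
        return AlleleRecord("t", "GX*01", seq, feats, False)

    def test_no_variants_is_identity(self):
        t = self._template()
        cons = apply_variants(t, [])
        assert cons.sequence == t.sequence
        assert cons.features == list(t.features)

    def test_intronic_deletion_shifts_downstream_exons(self):
        t = self._template()
        v = Variant("t", 450, t.sequence[450:452], "", "del", 10, 20)
        cons = apply_variants(t, [v])
        assert len(cons.sequence) == len(t.sequence) - 2
        # oracle: intervals at or after the deletion shift left by 2
        expected = [
            (k, s if s <= 450 else s - 2, e if e <= 450 else e - 2)
            for k, s, e in t.features
        ]
        assert cons.features == expected
        assert cons.coding_sequence == coding_sequence(t)

    def test_exonic_snv_changes_cds_by_one_base(self):
        t = self._template()
        ref = t.sequence[300]
        alt = "T" if ref != "T" else "G"
        v = Variant("t", 300, ref, alt, "snv", 10, 20)
        cons = apply_variants(t, [v])
        diff = [
            i for i, (a, b) in enumerate(zip(cons.coding_sequence, coding_sequence(t)))
            if a != b
        ]
        assert diff == [100]  # exon1 starts at 200, so CDS offset 100

    def test_ref_mismatch_rejected(self):
        t = self._template()
        wrong = "A" if t.sequence[100] != "A" else "C"
        v = Variant("t", 100, wrong, "T", "snv", 10, 20)
        with pytest.raises(ValueError, match="ref mismatch"):
            apply_variants(t, [v])

    def test_overlapping_variants_rejected(self):
        t = self._template()
        v1 = Variant("t", 100, t.sequence[100:103], "", "del", 10, 20)
        v2 = Variant("t", 101, t.sequence[101], "T", "snv", 10, 20)
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(t, [v1, v2])

    def test_roundtrip_diff_recovers_variants(self):
        t = self._template()
        vs = [
            Variant("t", 150, t.sequence[150], "T" if t.sequence[150] != "T" else "A",
                    "snv", 10, 20),
            Variant("t", 500, "", "GGCA", "ins", 10, 20),
            Variant("t", 700, t.sequence[700:703], "", "del", 10, 20),
        ]
        cons = apply_variants(t, vs)
        aln = align_pair(cons.sequence, t.sequence, "global")
        events = difference_events(aln, min_gap=1)
        assert len(events) == 3
        kinds = sorted(ev.kind for ev in events)
        assert kinds == ["gap", "gap", "substitution"]


class TestConsensusQV:
    def test_identical_sequences_capped_at_60(self):
        s = "ACGT" * 750
        assert consensus_qv(s, s) == (0, 60.0)

    def test_one_edit_in_ten_thousand_is_qv40(self):
        rng = np.random.default_rng(7)
        truth = random_dna(rng, 10000)
        cons = truth[:5000] + ("A" if truth[5000] != "A" else "C") + truth[5001:]
        edits, qv = consensus_qv(cons, truth)
        assert edits == 1
        assert qv == pytest.approx(40.0)

    def test_aggregate_matches_closed_form(self):
        # pooled example at the scale typing studies report: 3 edits over
        # 453 kb of aligned columns
        assert aggregate_qv([(1, 151000), (2, 151000), (0, 151000)]) == pytest.approx(
            -10 * np.log10(3 / 453000), abs=1e-9
        )
        assert aggregate_qv([(3, 453000)]) == pytest.approx(51.79, abs=0.01)

    def test_aggregate_perfect_capped(self):
        assert aggregate_qv([(0, 1000), (0, 2000)]) == 60.0


def test_vcf_emission(tmp_path):
    rng = np.random.default_rng(8)
    t = _rec("t", random_dna(rng, 300))
    vs = [
        Variant("t", 100, t.sequence[100], "T" if t.sequence[100] != "T" else "A",
                "snv", 12, 20),
        Variant("t", 150, "", "AC", "ins", 11, 20),
        Variant("t", 200, t.sequence[200:202], "", "del", 10, 19),
    ]
    path = tmp_path / "v.vcf"
    write_vcf(vs, t, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 3
    pos, ref, alt = lines[1].split("\t")[1], lines[1].split("\t")[3], lines[1].split("\t")[4]
    assert int(pos) == 150 and len(alt) == len(ref) + 2  # anchored insertion
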