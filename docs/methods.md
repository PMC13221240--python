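# Methods

## Pipeline model and assumptions

`longhla` types the classical HLA genes by *template reconstruction*:
rather than choosing the best database allele pair directly from read
evidence, it selects a diploid pair of template alleles, rebuilds each
haplotype's actual sequence from the reads phased to it, and only then
assigns names by comparing the reconstructed sequences back to the
database. The design assumptions are:

* exactly two copies of each targeted gene (no CNV handling);
* reads long enough that a single read spans a large fraction of a gene
  (HiFi/R10-scale, several kb);
* a reference database of full-length allele sequences with exon/intron
  annotation, plus optionally exon-only *partial* records;
* base qualities are ignored throughout; all evidence is alignment-based.

## Alignment layer

All pairwise alignment is unit-cost (match 0, mismatch/indel 1) edit
alignment via edlib, with extended CIGARs (`=`/`X`/`I`/`D`). Two modes
are used: global (`NW`) for consensus-vs-allele comparisons, and
semi-global (`HW`, target ends free) for placing reads inside alleles.

**End trimming.** WGS-like reads carry flanking sequence beyond the
allele span, and a semi-global aligner force-aligns that flank into the
allele as dense mismatch/indel tails, inflating mismatch rates and
polluting pileups. Every read-to-allele alignment is therefore trimmed
to its maximum-scoring contiguous segment (+1 per matched base, −2 per
edited base, computed over CIGAR runs) — the fit-alignment/soft-clip
recovery a long-read mapper performs natively. Alignments with no
positive-scoring segment are discarded.

**Banding.** Read-to-anchor screening caps edits at 25% of read length;
read-to-candidate-allele alignment at 15%. These bands comfortably
contain within-gene divergence (≤ ~6%) plus error plus untrimmed flank
cost, while rejecting cross-gene garbage early.

## Extraction thresholds

A read is informative for a gene when a surviving mapping to one of the
gene's anchors covers ≥ 40% of the anchor length or ≥ 200 bp touching an
anchor end (both inclusive). Mappings of one read are filtered at 10×
its best mismatch rate; the best rate is floored at 0.001 so that a
perfect mapping does not annihilate the near-perfect co-mappings a
heterozygote needs. A read may be informative for several genes; the
per-gene pipelines resolve ownership downstream.

## MOI comparison

A *difference event* is a maximal run of substitution columns or a
contiguous gap; gaps shorter than `min_gap = 3` bases are ignored as
sequencing-error-prone. Two alignments of one read are compared by event
count inside the intersection of their read intervals (events straddling
the boundary count; an empty intersection is a tie). In `high_error`
mode a difference of at most one event is also a tie.

`high_error` (the R10 preset) applies to *phasing* — assigning a noisy
read between the two selected templates, where a tie conservatively
lands the read on both haplotypes. It deliberately does not apply to
support selection: forgiving ties there would spread each read's support
across whole clusters of sibling alleles and erase the coverage signal
the template ranking depends on (measured on paired seeds, global
forgiveness cost ~7 accuracy points at fields 1–3; scoped to phasing it
costs none).

## Template pair selection

Per gene, each read supports the alleles that never lose a pairwise MOI
comparison among its alignments (the undominated set). Support tuples
S(A) = (n, c, m) accumulate unique reads, fractional coverage and
fractionally divided matched bases; pair scores add elementwise.
Candidates are pruned to the top 15 (HiFi) / 30 (R10) alleles by
coverage; all distinct pairs are ranked lexicographically on
**(c, n, m)** descending. Coverage leads the comparison because `n`
double-counts reads that tie between near-identical sibling alleles
(one read in both members' n), so an n-first ranking lets a pair of
siblings of *one* haplotype outrank the true genotype whenever the
sibling-distinguishing site is hard to observe; the fractional division
built into c (and m) neutralizes exactly that inflation. Self-pairs are
not enumerated: under additive pair scores a self-pair's score is
indistinguishable from a balanced heterozygote's, so homozygosity is
instead established by the coverage rule — if one member's coverage
times 4 is strictly below the other's, the weak member is removed and
the genotype forced homozygous (a singleton support pool is homozygous
by necessity).

## Variant calling and consensus

Reads phased to a haplotype (ties counted in both haplotypes) are piled
up on the template via their cached alignments. Indels are left-aligned
to their lowest equivalent template coordinate so equivalent placements
stack. A candidate becomes a variant when supported by ≥ 3 reads *and*
by more than half of the covering reads ("major"); overlapping
candidates are resolved by support, then leftmost. Evidence within 25 bp
of a read's own alignment boundary is ignored (depth still counts):
reads of one haplotype share identical flanking sequence, so
trim-boundary misalignments are *correlated* across reads and can
otherwise reach the support/af thresholds. The practical consequence is
that variants in the outermost ~25 bp of a gene are not callable.

Variants are applied right-to-left; exon/intron coordinates are lifted
through the indel offsets. Consensus quality versus a truth sequence is
QV = −10·log10(edits / alignment columns), capped at 60 for a perfect
sequence; aggregate QV pools edits and columns across sequences.

## Typing

Each consensus is globally aligned to every full-length allele of its
gene; events (no small-gap forgiveness here — `min_gap = 1`, since a
real 1-bp exonic indel must not be free) are classified exonic if they
overlap any exon interval of the *candidate's* annotation
(boundary-spanning events count as exonic, conservatively), and the
penalty is 9999 per exonic plus 1 per intronic event. Penalty 0 is an
exact call. Otherwise exon-only partial records are consulted: a perfect
coding-sequence match yields a partial-CDS call. A full-length allele
with identical CDS but an imperfect genomic match is deliberately *not*
a fallback — that situation is precisely a novel intronic variant, and
collapsing it would destroy novel-allele reporting. Remaining cases are
novel: the lowest-penalty full-length allele's name plus the extended
CIGAR of the alignment against it. Ties break by fewer exonic events,
then lexicographically smallest name.

## Synthetic data generator

The generator emulates a curated allele database and WGS read sampling
at desk scale; it defines the conditions every study runs under.

* **Genes**: 6 targeted + 2 decoy paralogs by default; exon/intron
  partitions with exons ≈ 40% of the gene.
* **Allele families**: field-2 founders differ by mutations across the
  whole gene at the within-gene divergence (default 3%, matching the
  several-percent pairwise diversity of class I/II genes); field-3
  variants add 1–2 exonic substitutions; field-4 variants 1–3 intronic
  substitutions — so field-resolution evaluation is meaningful by
  construction. A configurable fraction (default 10%) of non-founder
  alleles is emitted exon-only (partial).
* **Decoys** derive from a target gene's ancestor at 10% divergence;
  decoy alleles are ≥ 5% apart internally so each founds its own anchor
  cluster. This models *diverse* paralog families whose every member has
  a nearby representative; with a single dense decoy cluster the 10×
  ratio filter has no margin at 10% paralog divergence, because a decoy
  read's best rate would include within-family divergence.
* **Reads**: per haplotype at the configured depth, lengths
  ~Normal(mean, 0.1·mean), drawn from the allele embedded in 300 bp of
  random flank, either strand. Errors are independent per base:
  HiFi profile 0.2% substitutions + 0.2% indels (~0.4% total); R10
  profile 1% + 2% with the indel rate multiplied by run length inside
  homopolymers of ≥ 4 bp — reproducing the homopolymer-indel failure
  mode of nanopore data qualitatively (read-level indel enrichment in
  long homopolymers is asserted by test). No burst errors, chimeras,
  quality strings (constant Q) or coverage waviness.

What passing tests on this generator do **not** show: robustness to
structural variation between alleles (the generator plants substitutions
only, while real databases contain length variants), to coverage
dropouts, mapping ambiguity with all 40+ real HLA genes, or real R10
error burstiness.

## Study sizes and numerical choices

The acceptance studies use 2.8–3.4 kb genes with 3 kb reads at 30× per
haplotype — single reads span most of a gene, as HiFi reads do for real
HLA loci, while keeping each study in single-digit minutes on one CPU:
typing recovery on 20 heterozygous samples (240 alleles), novel-allele
plants (1–3 substitutions ≥ 100 bp from gene ends, ≥ 15 bp apart,
avoiding homopolymers) on 20 samples, homozygote recovery on 10, paired
strict/high-error comparison on 10 R10 seeds. The acceptance script
runs slightly smaller versions of the same studies. At these depths the
studies come out essentially perfect (100% full-field recovery,
byte-perfect consensus); the interesting regimes are lower depth,
higher error and sparser databases.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; the typing path itself contains no random
steps, so identical inputs give byte-identical reports (asserted by
test). Determinism of ranking and tie-breaks is fixed by explicit
secondary keys (allele id or name) everywhere.

## Known limitations

* No CNV or structural-variant handling; exactly-diploid assumption.
* Variants in the outermost ~25 bp of a gene are invisible (edge mask).
* Partial alleles participate only through the perfect-CDS fallback.
* G/P ambiguity groups and expression-suffix inference are out of scope
  (a matched name keeps whatever suffix the database carries).
* The built-in aligner is a full-sensitivity edit-distance engine; at
  database scale (tens of thousands of alleles) a seed-and-extend
  prefilter would be needed for speed, behind the same interface.
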