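import numpy as np
import pytest

from longhla.simdata import SimConfig, generate_allele_db

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def mutate(rng: np.random.Generator, seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


@pytest.fixture(scope="session")
def small_truth_db():
    """Two targeted genes + one decoy, modest allele counts; session-wide."""
    cfg = SimConfig(
        n_genes_target=2,
        n_decoy_genes=1,
        alleles_per_gene=8,
        gene_length_range=(1800, 2400),
        exon_count_range=(3, 5),
        read_length_mean=1800,
        depth_per_haplotype=30.0,
        seed=42,
    )
    return cfg, generate_allele_db(cfg)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook O(nm) Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def replay_columns(aln):
    """Expand an alignment into a per-column (op, read_pos, target_pos) list."""
    import re

    cols = []
    q, t = aln.query_interval[0], aln.target_interval[0]
    for m in re.finditer(r"(\d+)([=XID])", aln.cigar):
        n, op = int(m.group(1)), m.group(2)
        for _ in range(n):
            cols.append((op, q, t))
            if op in "=XI":
                q += 1
            if op in "=XD":
                t += 1
    return cols


def count_events_bruteforce(aln, window, min_gap=3):
    """Column-replay difference-event counter, independent of longhla.moi.

    Walks expanded columns, collects maximal X runs and maximal I/D runs
    (the latter kept only at >= min_gap), then counts events whose read
    interval intersects ``window`` (zero-width deletions count when
    inside or touching the window).
    """
    cols = replay_columns(aln)
    events = []
    i = 0
    while i < len(cols):
        op, q, t = cols[i]
        if op == "=":
            i += 1
            continue
        j = i
        while j < len(cols) and cols[j][0] == op:
            j += 1
        run = j - i
        if op == "X":
            events.append(("substitution", q, q + run))
        elif op == "I" and run >= min_gap:
            events.append(("gap", q, q + run))
        elif op == "D" and run >= min_gap:
            events.append(("gap", q, q))
        i = j
    lo, hi = window
    n = 0
    for _, s, e in events:
        if s == e:
            if lo <= s <= hi:
                n += 1
        elif max(s, lo) < min(e, hi):
            n += 1
    return n
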