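"""Independent brute-force oracles used to validate the pipeline.

Everything here works by exhaustive enumeration on small instances and stays
deliberately separate from the library's vectorized implementations: sliding
Hamming scans for the mapper, literal rule application for the reassignment
table, pair counting for ARI and ROC-AUC, rank enumeration for the exact
Mann-Whitney p-value.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def all_valid_placements(read_seq, genome_seq, max_mismatch_fraction=0.05):
    """Every end-to-end placement (both strands) passing the validity cutoff.

    Exhaustive sliding-window Hamming scan (no seeding); returns
    (start, strand, n_mismatches) tuples sorted by position.
    """
    import numpy as np

    L = len(read_seq)
    if len(genome_seq) < L:
        return []
    g = np.frombuffer(genome_seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    out = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        r = np.frombuffer(seq.encode(), dtype=np.uint8)
        nmm = (windows != r).sum(axis=1)
        for start in np.flatnonzero(nmm / L < max_mismatch_fraction):
            out.append((int(start), strand, int(nmm[start])))
    return sorted(out)


def brute_force_assign(reads, focal_genomes, background_genomes=(),
                       max_mismatch_fraction=0.05):
    """Literal application of the background filter and T1/T2/T3 rules.

    ``reads`` are (read_id, sequence) pairs; genomes are objects with .id and
    .sequence.  Returns the assignment identity set of
    {(genome_id, read_id, label, start, strand, n_mismatches)}.
    """
    # background filter: any valid placement on any background genome
    surviving = []
    for rid, seq in reads:
        hit = any(
            all_valid_placements(seq, g.sequence, max_mismatch_fraction)
            for g in background_genomes
        )
        if not hit:
            surviving.append((rid, seq))

    # candidate = best valid placement per (read, genome):
    # fewest mismatches, then leftmost, then plus strand
    candidates = {}  # read_id -> {genome_id: (nmm, start, strand)}
    for rid, seq in surviving:
        per_genome = {}
        for g in focal_genomes:
            placements = all_valid_placements(seq, g.sequence, max_mismatch_fraction)
            if placements:
                best = min(placements, key=lambda p: (p[2], p[0], p[1] != "+"))
                per_genome[g.id] = (best[2], best[0], best[1])
        if per_genome:
            candidates[rid] = per_genome

    # competitive classification
    t1 = defaultdict(list)  # genome_id -> [(read_id, nmm, start)]
    t3 = defaultdict(list)
    for rid, per_genome in candidates.items():
        m_star = min(nmm for nmm, _, _ in per_genome.values())
        winners = [g for g, (nmm, _, _) in per_genome.items() if nmm == m_star]
        for g in winners:
            nmm, start, strand = per_genome[g]
            entry = (rid, nmm, start, strand)
            (t1 if len(winners) == 1 else t3)[g].append(entry)

    result = set()
    for g, entries in t1.items():
        for rid, nmm, start, strand in entries:
            result.add((g, rid, "T1", start, strand, nmm))
    read_len = len(reads[0][1]) if reads else 0
    for g, entries in t3.items():
        for rid, nmm, start, strand in entries:
            rejected = False
            if nmm > 0:
                for _, t1_nmm, t1_start, _ in t1.get(g, []):
                    overlap = min(start + read_len, t1_start + read_len) - max(
                        start, t1_start
                    )
                    if overlap >= 1 and t1_nmm < nmm:
                        rejected = True
                        break
            if not rejected:
                result.add((g, rid, "T3", start, strand, nmm))
    return result


def ari_contingency(labels_a, labels_b) -> float:
    """Adjusted Rand index straight from the pair-counting contingency formula."""
    a_groups = defaultdict(set)
    b_groups = defaultdict(set)
    for i, (la, lb) in enumerate(zip(labels_a, labels_b)):
        a_groups[la].add(i)
        b_groups[lb].add(i)
    n = len(labels_a)
    sum_ij = sum(
        math.comb(len(sa & sb), 2)
        for sa in a_groups.values()
        for sb in b_groups.values()
    )
    sum_a = sum(math.comb(len(s), 2) for s in a_groups.values())
    sum_b = sum(math.comb(len(s), 2) for s in b_groups.values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def auc_pair_counting(scores, labels) -> float:
    """P(random positive outscores random negative), ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments.

    Assumes no ties across the pooled sample.
    """
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if min(u, n * m - u) <= min(u_obs, n * m - u_obs):
            count += 1
    return count / total


def bh_qvalues(pvalues):
    """Hand Benjamini-Hochberg: q_i = min_{j>=i} (m * p_(j) / j)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, m * pvalues[i] / (rank + 1))
        q[i] = running
    return q
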