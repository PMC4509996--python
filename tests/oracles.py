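"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: unions are computed
by per-base sweeps or sorted merges, statistics by explicit sums, and tail
probabilities by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def union_intervals(pairs):
    """Sorted merge (distance 0) of (start, end) pairs on one chromosome."""
    out = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def sweep_cnvrs(callsets):
    """Region boundaries + carrier sets, independent of build_cnvrs.

    callsets: mapping sample_id -> iterable of CNVCall. Returns a list of
    (chrom, start, end, frozenset(carriers)) sorted by (chrom, start).
    """
    by_chrom: dict[str, list] = {}
    for sid, calls in callsets.items():
        for c in calls:
            by_chrom.setdefault(c.interval.chrom, []).append(
                (c.interval.start, c.interval.end, sid)
            )
    regions = []
    for chrom in sorted(by_chrom):
        entries = by_chrom[chrom]
        merged = union_intervals([(s, e) for s, e, _ in entries])
        for ms, me in merged:
            carriers = frozenset(
                sid for s, e, sid in entries if s < me and e > ms
            )
            regions.append((chrom, ms, me, carriers))
    return regions


def per_base_gene_cn(gene, calls, baseline):
    """Average CN over the gene by explicit per-base expansion."""
    values = np.full(gene.interval.length, float(baseline))
    for c in calls:
        if c.interval.chrom != gene.interval.chrom:
            continue
        lo = max(c.interval.start, gene.interval.start) - gene.interval.start
        hi = min(c.interval.end, gene.interval.end) - gene.interval.start
        if hi > lo:
            values[lo:hi] = c.cn
    return float(values.mean())


def vst_explicit(x, y):
    """V_ST by explicit sums (divisor-n variances)."""
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)

    def var(v):
        m = sum(v) / len(v)
        return sum((a - m) ** 2 for a in v) / len(v)

    v_s = (n1 * var(x) + n2 * var(y)) / (n1 + n2)
    v_t = var(x + y)
    if v_t == 0:
        return None
    return (v_t - v_s) / v_t


def ks_statistic_enumerated(x, y):
    """sup |ECDF_x - ECDF_y| evaluated at every sample point."""
    x, y = sorted(x), sorted(y)
    points = sorted(set(x) | set(y))
    d = 0.0
    for t in points:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(fx - fy))
    return d


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) by summing the exact pmf."""
    total = comb(N, n)
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


def allele_count_oracle(cn_by_sample, ploidy_by_sample):
    """Deletion alleles by direct enumeration of integer genotypes."""
    n_alleles = n_del = 0
    for sid, cn in cn_by_sample.items():
        p = ploidy_by_sample[sid]
        cn = int(np.floor(cn + 0.5))
        n_alleles += p
        if p == 1:
            n_del += 1 if cn == 0 else 0
        else:
            n_del += {0: 2, 1: 1}.get(cn, 0)
    return n_del, n_alleles


def bh_stepup_by_hand(p):
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def exhaustive_overlap_probability(chrom_len, interval_len, gene_start, gene_end):
    """P(uniform placement overlaps the gene) over all valid starts."""
    starts = range(0, chrom_len - interval_len + 1)
    hits = sum(
        1 for s in starts if s < gene_end and s + interval_len > gene_start
    )
    return hits / len(starts)


def brute_force_overlap_bp(intervals, genes):
    """Gene bases covered by the union of intervals, by per-base marking."""
    total = 0
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for gene in genes:
        segs = by_chrom.get(gene.interval.chrom, [])
        covered = set()
        for s, e in segs:
            covered.update(
                range(max(s, gene.interval.start), min(e, gene.interval.end))
            )
        total += len(covered)
    return total
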