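"""Genome-randomization null for interval overlap statistics.

Observed CNVRs (or calls) are re-placed uniformly across the gap-free
genome, preserving their lengths but not their spacing or chromosome of
origin; placed intervals may overlap each other. Empirical p-values use the
plus-one correction and are therefore never zero.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .model import Genome, GenomicInterval, TranscriptionUnit

__all__ = [
    "PermutationResult",
    "gap_free_spans",
    "random_placement",
    "permutation_test",
    "overlap_statistic",
]

STATISTICS = ("n_overlapping_genes", "total_overlap_bp")


def gap_free_spans(genome: Genome) -> list[GenomicInterval]:
    """Maximal gap-free intervals of every chromosome."""
    spans = []
    for chrom in sorted(genome.chrom_lengths):
        length = genome.chrom_lengths[chrom]
        gaps = sorted(genome.gaps_on(chrom), key=lambda g: g.start)
        pos = 0
        for g in gaps:
            if g.start > pos:
                spans.append(GenomicInterval(chrom, pos, g.start))
            pos = max(pos, g.end)
        if pos < length:
            spans.append(GenomicInterval(chrom, pos, length))
    return spans


def random_placement(
    lengths: Sequence[int],
    genome: Genome,
    rng: np.random.Generator | int | None = None,
    chromosome: str | None = None,
) -> list[GenomicInterval]:
    """Place each length uniformly over all valid start positions.

    A start is valid when the placed interval fits inside a single gap-free
    span; the span (and hence chromosome) is chosen with probability
    proportional to its number of valid starts. With ``chromosome`` set,
    placement is restricted to that chromosome's spans.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    spans = gap_free_spans(genome)
    if chromosome is not None:
        spans = [s for s in spans if s.chrom == chromosome]
    out = []
    for length in lengths:
        n_starts = np.array(
            [max(0, s.length - length + 1) for s in spans], dtype=float
        )
        total = n_starts.sum()
        if total <= 0:
            raise ValueError(
                f"interval of length {length} does not fit in any gap-free span"
            )
        idx = rng.choice(len(spans), p=n_starts / total)
        span = spans[idx]
        start = span.start + int(rng.integers(0, int(n_starts[idx])))
        out.append(GenomicInterval(span.chrom, start, start + length))
    return out


def _merge(intervals: Sequence[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def overlap_statistic(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[TranscriptionUnit],
    statistic: str,
) -> float:
    """Overlap of a set of intervals with genes.

    ``n_overlapping_genes``: genes hit by >= 1 bp of any interval.
    ``total_overlap_bp``: gene bases covered by the union of the intervals,
    summed over genes.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    merged = _merge(intervals)
    # per chromosome: sorted disjoint segments -> arrays + length prefix sums
    arrays = {}
    for chrom, segs in merged.items():
        starts = np.fromiter((s for s, _ in segs), dtype=np.int64, count=len(segs))
        ends = np.fromiter((e for _, e in segs), dtype=np.int64, count=len(segs))
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        arrays[chrom] = (starts, ends, cum)
    total = 0.0
    for gene in genes:
        entry = arrays.get(gene.interval.chrom)
        bp = 0
        if entry is not None:
            starts, ends, cum = entry
            gs, ge = gene.interval.start, gene.interval.end
            i0 = int(np.searchsorted(ends, gs, side="right"))
            i1 = int(np.searchsorted(starts, ge, side="left"))
            if i1 > i0:
                bp = int(cum[i1] - cum[i0])
                bp -= max(0, gs - int(starts[i0]))
                bp -= max(0, int(ends[i1 - 1]) - ge)
        if statistic == "n_overlapping_genes":
            total += 1 if bp > 0 else 0
        else:
            total += bp
    return float(total)


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    statistic: str
    n_perm: int

    @property
    def p_emp(self) -> float:
        r = int((self.null_values >= self.observed).sum())
        return (r + 1) / (self.n_perm + 1)


def permutation_test(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[TranscriptionUnit],
    genome: Genome,
    statistic: str = "n_overlapping_genes",
    n_perm: int = 1000,
    seed: int | None = None,
    within_chromosome: bool = False,
) -> PermutationResult:
    """Upper-tail empirical test of interval-gene overlap enrichment.

    The observed statistic is compared with ``n_perm`` random placements of
    the same interval lengths; p = (r + 1) / (n_perm + 1) where r counts
    null values >= observed. For depletion, negate the statistic externally.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = overlap_statistic(intervals, genes, statistic)
    lengths = [iv.length for iv in intervals]
    chroms = [iv.chrom for iv in intervals] if within_chromosome else None
    null = np.empty(n_perm)
    for b in range(n_perm):
        if chroms is None:
            placed = random_placement(lengths, genome, rng)
        else:
            placed = [
                random_placement([ln], genome, rng, chromosome=ch)[0]
                for ln, ch in zip(lengths, chroms)
            ]
        null[b] = overlap_statistic(placed, genes, statistic)
    return PermutationResult(observed, null, statistic, n_perm)
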