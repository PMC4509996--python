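"""Genic CNVs: whole-gene containment, per-individual gene copy-number
genotyping, high-copy genes, and SD-overlap enrichment.

A "CNV gene" is a transcription unit completely contained within a single
CNV call of at least one individual; containment is closed at both ends on
half-open intervals. Gene genotypes are length-weighted averages of call
copy numbers over the gene body, with uncovered bases at the sex-aware
baseline (2 on autosomes and female X, 1 on male X).
"""

from __future__ import annotations

import os
from bisect import bisect_left
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (
    CNVCall,
    GenomicInterval,
    SampleSheet,
    SegmentalDuplication,
    TranscriptionUnit,
)

__all__ = [
    "SexRules",
    "CopyNumberMatrix",
    "SDAssociation",
    "HighCopyGene",
    "contains_gene",
    "find_cnv_genes",
    "genotype_gene",
    "build_cn_matrix",
    "high_copy_genes",
    "sd_association",
    "write_cn_matrix",
    "read_cn_matrix",
]


@dataclass(frozen=True)
class SexRules:
    """Expected (baseline) copy number per sample and chromosome.

    Autosomes are diploid for everyone; the X chromosome is hemizygous
    (baseline 1) in males.
    """

    sheet: SampleSheet
    x_chrom: str | None

    def baseline(self, sample_id: str, chrom: str) -> int:
        if self.x_chrom is not None and chrom == self.x_chrom:
            return 1 if self.sheet.sex_of(sample_id) == "male" else 2
        return 2


def contains_gene(call: CNVCall, gene: TranscriptionUnit) -> bool:
    """True iff the call fully contains the gene (shared bounds count)."""
    return call.interval.contains(gene.interval)


class _CallIndex:
    """Per-chromosome call lookup by overlap, sorted by start."""

    def __init__(self, calls: Iterable[CNVCall]):
        self._by_chrom: dict[str, list[CNVCall]] = {}
        for c in calls:
            self._by_chrom.setdefault(c.interval.chrom, []).append(c)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, cs in self._by_chrom.items():
            cs.sort(key=lambda c: (c.interval.start, c.interval.end))
            self._starts[chrom] = [c.interval.start for c in cs]
            self._max_len[chrom] = max(c.interval.length for c in cs)

    def overlapping(self, iv: GenomicInterval) -> list[CNVCall]:
        calls = self._by_chrom.get(iv.chrom)
        if not calls:
            return []
        starts = self._starts[iv.chrom]
        lo = bisect_left(starts, iv.start - self._max_len[iv.chrom])
        hi = bisect_left(starts, iv.end)
        return [c for c in calls[lo:hi] if c.interval.end > iv.start]


def find_cnv_genes(
    callsets: Mapping[str, Iterable[CNVCall]],
    genes: Sequence[TranscriptionUnit],
) -> list[TranscriptionUnit]:
    """Genes fully contained in >= 1 call of >= 1 individual, each once.

    Containment is per-call: a gene covered only by the union of abutting
    calls does not qualify. Output sorted by (chrom, start, gene_id).
    """
    hits: dict[str, TranscriptionUnit] = {}
    for calls in callsets.values():
        calls = list(calls)
        if not calls:
            continue
        index = _CallIndex(calls)
        for gene in genes:
            if gene.gene_id in hits:
                continue
            for call in index.overlapping(gene.interval):
                if contains_gene(call, gene):
                    hits[gene.gene_id] = gene
                    break
    return sorted(
        hits.values(),
        key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id),
    )


def genotype_gene(
    gene: TranscriptionUnit,
    calls: Iterable[CNVCall],
    sample_id: str,
    rules: SexRules,
) -> float:
    """Length-weighted average copy number across the gene body.

    Bases under a call take the call's cn; all other bases take the sample's
    baseline for the chromosome. Same-sample calls overlapping each other on
    the gene with different cn are contradictory and raise ValueError.
    """
    baseline = rules.baseline(sample_id, gene.interval.chrom)
    clipped = []
    for c in calls:
        ol = c.interval.overlap_len(gene.interval)
        if ol > 0:
            clipped.append(
                (
                    max(c.interval.start, gene.interval.start),
                    min(c.interval.end, gene.interval.end),
                    c.cn,
                )
            )
    clipped.sort()
    total = 0.0
    covered = 0
    cur_start = cur_end = None
    cur_cn = 0.0
    for start, end, cn in clipped:
        if cur_end is not None and start < cur_end:
            if cn != cur_cn:
                raise ValueError(
                    f"contradictory copy numbers {cur_cn} and {cn} for sample "
                    f"{sample_id} over gene {gene.gene_id}"
                )
            cur_end = max(cur_end, end)
        else:
            if cur_end is not None:
                total += (cur_end - cur_start) * cur_cn
                covered += cur_end - cur_start
            cur_start, cur_end, cur_cn = start, end, cn
    if cur_end is not None:
        gene_len = gene.interval.length
        if cur_start == gene.interval.start and cur_end == gene.interval.end and covered == 0:
            # fully covered by one uniform-cn component: exact, no rounding
            return cur_cn
        total += (cur_end - cur_start) * cur_cn
        covered += cur_end - cur_start
    gene_len = gene.interval.length
    total += (gene_len - covered) * baseline
    return total / gene_len


@dataclass
class CopyNumberMatrix:
    """Genes x samples matrix of diploid-scale gene copy numbers."""

    genes: list[TranscriptionUnit]
    samples: list[str]
    cn: np.ndarray

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=float)
        if self.cn.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.cn.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.cn.size and self.cn.min() < 0:
            raise ValueError("copy numbers must be >= 0")

    def row(self, gene_id: str) -> np.ndarray:
        idx = self.gene_ids.index(gene_id)
        return self.cn[idx]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def build_cn_matrix(
    callsets: Mapping[str, Iterable[CNVCall]],
    genes: Sequence[TranscriptionUnit],
    sheet: SampleSheet,
    rules: SexRules,
) -> CopyNumberMatrix:
    """Genotype every (gene, sample); ordering follows inputs."""
    samples = sheet.sample_ids
    cn = np.empty((len(genes), len(samples)), dtype=float)
    for j, sample_id in enumerate(samples):
        calls = list(callsets.get(sample_id, ()))
        index = _CallIndex(calls) if calls else None
        for i, gene in enumerate(genes):
            overlapping = index.overlapping(gene.interval) if index else []
            cn[i, j] = genotype_gene(gene, overlapping, sample_id, rules)
    return CopyNumberMatrix(list(genes), list(samples), cn)


@dataclass(frozen=True)
class HighCopyGene:
    gene: TranscriptionUnit
    mean_cn: float
    population_means: dict[str, float]


def high_copy_genes(
    matrix: CopyNumberMatrix, sheet: SampleSheet, threshold: float = 10.0
) -> list[HighCopyGene]:
    """Genes whose grand mean copy number is >= threshold (inclusive)."""
    pop_cols = {
        pop: [matrix.samples.index(s.sample_id) for s in sheet.samples_in(pop)]
        for pop in sheet.populations()
    }
    out = []
    for i, gene in enumerate(matrix.genes):
        mean_cn = float(matrix.cn[i].mean())
        if mean_cn >= threshold:
            pop_means = {
                pop: float(matrix.cn[i, cols].mean())
                for pop, cols in pop_cols.items()
            }
            out.append(HighCopyGene(gene, mean_cn, pop_means))
    return out


@dataclass(frozen=True)
class SDAssociation:
    """Hypergeometric upper-tail test of CNV-gene overlap with SDs."""

    k: int  # CNV genes overlapping an SD
    n: int  # CNV genes
    K: int  # background genes overlapping an SD
    N: int  # background genes
    p: float

    @property
    def cnv_fraction(self) -> float:
        return self.k / self.n if self.n else float("nan")

    @property
    def background_fraction(self) -> float:
        return self.K / self.N if self.N else float("nan")


def _overlaps_any_sd(
    gene: TranscriptionUnit, sds: Sequence[SegmentalDuplication]
) -> bool:
    return any(gene.interval.overlaps(sd.interval) for sd in sds)


def sd_association(
    cnv_genes: Sequence[TranscriptionUnit],
    all_genes: Sequence[TranscriptionUnit],
    sds: Sequence[SegmentalDuplication],
) -> SDAssociation:
    """P(X >= k) for the SD overlap count of CNV genes drawn from the full
    gene set; overlap means >= 1 bp with any SD."""
    all_ids = {g.gene_id for g in all_genes}
    missing = [g.gene_id for g in cnv_genes if g.gene_id not in all_ids]
    if missing:
        raise ValueError(f"CNV genes not in background set: {missing[:5]}")
    sds = list(sds)
    K = sum(_overlaps_any_sd(g, sds) for g in all_genes)
    k = sum(_overlaps_any_sd(g, sds) for g in cnv_genes)
    N, n = len(all_genes), len(cnv_genes)
    if n > N or k > K:
        raise ValueError("inconsistent counts for hypergeometric test")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return SDAssociation(k=k, n=n, K=K, N=N, p=p)


def write_cn_matrix(matrix: CopyNumberMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\t" + "\t".join(matrix.samples) + "\n")
        for i, g in enumerate(matrix.genes):
            vals = "\t".join(repr(v) for v in matrix.cn[i].tolist())
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.interval.start}"
                f"\t{g.interval.end}\t{vals}\n"
            )


def read_cn_matrix(path: str | os.PathLike) -> CopyNumberMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        genes = []
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            genes.append(
                TranscriptionUnit(
                    GenomicInterval(fields[1], int(fields[2]), int(fields[3])),
                    fields[0],
                )
            )
            rows.append([float(v) for v in fields[4:]])
    cn = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return CopyNumberMatrix(genes, samples, cn)
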