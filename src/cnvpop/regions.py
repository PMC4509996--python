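"""CNV regions: merge calls across individuals, presence spectra, and
segmental-duplication partition comparisons.

A CNV region (CNVR) is the connected component of overlapping calls across
all individuals on one chromosome; its borders are the outer coordinates of
the merged calls. Bookended calls (distance 0) merge by default.
"""

from __future__ import annotations

import math
import os
from bisect import bisect_left
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (
    CNVCall,
    GenomicInterval,
    SampleSheet,
    SegmentalDuplication,
)

__all__ = [
    "CNVRegion",
    "PresenceSpectrum",
    "PartitionReport",
    "build_cnvrs",
    "presence_spectrum",
    "partition_by_sd",
    "ks_two_sample",
    "cn_log2_haploid",
    "compare_partitions",
    "write_cnvrs",
]


@dataclass(frozen=True)
class CNVRegion:
    interval: GenomicInterval
    member_calls: tuple[CNVCall, ...]
    carriers: frozenset[str]

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def build_cnvrs(
    callsets: Mapping[str, Iterable[CNVCall]], merge_bookended: bool = True
) -> list[CNVRegion]:
    """Merge all overlapping calls across individuals into CNVRs.

    Per chromosome, calls are swept in coordinate order and joined into
    connected components; bookended calls ([a,b) followed by [b,c)) merge
    when ``merge_bookended`` (the default). Duplications and deletions merge
    together. Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[CNVCall]] = {}
    for sample_id, calls in callsets.items():
        for call in calls:
            by_chrom.setdefault(call.interval.chrom, []).append(call)

    regions: list[CNVRegion] = []
    for chrom in sorted(by_chrom):
        calls = sorted(
            by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end)
        )
        cur: list[CNVCall] = []
        cur_end = -1
        for call in calls:
            joins = (
                call.interval.start <= cur_end
                if merge_bookended
                else call.interval.start < cur_end
            )
            if cur and joins:
                cur.append(call)
                cur_end = max(cur_end, call.interval.end)
            else:
                if cur:
                    regions.append(_make_region(chrom, cur))
                cur = [call]
                cur_end = call.interval.end
        if cur:
            regions.append(_make_region(chrom, cur))
    return regions


def _make_region(chrom: str, calls: list[CNVCall]) -> CNVRegion:
    start = min(c.interval.start for c in calls)
    end = max(c.interval.end for c in calls)
    return CNVRegion(
        GenomicInterval(chrom, start, end),
        tuple(calls),
        frozenset(c.sample_id for c in calls),
    )


@dataclass
class PresenceSpectrum:
    """Histogram of CNVRs over the number of carrier individuals."""

    counts: dict[int, int]
    n_samples: int

    @property
    def n_regions(self) -> int:
        return sum(self.counts.values())

    @property
    def singleton_fraction(self) -> float:
        n = self.n_regions
        return self.counts.get(1, 0) / n if n else math.nan

    @property
    def shared_by_all_fraction(self) -> float:
        n = self.n_regions
        return self.counts.get(self.n_samples, 0) / n if n else math.nan


def presence_spectrum(
    cnvrs: Iterable[CNVRegion], sheet: SampleSheet
) -> PresenceSpectrum:
    counts: dict[int, int] = {}
    for r in cnvrs:
        unknown = r.carriers - set(sheet.sample_ids)
        if unknown:
            raise ValueError(f"carriers not in sample sheet: {sorted(unknown)}")
        counts[r.n_carriers] = counts.get(r.n_carriers, 0) + 1
    return PresenceSpectrum(counts, len(sheet))


def partition_by_sd(
    cnvrs: Iterable[CNVRegion], sds: Iterable[SegmentalDuplication]
) -> tuple[list[CNVRegion], list[CNVRegion]]:
    """Split CNVRs by >=1 bp overlap with any SD; returns (with, without)."""
    starts_by_chrom: dict[str, list[int]] = {}
    sds_by_chrom: dict[str, list[GenomicInterval]] = {}
    for sd in sds:
        sds_by_chrom.setdefault(sd.interval.chrom, []).append(sd.interval)
    for chrom, ivs in sds_by_chrom.items():
        ivs.sort(key=lambda i: i.start)
        starts_by_chrom[chrom] = [i.start for i in ivs]

    with_sd: list[CNVRegion] = []
    without_sd: list[CNVRegion] = []
    for r in cnvrs:
        ivs = sds_by_chrom.get(r.interval.chrom, [])
        hit = False
        if ivs:
            # candidates whose start precedes the CNVR end
            hi = bisect_left(starts_by_chrom[r.interval.chrom], r.interval.end)
            hit = any(iv.end > r.interval.start for iv in ivs[:hi])
        (with_sd if hit else without_sd).append(r)
    return with_sd, without_sd


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    with np.errstate(divide="ignore"):
        res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def cn_log2_haploid(cn_diploid: float, floor: float = 0.001) -> float:
    """log2 of the haploid copy number with a floor to keep zero events
    log-transformable (absolute deletions land near -10)."""
    if cn_diploid < 0:
        raise ValueError(f"cn must be >= 0, got {cn_diploid}")
    return math.log2(max(cn_diploid / 2.0, floor))


@dataclass
class PartitionReport:
    """Summary comparison of SD-overlapping vs non-overlapping CNVRs.

    Summaries are call-level: lengths and copy numbers are over member
    calls, not regions.
    """

    n_cnvrs: tuple[int, int]
    n_calls: tuple[int, int]
    median_call_length: tuple[float, float]
    mean_call_length: tuple[float, float]
    mean_haploid_cn: tuple[float, float]
    ks_length: tuple[float, float] | None
    ks_log2_cn: tuple[float, float] | None
    spectra: tuple[PresenceSpectrum, PresenceSpectrum] | None = None
    empty_partition: bool = field(default=False)


def _call_stats(cnvrs: list[CNVRegion]):
    lengths = [c.interval.length for r in cnvrs for c in r.member_calls]
    cns = [c.cn for r in cnvrs for c in r.member_calls]
    return lengths, cns


def compare_partitions(
    sd_overlapping: list[CNVRegion],
    sd_nonoverlapping: list[CNVRegion],
    sheet: SampleSheet | None = None,
) -> PartitionReport:
    len_a, cn_a = _call_stats(sd_overlapping)
    len_b, cn_b = _call_stats(sd_nonoverlapping)
    empty = not len_a or not len_b

    def med(v):
        return float(np.median(v)) if v else math.nan

    def mean(v):
        return float(np.mean(v)) if v else math.nan

    report = PartitionReport(
        n_cnvrs=(len(sd_overlapping), len(sd_nonoverlapping)),
        n_calls=(len(len_a), len(len_b)),
        median_call_length=(med(len_a), med(len_b)),
        mean_call_length=(mean(len_a), mean(len_b)),
        mean_haploid_cn=(mean(cn_a) / 2 if cn_a else math.nan,
                         mean(cn_b) / 2 if cn_b else math.nan),
        ks_length=None if empty else ks_two_sample(len_a, len_b),
        ks_log2_cn=None
        if empty
        else ks_two_sample(
            [cn_log2_haploid(c) for c in cn_a],
            [cn_log2_haploid(c) for c in cn_b],
        ),
        empty_partition=empty,
    )
    if sheet is not None:
        report.spectra = (
            presence_spectrum(sd_overlapping, sheet),
            presence_spectrum(sd_nonoverlapping, sheet),
        )
    return report


def write_cnvrs(cnvrs: Iterable[CNVRegion], path: str | os.PathLike) -> None:
    """BED6-like TSV: chrom, start, end, cnvr_id, n_carriers, carriers."""
    rows = sorted(cnvrs, key=lambda r: (r.interval.chrom, r.interval.start))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcnvr_id\tn_carriers\tcarriers\n")
        for i, r in enumerate(rows, start=1):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\tcnvr_{i:05d}\t{r.n_carriers}\t{','.join(sorted(r.carriers))}\n"
            )
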