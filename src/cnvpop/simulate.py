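"""Seeded generator of population-structured CNV call sets.

Emulates the data shape the analysis assumes: four populations of unequal
size, autosomes plus an X chromosome with male hemizygosity, SD-associated
high-frequency large duplications versus mostly rare small deletions outside
SDs, segregating whole-gene deletion alleles, a minority of very-high-copy
genes, and per-gene population mean shifts. Every planted feature is
recorded in a truth table; all generated calls survive the standard call
filter unless sub-threshold or gap-overlapping calls are explicitly
requested.

Layout conventions: each chromosome has a usable region starting at 100 kb
and a reserved tail where assembly gaps are placed, so ordinary calls never
touch gaps. Calls of one sample never overlap each other, mirroring a
segmentation-based caller's output.
"""

from __future__ import annotations

import math
import os
from bisect import bisect_left, insort
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genic import SexRules
from .model import (
    DELETION,
    DUPLICATION,
    CNVCall,
    Genome,
    GenomicInterval,
    Sample,
    SampleSheet,
    SegmentalDuplication,
    TranscriptionUnit,
    write_chrom_sizes,
    write_cnv_calls,
    write_genes,
    write_intervals,
    write_sample_sheet,
)

__all__ = ["SimulationConfig", "SimulationResult", "simulate",
           "plant_deletion_gene", "write_outputs", "DEFAULT_POPULATIONS"]

DEFAULT_POPULATIONS: dict[str, tuple[int, int]] = {
    # label -> (n_samples, n_males); the small island-like population
    # carries the study's two females.
    "popA": (8, 8),
    "popB": (8, 8),
    "popC": (8, 8),
    "popD": (3, 1),
}

_TAIL = 2_000_000  # reserved per-chromosome tail for assembly gaps
_MARGIN = 100_000  # unused head of every chromosome


@dataclass
class SimulationConfig:
    seed: int = 0
    n_autosomes: int = 3
    chrom_length: int = 30_000_000
    include_x: bool = True
    populations: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    # annotations
    n_genes: int = 2000
    gene_len_log_mean: float = math.log(8_000.0)
    gene_len_log_sd: float = 0.8
    n_gaps_per_chrom: int = 2
    gap_length: int = 50_000
    n_sd_blocks: int = 50
    sd_len_log_mean: float = math.log(30_000.0)
    sd_len_log_sd: float = 0.5
    # SD-associated CNVRs: few, large, high carrier frequency, dup-biased
    n_sd_cnvrs: int = 40
    sd_call_len_log_mean: float = math.log(10_700.0)
    sd_call_len_log_sd: float = 0.7
    sd_carrier_freq: tuple[float, float] = (0.3, 1.0)
    sd_dup_prob: float = 0.7
    # background calls outside SDs: many, small, deletion-biased
    background_calls_per_sample: float = 150.0
    bg_call_len_log_mean: float = math.log(3_800.0)
    bg_call_len_log_sd: float = 0.6
    bg_del_prob: float = 0.8
    # planted genic features
    n_divergent_genes: int = 30
    divergent_shift: float = 3.0
    n_deletion_genes: int = 40
    deletion_freq_range: tuple[float, float] = (0.05, 0.8)
    n_deletion_genes_on_x: int = 8
    n_high_copy_genes: int = 10
    high_copy_range: tuple[float, float] = (12.0, 35.0)
    noise_sd: float = 0.2
    breakpoint_jitter: int = 200
    # filter-exercise extras (off by default)
    n_subthreshold_calls: int = 0
    n_gap_calls: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_genes, self.n_sd_blocks, self.n_sd_cnvrs,
            self.n_divergent_genes, self.n_deletion_genes,
            self.n_high_copy_genes, self.n_gaps_per_chrom,
            self.n_subthreshold_calls, self.n_gap_calls,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lo, hi in (self.sd_carrier_freq, self.deletion_freq_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("frequency ranges must satisfy 0 <= lo <= hi <= 1")
        n_planted = (
            self.n_divergent_genes + self.n_deletion_genes + self.n_high_copy_genes
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"{n_planted} planted genes exceed n_genes={self.n_genes}"
            )
        if self.n_sd_cnvrs > self.n_sd_blocks:
            raise ValueError("n_sd_cnvrs must not exceed n_sd_blocks")

    # -- key=value config file round trip ------------------------------------

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for key, value in self.__dict__.items():
                if key == "populations":
                    value = ",".join(
                        f"{lab}:{n}:{m}" for lab, (n, m) in value.items()
                    )
                elif isinstance(value, tuple):
                    value = ",".join(repr(v) for v in value)
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "SimulationConfig":
        kwargs: dict = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "populations":
                    pops = {}
                    for part in value.split(","):
                        lab, n, m = part.split(":")
                        pops[lab] = (int(n), int(m))
                    kwargs[key] = pops
                elif key in ("include_x",):
                    kwargs[key] = value.lower() in ("true", "1", "yes")
                elif key in ("sd_carrier_freq", "deletion_freq_range",
                             "high_copy_range"):
                    lo, hi = value.split(",")
                    kwargs[key] = (float(lo), float(hi))
                else:
                    default = getattr(cls, key, None)
                    if isinstance(default, bool):
                        kwargs[key] = value.lower() in ("true", "1", "yes")
                    elif isinstance(default, int):
                        kwargs[key] = int(value)
                    else:
                        kwargs[key] = float(value) if "." in value or "e" in value.lower() else int(value) if value.lstrip("-").isdigit() else value
        return cls(**kwargs)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Genome
    genes: list[TranscriptionUnit]
    sds: list[SegmentalDuplication]
    sheet: SampleSheet
    callsets: dict[str, list[CNVCall]]
    truth: pd.DataFrame


class _Blocklist:
    """Per-chromosome sorted disjoint blocked intervals for rejection tests."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        self._by_chrom.setdefault(chrom, [])
        insort(self._by_chrom[chrom], (start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._by_chrom.get(chrom, ())
        if not ivs:
            return False
        i = bisect_left(ivs, (end, end))
        return any(e > start for _, e in ivs[:i])


def _draw_length(rng, log_mean, log_sd, lo, hi) -> int:
    return int(np.clip(rng.lognormal(log_mean, log_sd), lo, hi))


def _noisy_cn(rng, cn: float, noise_sd: float) -> float:
    if noise_sd > 0:
        cn = cn + rng.normal(0.0, noise_sd)
    return max(0.0, float(cn))


def _make_call(iv: GenomicInterval, sample_id: str, cn: float, baseline: int) -> CNVCall:
    call_type = DELETION if cn < baseline else DUPLICATION
    return CNVCall(iv, sample_id, call_type, cn)


def plant_deletion_gene(
    gene: TranscriptionUnit,
    pop_freqs: Mapping[str, float],
    sheet: SampleSheet,
    rules: SexRules,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Hardy-Weinberg genotypes for a whole-gene deletion allele.

    Autosomes and female X draw two alleles (CN in {0,1,2}); hemizygous male
    X draws one (CN in {0,1}). Returns integer CN per sample.
    """
    for f in pop_freqs.values():
        if not 0 <= f <= 1:
            raise ValueError("allele frequencies must be in [0, 1]")
    genotypes: dict[str, int] = {}
    for sample in sheet:
        f = pop_freqs[sample.population]
        ploidy = rules.baseline(sample.sample_id, gene.interval.chrom)
        n_del = int(rng.binomial(ploidy, f))
        genotypes[sample.sample_id] = ploidy - n_del
    return genotypes


def simulate(config: SimulationConfig | None = None, **overrides) -> SimulationResult:
    """Generate a full synthetic data set, deterministic under the seed."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    # -- genome ---------------------------------------------------------------
    chroms = [f"chr{i}" for i in range(1, config.n_autosomes + 1)]
    x_chrom = "chrX" if config.include_x else None
    if x_chrom:
        chroms.append(x_chrom)
    chrom_lengths = {c: config.chrom_length for c in chroms}
    usable_end = config.chrom_length - _TAIL - _MARGIN
    if usable_end <= _MARGIN:
        raise ValueError("chrom_length too small for the reserved layout")

    gaps = []
    tail_start = config.chrom_length - _TAIL
    for c in chroms:
        for k in range(config.n_gaps_per_chrom):
            lo = tail_start + k * (_TAIL // max(config.n_gaps_per_chrom, 1))
            start = lo + int(rng.integers(0, 200_000))
            gaps.append(GenomicInterval(c, start, start + config.gap_length))
    genome = Genome(chrom_lengths, sex_chrom=x_chrom, gaps=tuple(gaps))

    # -- sample sheet ---------------------------------------------------------
    samples = []
    for pop, (n, n_males) in config.populations.items():
        if n_males > n:
            raise ValueError(f"population {pop}: n_males > n_samples")
        for i in range(n):
            sex = "male" if i < n_males else "female"
            samples.append(Sample(f"{pop}_{i + 1:02d}", pop, sex))
    sheet = SampleSheet(samples)
    rules = SexRules(sheet, x_chrom)

    # -- genes: sequential placement with random spacing ----------------------
    genes: list[TranscriptionUnit] = []
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    gid = 0
    for c, n_on_chrom in zip(chroms, per_chrom):
        cursor = _MARGIN
        for _ in range(int(n_on_chrom)):
            cursor += int(rng.integers(2_000, 30_000))
            length = _draw_length(
                rng, config.gene_len_log_mean, config.gene_len_log_sd,
                1_000, 150_000,
            )
            if cursor + length >= usable_end:
                raise ValueError(
                    "infeasible config: genes do not fit on "
                    f"{c}; increase chrom_length or reduce n_genes"
                )
            gid += 1
            genes.append(
                TranscriptionUnit(
                    GenomicInterval(c, cursor, cursor + length), f"gene{gid:05d}"
                )
            )
            cursor += length

    # -- choose planted genes --------------------------------------------------
    autosomal_idx = [
        i for i, g in enumerate(genes) if g.interval.chrom != x_chrom
    ]
    x_idx = [i for i, g in enumerate(genes) if g.interval.chrom == x_chrom]
    n_del_x = min(config.n_deletion_genes_on_x, config.n_deletion_genes,
                  len(x_idx))
    need_autosomal = (
        config.n_divergent_genes
        + config.n_high_copy_genes
        + (config.n_deletion_genes - n_del_x)
    )
    if need_autosomal > len(autosomal_idx):
        raise ValueError("infeasible config: not enough autosomal genes to plant")
    picked = rng.choice(autosomal_idx, size=need_autosomal, replace=False)
    divergent = [genes[i] for i in picked[: config.n_divergent_genes]]
    high_copy = [
        genes[i]
        for i in picked[
            config.n_divergent_genes: config.n_divergent_genes
            + config.n_high_copy_genes
        ]
    ]
    deletion = [genes[i] for i in picked[config.n_divergent_genes
                                         + config.n_high_copy_genes:]]
    if n_del_x:
        picked_x = rng.choice(x_idx, size=n_del_x, replace=False)
        deletion.extend(genes[i] for i in picked_x)

    jitter = config.breakpoint_jitter
    blocked = _Blocklist()
    for g in divergent + high_copy + deletion:
        blocked.add(
            g.interval.chrom,
            max(0, g.interval.start - jitter - 1),
            g.interval.end + jitter + 1,
        )

    callsets: dict[str, list[CNVCall]] = {s.sample_id: [] for s in sheet}
    truth_rows: list[dict] = []

    def whole_gene_call(gene, sample_id, cn):
        start = max(0, gene.interval.start - int(rng.integers(0, jitter + 1)))
        end = gene.interval.end + int(rng.integers(0, jitter + 1))
        iv = GenomicInterval(gene.interval.chrom, start, end)
        base = rules.baseline(sample_id, gene.interval.chrom)
        callsets[sample_id].append(_make_call(iv, sample_id, cn, base))

    # -- divergent genes: one population mean-shifted upward -------------------
    # targets are drawn from well-sampled populations so the ANOVA scan
    # (which drops undersized populations) can see every planted shift
    pop_labels = sheet.populations()
    shift_pops = [p for p in pop_labels if len(sheet.samples_in(p)) >= 4]
    if not shift_pops:
        shift_pops = pop_labels
    for gene in divergent:
        target = shift_pops[int(rng.integers(0, len(shift_pops)))]
        for s in sheet.samples_in(target):
            cn = _noisy_cn(rng, 2.0 + config.divergent_shift, config.noise_sd)
            whole_gene_call(gene, s.sample_id, cn)
        truth_rows.append(
            dict(kind="divergent", gene_id=gene.gene_id,
                 chrom=gene.interval.chrom, start=gene.interval.start,
                 end=gene.interval.end, population=target,
                 value=2.0 + config.divergent_shift)
        )

    # -- high-copy genes: every sample far above baseline ----------------------
    for gene in high_copy:
        pop_means = {
            pop: float(rng.uniform(*config.high_copy_range)) for pop in pop_labels
        }
        for s in sheet:
            cn = _noisy_cn(rng, pop_means[s.population], config.noise_sd)
            whole_gene_call(gene, s.sample_id, cn)
        for pop, mean in pop_means.items():
            truth_rows.append(
                dict(kind="high_copy", gene_id=gene.gene_id,
                     chrom=gene.interval.chrom, start=gene.interval.start,
                     end=gene.interval.end, population=pop, value=mean)
            )

    # -- segregating whole-gene deletion alleles -------------------------------
    for gene in deletion:
        lo, hi = config.deletion_freq_range
        pop_freqs = {pop: float(rng.uniform(lo, hi)) for pop in pop_labels}
        genotypes = plant_deletion_gene(gene, pop_freqs, sheet, rules, rng)
        for sample in sheet:
            cn_int = genotypes[sample.sample_id]
            base = rules.baseline(sample.sample_id, gene.interval.chrom)
            if cn_int < base:
                cn = _noisy_cn(rng, float(cn_int), config.noise_sd)
                whole_gene_call(gene, sample.sample_id, cn)
        for pop, f in pop_freqs.items():
            truth_rows.append(
                dict(kind="deletion", gene_id=gene.gene_id,
                     chrom=gene.interval.chrom, start=gene.interval.start,
                     end=gene.interval.end, population=pop, value=f)
            )

    # -- SD blocks (autosomes, clear of planted genes) -------------------------
    autosomes = [c for c in chroms if c != x_chrom]
    sds: list[SegmentalDuplication] = []
    sd_zone = _Blocklist()  # keep SD blocks mutually disjoint
    # leave room so an anchor (<= 200 kb) plus jitter never reaches the tail
    sd_hi = usable_end - 210_000
    attempts = 0
    while len(sds) < config.n_sd_blocks:
        attempts += 1
        if attempts > 100 * config.n_sd_blocks + 100:
            raise ValueError("infeasible config: cannot place SD blocks")
        c = autosomes[int(rng.integers(0, len(autosomes)))]
        length = _draw_length(rng, config.sd_len_log_mean, config.sd_len_log_sd,
                              10_001, 500_000)
        if sd_hi - length <= _MARGIN:
            continue
        start = int(rng.integers(_MARGIN, sd_hi - length))
        # pad right: an anchor may extend up to ~200 kb past the block end
        # and must still stay clear of planted-gene call regions
        if blocked.overlaps(c, max(0, start - 500), start + length + 200_500):
            continue
        if sd_zone.overlaps(c, max(0, start - 201_000), start + length + 201_000):
            continue
        sd_zone.add(c, start, start + length)
        sds.append(SegmentalDuplication(GenomicInterval(c, start, start + length)))

    # -- SD-associated CNVRs: large, frequent, duplication-biased --------------
    block_order = rng.permutation(len(sds))[: config.n_sd_cnvrs]
    for bi in block_order:
        block = sds[int(bi)].interval
        length = _draw_length(rng, config.sd_call_len_log_mean,
                              config.sd_call_len_log_sd, 2_000, 200_000)
        s_hi = max(block.start + 1, block.end - length)
        anchor_start = int(rng.integers(block.start, s_hi))
        anchor = GenomicInterval(block.chrom, anchor_start, anchor_start + length)
        blocked.add(block.chrom, max(0, anchor.start - jitter - 1),
                    anchor.end + jitter + 1)
        freq = float(rng.uniform(*config.sd_carrier_freq))
        carriers = [
            s.sample_id for s in sheet if rng.random() < freq
        ]
        for sample_id in carriers:
            start = max(0, anchor.start - int(rng.integers(0, jitter + 1)))
            end = anchor.end + int(rng.integers(0, jitter + 1))
            iv = GenomicInterval(anchor.chrom, start, end)
            if rng.random() < config.sd_dup_prob:
                cn = 2.0 * (1.0 + rng.exponential(0.6))
            else:
                cn = 2.0 * rng.uniform(0.0, 0.75)
            callsets[sample_id].append(
                _make_call(iv, sample_id, max(0.0, float(cn)), 2)
            )
        truth_rows.append(
            dict(kind="sd_cnvr", gene_id="", chrom=anchor.chrom,
                 start=anchor.start, end=anchor.end, population="",
                 value=freq)
        )

    # -- background calls: small, rare, deletion-biased, off-SD ----------------
    for sd in sds:
        blocked.add(sd.interval.chrom, sd.interval.start, sd.interval.end)
    chrom_weights = np.array([usable_end - _MARGIN] * len(chroms), dtype=float)
    chrom_weights /= chrom_weights.sum()
    for sample in sheet:
        n_calls = int(rng.poisson(config.background_calls_per_sample))
        own = _Blocklist()
        placed = 0
        attempts = 0
        while placed < n_calls:
            attempts += 1
            if attempts > 50 * n_calls + 1000:
                break  # extremely crowded config; keep what fits
            c = chroms[int(rng.choice(len(chroms), p=chrom_weights))]
            length = _draw_length(rng, config.bg_call_len_log_mean,
                                  config.bg_call_len_log_sd, 1_000, 50_000)
            start = int(rng.integers(_MARGIN, usable_end - length))
            if blocked.overlaps(c, start, start + length):
                continue
            if own.overlaps(c, start, start + length):
                continue
            own.add(c, start, start + length)
            base = rules.baseline(sample.sample_id, c)
            if rng.random() < config.bg_del_prob:
                u = rng.uniform(0.0, 0.75)
            else:
                u = 1.0 + rng.exponential(0.75)
            iv = GenomicInterval(c, start, start + length)
            callsets[sample.sample_id].append(
                _make_call(iv, sample.sample_id, float(u * base), base)
            )
            placed += 1

    # -- optional filter-exercise calls ---------------------------------------
    sample_ids = sheet.sample_ids
    for _ in range(config.n_subthreshold_calls):
        sid = sample_ids[int(rng.integers(0, len(sample_ids)))]
        c = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(100, 1000))
        start = int(rng.integers(_MARGIN, usable_end - length))
        iv = GenomicInterval(c, start, start + length)
        callsets[sid].append(_make_call(iv, sid, 1.0, 2))
    for _ in range(config.n_gap_calls):
        sid = sample_ids[int(rng.integers(0, len(sample_ids)))]
        gap = gaps[int(rng.integers(0, len(gaps)))]
        start = max(0, gap.start - 2_000)
        iv = GenomicInterval(gap.chrom, start, gap.start + 500)
        callsets[sid].append(_make_call(iv, sid, 1.0, 2))

    for calls in callsets.values():
        calls.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                                  c.interval.end))
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "gene_id", "chrom", "start", "end", "population",
                 "value"],
    )
    return SimulationResult(config, genome, genes, sds, sheet, callsets, truth)


def write_outputs(sim: SimulationResult, outdir: str | os.PathLike) -> None:
    """Write the full simulated data set in the standard TSV dialects."""
    outdir = str(outdir)
    calls_dir = os.path.join(outdir, "calls")
    os.makedirs(calls_dir, exist_ok=True)
    for sample_id, calls in sim.callsets.items():
        write_cnv_calls(calls, os.path.join(calls_dir, f"{sample_id}.tsv"))
    write_genes(sim.genes, os.path.join(outdir, "genes.tsv"))
    write_intervals(
        [sd.interval for sd in sim.sds], os.path.join(outdir, "sds.tsv")
    )
    write_intervals(list(sim.genome.gaps), os.path.join(outdir, "gaps.tsv"))
    write_chrom_sizes(sim.genome.chrom_lengths, os.path.join(outdir, "chrom.sizes"))
    write_sample_sheet(sim.sheet, os.path.join(outdir, "samples.tsv"))
    sim.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    sim.config.to_file(os.path.join(outdir, "config.txt"))
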