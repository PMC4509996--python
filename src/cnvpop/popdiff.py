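"""Population differentiation on gene copy numbers.

Implements the V_ST statistic, deletion-allele frequencies with hemizygous-X
accounting, the one-way ANOVA + BH FDR + mean-difference + Tukey HSD scan,
per-gene standardization, and nonmetric MDS of inter-individual Euclidean
distances.

Variance conventions: V_ST uses population variances (divisor n), so two
identical groups give exactly v_st = 0; v_t = 0 is reported as undefined
rather than 0, and negative values are reported unclipped.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.manifold import smacof
from sklearn.utils import check_random_state

from .genic import CopyNumberMatrix, SexRules
from .model import SampleSheet, TranscriptionUnit

__all__ = [
    "VstResult",
    "VstScan",
    "DeletionFrequencyResult",
    "PopulationLoss",
    "AnovaResult",
    "TukeyPair",
    "ScanResult",
    "NMDSResult",
    "vst",
    "vst_scan",
    "deletion_allele_frequency",
    "round_half_up",
    "population_loss",
    "anova_oneway",
    "bh_fdr",
    "tukey_hsd",
    "divergence_scan",
    "standardize_matrix",
    "nmds",
    "nmds_from_distances",
]


# ---------------------------------------------------------------------------
# V_ST


@dataclass(frozen=True)
class VstResult:
    v_t: float
    v_s: float
    v_st: float  # NaN when undefined (v_t == 0)
    defined: bool
    gene_id: str | None = None
    pop_pair: tuple[str, str] | None = None


def vst(x, y, gene_id: str | None = None, pop_pair=None) -> VstResult:
    """V_ST = (V_T - V_S) / V_T for two populations' copy numbers.

    V_T is the pooled variance and V_S the sample-size-weighted mean of the
    within-population variances, all with divisor n. Undefined (flagged,
    NaN) when V_T = 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each population needs >= 2 values")
    n1, n2 = x.size, y.size
    v_s = (n1 * x.var() + n2 * y.var()) / (n1 + n2)
    # pooled variance via the exact within/between decomposition, so that
    # identical groups give v_st = 0 and zero within-variance gives 1 exactly
    m1, m2 = x.mean(), y.mean()
    m = (n1 * m1 + n2 * m2) / (n1 + n2)
    v_between = (n1 * (m1 - m) ** 2 + n2 * (m2 - m) ** 2) / (n1 + n2)
    v_t = float(v_s + v_between)
    if v_t == 0.0:
        return VstResult(0.0, float(v_s), math.nan, False, gene_id, pop_pair)
    return VstResult(
        float(v_t), float(v_s), float((v_t - v_s) / v_t), True, gene_id, pop_pair
    )


@dataclass
class VstScan:
    results: list[VstResult]
    pair_means: dict[tuple[str, str], float]  # mean over defined genes


def vst_scan(
    matrix: CopyNumberMatrix, sheet: SampleSheet, min_pop_size: int = 2
) -> VstScan:
    """V_ST for every gene and unordered population pair, plus per-pair
    means across genes (undefined genes excluded from the mean)."""
    pops = [
        p for p in sheet.populations() if len(sheet.samples_in(p)) >= min_pop_size
    ]
    if len(pops) < 2:
        raise ValueError("need >= 2 populations with enough samples")
    cols = {
        p: [matrix.samples.index(s.sample_id) for s in sheet.samples_in(p)]
        for p in pops
    }
    results: list[VstResult] = []
    sums: dict[tuple[str, str], list[float]] = {}
    for p1, p2 in itertools.combinations(pops, 2):
        sums[(p1, p2)] = []
    for i, gene in enumerate(matrix.genes):
        row = matrix.cn[i]
        for p1, p2 in itertools.combinations(pops, 2):
            r = vst(row[cols[p1]], row[cols[p2]], gene.gene_id, (p1, p2))
            results.append(r)
            if r.defined:
                sums[(p1, p2)].append(r.v_st)
    pair_means = {
        pair: (float(np.mean(v)) if v else math.nan) for pair, v in sums.items()
    }
    return VstScan(results, pair_means)


# ---------------------------------------------------------------------------
# deletion allele frequencies


def round_half_up(x: float) -> int:
    """Nearest integer, ties away from zero upward (1.5 -> 2, 1.4 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DeletionFrequencyResult:
    gene_id: str
    n_alleles: int
    n_del: int

    @property
    def freq(self) -> float:
        return self.n_del / self.n_alleles


def deletion_allele_frequency(
    gene: TranscriptionUnit,
    cn_row: Mapping[str, float],
    sheet: SampleSheet,
    rules: SexRules,
) -> DeletionFrequencyResult:
    """Deletion-allele frequency from integer-rounded copy numbers.

    Autosomes and female X: each sample carries 2 alleles; CN 0 counts 2
    deletion alleles and CN 1 counts 1. Hemizygous male X: 1 allele; CN 0
    counts 1. Samples with integer CN >= 2 (including >= 3, whose allelic
    configuration is ambiguous) contribute only non-deletion alleles, so the
    estimate is a lower bound.
    """
    if not cn_row:
        raise ValueError("empty copy-number row")
    chrom = gene.interval.chrom
    n_alleles = 0
    n_del = 0
    for sample_id, value in cn_row.items():
        cn = round_half_up(float(value))
        ploidy = rules.baseline(sample_id, chrom)
        n_alleles += ploidy
        if ploidy == 1:
            n_del += 1 if cn == 0 else 0
        else:
            n_del += 2 if cn == 0 else (1 if cn == 1 else 0)
    return DeletionFrequencyResult(gene.gene_id, n_alleles, n_del)


@dataclass
class PopulationLoss:
    """Whole-gene losses: per-population fixed losses and overall counts."""

    lost_per_population: dict[str, list[str]]
    homozygous_deleted_any: list[str]  # CN 0 in >= 1 individual
    homozygous_deleted_multiple: list[str]  # CN 0 in > 1 individual


def population_loss(
    matrix: CopyNumberMatrix, sheet: SampleSheet, rules: SexRules
) -> PopulationLoss:
    pops = sheet.populations()
    cols = {
        p: [matrix.samples.index(s.sample_id) for s in sheet.samples_in(p)]
        for p in pops
    }
    lost: dict[str, list[str]] = {p: [] for p in pops}
    any_del: list[str] = []
    multi_del: list[str] = []
    rounded = np.floor(matrix.cn + 0.5).astype(int)
    for i, gene in enumerate(matrix.genes):
        zeros = rounded[i] == 0
        n_zero = int(zeros.sum())
        if n_zero >= 1:
            any_del.append(gene.gene_id)
        if n_zero > 1:
            multi_del.append(gene.gene_id)
        for p in pops:
            if zeros[cols[p]].all():
                lost[p].append(gene.gene_id)
    return PopulationLoss(lost, any_del, multi_del)


# ---------------------------------------------------------------------------
# ANOVA / FDR / Tukey scan


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_between: float
    ms_within: float
    defined: bool


def anova_oneway(groups: Sequence[Iterable[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    MSE = 0 with MSB > 0 gives F = +inf, p = 0; MSE = MSB = 0 is flagged
    undefined.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    msb = ssb / df_b
    mse = sse / df_w
    if mse == 0.0:
        if msb == 0.0:
            return AnovaResult(math.nan, df_b, df_w, math.nan, 0.0, 0.0, False)
        return AnovaResult(math.inf, df_b, df_w, 0.0, float(msb), 0.0, True)
    F = msb / mse
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(msb), float(mse), True)


def bh_fdr(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class TukeyPair:
    groups: tuple[int, int]
    mean_diff: float
    q: float
    p_adj: float


def tukey_hsd(groups: Sequence[Iterable[float]]) -> list[TukeyPair]:
    """Tukey HSD (Tukey-Kramer for unequal sizes) over all group pairs.

    q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)); adjusted p from
    the studentized range distribution with k groups and the ANOVA
    within-groups df. Requires MSE > 0.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    res = anova_oneway(arrays)
    if res.ms_within == 0.0:
        raise ValueError("MSE = 0: post hoc comparison is meaningless")
    k = len(arrays)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = arrays[j].mean() - arrays[i].mean()
        se = math.sqrt(
            res.ms_within / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        )
        q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, res.df_within))
        out.append(TukeyPair((i, j), float(diff), float(q), min(p_adj, 1.0)))
    return out


@dataclass
class ScanResult:
    gene_id: str
    F: float
    df: tuple[int, int]
    p: float
    q: float
    max_pair_mean_diff: float
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)
    selected: bool = False
    defined: bool = True


def divergence_scan(
    matrix: CopyNumberMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
    min_mean_diff: float = 1.0,
    exclude_populations: Sequence[str] = (),
) -> list[ScanResult]:
    """Per-gene ANOVA across populations, BH FDR over all genes, retention
    of genes with q < alpha and a population mean-CN difference of at least
    ``min_mean_diff`` in some pair, then Tukey HSD on the retained genes.

    Populations with too few samples can be excluded by the caller.
    """
    pops = [p for p in sheet.populations() if p not in set(exclude_populations)]
    if len(pops) < 2:
        raise ValueError("need >= 2 populations after exclusion")
    cols = {
        p: [matrix.samples.index(s.sample_id) for s in sheet.samples_in(p)]
        for p in pops
    }
    results: list[ScanResult] = []
    for i, gene in enumerate(matrix.genes):
        groups = [matrix.cn[i, cols[p]] for p in pops]
        a = anova_oneway(groups)
        means = [g.mean() for g in groups]
        max_diff = max(
            abs(m1 - m2) for m1, m2 in itertools.combinations(means, 2)
        )
        results.append(
            ScanResult(
                gene_id=gene.gene_id,
                F=a.F,
                df=(a.df_between, a.df_within),
                p=a.p,
                q=math.nan,
                max_pair_mean_diff=float(max_diff),
                defined=a.defined,
            )
        )
    defined_idx = [i for i, r in enumerate(results) if r.defined]
    if defined_idx:
        q = bh_fdr([results[i].p for i in defined_idx])
        for i, qi in zip(defined_idx, q):
            results[i].q = float(qi)
    for i, r in enumerate(results):
        r.selected = bool(
            r.defined
            and r.q < alpha
            and r.max_pair_mean_diff >= min_mean_diff
        )
        if r.selected:
            groups = [matrix.cn[i, cols[p]] for p in pops]
            if anova_oneway(groups).ms_within > 0:
                pairs = tukey_hsd(groups)
                r.tukey = {
                    (pops[t.groups[0]], pops[t.groups[1]]): t.p_adj for t in pairs
                }
    return results


# ---------------------------------------------------------------------------
# standardization and nonmetric MDS


def standardize_matrix(
    matrix: CopyNumberMatrix,
) -> tuple[np.ndarray, list[TranscriptionUnit]]:
    """Per-gene z-scores across samples (mean 0, divisor-n sd 1).

    Zero-variance genes carry no ordering information and are dropped with
    a warning. Returns (z, kept_genes) with z of shape kept_genes x samples.
    """
    means = matrix.cn.mean(axis=1, keepdims=True)
    sds = matrix.cn.std(axis=1, keepdims=True)
    keep = sds[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} zero-variance genes before standardization",
            stacklevel=2,
        )
    z = (matrix.cn[keep] - means[keep]) / sds[keep]
    kept_genes = [g for g, k in zip(matrix.genes, keep) if k]
    return z, kept_genes


@dataclass
class NMDSResult:
    coordinates: np.ndarray  # samples x dims
    stress: float  # Kruskal stress-1 of the best configuration
    sample_ids: list[str] | None = None


def _classical_mds_init(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds_from_distances(
    distances: np.ndarray,
    dims: int = 2,
    seed: int | None = 0,
    n_restarts: int = 8,
    max_iter: int = 500,
    eps: float = 1e-9,
    sample_ids: list[str] | None = None,
) -> NMDSResult:
    """Kruskal nonmetric MDS (stress-1) with monotone regression.

    Runs one classical-scaling-initialized fit plus ``n_restarts`` seeded
    random restarts and keeps the lowest-stress configuration.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("need >= 3 points")
    if not np.any(d > 0):
        raise ValueError("all-zero distance matrix")
    rng = check_random_state(seed)

    best_coords: np.ndarray | None = None
    best_stress = math.inf
    inits: list[np.ndarray | None] = [_classical_mds_init(d, dims)]
    inits.extend(None for _ in range(n_restarts))
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, stress = smacof(
                d,
                metric=False,
                n_components=dims,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                random_state=rng,
                normalized_stress=True,
            )
        if stress < best_stress:
            best_stress = float(stress)
            best_coords = coords
    assert best_coords is not None
    return NMDSResult(best_coords, best_stress, sample_ids)


def nmds(
    z: np.ndarray,
    dims: int = 2,
    seed: int | None = 0,
    sample_ids: list[str] | None = None,
    **kwargs,
) -> NMDSResult:
    """NMDS of samples from a standardized genes x samples matrix, using
    Euclidean distances between sample columns."""
    z = np.asarray(z, dtype=float)
    diffs = z[:, :, None] - z[:, None, :]
    d = np.sqrt((diffs**2).sum(axis=0))
    return nmds_from_distances(d, dims=dims, seed=seed, sample_ids=sample_ids, **kwargs)
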