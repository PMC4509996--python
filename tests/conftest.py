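import numpy as np
import pytest

from cnvpop.genic import SexRules, build_cn_matrix, find_cnv_genes
from cnvpop.model import (
    CNVCall,
    Genome,
    GenomicInterval,
    Sample,
    SampleSheet,
    filter_calls,
)
from cnvpop.simulate import SimulationConfig, simulate


def make_call(chrom, start, end, sample_id="s1", cn=0.5, call_type=None):
    if call_type is None:
        call_type = "deletion" if cn < 2 else "duplication"
    return CNVCall(GenomicInterval(chrom, start, end), sample_id, call_type, cn)


def random_calls(rng, n, chroms=("chr1", "chr2"), span=100_000, sample_ids=("s1", "s2", "s3")):
    calls = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 5_000))
        sid = sample_ids[rng.integers(0, len(sample_ids))]
        cn = float(rng.uniform(0, 6))
        calls.append(make_call(chrom, start, start + length, sid, cn))
    return calls


@pytest.fixture
def two_pop_sheet():
    return SampleSheet(
        [Sample(f"a{i}", "popA", "male") for i in range(4)]
        + [Sample(f"b{i}", "popB", "male") for i in range(4)]
    )


@pytest.fixture
def mixed_sheet():
    """Two populations with mixed sexes for X-chromosome rules."""
    return SampleSheet(
        [
            Sample("m1", "popA", "male"),
            Sample("m2", "popA", "male"),
            Sample("m3", "popB", "male"),
            Sample("f1", "popB", "female"),
        ]
    )


@pytest.fixture
def small_genome():
    return Genome(
        {"chr1": 1_000_000, "chr2": 1_000_000, "chrX": 1_000_000},
        sex_chrom="chrX",
        gaps=(GenomicInterval("chr1", 500_000, 510_000),),
    )


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Filtered calls, CNV genes, and the copy-number matrix for the default
    simulation; shared across tests to avoid recomputation."""
    sim = default_sim
    filtered = {
        sid: filter_calls(calls, sim.genome)
        for sid, calls in sim.callsets.items()
    }
    rules = SexRules(sim.sheet, sim.genome.sex_chrom)
    cnv_genes = find_cnv_genes(filtered, sim.genes)
    matrix = build_cn_matrix(filtered, cnv_genes, sim.sheet, rules)
    return dict(
        sim=sim, filtered=filtered, rules=rules, cnv_genes=cnv_genes,
        matrix=matrix,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
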