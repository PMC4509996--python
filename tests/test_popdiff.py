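import math

import numpy as np
import pytest
from scipy import stats as sps

from cnvpop.genic import CopyNumberMatrix, SexRules
from cnvpop.model import GenomicInterval, Sample, SampleSheet, TranscriptionUnit
from cnvpop.popdiff import (
    anova_oneway,
    bh_fdr,
    deletion_allele_frequency,
    divergence_scan,
    nmds,
    nmds_from_distances,
    population_loss,
    round_half_up,
    standardize_matrix,
    tukey_hsd,
    vst,
    vst_scan,
)

from oracles import allele_count_oracle, bh_stepup_by_hand, vst_explicit


def gene(chrom="chr1", gid="g1"):
    return TranscriptionUnit(GenomicInterval(chrom, 0, 1000), gid)


def matrix_from_rows(rows, samples, chroms=None):
    genes = [
        TranscriptionUnit(
            GenomicInterval((chroms or ["chr1"] * len(rows))[i], 2000 * i, 2000 * i + 1000),
            f"g{i}",
        )
        for i in range(len(rows))
    ]
    return CopyNumberMatrix(genes, samples, np.array(rows, dtype=float))


class TestVst:
    def test_all_between_variance(self):
        r = vst([2, 2, 2, 2], [4, 4, 4, 4])
        assert (r.v_s, r.v_t, r.v_st) == (0.0, 1.0, 1.0)

    def test_identical_groups_zero(self):
        r = vst([1, 3], [1, 3])
        assert r.v_st == 0.0

    def test_hand_computed_example(self):
        r = vst([0, 1, 2], [4, 5])
        assert r.v_s == pytest.approx(0.5)
        assert r.v_t == pytest.approx(3.44)
        assert r.v_st == pytest.approx((3.44 - 0.5) / 3.44)

    def test_undefined_when_constant(self):
        r = vst([2, 2], [2, 2])
        assert not r.defined
        assert math.isnan(r.v_st)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            vst([1], [2, 3])

    def test_matches_explicit_sum_oracle(self, rng):
        for _ in range(200):
            x = rng.uniform(0, 10, size=int(rng.integers(2, 21)))
            y = rng.uniform(0, 10, size=int(rng.integers(2, 21)))
            expected = vst_explicit(x, y)
            got = vst(x, y)
            assert abs(got.v_st - expected) < 1e-12

    def test_shift_invariance_and_symmetry(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 5, size=6)
            y = rng.uniform(0, 5, size=4)
            base = vst(x, y).v_st
            assert vst(x + 7.3, y + 7.3).v_st == pytest.approx(base, abs=1e-10)
            assert vst(y, x).v_st == pytest.approx(base, abs=1e-12)


class TestVstScan:
    def sheet(self):
        return SampleSheet(
            [Sample(f"a{i}", "pA", "male") for i in range(3)]
            + [Sample(f"b{i}", "pB", "male") for i in range(3)]
            + [Sample(f"c{i}", "pC", "male") for i in range(2)]
        )

    def test_constant_matrix_undefined(self):
        samples = self.sheet().sample_ids
        m = matrix_from_rows([[2.0] * 8], samples)
        scan = vst_scan(m, self.sheet())
        assert all(not r.defined for r in scan.results)
        assert all(math.isnan(v) for v in scan.pair_means.values())

    def test_shifted_population_gives_one(self):
        samples = self.sheet().sample_ids
        m = matrix_from_rows([[6, 6, 6, 2, 2, 2, 2, 2]], samples)
        scan = vst_scan(m, self.sheet())
        by_pair = {r.pop_pair: r.v_st for r in scan.results}
        assert by_pair[("pA", "pB")] == 1.0
        assert by_pair[("pA", "pC")] == 1.0
        assert not [r for r in scan.results if r.pop_pair == ("pB", "pC")][0].defined

    def test_elementwise_equality(self, rng):
        sheet = self.sheet()
        rows = rng.uniform(0, 6, size=(50, 8)).tolist()
        m = matrix_from_rows(rows, sheet.sample_ids)
        scan = vst_scan(m, sheet)
        cols = {p: [sheet.sample_ids.index(s.sample_id) for s in sheet.samples_in(p)]
                for p in sheet.populations()}
        for r in scan.results:
            i = int(r.gene_id[1:])
            row = np.array(rows[i])
            direct = vst(row[cols[r.pop_pair[0]]], row[cols[r.pop_pair[1]]])
            assert r.v_st == direct.v_st or (
                math.isnan(r.v_st) and math.isnan(direct.v_st)
            )


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(1.4, 1), (1.5, 2), (0.5, 1), (0.49, 0), (2.5, 3)]
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected


class TestDeletionAlleleFrequency:
    def autosheet(self, n):
        return SampleSheet([Sample(f"s{i}", "p", "male") for i in range(n)])

    def test_autosomal_enumeration(self):
        cns = [0, 0, 1, 2, 2, 2, 2, 2]
        sheet = self.autosheet(8)
        rules = SexRules(sheet, "chrX")
        row = {f"s{i}": c for i, c in enumerate(cns)}
        res = deletion_allele_frequency(gene("chr1"), row, sheet, rules)
        assert (res.n_del, res.n_alleles) == (5, 16)
        assert res.freq == pytest.approx(0.3125)

    def test_no_deletions(self):
        sheet = self.autosheet(4)
        rules = SexRules(sheet, "chrX")
        row = {s: 2.0 for s in sheet.sample_ids}
        res = deletion_allele_frequency(gene("chr1"), row, sheet, rules)
        assert res.freq == 0.0

    def test_x_hemizygous_mixed(self):
        sheet = SampleSheet(
            [Sample("m1", "p", "male"), Sample("m2", "p", "male"),
             Sample("m3", "p", "male"), Sample("f1", "p", "female")]
        )
        rules = SexRules(sheet, "chrX")
        row = {"m1": 0, "m2": 1, "m3": 1, "f1": 1}
        res = deletion_allele_frequency(gene("chrX"), row, sheet, rules)
        assert (res.n_del, res.n_alleles) == (2, 5)
        assert res.freq == pytest.approx(0.4)

    def test_high_copy_counts_as_non_deletion(self):
        sheet = self.autosheet(2)
        rules = SexRules(sheet, "chrX")
        row = {"s0": 0.0, "s1": 7.0}
        res = deletion_allele_frequency(gene("chr1"), row, sheet, rules)
        assert (res.n_del, res.n_alleles) == (2, 4)

    def test_rounding_before_counting(self):
        sheet = self.autosheet(2)
        rules = SexRules(sheet, "chrX")
        row = {"s0": 1.4, "s1": 1.6}
        res = deletion_allele_frequency(gene("chr1"), row, sheet, rules)
        assert res.n_del == 1  # 1.4 -> CN 1, 1.6 -> CN 2

    def test_empty_row_errors(self):
        sheet = self.autosheet(1)
        rules = SexRules(sheet, "chrX")
        with pytest.raises(ValueError):
            deletion_allele_frequency(gene("chr1"), {}, sheet, rules)

    def test_matches_enumeration_oracle(self, rng):
        sheet = SampleSheet(
            [Sample(f"m{i}", "p", "male") for i in range(5)]
            + [Sample(f"f{i}", "p", "female") for i in range(3)]
        )
        rules = SexRules(sheet, "chrX")
        for chrom in ("chr1", "chrX"):
            for _ in range(20):
                row = {s: float(rng.uniform(0, 4)) for s in sheet.sample_ids}
                ploidy = {s: rules.baseline(s, chrom) for s in sheet.sample_ids}
                n_del, n_alleles = allele_count_oracle(row, ploidy)
                res = deletion_allele_frequency(gene(chrom), row, sheet, rules)
                assert (res.n_del, res.n_alleles) == (n_del, n_alleles)


class TestPopulationLoss:
    def sheet(self):
        return SampleSheet(
            [Sample("a1", "pA", "male"), Sample("a2", "pA", "male"),
             Sample("a3", "pA", "male"), Sample("b1", "pB", "male"),
             Sample("b2", "pB", "male")]
        )

    def test_fixed_loss_in_one_population(self):
        sheet = self.sheet()
        m = matrix_from_rows([[0, 0, 0, 2, 2]], sheet.sample_ids)
        rules = SexRules(sheet, "chrX")
        loss = population_loss(m, sheet, rules)
        assert loss.lost_per_population == {"pA": ["g0"], "pB": []}
        assert loss.homozygous_deleted_any == ["g0"]
        assert loss.homozygous_deleted_multiple == ["g0"]

    def test_no_zeros(self):
        sheet = self.sheet()
        m = matrix_from_rows([[2, 2, 2, 2, 2]], sheet.sample_ids)
        loss = population_loss(m, sheet, SexRules(sheet, "chrX"))
        assert loss.lost_per_population == {"pA": [], "pB": []}
        assert loss.homozygous_deleted_any == []

    def test_matches_recount(self, rng):
        sheet = self.sheet()
        rows = rng.uniform(0, 3, size=(30, 5))
        m = matrix_from_rows(rows.tolist(), sheet.sample_ids)
        loss = population_loss(m, sheet, SexRules(sheet, "chrX"))
        rounded = np.floor(rows + 0.5).astype(int)
        assert loss.homozygous_deleted_any == [
            f"g{i}" for i in range(30) if (rounded[i] == 0).sum() >= 1
        ]
        assert loss.lost_per_population["pA"] == [
            f"g{i}" for i in range(30) if (rounded[i, :3] == 0).all()
        ]


class TestAnova:
    def test_identical_groups(self):
        r = anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.F == 0.0
        assert r.p == 1.0

    def test_hand_computed_sums_of_squares(self):
        r = anova_oneway([[1, 2], [2, 3], [3, 4]])
        assert r.ms_between == pytest.approx(2.0)
        assert r.ms_within == pytest.approx(0.5)
        assert r.F == pytest.approx(4.0)
        assert (r.df_between, r.df_within) == (2, 3)

    def test_zero_within_variance(self):
        r = anova_oneway([[0, 0], [1, 1]])
        assert r.F == math.inf
        assert r.p == 0.0

    def test_all_constant_undefined(self):
        r = anova_oneway([[1, 1], [1, 1]])
        assert not r.defined

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            anova_oneway([[1], [2, 3]])

    def test_matches_scipy(self, rng):
        for _ in range(50):
            groups = [
                rng.uniform(0, 5, size=int(rng.integers(2, 10)))
                for _ in range(int(rng.integers(2, 5)))
            ]
            r = anova_oneway(groups)
            ref = sps.f_oneway(*groups)
            assert r.F == pytest.approx(ref.statistic, rel=1e-10)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-8)


class TestBH:
    def test_single_value(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_step_up_recursion(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1, 1, 1]).tolist() == [1, 1, 1]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_q_never_below_p(self, rng):
        p = rng.uniform(0, 1, size=100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()

    def test_matches_hand_recursion_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 30)))
            q = bh_fdr(p)
            assert np.allclose(q, bh_stepup_by_hand(p.tolist()), atol=1e-12)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, q_sm, atol=1e-12)


class TestTukey:
    def test_identical_means(self):
        pairs = tukey_hsd([[1, 2, 3], [1, 2, 3]])
        assert pairs[0].q == 0.0
        assert pairs[0].p_adj == pytest.approx(1.0)

    def test_hand_computed_q(self):
        pairs = tukey_hsd([[1, 2], [2, 3], [3, 4]])
        pair_13 = [p for p in pairs if p.groups == (0, 2)][0]
        assert pair_13.q == pytest.approx(4.0)

    def test_mse_zero_errors(self):
        with pytest.raises(ValueError):
            tukey_hsd([[1, 1], [2, 2]])

    def test_p_monotone_in_mean_diff(self):
        base = [0.0, 1.0, 0.5, 1.5]
        results = []
        for shift in (0.5, 1.0, 2.0, 4.0):
            pairs = tukey_hsd([base, [v + shift for v in base]])
            results.append(pairs[0].p_adj)
        assert results == sorted(results, reverse=True)

    def test_matches_scipy_tukey(self, rng):
        for _ in range(20):
            groups = [
                rng.uniform(0, 5, size=6)
                for _ in range(int(rng.integers(2, 5)))
            ]
            ours = tukey_hsd(groups)
            ref = sps.tukey_hsd(*groups)
            for pair in ours:
                i, j = pair.groups
                assert pair.p_adj == pytest.approx(
                    ref.pvalue[i, j], abs=1e-6
                )


class TestDivergenceScan:
    def sheet(self):
        return SampleSheet(
            [Sample(f"a{i}", "pA", "male") for i in range(4)]
            + [Sample(f"b{i}", "pB", "male") for i in range(4)]
            + [Sample(f"c{i}", "pC", "male") for i in range(4)]
        )

    def test_planted_shift_selected_with_tukey(self, rng):
        sheet = self.sheet()
        rows = rng.normal(2.0, 0.05, size=(20, 12)).tolist()
        shifted = np.concatenate(
            [rng.normal(2.0, 0.05, 8), rng.normal(6.0, 0.05, 4)]
        ).tolist()
        rows.append(shifted)
        m = matrix_from_rows(rows, sheet.sample_ids)
        results = divergence_scan(m, sheet)
        hit = results[-1]
        assert hit.selected
        assert hit.tukey[("pA", "pC")] < 0.05
        assert hit.tukey[("pB", "pC")] < 0.05
        assert hit.tukey[("pA", "pB")] > 0.05

    def test_small_shift_filtered_by_mean_diff(self, rng):
        sheet = self.sheet()
        rows = [
            np.concatenate(
                [rng.normal(2.0, 0.01, 8), rng.normal(2.5, 0.01, 4)]
            ).tolist()
        ]
        m = matrix_from_rows(rows, sheet.sample_ids)
        (r,) = divergence_scan(m, sheet)
        assert r.q < 0.05
        assert r.max_pair_mean_diff < 1.0
        assert not r.selected

    def test_exclusion_of_population(self, rng):
        sheet = SampleSheet(
            [Sample(f"a{i}", "pA", "male") for i in range(4)]
            + [Sample(f"b{i}", "pB", "male") for i in range(4)]
            + [Sample("h1", "pH", "male"), Sample("h2", "pH", "male")]
        )
        rows = rng.normal(2, 0.1, size=(5, 10)).tolist()
        m = matrix_from_rows(rows, sheet.sample_ids)
        results = divergence_scan(m, sheet, exclude_populations=["pH"])
        assert all(r.df == (1, 6) for r in results)

    def test_selected_invariant(self, rng):
        sheet = self.sheet()
        rows = np.clip(rng.normal(2, 0.8, size=(100, 12)), 0, None).tolist()
        m = matrix_from_rows(rows, sheet.sample_ids)
        for r in divergence_scan(m, sheet):
            if r.selected:
                assert r.q < 0.05 and r.max_pair_mean_diff >= 1.0
            assert not r.defined or r.q >= r.p - 1e-15


class TestStandardize:
    def test_two_point_row(self):
        m = matrix_from_rows([[1.0, 3.0]], ["s1", "s2"])
        z, kept = standardize_matrix(m)
        assert np.allclose(z, [[-1.0, 1.0]])
        assert len(kept) == 1

    def test_constant_row_dropped_with_warning(self):
        m = matrix_from_rows([[2.0, 2.0], [1.0, 3.0]], ["s1", "s2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            z, kept = standardize_matrix(m)
        assert z.shape == (1, 2)
        assert kept[0].gene_id == "g1"

    def test_rows_zero_mean_unit_sd(self, rng):
        m = matrix_from_rows(rng.uniform(0, 5, size=(20, 10)).tolist(),
                             [f"s{i}" for i in range(10)])
        z, _ = standardize_matrix(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)


class TestNMDS:
    def test_exact_planar_configuration(self, rng):
        points = rng.uniform(0, 10, size=(10, 2))
        d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        res = nmds_from_distances(d, seed=0)
        assert res.stress < 1e-3

    def test_three_points_embed_exactly(self):
        d = np.array([[0, 1, 2.0], [1, 0, 2.5], [2.0, 2.5, 0]])
        res = nmds_from_distances(d, seed=0)
        assert res.stress < 1e-3

    def test_equidistant_four_points_have_stress(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = nmds_from_distances(d, seed=0)
        assert res.stress > 0.0

    def test_all_zero_distances_error(self):
        with pytest.raises(ValueError):
            nmds_from_distances(np.zeros((4, 4)))

    def test_deterministic_under_seed(self, rng):
        z = rng.normal(size=(30, 8))
        a = nmds(z, seed=42)
        b = nmds(z, seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress
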