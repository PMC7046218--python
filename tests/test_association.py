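import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prfr import (
    QCThresholds,
    association_table,
    compute_maf,
    filter_snps_by_p,
    genomic_inflation,
    hwe_test,
    impute_sporadic_missing,
    qc_filter,
    qq_points,
    trend_test,
    univariate_clinical_tests,
)
from prfr.association import CHI2_1DF_MEDIAN, _genotype_counts

from conftest import make_matrix, make_phenotypes


def logistic_score_test(table):
    """Independent oracle: Rao score test of logistic outcome ~ dosage.

    chi2 = U^2 / V with U = sum x_i (y_i - ybar) and
    V = ybar (1 - ybar) * sum (x_i - xbar)^2.
    """
    x, y = [], []
    for g in (0, 1, 2):
        x += [g] * int(table[0][g]); y += [1] * int(table[0][g])
        x += [g] * int(table[1][g]); y += [0] * int(table[1][g])
    x, y = np.array(x, float), np.array(y, float)
    ybar = y.mean()
    u = np.sum(x * (y - ybar))
    v = ybar * (1 - ybar) * np.sum((x - x.mean()) ** 2)
    return 0.0 if v == 0 else u**2 / v


class TestMAF:
    @pytest.mark.parametrize(
        "dosages,expected",
        [([0, 1, 2, 2], 0.375), ([0, 0, 0], 0.0), ([2, 2], 0.0)],
    )
    def test_hand_counts(self, dosages, expected):
        assert compute_maf(np.array(dosages, float)) == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([np.nan, np.nan]))


class TestHWE:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # expected (25,50,25) at f=0.5; chi2 = 1 + 2 + 1 = 4
        p = hwe_test((30, 40, 30))
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-12)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_monomorphic_p_one(self):
        assert hwe_test((100, 0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = tuple(int(v) for v in rng.integers(0, 60, 3))
            if sum(c) == 0:
                continue
            assert hwe_test(c) == pytest.approx(hwe_test(c[::-1]), abs=1e-12)


class TestQCFilter:
    def test_boundary_conventions(self):
        # 100 samples; SNP A: maf exactly 0.01 (2 alt alleles); SNP B: 5%
        # missing; SNP C: HWE p exactly at threshold is removed via a
        # constructed extreme departure; use a far-from-HWE SNP instead.
        n = 100
        col_maf = np.zeros(n); col_maf[0] = 1; col_maf[1] = 1  # maf = 0.01
        col_miss = np.array([np.nan] * 5 + [0.0] * 90 + [1.0] * 5)
        col_hwe = np.array([0.0] * 50 + [2.0] * 50)  # no hets: hwe p ~ 0
        filler = np.tile([0, 1, 2, 1], 25).astype(float)
        # 20 columns total so a sample with one missing cell sits exactly at
        # the 0.05 sample-missing boundary (inclusive, retained)
        gm = make_matrix(
            np.column_stack([col_maf, col_miss, col_hwe] + [filler] * 17)
        )
        kept, report = qc_filter(gm)
        assert kept.n_individuals == 100  # sample missing 0.05 inclusive
        assert "s1" in kept.snp_ids  # maf >= 0.01 inclusive
        assert "s2" in kept.snp_ids  # SNP missing <= 0.05 inclusive
        assert "s3" not in kept.snp_ids  # hwe p must be strictly > 1e-5
        assert report.removed["hwe"] == 1

    def test_hwe_exact_threshold_removed(self):
        # construct counts with hwe p <= 1e-5? use strict comparison contract:
        # a SNP whose hwe_p equals the threshold must be removed
        counts = (30, 40, 30)
        p = hwe_test(counts)
        thr = QCThresholds(hwe_p_min=p)  # boundary: p > thr is False
        col = np.array([0.0] * 30 + [1.0] * 40 + [2.0] * 30)
        gm = make_matrix(np.column_stack([col, np.tile([0, 1, 2, 1], 25)]))
        kept, _ = qc_filter(gm, thr)
        assert "s1" not in kept.snp_ids

    def test_idempotent(self, null_cohort):
        kept1, _ = qc_filter(null_cohort.genotypes)
        kept2, rep2 = qc_filter(kept1)
        assert kept2 == kept1
        assert sum(rep2.removed.values()) == 0

    def test_all_snps_removed_errors_with_report(self):
        gm = make_matrix([[0, 0], [0, 0], [0, 0]])  # monomorphic, maf 0
        with pytest.raises(ValueError, match="report"):
            qc_filter(gm)


class TestImputation:
    def test_mode_fill_and_tie_rule(self):
        gm = make_matrix(
            np.array([[0, 0], [0, 2], [2, np.nan], [np.nan, np.nan]])
        )
        out = impute_sporadic_missing(gm)
        assert out.dosages[3, 0] == 0  # mode of [0,0,2]
        assert out.dosages[2, 1] == 0  # tie between 0 and 2 -> smaller
        assert out.dosages[3, 1] == 0

    def test_no_missing_returns_same_object(self):
        gm = make_matrix([[0, 1], [2, 1]])
        assert impute_sporadic_missing(gm) is gm

    def test_all_missing_snp_rejected(self):
        gm = make_matrix(np.array([[np.nan, 0.0], [np.nan, 1.0]]))
        with pytest.raises(ValueError):
            impute_sporadic_missing(gm)


class TestTrendTest:
    def test_identical_distributions(self):
        chi2, p = trend_test([[10, 10, 10], [10, 10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_separation(self):
        _, p = trend_test([[0, 0, 20], [20, 0, 0]])
        assert p < 1e-6

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            trend_test([[0, 0, 0], [5, 5, 5]])

    def test_degenerate_variance(self):
        chi2, p = trend_test([[0, 5, 0], [0, 7, 0]])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_logistic_score_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            table = rng.integers(0, 30, size=(2, 3))
            if table[0].sum() == 0 or table[1].sum() == 0:
                continue
            chi2, _ = trend_test(table)
            assert chi2 == pytest.approx(logistic_score_test(table), abs=1e-8)
            checked += 1


class TestAssociationTable:
    def test_vectorized_equals_scalar_reference(self):
        rng = np.random.default_rng(3)
        D = rng.binomial(2, 0.3, size=(60, 25)).astype(float)
        D[rng.random(D.shape) < 0.08] = np.nan
        gm = make_matrix(D)
        y = rng.binomial(1, 0.4, 60)
        ph = make_phenotypes(y)
        tab = association_table(gm, ph)
        for j in range(25):
            col = D[:, j]
            ok = ~np.isnan(col)
            d, yy = col[ok], y[ok]
            table = [
                [int((d[yy == 1] == g).sum()) for g in (0, 1, 2)],
                [int((d[yy == 0] == g).sum()) for g in (0, 1, 2)],
            ]
            chi2, p = trend_test(table)
            assert tab.chi2[j] == pytest.approx(chi2, abs=1e-10)
            assert tab.p[j] == pytest.approx(p, abs=1e-10)
            assert tab.maf[j] == pytest.approx(compute_maf(d), abs=1e-12)
            assert tab.hwe_p[j] == pytest.approx(
                hwe_test(_genotype_counts(d)), abs=1e-10
            )

    def test_single_class_rejected(self):
        gm = make_matrix([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            association_table(gm, make_phenotypes([1, 1]))


class TestGenomicInflation:
    def test_definition_and_scaling(self):
        assert genomic_inflation(np.full(5, CHI2_1DF_MEDIAN)) == pytest.approx(1.0)
        assert genomic_inflation(np.full(5, 2 * CHI2_1DF_MEDIAN)) == pytest.approx(2.0)

    def test_null_sampling_band(self):
        z = np.random.default_rng(1).standard_normal(100_000)
        lam = genomic_inflation(z**2)
        assert 0.98 <= lam <= 1.02

    def test_monotone_under_shift(self):
        chi2 = np.random.default_rng(2).chisquare(1, 1000)
        assert genomic_inflation(chi2 + 0.5) > genomic_inflation(chi2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))


class TestQQPoints:
    def test_single_point_expected_half(self):
        df = qq_points(np.array([0.5]))
        assert df["expected_neglog10"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_band_coverage_under_null(self):
        p = np.random.default_rng(4).uniform(size=10_000)
        df = qq_points(p)
        inside = (
            (df["observed_neglog10"] >= df["band_low_neglog10"])
            & (df["observed_neglog10"] <= df["band_high_neglog10"])
        ).mean()
        assert inside >= 0.95

    def test_monotone_output(self):
        df = qq_points(np.random.default_rng(5).uniform(size=100))
        assert (np.diff(df["observed_neglog10"]) <= 1e-12).all()

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            qq_points(np.array([0.0, 0.5]))


class TestClinicalTests:
    def test_two_by_two_odds_ratio_cross_product(self):
        # cases: 10 exposed, 5 reference; controls: 20 exposed, 40 reference
        y = [1] * 10 + [0] * 20 + [1] * 5 + [0] * 40
        grp = ["exp"] * 30 + ["ref"] * 45
        ph = make_phenotypes(y, grp=grp)
        ph.reference_levels["grp"] = "ref"
        res = univariate_clinical_tests(ph)
        row = res[(res.variable == "grp") & (res.level == "exp")].iloc[0]
        assert row.odds_ratio == pytest.approx(4.0)
        assert row.ci_low < 4.0 < row.ci_high

    def test_identical_distribution_or_one(self):
        y = [1, 0] * 20
        grp = (["a"] * 2 + ["b"] * 2) * 10
        res = univariate_clinical_tests(make_phenotypes(y, grp=grp))
        ors = res[res.variable == "grp"]["odds_ratio"]
        assert np.allclose(ors, 1.0)

    def test_zero_cell_haldane_correction_finite(self):
        y = [1] * 5 + [0] * 5
        grp = ["a"] * 5 + ["b"] * 5  # zero cells in both off-diagonals
        res = univariate_clinical_tests(make_phenotypes(y, grp=grp))
        assert np.isfinite(res[res.level != "a (ref)"]["odds_ratio"]).all()

    def test_continuous_null_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(300):
            y = rng.binomial(1, 0.3, 300)
            x = rng.normal(size=300)
            res = univariate_clinical_tests(make_phenotypes(y, dose=x))
            ps.append(res.p.iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_clinical_tests(make_phenotypes([0, 1, 0, 1], x=[1.0] * 4))


class TestPFilter:
    def test_boundary_is_strict(self):
        assoc = pd.DataFrame({"snp_id": ["a", "b"], "p": [0.001, 0.0009999]})
        assert filter_snps_by_p(assoc, 0.001) == ["b"]

    def test_order_ascending_p_then_id(self):
        assoc = pd.DataFrame(
            {"snp_id": ["c", "a", "b"], "p": [0.0001, 0.0001, 0.00005]}
        )
        assert filter_snps_by_p(assoc, 0.001) == ["b", "a", "c"]

    def test_empty_result_allowed(self):
        assoc = pd.DataFrame({"snp_id": ["a"], "p": [0.5]})
        assert filter_snps_by_p(assoc, 0.001) == []

    def test_null_retention_within_binomial_band(self):
        rng = np.random.default_rng(7)
        assoc = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(20_000)], "p": rng.uniform(size=20_000)}
        )
        k = len(filter_snps_by_p(assoc, 0.001))
        mu, sigma = 20, np.sqrt(20_000 * 0.001 * 0.999)
        assert abs(k - mu) <= 3 * sigma
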