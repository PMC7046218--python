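import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prfr import (
    AUCDistribution,
    ancestry_pc_baseline,
    auc,
    auc_pvalue,
    bootstrap_auc_ci,
    compare_auc_distributions,
    qc_filter,
    repeated_cv_auc,
    stratified_split,
)
from prfr.modeling import ForestSpec

from conftest import make_matrix, make_phenotypes


class TestStratifiedSplit:
    def test_reproduces_cohort_shape_137_68(self):
        """205 samples with 52 cases split 2:1 -> 137/68 with 35/17 cases."""
        y = np.array([1] * 52 + [0] * 153)
        ph = make_phenotypes(y)
        split = stratified_split(ph, fraction_train=2 / 3, seed=0)
        assert len(split.training) == 137
        assert len(split.validation) == 68
        assert ph.outcomes_for(split.training).sum() == 35
        assert ph.outcomes_for(split.validation).sum() == 17

    def test_full_fraction_rejected(self):
        ph = make_phenotypes([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            stratified_split(ph, fraction_train=0.99)

    def test_seed_determinism(self):
        ph = make_phenotypes(np.array([1] * 10 + [0] * 30))
        a = stratified_split(ph, seed=5)
        b = stratified_split(ph, seed=5)
        assert a.training == b.training and a.validation == b.validation

    def test_priority_balancing_improves_on_single_draw(self):
        rng = np.random.default_rng(6)
        y = np.array([1] * 30 + [0] * 90)
        age = rng.normal(35, 5, 120)
        ph = make_phenotypes(y, age=age)
        from prfr.evaluation import _imbalance

        balanced = stratified_split(ph, priority=["age"], seed=7, n_candidates=200)
        single = stratified_split(ph, seed=7)
        imb_single = _imbalance(ph, single.training, single.validation, "age")
        assert balanced.balance["age"] <= imb_single + 1e-12

    def test_unknown_priority_variable_rejected(self):
        ph = make_phenotypes([1, 0, 1, 0])
        with pytest.raises(KeyError):
            stratified_split(ph, priority=["nope"])


class TestAUC:
    def test_perfect_and_tied_scores(self):
        labels = np.array([0, 0, 1, 1])
        assert auc(labels.astype(float), labels) == 1.0
        assert auc(np.zeros(4), labels) == 0.5

    def test_pair_counting_fixture(self):
        # pairs: (0.35>0.1), (0.8>0.1), (0.8>0.4) concordant; (0.35<0.4) not
        assert auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])) == 0.75

    def test_score_negation_complement(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=50)
        l = rng.binomial(1, 0.4, 50)
        if l.min() == l.max():
            l[0] = 1 - l[0]
        assert auc(s, l) + auc(-s, l) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestAUCPValue:
    def test_perfect_separation_tiny_p(self):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        scores = labels + 0.0
        assert auc_pvalue(scores, labels) < 1e-10

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            scores = rng.normal(size=8)
            labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
            rng.shuffle(labels)
            u_obs = auc(scores, labels) * 16
            count = total = 0
            for comb in itertools.combinations(range(8), 4):
                lab = np.zeros(8, int)
                lab[list(comb)] = 1
                total += 1
                if auc(scores, lab) * 16 >= u_obs - 1e-12:
                    count += 1
            assert auc_pvalue(scores, labels) == pytest.approx(
                count / total, abs=0.01
            )

    def test_null_p_uniform(self):
        rng = np.random.default_rng(10)
        ps = [
            auc_pvalue(rng.normal(size=60), np.r_[np.ones(20, int), np.zeros(40, int)])
            for _ in range(2000)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBootstrapCI:
    def test_perfect_separation_concentrates(self):
        labels = np.r_[np.ones(100, int), np.zeros(200, int)]
        scores = labels + 0.0
        lo, hi = bootstrap_auc_ci(scores, labels, seed=11)
        assert lo >= 0.95 and hi <= 1.0

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(12)
        ok = 0
        for seed in range(20):
            labels = np.r_[np.ones(30, int), np.zeros(60, int)]
            scores = rng.normal(size=90) + 0.5 * labels
            point = auc(scores, labels)
            lo, hi = bootstrap_auc_ci(scores, labels, n_boot=500, seed=seed)
            ok += lo <= point <= hi
        assert ok >= 19

    def test_seed_determinism(self):
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        scores = np.random.default_rng(13).normal(size=50)
        assert bootstrap_auc_ci(scores, labels, seed=14) == bootstrap_auc_ci(
            scores, labels, seed=14
        )


class TestCompareDistributions:
    def test_identical_vectors_p_one(self):
        d = AUCDistribution("a", np.full(10, 0.6))
        assert compare_auc_distributions(d, d) == 1.0

    def test_power_on_separated_normals(self):
        rng = np.random.default_rng(15)
        a = AUCDistribution("a", rng.normal(0.60, 0.01, 500))
        b = AUCDistribution("b", rng.normal(0.55, 0.01, 500))
        assert compare_auc_distributions(a, b) < 1e-10

    def test_matches_welch_formula_oracle(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0.6, 0.02, 40)
        y = rng.normal(0.58, 0.03, 60)
        p = compare_auc_distributions(
            AUCDistribution("a", x), AUCDistribution("b", y)
        )
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        oracle = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_distributions(
                AUCDistribution("a", np.array([0.5])),
                AUCDistribution("b", np.array([0.5, 0.6])),
            )


@pytest.fixture(scope="module")
def split_signal(small_signal_cohort):
    cohort = small_signal_cohort
    gm, _ = qc_filter(cohort.genotypes)
    split = stratified_split(cohort.phenotypes, seed=1)
    return (
        gm.subset_samples(split.training),
        cohort.phenotypes.outcomes_for(split.training),
        gm.subset_samples(split.validation),
        cohort.phenotypes.outcomes_for(split.validation),
    )


class TestRepeatedCV:
    def test_model_count_and_determinism(self, split_signal):
        gt, yt, gv, yv = split_signal
        kwargs = dict(
            n_repeats=3,
            n_folds=5,
            seed=2,
            snp_p_cutoff=0.01,
            forest_spec=ForestSpec(n_trees=25),
        )
        a = repeated_cv_auc(gt, yt, gv, yv, "prfr", **kwargs)
        b = repeated_cv_auc(gt, yt, gv, yv, "prfr", **kwargs)
        assert a.aucs.size == 15
        assert np.array_equal(a.aucs, b.aucs)
        assert ((a.aucs >= 0) & (a.aucs <= 1)).all()

    def test_signal_beats_chance(self, split_signal):
        gt, yt, gv, yv = split_signal
        d = repeated_cv_auc(
            gt, yt, gv, yv, "prfr",
            n_repeats=4, n_folds=5, seed=3, snp_p_cutoff=0.01,
            forest_spec=ForestSpec(n_trees=100),
        )
        assert d.mean > 0.5 + 3 * d.aucs.std(ddof=1) / np.sqrt(d.aucs.size)

    def test_all_families_run(self, split_signal):
        gt, yt, gv, yv = split_signal
        for family in ("rf_classifier", "lasso", "preconditioned_lasso"):
            d = repeated_cv_auc(
                gt, yt, gv, yv, family,
                n_repeats=1, n_folds=5, seed=4, snp_p_cutoff=0.01,
                forest_spec=ForestSpec(n_trees=25),
            )
            assert d.aucs.size == 5

    def test_unknown_family_rejected(self, split_signal):
        gt, yt, gv, yv = split_signal
        with pytest.raises(ValueError):
            repeated_cv_auc(gt, yt, gv, yv, "boosting", n_repeats=1)


class TestAncestryBaseline:
    def test_three_coefficients_and_determinism(self, split_signal):
        gt, yt, gv, yv = split_signal
        model_a, auc_a = ancestry_pc_baseline(gt, yt, gv, yv)
        model_b, auc_b = ancestry_pc_baseline(gt, yt, gv, yv)
        assert len(model_a["coefficients"]) == 3
        assert auc_a == auc_b

    def test_structure_free_cohort_near_chance(self, null_cohort):
        gm, _ = qc_filter(null_cohort.genotypes)
        split = stratified_split(null_cohort.phenotypes, seed=5)
        _, a = ancestry_pc_baseline(
            gm.subset_samples(split.training),
            null_cohort.phenotypes.outcomes_for(split.training),
            gm.subset_samples(split.validation),
            null_cohort.phenotypes.outcomes_for(split.validation),
        )
        assert 0.3 <= a <= 0.7

    def test_too_few_snps_rejected(self, null_cohort):
        gm = null_cohort.genotypes.subset_snps(null_cohort.genotypes.snp_ids[:2])
        y = null_cohort.phenotypes.outcome
        with pytest.raises(ValueError):
            ancestry_pc_baseline(gm, y, gm, y)
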