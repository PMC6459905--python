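import numpy as np
import pandas as pd
import pytest

from exoburden import isub
from .conftest import make_study


def annotated_study(g, pheno, classes=None, scores=None, labels=None,
                    ref_maf=None, countries=None):
    m = np.asarray(g).shape[1]
    study = make_study(
        g, pheno,
        gene=["G1"] * m,
        functional_class=classes or ["missense"] * m,
        score=scores if scores is not None else [0.5] * m,
        label=labels or ["deleterious"] * m,
        ref_maf=ref_maf if ref_maf is not None else [0.001] * m,
    )
    if countries is not None:
        study.samples["country"] = countries
    return study


class TestSetUnique:
    def test_case_only_carrier_is_case_unique(self):
        g = np.array([[1], [0], [0], [0]])
        study = annotated_study(g, [1, 1, 0, 0])
        cu, ku = isub.set_unique_variants(study)
        assert list(cu) == [0] and list(ku) == []

    def test_shared_variant_in_neither_set(self):
        g = np.array([[1], [0], [1], [0]])
        study = annotated_study(g, [1, 1, 0, 0])
        cu, ku = isub.set_unique_variants(study)
        assert list(cu) == [] and list(ku) == []

    def test_sets_are_disjoint(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.05, size=(60, 200)).astype(np.int8)
        study = annotated_study(g, rng.binomial(1, 0.5, 60),
                                classes=["missense"] * 200,
                                scores=[0.5] * 200, labels=["neutral"] * 200,
                                ref_maf=[0.001] * 200)
        cu, ku = isub.set_unique_variants(study)
        assert not set(cu) & set(ku)

    def test_imbalance_produces_more_case_unique(self):
        """The larger group accumulates more group-unique variants and
        higher per-individual counts under the null."""
        rng = np.random.default_rng(1)
        n_ca, n_co = 425, 311
        m = 4000
        g = (rng.random((n_ca + n_co, m)) < 0.0015).astype(np.int8)
        pheno = np.r_[np.ones(n_ca), np.zeros(n_co)].astype(np.int8)
        study = annotated_study(g, pheno, classes=["missense"] * m,
                                scores=[0.5] * m, labels=["neutral"] * m,
                                ref_maf=[1e-4] * m)
        cu, ku = isub.set_unique_variants(study)
        assert len(cu) > len(ku)
        res = isub.run_isub(study)["NS"]
        assert res.counts[study.is_case].mean() > res.counts[study.is_control].mean()


class TestReferenceMafFilter:
    def test_threshold_and_missing_convention(self):
        variants = pd.DataFrame(
            {"variant_id": ["a", "b", "c"], "ref_maf": [0.004, 0.02, np.nan]}
        )
        kept = isub.filter_reference_maf(np.arange(3), variants, 0.005)
        assert list(kept) == [0, 2]  # 0.004 kept, 0.02 dropped, missing kept


class TestClassSets:
    def test_deleterious_missense_in_both_classes(self):
        g = np.array([[1], [0], [0], [0]])
        study = annotated_study(g, [1, 1, 0, 0], classes=["missense"],
                                scores=[0.7], labels=["deleterious"])
        ns, dl = isub.build_class_sets(study, np.array([0]), np.array([], int))
        assert list(ns.variant_idx) == [0] and ns.scores[0] == 0.7
        assert list(dl.variant_idx) == [0]

    def test_synonymous_in_neither_class(self):
        g = np.array([[1], [0], [0], [0]])
        study = annotated_study(g, [1, 1, 0, 0], classes=["synonymous"])
        ns, dl = isub.build_class_sets(study, np.array([0]), np.array([], int))
        assert ns.variant_idx.size == 0 and dl.variant_idx.size == 0

    def test_unscored_lof_gets_group_max_score_and_deleterious_label(self):
        g = np.array([[1, 1, 0], [0, 0, 0], [0, 0, 1], [0, 0, 0]])
        study = annotated_study(
            g, [1, 1, 0, 0],
            classes=["missense", "LoF", "missense"],
            scores=[0.93, np.nan, 0.4],
            labels=["deleterious", None, "neutral"],
        )
        ns, dl = isub.build_class_sets(study, np.array([0, 1]), np.array([2]))
        lof_pos = list(ns.variant_idx).index(1)
        assert ns.scores[lof_pos] == pytest.approx(0.93)  # case-unique max
        assert 1 in dl.variant_idx

    def test_del_subset_of_ns(self):
        rng = np.random.default_rng(2)
        m = 50
        g = rng.binomial(2, 0.03, size=(40, m)).astype(np.int8)
        study = annotated_study(
            g, rng.binomial(1, 0.5, 40),
            classes=list(rng.choice(["missense", "LoF", "synonymous"], m)),
            scores=list(rng.uniform(0, 1, m)),
            labels=list(rng.choice(["deleterious", "neutral"], m)),
        )
        cu, ku = isub.set_unique_variants(study)
        ns, dl = isub.build_class_sets(study, cu, ku)
        assert set(dl.variant_idx) <= set(ns.variant_idx)


class TestScoring:
    def test_homozygote_counted_once(self):
        """Dominant model: genotype 2 contributes its score once."""
        g = np.array([[2], [0], [0], [0]])
        study = annotated_study(g, [1, 1, 0, 0], scores=[0.8])
        cs = isub.ClassSet(np.array([0]), np.array([0.8]), np.array([True]))
        scores, counts = isub.isub_scores(study, cs)
        assert scores[0] == pytest.approx(0.8)
        assert counts[0] == 1

    def test_scores_sum_over_carried_variants(self):
        g = np.array([[1, 1], [0, 0], [0, 0], [0, 0]])
        study = annotated_study(g, [1, 1, 0, 0], scores=[0.5, 0.25])
        cs = isub.ClassSet(np.array([0, 1]), np.array([0.5, 0.25]),
                           np.array([True, True]))
        scores, _ = isub.isub_scores(study, cs)
        assert scores[0] == pytest.approx(0.75)
        assert scores[1] == 0.0


class TestComparison:
    def test_zero_variance_scores_undefined(self):
        g = np.zeros((10, 2), dtype=np.int8)
        study = annotated_study(g, [1] * 5 + [0] * 5)
        assert np.isnan(isub.compare_isub(np.zeros(10), study))

    def test_count_diagnostics_disentangle_mechanisms(self):
        """Imbalanced null: count comparison significant while
        per-variant scores (one distribution) are not."""
        rng = np.random.default_rng(3)
        n_ca, n_co = 600, 430
        m = 6000
        g = (rng.random((n_ca + n_co, m)) < 0.001).astype(np.int8)
        pheno = np.r_[np.ones(n_ca), np.zeros(n_co)].astype(np.int8)
        study = annotated_study(g, pheno, classes=["missense"] * m,
                                scores=list(rng.uniform(0, 1, m)),
                                labels=["neutral"] * m, ref_maf=[1e-4] * m)
        res = isub.run_isub(study)["NS"]
        assert res.count_comparison_p < 0.01
        assert res.per_variant_score_comparison_p > 0.01

    def test_shifted_counts_detected(self):
        rng = np.random.default_rng(4)
        counts_a = rng.poisson(3, 500)
        counts_b = rng.poisson(3, 500) + 2
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(counts_a, counts_b, alternative="two-sided").pvalue
        assert p < 0.01


class TestBalancedSubset:
    def _multi_country_study(self, seed=5):
        rng = np.random.default_rng(seed)
        n = 300
        m = 800
        g = (rng.random((n, m)) < 0.003).astype(np.int8)
        pheno = rng.binomial(1, 0.5, n).astype(np.int8)
        countries = rng.choice(["NL", "BE", "IE", "DE"], n)
        return annotated_study(g, pheno, classes=["missense"] * m,
                               scores=[0.5] * m, labels=["neutral"] * m,
                               ref_maf=[1e-4] * m, countries=countries)

    def test_subset_uniqueness_is_subset_relative(self):
        """A variant's membership in the subset sets follows the
        uniqueness rule evaluated inside the subset."""
        study = self._multi_country_study()
        sub_mask = study.samples["country"].isin(["NL", "BE"]).to_numpy()
        sub = study.take_samples(sub_mask)
        cu_sub, ku_sub = isub.set_unique_variants(sub)
        res = isub.run_isub(study, cohorts=("NL", "BE"))["NS"]
        mac_ca, _ = sub.allele_counts(sub.is_case)
        mac_co, _ = sub.allele_counts(sub.is_control)
        expect_cu = set(np.flatnonzero((mac_ca > 0) & (mac_co == 0)))
        assert set(cu_sub) == expect_cu

    def test_full_study_subset_is_identity(self):
        study = self._multi_country_study(seed=6)
        all_c = tuple(study.samples["country"].unique())
        full = isub.run_isub(study)["NS"]
        sub = isub.run_isub(study, cohorts=all_c)["NS"]
        assert np.allclose(full.scores, sub.scores)
        assert full.comparison_p == pytest.approx(sub.comparison_p, rel=1e-9, nan_ok=True)

    def test_absent_cohort_rejected(self):
        study = self._multi_country_study(seed=7)
        with pytest.raises(ValueError, match="absent"):
            isub.run_isub(study, cohorts=("NL", "XX"))


class TestSensitivity:
    def test_no_outliers_leaves_p_unchanged(self):
        rng = np.random.default_rng(8)
        n = 200
        m = 600
        g = (rng.random((n, m)) < 0.004).astype(np.int8)
        study = annotated_study(g, rng.binomial(1, 0.5, n),
                                classes=["missense"] * m, scores=[0.5] * m,
                                labels=["neutral"] * m, ref_maf=[1e-4] * m)
        res = isub.run_isub(study)["NS"]
        if np.isfinite(res.comparison_p):
            s = res.scores
            if np.abs(s - s.mean()).max() <= 5 * s.std():
                assert res.outlier_removed_p == pytest.approx(res.comparison_p)

    def test_injected_extreme_score_removed_by_outlier_rule(self):
        rng = np.random.default_rng(9)
        n = 400
        scores = rng.gamma(2, 0.5, n)
        scores[0] = scores.mean() + 25 * scores.std()
        study = annotated_study(np.zeros((n, 1), dtype=np.int8),
                                rng.binomial(1, 0.5, n))
        res = isub.ISUBResult(
            variant_class="NS", scores=scores, counts=np.zeros(n, int),
            group_summary=pd.DataFrame(),
            comparison_p=isub.compare_isub(scores, study),
        )
        res = isub.sensitivity_analyses(res, study)
        assert np.isfinite(res.outlier_removed_p)
        assert np.isfinite(res.log_transformed_p)
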