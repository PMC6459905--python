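import math
from fractions import Fraction

import numpy as np
import pytest

from exoburden import qc
from .conftest import make_study


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-arithmetic enumeration of the conditional HWE distribution."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    nb = min(nb, 2 * n - nb)
    if nb == 0:
        return 1.0
    probs = {}
    for h in range(nb % 2, nb + 1, 2):
        bb = (nb - h) // 2
        aa = n - bb - h
        probs[h] = (
            Fraction(math.factorial(n), math.factorial(aa) * math.factorial(h) * math.factorial(bb))
            * Fraction(2) ** h
        )
    total = sum(probs.values())
    obs = probs[min(n_ab, nb)]
    p = sum(v for v in probs.values() if v <= obs) / total
    return float(p)


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_p(100, 0, 0) == 1.0

    def test_exact_proportions_give_large_p(self):
        # 2pq het fraction exactly: p=0.5, n=400 -> 100/200/100
        assert qc.hwe_exact_p(100, 200, 100) > 0.5

    def test_matches_enumeration_for_all_small_tables(self):
        """Exhaustive agreement with the exact-arithmetic oracle for
        every genotype table with at most 12 minor-allele copies."""
        checked = 0
        for n in (5, 20, 50):
            for minor in range(0, 13):
                for het in range(minor % 2, minor + 1, 2):
                    bb = (minor - het) // 2
                    aa = n - bb - het
                    if aa < 0:
                        continue
                    got = qc.hwe_exact_p(aa, het, bb)
                    want = hwe_enumeration_oracle(aa, het, bb)
                    assert got == pytest.approx(want, rel=1e-9), (aa, het, bb)
                    checked += 1
        assert checked > 100

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_p(0, 0, 0)


class TestPiHat:
    def test_identical_samples_near_one(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.1, 0.5, 2000)
        g = rng.binomial(2, freqs).astype(np.int8)
        assert qc.ibd_pihat(g, g, freqs) > 0.95

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.1, 0.5, 5000)
        a = rng.binomial(2, freqs).astype(np.int8)
        b = rng.binomial(2, freqs).astype(np.int8)
        assert abs(qc.ibd_pihat(a, b, freqs)) < 0.05

    def test_full_siblings_near_half(self):
        rng = np.random.default_rng(2)
        m = 5000
        freqs = rng.uniform(0.1, 0.5, m)
        pat = rng.binomial(1, freqs, (2, m)) + rng.binomial(1, freqs, (2, m))

        # transmit one allele per parent; hets pass either with prob 1/2
        def transmit(par):
            return np.where(
                par == 1, rng.integers(0, 2, m), (par // 2)
            ).astype(np.int8)
        c1 = transmit(pat[0]) + transmit(pat[1])
        c2 = transmit(pat[0]) + transmit(pat[1])
        assert qc.ibd_pihat(c1.astype(np.int8), c2.astype(np.int8), freqs) == pytest.approx(
            0.5, abs=0.1
        )

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(3)
        m = 5000
        freqs = rng.uniform(0.1, 0.5, m)
        father = rng.binomial(2, freqs).astype(np.int8)
        mother = rng.binomial(2, freqs).astype(np.int8)
        def transmit(par):
            return np.where(par == 1, rng.integers(0, 2, m), par // 2)
        child = (transmit(father) + transmit(mother)).astype(np.int8)
        assert qc.ibd_pihat(father, child, freqs) == pytest.approx(0.5, abs=0.05)

    def test_too_few_overlapping_snps_flagged(self):
        a = np.full(50, -1, dtype=np.int8)
        b = np.zeros(50, dtype=np.int8)
        assert np.isnan(qc.ibd_pihat(a, b, np.full(50, 0.3), min_overlap=100))


class TestLDPrune:
    def _random_study(self, n=200, m=60, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(np.int8)
        return make_study(g, rng.binomial(1, 0.5, n))

    def test_ambiguous_strand_snp_excluded(self):
        study = self._random_study(m=10)
        study.variants.loc[3, ["a1", "a2"]] = ["A", "T"]
        kept = qc.ld_prune(study, r2_max=1.1)
        assert 3 not in kept

    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(4)
        col = rng.binomial(2, 0.4, 300).astype(np.int8)
        g = np.column_stack([col, col, rng.binomial(2, 0.3, 300)]).astype(np.int8)
        study = make_study(g, rng.binomial(1, 0.5, 300))
        kept = qc.ld_prune(study, r2_max=0.05)
        assert sum(j in kept for j in (0, 1)) == 1

    def test_retained_pairs_below_r2_threshold(self):
        """Post-condition verified by exhaustive pair check."""
        study = self._random_study(n=300, m=80, seed=5)
        kept = qc.ld_prune(study, r2_max=0.05)
        g = study.genotypes[:, kept].astype(float)
        g -= g.mean(axis=0)
        g /= g.std(axis=0)
        r2 = (g.T @ g / len(g)) ** 2
        np.fill_diagonal(r2, 0.0)
        assert r2.max() < 0.05

    def test_high_ld_region_exclusion(self):
        import pandas as pd

        study = self._random_study(m=20)
        regions = pd.DataFrame({"chrom": [1], "start": [1000], "end": [5000]})
        kept = qc.ld_prune(study, high_ld_regions=regions, r2_max=1.1)
        assert all(study.variants["pos"].iloc[j] > 5000 for j in kept)


class TestSampleQC:
    def test_high_missingness_sample_removed(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, rng.uniform(0.2, 0.5, 300), size=(40, 300)).astype(np.int8)
        g[0, : int(300 * 0.06)] = -1  # 6% missing
        study = make_study(g, rng.binomial(1, 0.5, 40))
        out, report = qc.sample_qc(study, pruned_variants=np.arange(300))
        step = report.steps[0]
        assert step.name == "sample_missingness"
        assert "s0" in step.ids_removed
        assert "s0" not in set(out.samples["sample_id"])

    def test_duplicate_sample_pair_loses_one(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, rng.uniform(0.2, 0.5, 2000), size=(30, 2000)).astype(np.int8)
        g[1] = g[0]  # duplicate
        study = make_study(g, rng.binomial(1, 0.5, 30))
        out, report = qc.sample_qc(study, pruned_variants=np.arange(2000))
        rel = [s for s in report.steps if s.name == "relatedness"][0]
        assert rel.n_samples_removed == 1
        assert set(rel.ids_removed) <= {"s0", "s1"}

    def test_sex_discordance_step(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        g = rng.binomial(2, rng.uniform(0.2, 0.5, 300), size=(20, 300)).astype(np.int8)
        study = make_study(g, rng.binomial(1, 0.5, 20))
        genotypic = pd.Series([1] * 20)
        study.samples.loc[4, "sex"] = 2  # reported female, genotypic male
        out, report = qc.sample_qc(
            study, pruned_variants=np.arange(300), genotypic_sex=genotypic
        )
        disc = [s for s in report.steps if s.name == "sex_discordance"][0]
        assert disc.ids_removed == ["s4"]

    def test_empty_pruned_subset_raises(self):
        study = make_study(np.zeros((5, 4)), [1, 0, 1, 0, 1])
        with pytest.raises(ValueError, match="relax"):
            qc.sample_qc(study, pruned_variants=np.array([], dtype=int))


class TestVariantQC:
    def test_extreme_differential_missingness_removed(self):
        rng = np.random.default_rng(9)
        n = 400
        pheno = np.r_[np.ones(200), np.zeros(200)].astype(np.int8)
        g = rng.binomial(2, 0.3, size=(n, 5)).astype(np.int8)
        cases = pheno == 1
        g[np.flatnonzero(cases)[:60], 0] = -1  # 30% missing in cases only
        study = make_study(g, pheno)
        # permissive call-rate threshold isolates the differential test
        out, report = qc.variant_qc(study, call_rate_min=0.5)
        dm = [s for s in report.steps if s.name == "differential_missingness"][0]
        assert "v0" in dm.ids_removed

    def test_zero_missingness_variant_retained(self):
        rng = np.random.default_rng(10)
        g = rng.binomial(2, 0.3, size=(200, 3)).astype(np.int8)
        study = make_study(g, rng.binomial(1, 0.5, 200))
        out, _ = qc.variant_qc(study)
        assert out.n_variants == 3

    def test_constructed_fixture_three_violations(self):
        """10 variants, exactly 3 violating one filter each -> 7 survive."""
        rng = np.random.default_rng(11)
        n = 300
        pheno = np.r_[np.ones(150), np.zeros(150)].astype(np.int8)
        g = rng.binomial(2, 0.3, size=(n, 10)).astype(np.int8)
        chrom = [1] * 10
        chrom[2] = 23  # non-autosomal
        g[: int(n * 0.05), 5] = -1  # call rate 95% < 98%
        # HWE violation in controls: all het
        g[150:, 8] = 1
        g[:150, 8] = rng.binomial(2, 0.5, 150)
        study = make_study(g, pheno, chrom=chrom)
        out, report = qc.variant_qc(study)
        assert out.n_variants == 7
        removed = {s.name: s.n_variants_removed for s in report.steps}
        assert removed["non_autosomal"] == 1
        assert removed["call_rate"] == 1
        assert removed["hwe_controls"] == 1

    def test_every_removal_attributable(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, rng.uniform(0.05, 0.5, 30), size=(200, 30)).astype(np.int8)
        study = make_study(g, rng.binomial(1, 0.5, 200))
        _, report = qc.variant_qc(study)
        for step in report.steps:
            assert len(step.ids_removed) == (
                step.n_samples_removed + step.n_variants_removed
            )

    def test_qc_idempotent(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, rng.uniform(0.05, 0.5, 40), size=(300, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.03] = -1
        study = make_study(g, rng.binomial(1, 0.5, 300))
        once, _ = qc.variant_qc(study)
        twice, report2 = qc.variant_qc(once)
        assert twice.n_variants == once.n_variants
        assert all(s.n_variants_removed == 0 for s in report2.steps)


class TestNonmonomorphic:
    def test_monomorphic_excluded_singleton_retained(self):
        g = np.zeros((6, 2), dtype=np.int8)
        g[0, 1] = 1  # one heterozygote in a control
        study = make_study(g, [0, 0, 0, 1, 1, 1])
        kept = qc.nonmonomorphic_filter(study)
        assert list(kept) == [1]

    def test_per_group_reading_stricter(self):
        g = np.zeros((6, 1), dtype=np.int8)
        g[0, 0] = 1  # carried by a control only
        study = make_study(g, [0, 0, 0, 1, 1, 1])
        assert list(qc.nonmonomorphic_filter(study)) == [0]
        assert list(qc.nonmonomorphic_filter(study, per_group=True)) == []

    def test_retained_fraction_matches_generator_truth(self, small_null_study):
        kept = qc.nonmonomorphic_filter(small_null_study)
        mac, _ = small_null_study.allele_counts()
        assert len(kept) == int((mac >= 1).sum())
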