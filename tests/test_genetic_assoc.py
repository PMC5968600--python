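import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import comb

from twinherit.errors import (
    ConfigurationError,
    DataError,
    DegenerateDataError,
    SeparationError,
    UndefinedOddsRatioError,
)
from twinherit.genetic_assoc import (
    DEFAULT_SNPS,
    AssociationResult,
    ContingencyTable2x2,
    GenotypeCounts,
    SnpDefinition,
    _hwe_exact_p,
    combination_analysis,
    contingency_or,
    degree_stratified_table,
    encode_model,
    genotype_counts,
    hwe_test,
    logistic_fit,
    minor_allele_frequency,
    model_association,
    normalize_genotype,
)

SNP1 = DEFAULT_SNPS["rs634990"]   # alleles C/T, risk C
SNP2 = DEFAULT_SNPS["rs8027411"]  # alleles G/T, risk G


class TestGenotypeCounts:
    def test_basic_tally(self):
        counts = genotype_counts(["CC", "CT", "CT"], SNP1)
        assert (counts.n_aa, counts.n_ab, counts.n_bb) == (1, 2, 0)

    def test_all_missing(self):
        counts = genotype_counts(["", None, ""], SNP1)
        assert counts.n == 0 and counts.n_missing == 3

    def test_unordered_allele_pair(self):
        assert normalize_genotype("TC", SNP1) == "CT"
        counts = genotype_counts(["TC", "CT"], SNP1)
        assert counts.n_ab == 2

    def test_foreign_allele_rejected(self):
        with pytest.raises(DataError):
            genotype_counts(["CG"], SNP1)


class TestMAF:
    def test_table_counts_rs634990(self):
        counts = GenotypeCounts("rs634990", ("C", "T"), 56, 147, 69)
        allele, freq = minor_allele_frequency(counts)
        assert allele == "C"
        assert freq == pytest.approx(259 / 544)
        assert round(freq * 100, 1) == 47.6

    def test_table_counts_rs8027411(self):
        counts = GenotypeCounts("rs8027411", ("G", "T"), 60, 157, 68)
        allele, freq = minor_allele_frequency(counts)
        assert allele == "G"
        assert freq == pytest.approx(277 / 570)

    def test_monomorphic(self):
        counts = GenotypeCounts("x", ("C", "T"), 100, 0, 0)
        allele, freq = minor_allele_frequency(counts)
        assert allele == "T" and freq == 0.0

    @given(n_aa=st.integers(0, 200), n_ab=st.integers(0, 200),
           n_bb=st.integers(0, 200))
    def test_maf_at_most_half(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        counts = GenotypeCounts("x", ("A", "B"), n_aa, n_ab, n_bb)
        _, freq = minor_allele_frequency(counts)
        assert 0.0 <= freq <= 0.5


class TestHWE:
    def test_exact_equilibrium(self):
        chi2, p = hwe_test(GenotypeCounts("x", ("A", "B"), 25, 50, 25))
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_complete_disequilibrium_statistic_equals_n(self):
        chi2, _ = hwe_test(GenotypeCounts("x", ("A", "B"), 50, 0, 50))
        assert chi2 == pytest.approx(100.0)

    def test_study_counts_consistent_with_equilibrium(self):
        chi2, p = hwe_test(GenotypeCounts("rs634990", ("C", "T"), 56, 147, 69))
        assert chi2 == pytest.approx(1.89, abs=0.01)
        assert p == pytest.approx(0.17, abs=0.01)

    def test_monomorphic_undefined(self):
        with pytest.raises(DegenerateDataError):
            hwe_test(GenotypeCounts("x", ("A", "B"), 30, 0, 0))

    def test_exact_matches_enumeration(self):
        """Exact conditional p agrees with direct enumeration (small N)."""
        def enumerate_p(n_aa, n_ab, n_bb):
            n = n_aa + n_ab + n_bb
            n_a = 2 * n_aa + n_ab
            n_rare = min(n_a, 2 * n - n_a)
            probs = {}
            for h in range(n_rare % 2, n_rare + 1, 2):
                aa = (n_rare - h) // 2
                bb = n - h - aa
                # P(h | allele counts) ∝ n! / (aa! h! bb!) * 2^h
                probs[h] = (comb(n, aa, exact=True)
                            * comb(n - aa, h, exact=True) * 2 ** h)
            total = sum(probs.values())
            p_obs = probs[n_ab]
            return sum(v for v in probs.values() if v <= p_obs) / total

        for counts in [(5, 10, 5), (2, 3, 9), (7, 1, 4), (0, 4, 6),
                       (3, 0, 3)]:
            expected = enumerate_p(*counts)
            assert _hwe_exact_p(*counts) == pytest.approx(expected, rel=1e-9)

    def test_chi2_and_exact_broadly_agree(self):
        counts = GenotypeCounts("x", ("A", "B"), 56, 147, 69)
        _, p_chi = hwe_test(counts)
        _, p_exact = hwe_test(counts, method="exact")
        assert abs(p_chi - p_exact) < 0.05


class TestEncodeModel:
    @pytest.mark.parametrize("genotype,model,expected", [
        ("CT", "dominant", 1),      # (CC + CT) versus TT
        ("TT", "dominant", 0),
        ("CC", "recessive", 0),     # (CT + TT) versus CC
        ("CT", "recessive", 1),
        ("CT", "overdominant", 0),  # (CC + TT) versus CT
        ("CC", "overdominant", 1),
        ("TT", "overdominant", 1),
        ("CC", "additive", 2),
        ("CT", "additive", 1),
        ("TT", "additive", 0),
        ("CT", "codominant", (1, 0)),
        ("CC", "codominant", (0, 1)),
        ("TT", "codominant", (0, 0)),
    ])
    def test_contrasts(self, genotype, model, expected):
        assert encode_model(genotype, model, SNP1) == expected

    def test_unknown_model(self):
        with pytest.raises(ConfigurationError):
            encode_model("CC", "multiplicative", SNP1)


class TestLogisticFit:
    def test_balanced_table_gives_null_effect(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([10.0, 10.0, 10.0, 10.0])
        fit = logistic_fit(x[:, None], y, weights=w, term_names=["e"])
        assert fit.result("e").or_point == pytest.approx(1.0, abs=1e-8)

    def test_single_binary_covariate_equals_cross_product_ratio(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([24.0, 8.0, 151.0, 88.0])
        fit = logistic_fit(x[:, None], y, weights=w, term_names=["e"])
        assert fit.result("e").or_point == pytest.approx(
            (24 * 88) / (151 * 8), rel=1e-9)

    def test_intercept_only_recovers_success_fraction(self):
        y = np.array([1.0] * 7 + [0.0] * 13)
        fit = logistic_fit(np.empty((20, 0)), y)
        p = 1 / (1 + np.exp(-fit.beta[0]))
        assert p == pytest.approx(7 / 20, rel=1e-9)

    def test_separation_detected(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        with pytest.raises(SeparationError):
            logistic_fit(x[:, None], y)

    def test_matches_statsmodels_on_random_data(self, rng):
        import statsmodels.api as sm
        x = rng.normal(size=(120, 2))
        eta = 0.3 + 0.8 * x[:, 0] - 0.5 * x[:, 1]
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_fit(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    @given(a=st.integers(1, 200), b=st.integers(1, 200),
           c=st.integers(1, 200), d=st.integers(1, 200))
    def test_binary_logistic_reproduces_contingency_or(self, a, b, c, d):
        table = ContingencyTable2x2(a, b, c, d)
        ref = contingency_or(table)
        x = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([a, c, b, d], dtype=float)
        fit = logistic_fit(x[:, None], y, weights=w, term_names=["e"])
        res = fit.result("e")
        assert res.or_point == pytest.approx(ref.or_point, rel=1e-6)
        assert res.ci_low == pytest.approx(ref.ci_low, rel=1e-4)
        assert res.ci_high == pytest.approx(ref.ci_high, rel=1e-4)


class TestContingencyOR:
    def test_null_table(self):
        assert contingency_or(
            ContingencyTable2x2(10, 10, 10, 10)).or_point == 1.0

    def test_hand_computed(self):
        res = contingency_or(ContingencyTable2x2(24, 151, 8, 88))
        assert res.or_point == pytest.approx(2112 / 1208)

    def test_haldane_correction(self):
        res = contingency_or(ContingencyTable2x2(5, 0, 5, 5),
                             correction="haldane")
        assert res.or_point == pytest.approx(11.0)
        assert "haldane" in res.method

    def test_zero_cell_without_correction_rejected(self):
        with pytest.raises(UndefinedOddsRatioError):
            contingency_or(ContingencyTable2x2(5, 0, 5, 5))

    @given(a=st.integers(1, 99), b=st.integers(1, 99),
           c=st.integers(1, 99), d=st.integers(1, 99))
    def test_swap_and_reciprocal_invariances(self, a, b, c, d):
        orig = contingency_or(ContingencyTable2x2(a, b, c, d))
        swapped = contingency_or(ContingencyTable2x2(d, c, b, a))
        assert swapped.or_point == pytest.approx(orig.or_point)
        flipped = contingency_or(ContingencyTable2x2(c, d, a, b))
        assert flipped.or_point == pytest.approx(1.0 / orig.or_point)


class TestModelAssociation:
    CASE = GenotypeCounts("rs634990", ("C", "T"), 40, 90, 59)
    CTRL = GenotypeCounts("rs634990", ("C", "T"), 16, 57, 23)

    def test_identical_counts_give_unit_or_in_every_model(self):
        for model in ("dominant", "recessive", "overdominant", "additive",
                      "codominant"):
            for res in model_association(self.CASE, self.CASE, model):
                assert res.or_point == pytest.approx(1.0, abs=1e-7)

    @pytest.mark.parametrize("model,collapse", [
        ("dominant", lambda c: (c.n_aa + c.n_ab, c.n_bb)),
        ("recessive", lambda c: (c.n_ab + c.n_bb, c.n_aa)),
        ("overdominant", lambda c: (c.n_aa + c.n_bb, c.n_ab)),
    ])
    def test_single_indicator_models_equal_collapsed_2x2(self, model,
                                                         collapse):
        (res,) = model_association(self.CASE, self.CTRL, model)
        a, b = collapse(self.CASE)
        c, d = collapse(self.CTRL)
        ref = contingency_or(ContingencyTable2x2(a, b, c, d))
        assert res.or_point == pytest.approx(ref.or_point, rel=1e-6)

    def test_codominant_returns_two_contrasts(self):
        results = model_association(self.CASE, self.CTRL, "codominant")
        assert len(results) == 2
        labels = [r.label for r in results]
        assert any("CT" in lab for lab in labels)
        assert any("CC" in lab for lab in labels)

    def test_additive_recovers_generative_odds_ratio(self):
        """Genotypes drawn under HWE with a true per-allele OR of 1.5."""
        rng = np.random.default_rng(42)
        n = 4000
        g = rng.binomial(2, 0.4, size=n).astype(float)
        eta = -0.5 + np.log(1.5) * g
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        case = GenotypeCounts("rs634990", ("C", "T"),
                              *(int(np.sum((g == k) & (y == 1)))
                                for k in (2, 1, 0)))
        ctrl = GenotypeCounts("rs634990", ("C", "T"),
                              *(int(np.sum((g == k) & (y == 0)))
                                for k in (2, 1, 0)))
        (res,) = model_association(case, ctrl, "additive")
        assert res.ci_low <= 1.5 <= res.ci_high


class TestCombinationAnalysis:
    def _cohort(self, rng, n=600):
        g1 = rng.choice(["CC", "CT", "TT"], size=n, p=[0.25, 0.5, 0.25])
        g2 = rng.choice(["GG", "GT", "TT"], size=n, p=[0.25, 0.5, 0.25])
        return g1, g2

    def test_outcome_independent_of_combination(self, rng):
        g1, g2 = self._cohort(rng)
        # duplicate each subject once as case and once as control:
        # outcome exactly independent of genotype
        gg1 = np.concatenate([g1, g1])
        gg2 = np.concatenate([g2, g2])
        y = np.concatenate([np.ones(len(g1)), np.zeros(len(g1))])
        for res in combination_analysis(gg1, gg2, y):
            if res.estimable:
                assert res.or_point == pytest.approx(1.0, abs=1e-6)

    def test_constructed_table_reduces_to_contingency_or(self):
        # combination CC+GG carried by 24 of 175 cases and 8 of 96 controls
        g1 = (["CC"] * 24 + ["TT"] * 151) + (["CC"] * 8 + ["TT"] * 88)
        g2 = ["GG"] * len(g1)
        y = [1] * 175 + [0] * 96
        results = {r.label: r for r in combination_analysis(g1, g2, y)}
        res = results["CC+GG"]
        assert res.or_point == pytest.approx((24 * 88) / (151 * 8), rel=1e-6)
        ref = contingency_or(ContingencyTable2x2(24, 151, 8, 88))
        assert res.or_point == pytest.approx(ref.or_point, rel=1e-6)

    def test_absent_combination_flagged(self):
        g1 = ["CC", "CC", "TT", "TT"]
        g2 = ["GG", "GG", "TT", "TT"]
        y = [1, 0, 1, 0]
        results = {r.label: r for r in combination_analysis(g1, g2, y)}
        assert not results["CT+GT"].estimable
        assert len(results) == 9

    def test_missing_genotypes_pairwise_deleted(self):
        g1 = ["CC", "", "CC", "TT"]
        g2 = ["GG", "GG", None, "TT"]
        y = [1, 1, 0, 0]
        results = combination_analysis(g1, g2, y)
        used = results[0].counts
        total = (used["carrier_cases"] + used["other_cases"]
                 + used["carrier_controls"] + used["other_controls"])
        assert total == 2  # only fully genotyped subjects


class TestDegreeStratifiedTable:
    def test_empty_cohort_all_zero(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["group", "degree",
                                      "rs634990", "rs8027411"])
        table = degree_stratified_table(empty)
        assert (table.to_numpy() == 0).all()
        assert list(table.index) == ["high", "medium", "mild", "control"]

    def test_partition_sums(self, classified):
        table = degree_stratified_table(classified)
        combo_cols = [c for c in table.columns if "+" in c]
        snp1_cols = [c for c in table.columns if c.startswith("rs634990:")]
        snp2_cols = [c for c in table.columns if c.startswith("rs8027411:")]
        for _, row in table.iterrows():
            # each SNP's genotype cells partition that stratum's genotyped N
            assert row[snp1_cols].sum() <= row["n"]
            assert row[snp2_cols].sum() <= row["n"]
            # the 9 combination cells partition the doubly-genotyped subjects
            assert row[combo_cols].sum() <= row["n"]
        # simulated data are fully genotyped: partitions are exact
        assert (table[snp1_cols].sum(axis=1) == table["n"]).all()
        assert (table[combo_cols].sum(axis=1) == table["n"]).all()
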