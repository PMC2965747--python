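"""QC cascade: exact HWE test, filters, iteration, ancestry, LD, ledger."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from carriermod.cohort import ValidationError
from carriermod.genotypes import MISSING, GenotypeMatrix, snp_table
from carriermod.qc import (
    QCReport,
    QCStep,
    QCThresholds,
    ancestry_outliers,
    differential_missingness,
    hwe_exact_test,
    ibs_matrix,
    iterative_qc,
    ld_prune,
    ld_r2,
    qc_ledger,
    sample_filters,
    snp_filters,
)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-fraction enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h] = Fraction(
            math.factorial(n) * math.factorial(rare) * math.factorial(2 * n - rare) * 2**h,
            math.factorial(hom_rare)
            * math.factorial(h)
            * math.factorial(hom_common)
            * math.factorial(2 * n),
        )
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExact:
    def test_modal_table_is_one(self):
        assert hwe_exact_test(25, 50, 25) == 1.0

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) == pytest.approx(
            hwe_enumeration_oracle(50, 0, 50), rel=1e-10
        )

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(60, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 61))
            cut = np.sort(rng.integers(0, n + 1, size=2))
            table = (int(cut[0]), int(cut[1] - cut[0]), int(n - cut[1]))
            assert hwe_exact_test(*table) == pytest.approx(
                hwe_enumeration_oracle(*table), rel=1e-9
            ), table


class TestDifferentialMissingness:
    def test_equal_proportions_p_one(self):
        miss = np.array([True] * 10 + [False] * 90 + [True] * 10 + [False] * 90)
        groups = np.array([0] * 100 + [1] * 100)
        assert differential_missingness(miss, groups) == 1.0

    def test_matches_contingency_oracle(self):
        miss = np.array([True] * 10 + [False] * 90 + [False] * 100)
        groups = np.array([0] * 100 + [1] * 100)
        table = np.array([[90, 10], [100, 0]])
        exp = st.contingency.chi2_contingency(table, correction=False)[1]
        assert differential_missingness(miss, groups) == pytest.approx(exp, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            differential_missingness(np.array([True, False]), np.array([0, 0]))

    def test_permutation_invariance(self, rng):
        """The statistic's permutation-null distribution ignores label names."""
        miss = rng.random(60) < 0.2
        groups = np.array([0] * 30 + [1] * 30)
        p1 = differential_missingness(miss, groups)
        p2 = differential_missingness(miss, 1 - groups)
        assert p1 == pytest.approx(p2)


def _random_gm(rng, n=60, m=40, maf=0.3):
    calls = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    return GenotypeMatrix([f"s{i}" for i in range(n)], snp_table(m), calls)


class TestSampleFilters:
    def test_clean_matrix_unchanged(self, rng):
        gm = _random_gm(rng)
        out, report = sample_filters(gm)
        assert out.n_samples == gm.n_samples
        assert all(s.n_removed == 0 for s in report.steps)

    def test_planted_duplicate_detected(self, rng):
        gm = _random_gm(rng, n=30, m=100)
        gm.calls[5] = gm.calls[17]
        out, report = sample_filters(gm)
        dup_step = next(s for s in report.steps if s.name == "ibs_duplicates")
        assert dup_step.n_removed == 1
        assert out.n_samples == 29

    def test_het_outlier_power(self):
        """10 heterozygosity-inflated samples of 1,000: >= 8 removed at FDR 0.1%."""
        rng = np.random.default_rng(20)
        gm = _random_gm(rng, n=1000, m=300)
        planted = rng.choice(1000, 10, replace=False)
        for i in planted:
            hom = np.flatnonzero(gm.calls[i] != 1)
            flip = hom[rng.random(hom.size) < 0.6]
            gm.calls[i, flip] = 1
        out, report = sample_filters(gm)
        removed = set(next(s for s in report.steps if s.name == "heterozygosity_fdr").removed_ids)
        hits = sum(1 for i in planted if f"s{i}" in removed)
        assert hits >= 8

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValidationError):
            sample_filters(_random_gm(rng), QCThresholds(sample_call_rate=1.5))


class TestSNPFilters:
    def test_monomorphic_removed(self, rng):
        gm = _random_gm(rng, m=10)
        gm.calls[:, 3] = 0
        out, report = snp_filters(gm)
        assert "snp3" not in list(out.snps["snp_id"])

    def test_maf_boundary(self):
        rng = np.random.default_rng(1)
        n = 1000
        calls = np.zeros((n, 2), dtype=np.int8)
        calls[:9, 0] = 1  # MAF 0.0045
        calls[:22, 1] = 1  # MAF 0.011
        gm = GenotypeMatrix([f"s{i}" for i in range(n)], snp_table(2), calls)
        out, _ = snp_filters(gm)
        assert list(out.snps["snp_id"]) == ["snp1"]

    def test_differential_missingness_filter(self, rng):
        gm = _random_gm(rng, n=200, m=20)
        aff = np.array([True] * 100 + [False] * 100)
        gm.calls[:60, 7] = MISSING  # heavy missingness in cases only
        out, report = snp_filters(gm, affected=aff)
        assert "snp7" not in list(out.snps["snp_id"])


class TestIterativeQC:
    def test_clean_fixed_point(self, rng):
        gm = _random_gm(rng)
        out, report = iterative_qc(gm)
        assert report.converged
        assert out.n_samples == gm.n_samples and out.n_snps == gm.n_snps

    def test_idempotent(self, rng):
        gm = _random_gm(rng, n=80, m=60)
        gm.calls[rng.random(gm.calls.shape) < 0.02] = MISSING
        out1, _ = iterative_qc(gm)
        out2, _ = iterative_qc(out1)
        assert np.array_equal(out1.calls, out2.calls)

    def test_bad_samples_rescue_borderline_snps(self):
        """Removing low-call-rate samples saves SNPs that would fail single-pass."""
        rng = np.random.default_rng(2)
        n, m = 100, 50
        gm = _random_gm(rng, n=n, m=m)
        bad_samples = list(range(8))
        borderline = list(range(10, 20))
        for i in bad_samples:
            gm.calls[i, rng.random(m) < 0.5] = MISSING  # fails sample call rate
        for j in borderline:
            gm.calls[bad_samples, j] = MISSING  # their missingness sits in bad samples
        iter_out, _ = iterative_qc(gm)
        single_out, _ = snp_filters(gm.copy())
        assert iter_out.n_snps > single_out.n_snps

    def test_everything_filtered_rejected(self):
        calls = np.full((5, 5), MISSING, dtype=np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(5)], snp_table(5), calls)
        with pytest.raises(ValidationError, match="empty"):
            iterative_qc(gm)

    def test_report_telescoping(self, rng):
        gm = _random_gm(rng, n=80, m=60)
        gm.calls[rng.random(gm.calls.shape) < 0.03] = MISSING
        _, report = iterative_qc(gm)
        report.validate()  # raises on inconsistency
        bad = QCReport(
            steps=[QCStep("a", "snp", 0, 1, 10), QCStep("b", "snp", 0, 2, 9)]
        )
        with pytest.raises(ValidationError, match="inconsistent"):
            bad.validate()


class TestAncestry:
    def test_homogeneous_cohort_clean(self):
        rng = np.random.default_rng(3)
        gm = _random_gm(rng, n=300, m=400)
        flagged, _ = ancestry_outliers(gm)
        assert len(flagged) < 3  # < 1%

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(4)
        n, m = 1000, 400
        p = rng.uniform(0.1, 0.5, m)
        calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        f = 0.15
        p_shift = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
        planted = rng.choice(n, 20, replace=False)
        for i in planted:
            calls[i] = rng.binomial(2, p_shift).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(n)], snp_table(m), calls)
        flagged, _ = ancestry_outliers(gm)
        hits = sum(1 for i in planted if f"s{i}" in set(flagged))
        assert hits >= 18
        false = len(set(flagged) - {f"s{i}" for i in planted})
        assert false <= 5

    def test_duplicate_of_inlier_not_flagged(self):
        rng = np.random.default_rng(5)
        gm = _random_gm(rng, n=200, m=300)
        gm.calls[0] = gm.calls[1]
        flagged, _ = ancestry_outliers(gm)
        assert "s0" not in flagged and "s1" not in flagged

    def test_too_few_snps_rejected(self, rng):
        with pytest.raises(ValidationError):
            ancestry_outliers(_random_gm(rng, m=5))


class TestLD:
    def test_identical_vectors_r2_one(self, rng):
        g = rng.binomial(2, 0.4, 50)
        assert ld_r2(g, g.copy()) == pytest.approx(1.0)

    def test_independent_snps_tiny_mean_r2(self):
        rng = np.random.default_rng(6)
        n = 10_000
        g1 = rng.binomial(2, 0.3, (n, 50))
        mean_r2 = np.mean([ld_r2(g1[:, 2 * k], g1[:, 2 * k + 1]) for k in range(25)])
        assert mean_r2 < 0.001

    def test_zero_variance_flagged_nan(self, rng):
        g1 = np.zeros(20, dtype=np.int8)
        g2 = rng.binomial(2, 0.4, 20)
        assert math.isnan(ld_r2(g1, g2))

    def test_prune_keeps_best_and_independent(self):
        """A (best p) tags B and C but not D: pruning keeps {A, D}."""
        rng = np.random.default_rng(7)
        n = 400
        a = rng.binomial(2, 0.4, n).astype(np.int8)
        noise = lambda: rng.binomial(1, 0.02, n)
        b = np.clip(a + noise() - noise(), 0, 2).astype(np.int8)
        c = np.clip(a + noise() - noise(), 0, 2).astype(np.int8)
        d = rng.binomial(2, 0.4, n).astype(np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], snp_table(4), np.stack([a, b, c, d], axis=1)
        )
        kept = ld_prune(gm, np.array([0.001, 0.01, 0.02, 0.5]), r2_max=0.8)
        assert kept == [0, 3]


class TestLedger:
    def test_empty_removals(self):
        assert qc_ledger(100, [])[0] == 100

    def test_sequential_accounting(self):
        n, report = qc_ledger(1000, [100, 50, 25])
        assert n == 825
        assert [s.n_remaining for s in report.steps] == [900, 850, 825]

    def test_negative_intermediate_rejected(self):
        with pytest.raises(ValidationError):
            qc_ledger(10, [5, 6])
        with pytest.raises(ValidationError):
            qc_ledger(10, [-1])


def test_ibs_matrix_handles_missing(rng):
    gm = _random_gm(rng, n=10, m=50)
    gm.calls[0, :25] = MISSING
    ibs = ibs_matrix(gm)
    assert np.isfinite(ibs[0, 1])
    assert ibs[2, 2] == pytest.approx(1.0)
    assert np.allclose(ibs, ibs.T, equal_nan=True)
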