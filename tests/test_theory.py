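"""Closed-form model values, limits, symmetries, and exact-rational checks."""

from fractions import Fraction

import numpy as np
import pytest

from sexmer import (
    HetAlleleDistribution,
    MarkerCensus,
    TheoryParams,
    absence_prob,
    fp_coverage,
    fp_heterozygosity,
    fp_total,
    het_multi_site_prob,
    lambda_rate,
    misid_prob,
    msk_precision,
    presence_prob,
    read_sort_prob,
    tpr_msk,
)
from _oracles import binom_tail_exact

BASE = TheoryParams(n=5, d=5, l=150, r=0.01, k=21)


class TestLambdaAndAbsence:
    def test_lambda_value(self):
        assert lambda_rate(5, 0.01, 21, 150) == pytest.approx(
            5 * 0.99**21 * 130 / 150, rel=1e-12
        )
        assert lambda_rate(5, 0.01, 21, 150) == pytest.approx(3.5088, abs=2e-4)

    def test_limits(self):
        assert lambda_rate(0, 0.01, 21, 150) == 0.0
        # r=0 and l >> k approaches d
        assert lambda_rate(5, 0.0, 21, 10**7) == pytest.approx(5.0, rel=1e-5)
        with pytest.raises(ValueError):
            lambda_rate(5, 0.01, 21, 21)

    def test_absence_prob(self):
        assert absence_prob(0.0) == 1.0
        lam = lambda_rate(5, 0.01, 21, 150)
        assert absence_prob(lam) == pytest.approx(0.1349, abs=1e-3)
        assert absence_prob(800.0) == pytest.approx(0.0, abs=1e-300)
        assert presence_prob(lam) == pytest.approx(1 - absence_prob(lam), rel=1e-12)
        with pytest.raises(ValueError):
            absence_prob(-0.1)


class TestBinomialTailAccuracy:
    @pytest.mark.parametrize("n,m,p", [(5, 3, 0.865), (10, 7, 0.865), (20, 14, 0.1), (15, 1, 0.99)])
    def test_relative_error_vs_exact_rational(self, n, m, p):
        from sexmer.theory import _binom_tail

        exact = binom_tail_exact(m, n, Fraction(p).limit_denominator(10**12))
        assert _binom_tail(m, n, p) == pytest.approx(float(exact), rel=1e-10)


class TestCoverageFalsePositive:
    def test_published_values(self):
        assert fp_coverage(BASE) == pytest.approx(4.4e-5, rel=0.02)
        assert fp_coverage(TheoryParams(n=10, d=5, l=150, r=0.01, k=21)) == pytest.approx(
            1.9e-9, rel=0.03
        )

    def test_ceil_rule_gives_different_n5_value(self):
        # the ceiling variant is a documented option but does not reproduce
        # the published n=5 value
        alt = fp_coverage(TheoryParams(n=5, d=5, l=150, r=0.01, k=21, m_rule="ceil"))
        assert alt == pytest.approx(3.86e-5, rel=0.02)

    def test_vanishes_at_high_depth(self):
        assert fp_coverage(TheoryParams(n=5, d=200, l=150, r=0.01, k=21)) < 1e-200

    def test_monotone_in_depth_and_commensurate_n(self):
        f_by_d = [fp_coverage(TheoryParams(n=5, d=d, l=150, r=0.01, k=21)) for d in (2, 4, 8, 16)]
        assert all(a >= b for a, b in zip(f_by_d, f_by_d[1:]))
        # over n multiples of 3 the m/n ratio is constant and f1 decreases
        f_by_n = [fp_coverage(TheoryParams(n=n, d=5, l=150, r=0.01, k=21)) for n in (3, 6, 9, 12)]
        assert all(a >= b for a, b in zip(f_by_n, f_by_n[1:]))


class TestHeterozygosityFalsePositive:
    def test_symmetry_in_alleles(self):
        for x in (0.05, 0.2, 0.45):
            assert fp_heterozygosity(BASE, x) == pytest.approx(
                fp_heterozygosity(BASE, 1 - x), rel=1e-12
            )

    def test_small_p_h1_limit_approaches_coverage_value(self):
        # one allele vanishes (its term -> 0), the other carries the full
        # rate, so f2 collapses to the pure-coverage rate f1
        assert fp_heterozygosity(BASE, 1e-9) == pytest.approx(fp_coverage(BASE), rel=1e-6)

    def test_domain(self):
        with pytest.raises(ValueError):
            fp_heterozygosity(BASE, 0.0)


class TestTotalFalsePositive:
    def test_h_zero_reduces_to_coverage(self):
        p = TheoryParams(n=5, d=5, l=150, r=0.01, k=21, h=0.0)
        assert fp_total(p) == fp_coverage(p)

    def test_convex_combination_bounds(self):
        het = HetAlleleDistribution()
        f = fp_total(BASE, het)
        f2s = [fp_heterozygosity(BASE, x) for x in het.values]
        lo = min(fp_coverage(BASE), min(f2s))
        hi = max(fp_coverage(BASE), max(f2s))
        assert lo <= f <= hi

    def test_term_by_term_recomputation(self):
        """Independent arbitrary-precision recomputation of the weighted sum."""
        import mpmath

        mpmath.mp.dps = 50
        het = HetAlleleDistribution()
        lam = mpmath.mpf(5) * mpmath.mpf("0.99") ** 21 * 130 / 150

        def q(l):
            return (1 + l) * mpmath.e ** (-l)

        def tail(qv):
            p = 1 - qv
            return sum(mpmath.binomial(5, i) * p**i * qv ** (5 - i) for i in range(3, 6))

        f1 = q(lam) ** 5 * tail(q(lam))
        f2s = []
        for x in het.values:
            t = mpmath.mpf(0)
            for ph in (x, 1 - x):
                qj = q(mpmath.mpf(repr(ph)) * lam)
                t += qj**5 * tail(qj)
            f2s.append(t)
        kh = 21 * mpmath.mpf("0.001")
        expected = (1 - kh) * f1 + kh * sum(
            mpmath.mpf(repr(p)) * f for p, f in zip(het.probs, f2s)
        )
        got = fp_total(TheoryParams(n=5, d=5, l=150, r=0.01, k=21, h=0.001), het)
        assert got == pytest.approx(float(expected), rel=1e-9)

    def test_het_distribution_validation(self):
        with pytest.raises(ValueError):
            HetAlleleDistribution(values=(0.1, 0.2), probs=(0.5, 0.6))
        with pytest.raises(ValueError):
            HetAlleleDistribution(values=(0.6,), probs=(1.0,))


class TestTruePositiveRate:
    def test_limits(self):
        assert tpr_msk(TheoryParams(n=5, d=500, l=150, r=0.0, k=21)) == pytest.approx(1.0)
        p1 = TheoryParams(n=1, d=5, l=150, r=0.01, k=21)
        lam = lambda_rate(5, 0.01, 21, 150)
        assert tpr_msk(p1) == pytest.approx(presence_prob(lam), rel=1e-12)

    def test_reference_value(self):
        # n=5, m=3 at the default parameters: binomial tail ~0.980
        lam = lambda_rate(5, 0.01, 21, 150)
        exact = binom_tail_exact(3, 5, Fraction(presence_prob(lam)).limit_denominator(10**12))
        assert tpr_msk(BASE) == pytest.approx(float(exact), rel=1e-10)
        assert tpr_msk(BASE) == pytest.approx(0.980, abs=2e-3)

    def test_effective_depth_option(self):
        half = tpr_msk(BASE, effective_depth=2.5)
        assert half < tpr_msk(BASE)


class TestReadSortProbability:
    def test_boundaries(self):
        assert read_sort_prob(10, 0, 0.3) == 1.0
        assert read_sort_prob(5, 6, 0.99) == 0.0

    def test_enumeration_oracle(self):
        # N=3, M=2, p=1/2: 4 of 8 outcomes have >= 2 successes
        assert read_sort_prob(3, 2, 0.5) == pytest.approx(0.5, rel=1e-12)

    def test_monotonicity(self):
        ps = [read_sort_prob(70, 7, p) for p in (0.1, 0.3, 0.5, 0.8)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        ns = [read_sort_prob(n, 7, 0.3) for n in (10, 30, 60, 120)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))
        ms = [read_sort_prob(70, m, 0.3) for m in (1, 7, 20, 40)]
        assert all(a >= b for a, b in zip(ms, ms[1:]))


class TestSideCalculations:
    def test_multi_site_heterozygosity(self):
        assert het_multi_site_prob(21, 0.001) == pytest.approx(2.1e-4, rel=0.02)
        assert het_multi_site_prob(21, 0.0) == 0.0
        # k=2, h=0.5: both sites het with probability 0.25
        assert het_multi_site_prob(2, 0.5) == pytest.approx(0.25, rel=1e-12)

    def test_misidentification(self):
        assert misid_prob(21, 0.01) == pytest.approx(0.003, abs=5e-4)
        assert misid_prob(21, 0.0) == 0.0
        assert misid_prob(2, 0.03) == pytest.approx(0.97 * 0.01, rel=1e-12)


class TestPrecisionFormula:
    def test_examples(self):
        c = MarkerCensus(YSK=100, AXK=900)
        assert msk_precision(c, 0.9, 0.1) == pytest.approx(0.5, rel=1e-12)
        assert msk_precision(c, 0.9, 0.0) == 1.0
        assert msk_precision(c, 0.0, 0.1) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            msk_precision(MarkerCensus(10, 10), 0.0, 0.0)


class TestParamValidation:
    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TheoryParams(r=1.5)
        with pytest.raises(ValueError):
            TheoryParams(l=21, k=21)
        with pytest.raises(ValueError):
            TheoryParams(n=0)
        with pytest.raises(ValueError):
            fp_total(TheoryParams(h=1.0, k=21))


class TestOutputsAreProbabilities:
    @pytest.mark.parametrize("n", [1, 2, 5, 9, 15])
    @pytest.mark.parametrize("d", [0.5, 2.0, 5.0, 30.0])
    def test_unit_interval(self, n, d):
        p = TheoryParams(n=n, d=d, l=150, r=0.01, k=21)
        for v in (fp_coverage(p), fp_heterozygosity(p, 0.3), fp_total(p), tpr_msk(p)):
            assert 0.0 <= v <= 1.0
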