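"""TPM, the two-library Poisson test, corrections and regulation calls."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from saltmir.de import (
    ac_conditional,
    ac_pvalue,
    bonferroni,
    call_regulation,
    differential_expression,
    fdr_bh,
    log2_ratio,
    poisson_pmf,
    tpm,
)

# enough working precision that the oracle's own 1 - S branch never cancels
mpmath.mp.dps = 300


def mp_ac_conditional(y, x, n1, n2):
    r = mpmath.mpf(n2) / n1
    return r**y * mpmath.binomial(x + y, y) * (1 + r) ** (-(x + y + 1))


def mp_ac_pvalue(x, y, n1, n2):
    s = mpmath.fsum(mp_ac_conditional(i, x, n1, n2) for i in range(y + 1))
    p = 2 * s if s <= mpmath.mpf("0.5") else 2 * (1 - s)
    return float(min(max(p, 0), 1))


class TestTpm:
    def test_zero_count_gets_floor(self):
        assert tpm(0, 47942551) == 0.001

    def test_identity(self):
        assert tpm(12345, 12345) == 1e6

    def test_per_million(self):
        assert tpm(1, 10**6) == 1.0

    def test_zero_total_fails(self):
        with pytest.raises(ValueError):
            tpm(1, 0)


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (5.12, 31.31, 2.612408),
            (0.001, 1.73, 10.75656),
            (10.21, 0.001, -13.317695),
            (14.38, 310.9, 4.434315),
        ],
    )
    def test_printed_table_rows(self, a, b, expected):
        assert log2_ratio(a, b) == pytest.approx(expected, abs=5e-6)

    def test_equal_tpm_gives_zero(self):
        assert log2_ratio(3.3, 3.3) == 0.0

    def test_nonpositive_fails(self):
        with pytest.raises(ValueError):
            log2_ratio(0.0, 1.0)


class TestPoissonPmf:
    def test_closed_form_at_zero(self):
        assert poisson_pmf(0, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_against_high_precision(self):
        expected = float(mpmath.e ** (-5) * mpmath.mpf(5) ** 5 / mpmath.factorial(5))
        assert poisson_pmf(5, 5.0) == pytest.approx(expected, rel=1e-12)
        assert poisson_pmf(5, 5.0) == pytest.approx(0.175467, abs=5e-7)

    def test_normalisation(self):
        lam = 7.3
        upper = int(lam + 40 * math.sqrt(lam))
        assert sum(poisson_pmf(x, lam) for x in range(upper)) == pytest.approx(1.0, abs=1e-12)


class TestAcConditional:
    def test_equal_libraries_zero_zero(self):
        assert ac_conditional(0, 0, 10**6, 10**6) == pytest.approx(0.5, rel=1e-12)

    def test_small_case_oracle(self):
        # P(y=2 | x=0) with N1=N2: C(2,0) * 2^-3 = 0.125
        assert ac_conditional(2, 0, 10**4, 10**4) == pytest.approx(0.125, rel=1e-12)

    @pytest.mark.parametrize("x", [0, 3, 17, 50])
    @pytest.mark.parametrize("ratio", [1.0, 2.5])
    def test_normalisation_over_y(self, x, ratio):
        n1, n2 = 10**5, int(10**5 * ratio)
        mean = (x + 1) * n2 / n1
        upper = int(mean + 50 * math.sqrt(mean + 1)) + 50
        total = sum(ac_conditional(y, x, n1, n2) for y in range(upper))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestAcPvalue:
    def test_doubled_lower_tail(self):
        assert ac_pvalue(2, 0, 10**6, 10**6) == pytest.approx(0.25, rel=1e-10)

    def test_near_null_large_counts(self):
        assert ac_pvalue(100, 100, 10**6, 10**6) >= 0.9

    def test_clamped_to_unit_interval(self):
        for x, y in [(0, 0), (1, 1), (10, 10)]:
            p = ac_pvalue(x, y, 10**4, 10**4)
            assert 0.0 <= p <= 1.0

    def test_matches_arbitrary_precision_oracle(self):
        """Relative agreement to 1e-10 against direct high-precision summation."""
        for n1, n2 in [(10**4, 10**4), (10**4, 10**6), (10**6, 10**4)]:
            for x in range(0, 31, 3):
                for y in range(0, 31, 3):
                    got = ac_pvalue(x, y, n1, n2)
                    want = mp_ac_pvalue(x, y, n1, n2)
                    assert got == pytest.approx(want, rel=1e-10, abs=1e-300), (x, y, n1, n2)

    def test_agrees_with_negative_binomial_cdf(self):
        """Independent route: the conditional law of y given x is NB(x+1, N1/(N1+N2))."""
        n1, n2 = 3 * 10**5, 7 * 10**5
        for x, y in [(5, 2), (12, 30), (0, 4), (40, 20)]:
            s = sps.nbinom.cdf(y, x + 1, n1 / (n1 + n2))
            expected = min(1.0, 2 * s if s <= 0.5 else 2 * (1 - s))
            assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=1000, max_value=10**7),
        st.integers(min_value=1000, max_value=10**7),
    )
    def test_symmetry(self, x, y, n1, n2):
        assert ac_pvalue(x, y, n1, n2) == pytest.approx(ac_pvalue(y, x, n2, n1), abs=1e-9)


class TestCorrections:
    def test_bonferroni(self):
        assert list(bonferroni([0.01])) == [0.01]
        assert list(bonferroni([0.01, 0.4])) == [0.02, 0.8]
        assert list(bonferroni([0.9, 0.9])) == [1.0, 1.0]

    def test_fdr_bh_by_hand(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert list(fdr_bh([0.5])) == [0.5]

    def test_fdr_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr_bh(p), q_ref)

    def test_fdr_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=50))
        q = fdr_bh(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestCallRegulation:
    @pytest.mark.parametrize(
        "fdr,lfc,expected",
        [
            (2.31e-152, 2.612408, "up"),
            (0.000477, -8.71425, "down"),
            (0.01, 3.0, "ns"),
            (1e-5, 0.5, "ns"),
        ],
    )
    def test_threshold_gates(self, fdr, lfc, expected):
        assert call_regulation([lfc], [fdr])[0] == expected


class TestDifferentialExpression:
    def test_null_calibration(self):
        """Equal expression, Poisson counts: p <= 0.05 for ~5% of loci."""
        rng = np.random.default_rng(12)
        means = rng.uniform(20, 200, size=2000)
        x = rng.poisson(means)
        y = rng.poisson(means)
        n = int(means.sum())
        pvals = np.array([ac_pvalue(int(a), int(b), n, n) for a, b in zip(x, y)])
        frac = (pvals <= 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_spiked_fold_changes_recovered(self):
        """|log2 fc| >= 2 at mean >= 50 is called in the right direction >= 90%."""
        rng = np.random.default_rng(3)
        n_spike, n_null = 150, 850
        means = rng.uniform(50, 500, size=n_spike + n_null)
        folds = np.ones(n_spike + n_null)
        folds[:n_spike] = rng.choice([0.25, 4.0], size=n_spike)
        x = rng.poisson(means)
        y = rng.poisson(means * folds)
        total = int(means.sum())
        results = differential_expression(
            [f"locus{i}" for i in range(len(means))], x.tolist(), y.tolist(), total, total
        )
        correct = 0
        for i in range(n_spike):
            want = "up" if folds[i] > 1 else "down"
            if results[i].regulation == want:
                correct += 1
        assert correct / n_spike >= 0.9

    def test_zero_count_rows_get_finite_ratio(self):
        res = differential_expression(["a"], [0], [48], 10**6, 10**6)
        assert res[0].tpm_a == 0.001 and math.isfinite(res[0].log2_ratio)
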