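"""Exact count test, normalization, filtering and tier classification."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from srnapipe.diffexpr import (
    LibraryTotals,
    classify,
    differential_expression,
    exact_count_pvalue,
    filter_low,
    fold_change,
    normalize,
    tpm_with_substitution,
)
from srnapipe.experiments import exact_pvalue_fraction

EQ = LibraryTotals(10**6, 10**6)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,total,expected",
        [
            (643_669, 26_260_294, 24511.11),  # abundant miRNA class, real scale
            (0, 100, 0.0),
            (100, 100, 1_000_000.0),
        ],
    )
    def test_tpm_values(self, raw, total, expected):
        assert normalize(raw, total) == pytest.approx(expected, abs=0.01)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize(5, 0)

    def test_zero_in_one_library_substituted(self):
        tpm_ck, tpm_hyp = tpm_with_substitution(0, 50, 1000, 1000)
        assert tpm_ck == 0.01
        assert tpm_hyp == 50_000.0
        tpm_ck, tpm_hyp = tpm_with_substitution(50, 0, 1000, 1000)
        assert (tpm_ck, tpm_hyp) == (50_000.0, 0.01)

    def test_substitution_not_applied_when_both_present(self):
        tpm_ck, tpm_hyp = tpm_with_substitution(1, 1, 1000, 1000)
        assert tpm_ck == tpm_hyp == 1000.0


class TestFilterAndFold:
    @pytest.mark.parametrize(
        "tpms,kept",
        [
            ((0.4, 0.7), False),   # below 1 TPM in both -> filtered
            ((0.01, 5.0), True),   # substituted zero, expressed in other
            ((1.0, 0.2), True),    # boundary is inclusive
            ((0.999, 0.999), False),
        ],
    )
    def test_low_tpm_retention_rule(self, tpms, kept):
        df = pd.DataFrame([{"tpm_ck": tpms[0], "tpm_hypoxia": tpms[1]}])
        assert (len(filter_low(df)) == 1) is kept

    @pytest.mark.parametrize(
        "tpm_ck,tpm_hyp,expected",
        [
            (854.24, 1272.13, -0.574),  # induced under hypoxia
            (10.0, 10.0, 0.0),
            (0.01, 10.0, math.log2(0.001)),  # substitution-driven extreme
        ],
    )
    def test_log2_fold_change(self, tpm_ck, tpm_hyp, expected):
        assert fold_change(tpm_ck, tpm_hyp) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_tpm_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 5.0)


class TestExactCountPValue:
    def test_equal_depth_point_probabilities(self):
        # closed forms at r=1: p(0|0) = 1/2, p(5|5) = C(10,5)/2^11
        assert exact_count_pvalue(0, 0, EQ).p_point == pytest.approx(0.5, rel=1e-12)
        assert exact_count_pvalue(5, 5, EQ).p_point == pytest.approx(
            0.123046875, rel=1e-12
        )

    def test_matches_rational_arithmetic_oracle(self):
        totals = LibraryTotals(1_000_000, 500_000)
        for x, y in [(0, 0), (3, 7), (10, 2), (25, 25)]:
            pt, lo = exact_pvalue_fraction(x, y, totals.n1, totals.n2)
            got = exact_count_pvalue(x, y, totals)
            assert got.p_point == pytest.approx(float(pt), rel=1e-12)
            assert got.p_lower == pytest.approx(float(lo), rel=1e-12)

    def test_matches_negative_binomial_cdf(self):
        # independent scipy route: y|x ~ NB(x+1, 1/(1+r))
        totals = LibraryTotals(3_000_000, 1_500_000)
        r = totals.ratio
        for x, y in [(0, 5), (8, 3), (100, 120)]:
            got = exact_count_pvalue(x, y, totals)
            assert got.p_lower == pytest.approx(
                stats.nbinom.cdf(y, x + 1, 1 / (1 + r)), rel=1e-10
            )

    def test_tail_identity_and_swap(self):
        a = exact_count_pvalue(3, 9, LibraryTotals(1000, 2000))
        b = exact_count_pvalue(9, 3, LibraryTotals(2000, 1000))
        # inclusive tails overlap in the point mass, so swapping the two
        # libraries exchanges the tails up to that point term
        assert b.p_upper == pytest.approx(a.p_lower + b.p_point, abs=1e-12)
        assert a.p_upper == pytest.approx(b.p_lower + a.p_point, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_count_pvalue(-1, 0, EQ)

    @given(
        x=st.integers(0, 300),
        y=st.integers(0, 300),
        n1=st.integers(10_000, 10**7),
        n2=st.integers(10_000, 10**7),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_probability_structure(self, x, y, n1, n2):
        res = exact_count_pvalue(x, y, LibraryTotals(n1, n2))
        assert 0 < res.p_point <= 1
        assert 0 < res.p_two_sided <= 1
        assert res.p_lower + res.p_upper - res.p_point == pytest.approx(1, abs=1e-9)

    def test_lower_tail_monotone_in_y(self):
        totals = LibraryTotals(2_000_000, 900_000)
        lowers = [exact_count_pvalue(40, y, totals).p_lower for y in range(0, 120)]
        assert all(b >= a for a, b in zip(lowers, lowers[1:]))

    def test_distribution_normalizes(self):
        from srnapipe.diffexpr import _log_pmf_array
        from scipy.special import logsumexp

        # the +60 keeps the geometric tail below 1e-9 even at x = 0
        for x, r in [(0, 1.0), (5, 0.5), (50, 2.0), (500, 1.3)]:
            y_max = int(20 * (x + 1) * max(1, r)) + 60
            total = float(np.exp(logsumexp(_log_pmf_array(x, y_max, r))))
            assert total >= 1 - 1e-9
            assert total <= 1 + 1e-9


class TestClassify:
    @pytest.mark.parametrize(
        "fc,p,tier",
        [
            (1.0, 0.005, "significant"),
            (0.59, 0.001, "not_DE"),   # |FC| below 0.6 never called
            (-0.8, 0.03, "DE"),
            (0.6, 0.01, "DE"),         # p = 0.01 falls in the DE band
            (0.6, 0.05, "not_DE"),     # p = 0.05 is outside both bands
            (2.0, 0.0099, "significant"),
        ],
    )
    def test_two_tier_rule(self, fc, p, tier):
        assert classify(fc, p) == tier


class TestDifferentialExpression:
    def test_table_fields_and_direction(self):
        counts = pd.DataFrame(
            [
                {"mirna_id": "up", "count_ck": 20, "count_hypoxia": 400},
                {"mirna_id": "down", "count_ck": 400, "count_hypoxia": 20},
                {"mirna_id": "flat", "count_ck": 100, "count_hypoxia": 100},
                {"mirna_id": "rare", "count_ck": 1, "count_hypoxia": 0},
            ]
        )
        de = differential_expression(counts, LibraryTotals(100_000, 100_000))
        by_id = de.set_index("mirna_id")
        assert by_id.loc["up", "direction"] == "up_in_hypoxia"
        assert by_id.loc["up", "tier"] == "significant"
        assert by_id.loc["down", "direction"] == "down_in_hypoxia"
        assert by_id.loc["flat", "tier"] == "not_DE"
        # zero in one library: substituted TPM and retained (other side >= 1)
        assert by_id.loc["rare", "tpm_hypoxia"] == 0.01
        # sorted by |fold change| descending
        absfc = de["fold_change"].abs().to_numpy()
        assert (absfc[:-1] >= absfc[1:]).all()

    def test_zero_both_dropped_and_low_tpm_filtered(self):
        counts = pd.DataFrame(
            [
                {"mirna_id": "gone", "count_ck": 0, "count_hypoxia": 0},
                {"mirna_id": "dust", "count_ck": 1, "count_hypoxia": 1},
            ]
        )
        # 1 read in 10M is 0.1 TPM: below the 1-TPM retention rule
        de = differential_expression(counts, LibraryTotals(10**7, 10**7))
        assert de.empty
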