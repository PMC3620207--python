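"""Normalisation, filtering, fold change and the exact count test."""

import math

import mpmath as mp
import numpy as np
import pandas as pd
import pytest

from mirmet import diffexpr as de
from mirmet.diffexpr import (CountPair, ac_log_pmf, call_de, classify_status,
                             count_test_pvalue, floor_and_filter, fold_change,
                             normalize)

mp.mp.dps = 50


def ac_pvalue_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Arbitrary-precision direct summation of the same formula."""
    q = mp.mpf(n2) / n1

    def pmf(t):
        return (q ** t * mp.factorial(x + t)
                / (mp.factorial(x) * mp.factorial(t) * (1 + q) ** (x + t + 1)))

    lower = mp.fsum(pmf(t) for t in range(0, y + 1))
    upper = 1 - lower + pmf(y)
    return float(min(1, 2 * min(lower, upper)))


class TestNormalize:
    def test_full_library_is_one_million(self):
        assert normalize(100, 100) == 1_000_000.0

    def test_per_million_arithmetic(self):
        assert normalize(246, 24_600_000) == pytest.approx(10.0)

    def test_zero_count_stays_zero(self):
        assert normalize(0, 1000) == 0.0

    def test_zero_total_fails(self):
        with pytest.raises(ValueError):
            normalize(0, 0)


class TestFloorAndFilter:
    def test_both_below_one_removed(self):
        kept, removed = floor_and_filter({"m": (0.5, 0.7)})
        assert removed == ["m"] and not kept

    def test_zero_floored_to_001(self):
        kept, _ = floor_and_filter({"m": (0.0, 25.0)})
        assert kept["m"] == (0.01, 25.0)

    def test_one_side_expressed_retained_under_both_mode(self):
        kept, _ = floor_and_filter({"m": (1.0, 0.2)}, mode="both")
        assert "m" in kept

    def test_either_mode_flips_the_call(self):
        kept, removed = floor_and_filter({"m": (1.0, 0.2)}, mode="either")
        assert removed == ["m"] and not kept


class TestFoldChange:
    def test_equal_expression_is_zero(self):
        assert fold_change(10, 10) == 0.0

    def test_log2_of_128(self):
        assert fold_change(0.01, 1.28) == pytest.approx(7.0)

    def test_exact_minus_two_is_not_called(self):
        fc = fold_change(40, 10)
        assert fc == -2.0
        assert classify_status(fc, 1e-6) == de.NS  # strictly less than -2 required

    def test_nonpositive_input_fails(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 5.0)


class TestCountTest:
    def test_identical_counts_equal_totals_capped_at_one(self):
        p = count_test_pvalue(CountPair(5, 5, 10**6, 10**6))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_arbitrary_precision_oracle(self):
        p = count_test_pvalue(CountPair(5, 0, 10**6, 10**6))
        assert p == pytest.approx(ac_pvalue_oracle(5, 0, 10**6, 10**6), abs=1e-12)

    def test_pmf_exchange_symmetry(self):
        # p(y|x; N1,N2) equals p(x|y; N2,N1) up to the N2/N1 density ratio;
        # at equal totals the conditional pmf is exactly exchange-symmetric
        a = ac_log_pmf(3, 9, 10**6, 10**6)
        b = ac_log_pmf(9, 3, 10**6, 10**6)
        assert a == pytest.approx(b, abs=1e-12)

    def test_oracle_agreement_on_unequal_totals(self):
        for x, y, n1, n2 in [(0, 12, 10**6, 2 * 10**6), (30, 4, 2 * 10**6, 10**6)]:
            p = count_test_pvalue(CountPair(x, y, n1, n2))
            assert p == pytest.approx(ac_pvalue_oracle(x, y, n1, n2), abs=1e-10)

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            CountPair(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            CountPair(11, 0, 10, 10)


class TestCallDe:
    def test_reported_threshold_examples(self):
        assert classify_status(2.09915672, 0.012601836) == de.UP
        assert classify_status(-3.93085912, 0.000279664) == de.DOWN
        assert classify_status(5.0, 0.2) == de.NS

    def test_table_sorted_and_statuses_consistent(self):
        counts = pd.DataFrame({
            "mir_name": ["a", "b", "c", "d"],
            "count_control": [100, 5, 400, 0],
            "count_treatment": [800, 6, 40, 0],
        })
        out = call_de(counts, 10**6, 10**6)
        assert out.loc[out["mir_name"] == "d", "status"].item() == de.FILTERED
        ranked = out[out["status"] != de.FILTERED]
        assert list(ranked["fold_change"]) == sorted(ranked["fold_change"])
        a = ranked.set_index("mir_name").loc["a"]
        assert a["status"] == de.UP and a["fold_change"] == pytest.approx(3.0)

    def test_status_invariant_holds_for_every_row(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame({
            "mir_name": [f"m{i}" for i in range(50)],
            "count_control": rng.poisson(80, 50),
            "count_treatment": rng.poisson(80, 50),
        })
        out = call_de(counts, 10**6, 10**6)
        for r in out.itertuples():
            if r.status == de.UP:
                assert r.fold_change > 2 and r.p_value < 0.05
            elif r.status == de.DOWN:
                assert r.fold_change < -2 and r.p_value < 0.05
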