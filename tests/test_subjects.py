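import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splitprev import (BaselineSpec, binomial_test_one_sided, flag_significant,
                       pooled_baseline_rate, summarize_subjects)
from conftest import hand_trials


def brute_force_upper_tail(k, n, p0):
    """Independent oracle: sum the binomial pmf from k to n."""
    return math.fsum(stats.binom.pmf(i, n, p0) for i in range(k, n + 1))


def exact_fraction_tail(k, n, p0_frac):
    """Exact rational upper tail for small n."""
    total = Fraction(0)
    for i in range(k, n + 1):
        total += (math.comb(n, i) * p0_frac**i * (1 - p0_frac)**(n - i))
    return float(total)


class TestBinomialTest:
    def test_zero_successes_gives_one(self):
        assert binomial_test_one_sided(0, 45, 0.05) == 1.0

    def test_all_successes_gives_power_of_p0(self):
        assert binomial_test_one_sided(45, 45, 0.05) == pytest.approx(
            0.05**45, rel=1e-12)

    def test_known_half_case(self):
        # frozen from brute-force pmf summation of Binomial(10, 0.5) over 5..10
        assert binomial_test_one_sided(5, 10, 0.5) == pytest.approx(
            0.623046875, abs=1e-15)

    @pytest.mark.parametrize("n", [1, 7, 45, 288, 1000])
    @pytest.mark.parametrize("p0", [0.0327, 0.05, 0.5, 0.9])
    def test_matches_brute_force_summation(self, n, p0):
        ks = np.unique(np.linspace(0, n, 25).astype(int))
        for k in ks:
            assert binomial_test_one_sided(int(k), n, p0) == pytest.approx(
                brute_force_upper_tail(int(k), n, p0), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 12])
    def test_matches_exact_rational_arithmetic(self, n):
        p0 = Fraction(1, 20)
        for k in range(n + 1):
            assert binomial_test_one_sided(k, n, float(p0)) == pytest.approx(
                exact_fraction_tail(k, n, p0), abs=1e-14)

    def test_monotone_nonincreasing_in_k(self):
        ps = [binomial_test_one_sided(k, 50, 0.1) for k in range(51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_monotone_nondecreasing_in_p0(self):
        grid = np.linspace(0.01, 0.99, 40)
        ps = [binomial_test_one_sided(12, 50, p0) for p0 in grid]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_p0_zero_limit_and_warning(self):
        assert binomial_test_one_sided(0, 10, 0.0) == 1.0
        with pytest.warns(UserWarning, match="baseline rate"):
            assert binomial_test_one_sided(1, 10, 0.0) == 0.0

    @pytest.mark.parametrize("k,n,p0", [(-1, 10, 0.5), (11, 10, 0.5),
                                        (5, 10, 1.5)])
    def test_invalid_inputs(self, k, n, p0):
        with pytest.raises(ValueError):
            binomial_test_one_sided(k, n, p0)


@pytest.fixture
def hand_table(mini_design):
    """3 participants with hand-countable responses.

    a: level 0: 12 experimental (3 twos, 1 zero), 4 catch (1 commission);
       level 1: 12 experimental (6 twos), 4 catch (0 commission)
    b: all ones, no errors
    c: 2 twos at each level, 2 commissions at level 0
    """
    rows = []
    rows += [("a", 0, "experimental", 2)] * 3 + [("a", 0, "experimental", 0)]
    rows += [("a", 0, "experimental", 1)] * 8
    rows += [("a", 0, "catch", 1)] + [("a", 0, "catch", 0)] * 3
    rows += [("a", 1, "experimental", 2)] * 6 + [("a", 1, "experimental", 1)] * 6
    rows += [("a", 1, "catch", 0)] * 4
    for lv in (0, 1):
        rows += [("b", lv, "experimental", 1)] * 12
        rows += [("b", lv, "catch", 0)] * 4
    rows += [("c", 0, "experimental", 2)] * 2 + [("c", 0, "experimental", 1)] * 10
    rows += [("c", 0, "catch", 2), ("c", 0, "catch", 1)] + [("c", 0, "catch", 0)] * 2
    rows += [("c", 1, "experimental", 2)] * 2 + [("c", 1, "experimental", 1)] * 10
    rows += [("c", 1, "catch", 0)] * 4
    return hand_trials(rows)


class TestSummaries:
    def test_hand_counted_rates(self, hand_table, mini_design):
        s = summarize_subjects(hand_table, mini_design)
        a = s[(s["participant_id"] == "a") & (s["level_index"] == -1)].iloc[0]
        assert a["n_experimental"] == 24
        assert a["n_report2"] == 9
        assert a["pct_report2"] == pytest.approx(100 * 9 / 24)
        assert a["n_commission"] == 1
        assert a["pct_commission"] == pytest.approx(100 * 1 / 8)
        assert a["n_omission"] == 1
        b = s[(s["participant_id"] == "b") & (s["level_index"] == -1)].iloc[0]
        assert b["pct_report2"] == 0.0
        assert b["pct_commission"] == 0.0
        c0 = s[(s["participant_id"] == "c") & (s["level_index"] == 0)].iloc[0]
        assert c0["n_commission"] == 2  # both 1- and 2-responses count

    def test_printed_rate_example(self):
        assert round(100 * 30 / 288, 2) == 10.42

    def test_zero_experimental_trials_is_an_error(self, mini_design):
        rows = [("lonely", 0, "catch", 0)] * 4
        with pytest.raises(ValueError, match="lonely"):
            summarize_subjects(hand_trials(rows), mini_design)

    def test_two_only_commission_option(self, hand_table, mini_design):
        s = summarize_subjects(hand_table, mini_design,
                               commission_counts="two_only")
        c = s[(s["participant_id"] == "c") & (s["level_index"] == -1)].iloc[0]
        assert c["n_commission"] == 1


class TestBaseline:
    def test_pooled_is_trial_weighted(self, hand_table, mini_design):
        s = summarize_subjects(hand_table, mini_design)
        spec = BaselineSpec(kind="commission")
        # total commissions 3 over total catch 24
        assert pooled_baseline_rate(s, spec) == pytest.approx(3 / 24)

    def test_mean_of_rates_differs_on_unbalanced_rates(self, hand_table,
                                                       mini_design):
        s = summarize_subjects(hand_table, mini_design)
        spec = BaselineSpec(kind="commission", rate_method="mean_of_rates")
        assert pooled_baseline_rate(s, spec) == pytest.approx(
            (1 / 8 + 0.0 + 2 / 8) / 3)

    def test_omission_baseline(self, hand_table, mini_design):
        s = summarize_subjects(hand_table, mini_design)
        spec = BaselineSpec(kind="omission")
        assert pooled_baseline_rate(s, spec) == pytest.approx(1 / 72)

    def test_bad_spec_values_rejected(self):
        with pytest.raises(ValueError):
            BaselineSpec(kind="typo")
        with pytest.raises(ValueError):
            BaselineSpec(alpha=0.0)


class TestFlagging:
    def test_no_reports_no_flags(self, mini_design):
        rows = []
        for pid in ("a", "b"):
            for lv in (0, 1):
                rows += [(pid, lv, "experimental", 1)] * 12
                rows += [(pid, lv, "catch", 1)] + [(pid, lv, "catch", 0)] * 3
        s = summarize_subjects(hand_trials(rows), mini_design)
        _, k_sig, n = flag_significant(s, BaselineSpec())
        assert (k_sig, n) == (0, 2)

    def test_strong_reporter_is_flagged(self):
        # 60 of 288 at baseline 3.27% is overwhelming evidence
        p = binomial_test_one_sided(60, 288, 0.0327)
        assert p < 1e-20

    def test_flags_against_pooled_baseline(self, hand_table, mini_design):
        s = summarize_subjects(hand_table, mini_design)
        table, k_sig, n = flag_significant(s, BaselineSpec(alpha=0.05))
        assert n == 3
        byid = table.set_index("participant_id")
        # p0 = 3/24; a: 9/24 reports is significant, b and c are not
        assert bool(byid.loc["a", "significant"]) is True
        assert bool(byid.loc["b", "significant"]) is False
        assert k_sig == int(table["significant"].sum())
        assert (table["p_value"] > 0).all() and (table["p_value"] <= 1).all()

    def test_per_level_tests_reuse_overall_baseline(self, hand_table,
                                                    mini_design):
        s = summarize_subjects(hand_table, mini_design)
        table, _, _ = flag_significant(s, BaselineSpec(), per_level=True)
        assert set(table["level_index"]) == {-1, 0, 1}
        assert table["p0"].nunique() == 1

    def test_per_participant_pooling(self, hand_table, mini_design):
        s = summarize_subjects(hand_table, mini_design)
        spec = BaselineSpec(pooling="per_participant")
        table, _, _ = flag_significant(s, spec)
        byid = table.set_index("participant_id")
        assert byid.loc["a", "p0"] == pytest.approx(1 / 8)
        assert byid.loc["c", "p0"] == pytest.approx(2 / 8)
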