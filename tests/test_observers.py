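import numpy as np
import pandas as pd
import pytest

from splitprev import (ObserverProfile, PopulationModel, builtin_design,
                       counts_from_trials, default_population_model,
                       draw_population, simulate_counts, simulate_trials,
                       validate_trials)
from splitprev.designs import ConditionLevel, StudyDesign


def one_level_design(n_participants, n_exp=32, n_catch=8):
    lv = ConditionLevel((("frame_speed", 20.0),), n_exp, n_catch)
    return StudyDesign("custom", n_participants, (lv,), "commission",
                       "frame_speed")


def flat_profiles(design, p2, p_com=0.0, p_om=0.0, perceiver=True):
    return [
        ObserverProfile(f"p{i}", perceiver, (p2,) * design.n_levels, p_com, p_om)
        for i in range(design.n_participants)
    ]


class TestDrawPopulation:
    @pytest.mark.parametrize("gamma,expect", [(0.0, False), (1.0, True)])
    def test_degenerate_mixture(self, gamma, expect, mini_design):
        model = PopulationModel(gamma=gamma)
        profs = draw_population(model, mini_design, seed=0)
        assert len(profs) == mini_design.n_participants
        assert all(p.is_perceiver is expect for p in profs)

    def test_nonperceiver_reports_at_own_commission_rate(self, mini_design):
        model = PopulationModel(gamma=0.0, commission_mean=0.04,
                                commission_spread=0.03)
        profs = draw_population(model, mini_design, seed=5)
        for p in profs:
            assert len(set(p.p_report2_by_level)) == 1
            assert p.p_report2_by_level[0] == pytest.approx(p.p_commission)

    def test_perceiver_link_increases_with_speed(self, mini_design):
        model = PopulationModel(gamma=1.0, link_intercept=-2.8, link_slope=0.07)
        prof = draw_population(model, mini_design, seed=1)[0]
        assert prof.p_report2_by_level[0] < prof.p_report2_by_level[1]

    def test_perceiver_count_matches_binomial_moments(self):
        # mean over many seeds of the perceiver count ~ Binomial(45, 0.5)
        d = builtin_design("exp1a")
        model = PopulationModel(gamma=0.5)
        n_reps = 1000
        counts = [sum(p.is_perceiver
                      for p in draw_population(model, d, seed=s))
                  for s in range(n_reps)]
        mean_expect = 45 * 0.5
        se = np.sqrt(45 * 0.25 / n_reps)
        assert abs(np.mean(counts) - mean_expect) < 3 * se

    def test_reproducible_from_seed(self, mini_design):
        model = PopulationModel(gamma=0.5, commission_spread=0.02)
        a = draw_population(model, mini_design, seed=9)
        b = draw_population(model, mini_design, seed=9)
        assert a == b

    def test_invalid_model_rejected(self, mini_design):
        model = PopulationModel(gamma=1.5)
        with pytest.raises(ValueError, match="gamma"):
            draw_population(model, mini_design, seed=0)
        with pytest.raises(ValueError, match="spread"):
            draw_population(PopulationModel(commission_mean=0.5,
                                            commission_spread=0.6),
                            mini_design, seed=0)


class TestSimulateTrials:
    def test_trial_counts_match_design_exactly(self, mini_design, mini_trials):
        per_cell = mini_trials.groupby(
            ["participant_id", "level_index", "trial_type"]).size()
        for pid in mini_trials["participant_id"].unique():
            for j, lv in enumerate(mini_design.levels):
                assert per_cell[pid, j, "experimental"] == lv.n_experimental
                assert per_cell[pid, j, "catch"] == lv.n_catch

    def test_same_seed_identical_different_seed_differs(self, mini_design):
        model = PopulationModel(gamma=0.5, commission_mean=0.05)
        profs = draw_population(model, mini_design, seed=3)
        t1 = simulate_trials(profs, mini_design, seed=4)
        t2 = simulate_trials(profs, mini_design, seed=4)
        t3 = simulate_trials(profs, mini_design, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1.equals(t3)

    def test_certain_perceiver_always_reports_two(self):
        d = one_level_design(2)
        profs = flat_profiles(d, p2=1.0)
        tr = simulate_trials(profs, d, seed=0)
        exp = tr[tr["trial_type"] == "experimental"]
        assert (exp["response"] == 2).all()

    def test_error_free_nonperceiver(self):
        d = one_level_design(2)
        profs = flat_profiles(d, p2=0.0, perceiver=False)
        tr = simulate_trials(profs, d, seed=0)
        assert (tr.loc[tr["trial_type"] == "experimental", "response"] == 1).all()
        assert (tr.loc[tr["trial_type"] == "catch", "response"] == 0).all()

    def test_catch_rows_present_nothing(self, mini_trials):
        catch = mini_trials[mini_trials["trial_type"] == "catch"]
        exp = mini_trials[mini_trials["trial_type"] == "experimental"]
        assert (catch["n_presented"] == 0).all()
        assert (exp["n_presented"] == 1).all()

    def test_report_two_count_matches_binomial_moments(self):
        # many iid subjects in one call stand in for many seeds
        n_subj, p2, n_exp = 600, 0.3, 32
        d = one_level_design(n_subj, n_exp=n_exp, n_catch=0)
        profs = flat_profiles(d, p2=p2)
        tr = simulate_trials(profs, d, seed=8)
        counts = tr[tr["response"] == 2].groupby("participant_id").size()
        counts = counts.reindex(
            [p.participant_id for p in profs], fill_value=0)
        se = np.sqrt(n_exp * p2 * (1 - p2) / n_subj)
        assert abs(counts.mean() - n_exp * p2) < 3 * se

    def test_profile_design_mismatch_raises(self, mini_design):
        d_other = one_level_design(mini_design.n_participants)
        profs = flat_profiles(d_other, p2=0.1)
        with pytest.raises(ValueError):
            simulate_trials(profs, mini_design, seed=0)


class TestCounts:
    def test_counts_from_trials_matches_manual_count(self, mini_trials,
                                                     mini_design):
        counts = counts_from_trials(mini_trials)
        pid = counts["participant_id"].iloc[0]
        sub = mini_trials[(mini_trials["participant_id"] == pid)
                          & (mini_trials["level_index"] == 0)]
        exp = sub[sub["trial_type"] == "experimental"]
        row = counts[(counts["participant_id"] == pid)
                     & (counts["level_index"] == 0)].iloc[0]
        assert row["n_report2"] == (exp["response"] == 2).sum()
        assert row["n_omission"] == (exp["response"] == 0).sum()
        assert row["n_commission"] == (
            sub.loc[sub["trial_type"] == "catch", "response"] >= 1).sum()

    def test_fast_path_matches_trial_path_in_distribution(self):
        # identical moments for report-2 counts under the two samplers
        n_subj, p2, pom = 400, 0.25, 0.1
        d = one_level_design(n_subj, n_exp=32, n_catch=8)
        profs = flat_profiles(d, p2=p2, p_com=0.05, p_om=pom)
        via_trials = counts_from_trials(simulate_trials(profs, d, seed=21))
        direct = simulate_counts(profs, d, seed=22)
        for col, p in [("n_report2", p2), ("n_omission", pom),
                       ("n_commission", 0.05)]:
            n = 32 if col != "n_commission" else 8
            se = np.sqrt(n * p * (1 - p) / n_subj)
            assert abs(via_trials[col].mean() - n * p) < 4 * se
            assert abs(direct[col].mean() - n * p) < 4 * se


class TestValidateTrials:
    def test_valid_table_passes(self, mini_trials, mini_design):
        assert validate_trials(mini_trials, mini_design) == []

    def test_bad_response_named_by_row(self, mini_trials, mini_design):
        bad = mini_trials.copy()
        bad.loc[7, "response"] = 3
        msgs = validate_trials(bad, mini_design)
        assert any("row 7" in m and "response" in m for m in msgs)

    def test_inconsistent_presentation_flagged(self, mini_trials, mini_design):
        bad = mini_trials.copy()
        idx = bad.index[bad["trial_type"] == "catch"][0]
        bad.loc[idx, "n_presented"] = 1
        msgs = validate_trials(bad, mini_design)
        assert any("n_presented" in m for m in msgs)


def test_default_model_matches_design_factor():
    speed = default_population_model(builtin_design("exp1a"))
    opacity = default_population_model(builtin_design("exp1b"))
    assert speed.link_slope > opacity.link_slope  # per-unit scales differ
    with pytest.raises(ValueError, match="gamma"):
        default_population_model(builtin_design("exp1a"), gamma=2.0)
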