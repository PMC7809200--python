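"""Trial-level scoring: filtering, task scores, SES, reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from efspan.scoring import (
    filter_rt_trials,
    ospan_scores,
    reliability,
    ses_index,
    standardized_alpha,
    stroop_congruency_effect,
    switching_costs,
    toh_absolute_score,
)
from .conftest import rt_frame


class TestFilterRT:
    def test_constant_rts_all_retained(self):
        trials = rt_frame([500.0] * 10)
        assert len(filter_rt_trials(trials)) == 10

    def test_fast_guesses_excluded_regardless_of_distribution(self):
        trials = rt_frame([150.0] + [500.0] * 20)
        out = filter_rt_trials(trials)
        assert len(out) == 20 and (out["rt_ms"] > 200).all()

    def test_inaccurate_and_timed_out_excluded(self):
        trials = rt_frame([500.0] * 6, accurate=[True, False] * 3, timed_out=False)
        trials.loc[0, "timed_out"] = True
        assert len(filter_rt_trials(trials)) == 2

    def test_outlier_excluded_matches_direct_mean_sd_oracle(self):
        # 99 trials at 500 ms plus one far outlier; the mean/SD are computed
        # once over the full eligible set before any exclusion
        rts = np.array([500.0] * 99 + [800.0])
        m, s = rts.mean(), rts.std(ddof=1)
        keep_oracle = np.abs(rts - m) <= 2.5 * s
        assert keep_oracle.sum() == 99 and not keep_oracle[-1]
        out = filter_rt_trials(rt_frame(rts))
        assert len(out) == 99 and 800.0 not in out["rt_ms"].values

    def test_retained_trials_satisfy_contract(self):
        rng = np.random.default_rng(3)
        rts = rng.lognormal(6.8, 0.4, 80)
        trials = rt_frame(rts, accurate=rng.random(80) < 0.9)
        out = filter_rt_trials(trials)
        eligible = trials[(trials["accurate"]) & (trials["rt_ms"] > 200)]
        m, s = eligible["rt_ms"].mean(), eligible["rt_ms"].std(ddof=1)
        assert out["accurate"].all()
        assert (out["rt_ms"] > 200).all()
        assert (np.abs(out["rt_ms"] - m) <= 2.5 * s).all()
        # and nothing eligible that satisfies the window was dropped
        should_keep = eligible[np.abs(eligible["rt_ms"] - m) <= 2.5 * s]
        assert len(out) == len(should_keep)

    def test_single_eligible_trial_warns_and_skips_sd_trim(self):
        trials = rt_frame([500.0, 150.0], accurate=[True, True])
        with pytest.warns(UserWarning):
            out = filter_rt_trials(trials)
        assert len(out) == 1

    def test_empty_input_empty_output(self):
        assert filter_rt_trials(rt_frame([])).empty


class TestStroop:
    def test_identical_distributions_zero_effect(self):
        trials = pd.concat(
            [rt_frame([600.0] * 5, "congruent"), rt_frame([600.0] * 5, "incongruent")]
        )
        assert stroop_congruency_effect(trials) == 0.0

    def test_hand_arithmetic_on_log_scale(self):
        trials = pd.concat(
            [
                rt_frame(np.exp([6.8, 7.0]), "congruent"),
                rt_frame(np.exp([7.0, 7.2]), "incongruent"),
            ]
        )
        assert stroop_congruency_effect(trials) == pytest.approx(-0.2)

    def test_untransformed_flag_uses_raw_ms(self):
        trials = pd.concat(
            [rt_frame([600.0] * 4, "congruent"), rt_frame([700.0] * 4, "incongruent")]
        )
        assert stroop_congruency_effect(trials, log_transform=False) == pytest.approx(-100.0)

    def test_missing_condition_gives_missing_score(self):
        assert np.isnan(stroop_congruency_effect(rt_frame([600.0] * 4, "congruent")))

    def test_interference_monotonicity_higher_is_better(self):
        # slowing all incongruent trials strictly lowers the reversed score
        con = rt_frame([600.0, 620.0], "congruent")
        inc = rt_frame([700.0, 720.0], "incongruent")
        base = stroop_congruency_effect(pd.concat([con, inc]))
        slower = inc.assign(rt_ms=inc["rt_ms"] * 1.2)
        assert stroop_congruency_effect(pd.concat([con, slower])) < base

    def test_invariant_to_trial_order(self):
        rng = np.random.default_rng(0)
        con = rt_frame(rng.uniform(400, 900, 20), "congruent")
        inc = rt_frame(rng.uniform(400, 900, 20), "incongruent")
        trials = pd.concat([con, inc])
        shuffled = trials.sample(frac=1.0, random_state=1)
        assert stroop_congruency_effect(trials) == pytest.approx(
            stroop_congruency_effect(shuffled)
        )


def ospan_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "span", "presented", "recalled"])


class TestOSpan:
    def test_mixed_recall_counts(self):
        trials = ospan_frame(
            [("p", 2, "FH", "FH"), ("p", 3, "JKL", "JKL"), ("p", 4, "NPQR", "NXQR")]
        )
        assert ospan_scores(trials) == (5, 8)

    def test_perfect_standard_design_scores_81(self):
        rows = []
        letters = "FHJKLNP"
        for span in range(2, 8):
            for _ in range(3):
                rows.append(("p", span, letters[:span], letters[:span]))
        assert ospan_scores(ospan_frame(rows)) == (81, 81)

    def test_all_blank_scores_zero(self):
        trials = ospan_frame([("p", 3, "FHJ", "---"), ("p", 2, "KL", "--")])
        assert ospan_scores(trials) == (0, 0)

    def test_extra_recall_positions_ignored(self):
        trials = ospan_frame([("p", 2, "FH", "FHJKL")])
        # extra clicks beyond the span add nothing, and the set is not perfect
        assert ospan_scores(trials) == (0, 2)

    @given(
        st.lists(
            st.tuples(
                st.integers(2, 7),
                st.integers(0, 10**9),
            ),
            min_size=1,
            max_size=18,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partial_never_below_absolute(self, trial_seeds):
        pool = "FHJKLNPQRSTY"
        rows = []
        for span, seed in trial_seeds:
            rng = np.random.default_rng(seed)
            presented = "".join(rng.choice(list(pool), span, replace=False))
            recalled = "".join(
                rng.choice(list(pool) + ["-"]) for _ in range(rng.integers(0, span + 2))
            )
            rows.append(("p", span, presented, recalled))
        absolute, partial = ospan_scores(ospan_frame(rows))
        assert partial >= absolute >= 0


def switching_frames(single_logs, nonswitch_logs, switch_logs):
    single = rt_frame(np.exp(single_logs), "single")
    mixed = pd.concat(
        [
            rt_frame(np.exp(nonswitch_logs), "nonswitch"),
            rt_frame(np.exp(switch_logs), "switch"),
        ]
    )
    return single, mixed


class TestSwitching:
    def test_equal_means_zero_costs(self):
        single, mixed = switching_frames([6.55] * 4, [6.55] * 4, [6.55] * 4)
        assert switching_costs(single, mixed) == pytest.approx((0.0, 0.0))

    def test_hand_arithmetic_on_condition_means(self):
        single, mixed = switching_frames([6.42], [6.88], [7.21])
        sw, mx = switching_costs(single, mixed)
        assert sw == pytest.approx(-0.33)
        assert mx == pytest.approx(-0.46)

    def test_block_initial_mixed_trials_excluded(self):
        single = rt_frame([np.exp(6.5)] * 4, "single")
        mixed = pd.concat(
            [
                rt_frame([np.exp(7.0)] * 3, "nonswitch"),
                rt_frame([np.exp(7.3)] * 3, "switch"),
            ]
        )
        # put an absurd RT on a block-initial trial; it must not move the costs
        spoiled = pd.concat(
            [mixed, rt_frame([np.exp(12.0)], "switch").assign(trial_index=0)]
        )
        assert switching_costs(single, spoiled) == pytest.approx(
            switching_costs(single, mixed)
        )

    def test_missing_condition_propagates_nan(self):
        single, mixed = switching_frames([6.5] * 3, [6.9] * 3, [7.2] * 3)
        sw, mx = switching_costs(single, mixed.loc[mixed["condition"] != "switch"])
        assert np.isnan(sw) and not np.isnan(mx)
        sw2, mx2 = switching_costs(single.iloc[:0], mixed)
        assert not np.isnan(sw2) and np.isnan(mx2)

    def test_slowing_switch_trials_lowers_switch_cost_score(self):
        single, mixed = switching_frames([6.5] * 4, [6.9] * 4, [7.1] * 4)
        base_sw, base_mx = switching_costs(single, mixed)
        slowed = mixed.copy()
        slowed.loc[slowed["condition"] == "switch", "rt_ms"] *= 1.3
        sw, mx = switching_costs(single, slowed)
        assert sw < base_sw and mx == pytest.approx(base_mx)


class TestTOHScore:
    def test_perfect_five_step_trial_contributes_five(self):
        trials = pd.DataFrame(
            [("p", 0, 5, True, 0)],
            columns=["participant_id", "trial_index", "required_steps", "perfect", "error_moves"],
        )
        assert toh_absolute_score(trials) == 5

    def test_no_perfect_trials_scores_zero(self):
        trials = pd.DataFrame(
            [("p", 0, 5, False, 2), ("p", 1, 7, False, 1)],
            columns=["participant_id", "trial_index", "required_steps", "perfect", "error_moves"],
        )
        assert toh_absolute_score(trials) == 0

    def test_all_perfect_standard_design_scores_104(self):
        rows = [("p", i, s, True, 0) for i, s in enumerate([s for s in range(3, 11)] * 2)]
        trials = pd.DataFrame(
            rows,
            columns=["participant_id", "trial_index", "required_steps", "perfect", "error_moves"],
        )
        assert toh_absolute_score(trials) == 104


class TestSES:
    @pytest.mark.parametrize(
        "codes,expected", [((1, 1, 1), 3), ((6, 7, 7), 20), ((3, 4, 5), 12)]
    )
    def test_index_is_component_sum(self, codes, expected):
        assert ses_index(*codes) == expected

    def test_missing_component_gives_missing_index(self):
        assert np.isnan(ses_index(np.nan, 4, 5))

    @pytest.mark.parametrize("codes", [(0, 4, 5), (7, 4, 5), (3, 8, 5), (3, 4, 0)])
    def test_out_of_range_codes_rejected(self, codes):
        with pytest.raises(ValueError):
            ses_index(*codes)


class TestReliability:
    def test_identical_items_give_alpha_one(self):
        col = np.arange(10.0)
        m = np.column_stack([col] * 4)
        rep = reliability(m)
        assert rep.cronbach_alpha == pytest.approx(1.0)
        assert rep.avg_inter_item_r == pytest.approx(1.0)

    def test_standardized_alpha_16_items_r_02(self):
        assert standardized_alpha(16, 0.20) == pytest.approx(0.80)

    def test_raw_alpha_matches_covariance_arithmetic(self):
        m = np.array(
            [[3.0, 4.0, 3.0], [5.0, 7.0, 6.0], [1.0, 2.0, 2.0], [4.0, 4.0, 5.0]]
        )
        k = 3
        oracle = k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum() / m.sum(axis=1).var(ddof=1))
        assert reliability(m).cronbach_alpha == pytest.approx(oracle)

    def test_standardized_form_agrees_on_exchangeable_items(self):
        # equicorrelated equal-variance items: alpha from (k, mean r) should
        # track the raw covariance alpha to within sampling error
        rng = np.random.default_rng(11)
        common = rng.normal(size=500)
        m = np.column_stack([common + rng.normal(0, 1.5, 500) for _ in range(6)])
        raw = reliability(m)
        std = reliability(m, standardized=True)
        assert std.cronbach_alpha == pytest.approx(
            standardized_alpha(6, raw.avg_inter_item_r)
        )
        assert abs(std.cronbach_alpha - raw.cronbach_alpha) < 0.02

    def test_zero_variance_total_reported_missing(self):
        m = np.array([[1.0, -1.0]] * 4 + [[2.0, -2.0]] * 0)
        m = np.vstack([m, [[3.0, -3.0]]])
        rep = reliability(m)
        assert np.isnan(rep.cronbach_alpha)
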