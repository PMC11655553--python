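"""Tests of schedules, outcome realisation, sessions and cohort generation."""

import numpy as np
import pandas as pd
import pytest

from iblt.model import AgentParams
from iblt.task import (
    CohortSpec,
    make_block_schedule,
    make_session_design,
    payoff,
    realize_outcomes,
    simulate_agent,
    simulate_cohort,
)


class TestBlockSchedule:
    def test_streams_by_condition(self):
        for cond, win_flat, loss_flat in [
            ("wins-volatile", False, True),
            ("losses-volatile", True, False),
            ("both-volatile", False, False),
        ]:
            s = make_block_schedule(cond, seed=3)
            assert np.all(np.isin(s.win_p_shapeA, [0.8, 0.2, 0.5]))
            assert (s.win_p_shapeA == 0.5).all() == win_flat
            assert (s.loss_p_shapeA == 0.5).all() == loss_flat

    def test_reversals_and_segments(self):
        s = make_block_schedule("wins-volatile", seed=9)
        assert len(s.reversal_trials_win) == 3
        assert list(s.reversal_trials_win) == sorted(set(s.reversal_trials_win))
        bounds = [1, *s.reversal_trials_win, 81]
        seg_lengths = np.diff(bounds)
        assert (seg_lengths >= 14).all()
        assert all(l % 5 == 0 for l in seg_lengths)  # 80% counts integral

    def test_seeded_determinism(self):
        a = make_block_schedule("wins-volatile", seed=1)
        b = make_block_schedule("wins-volatile", seed=1)
        assert np.array_equal(a.win_p_shapeA, b.win_p_shapeA)
        assert a.reversal_trials_win == b.reversal_trials_win

    def test_infeasible_arithmetic_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_block_schedule("wins-volatile", n_trials=78, seed=0)
        with pytest.raises(ValueError, match="cannot fit"):
            make_block_schedule("wins-volatile", n_trials=80, n_reversals=5, seed=0)
        with pytest.raises(ValueError):
            make_block_schedule("wins-volatile", p_high=0.4, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_counts_overall_and_per_segment(self, seed):
        s = make_block_schedule("wins-volatile", seed=seed)
        rng = np.random.default_rng(seed + 100)
        win_a, loss_a = realize_outcomes(s, rng)
        favoured = np.where(s.win_p_shapeA == 0.8, True, False)
        assert int((win_a == favoured).sum()) == 64  # 80% of 80 exactly
        assert int(loss_a.sum()) == 40  # 50% of 80 exactly
        bounds = [0, *(np.asarray(s.reversal_trials_win) - 1), 80]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n_fav = int((win_a[lo:hi] == favoured[lo:hi]).sum())
            assert n_fav == round(0.8 * (hi - lo))

    def test_outcome_independence_in_both_volatile(self):
        """Realised win and loss assignments are uncorrelated across blocks.

        The scheduled contingency patterns themselves are partialled out, so
        the check isolates the independence of the two realisations.
        """
        rs = []
        for seed in range(200):
            s = make_block_schedule("both-volatile", seed=seed)
            win_a, loss_a = realize_outcomes(s, np.random.default_rng(10_000 + seed))
            rs.append(np.corrcoef(win_a - s.win_p_shapeA, loss_a - s.loss_p_shapeA)[0, 1])
        # mean of 200 per-block correlations; SE ~ (1/sqrt(80))/sqrt(200)
        assert abs(np.mean(rs)) < 0.025


class TestSessionDesign:
    @pytest.mark.parametrize(
        "order, expected_middle",
        [
            ("wins-first", ["wins-volatile", "losses-volatile"] * 2),
            ("losses-first", ["losses-volatile", "wins-volatile"] * 2),
        ],
    )
    def test_block_sequence(self, order, expected_middle):
        d = make_session_design("during-task", "real", order, seed=0)
        assert list(d.conditions) == ["both-volatile", *expected_middle, "both-volatile"]

    def test_stim_metadata(self):
        during = make_session_design("during-task", "real", "wins-first", seed=0)
        before = make_session_design("before-task", "real", "wins-first", seed=0)
        assert during.stim_blocks == frozenset({2, 3}) and not during.pre_task_stim
        assert before.stim_blocks == frozenset() and before.pre_task_stim

    def test_full_session_size(self):
        d = make_session_design("healthy-baseline", "sham", "wins-first", seed=4)
        trials = simulate_agent(AgentParams(0.3, 0.3, 5, 5), d, seed=5)
        assert len(trials) == 480
        assert trials.groupby("block_index").size().eq(80).all()

    def test_enum_validation(self):
        with pytest.raises(ValueError):
            make_session_design("nogroup", "real", "wins-first")
        with pytest.raises(ValueError):
            make_session_design("during-task", "maybe", "wins-first")


class TestAgentSimulation:
    def test_payoff_mapping_is_total(self):
        # all eight (choice, win_shape, loss_shape) combinations are defined
        for c in "AB":
            for w in "AB":
                for l in "AB":
                    expected = 10 * (w == c) - 10 * (l == c)
                    assert payoff(c, w, l) == expected

    def test_payoff_columns_consistent(self, session_trials):
        recomputed = session_trials.apply(
            lambda r: payoff(r.choice, r.win_shape, r.loss_shape), axis=1
        )
        assert (recomputed == session_trials.payoff).all()
        assert (session_trials.winout == (session_trials.win_shape == "A")).all()

    def test_zero_beta_agent_chooses_at_chance(self):
        d = make_session_design("during-task", "sham", "wins-first", seed=6)
        trials = simulate_agent(AgentParams(0.3, 0.3, 0.0, 0.0), d, seed=7)
        p_a = (trials.choice == "A").mean()
        assert abs(p_a - 0.5) < 3 * 0.5 / np.sqrt(480)  # within binomial error

    def test_learning_agent_tracks_win_contingency(self):
        """Across replicate agents, the win-favoured shape is chosen above chance."""
        fractions = []
        for seed in range(60):
            d = make_session_design("during-task", "sham", "wins-first", seed=seed)
            trials = simulate_agent(AgentParams(0.3, 0.3, 5.0, 5.0), d, seed=1000 + seed)
            block = trials[trials.block_index == 2]  # wins-volatile
            sched = d.blocks[1]
            favoured_a = sched.win_p_shapeA == 0.8
            chose_fav = (block.choice.to_numpy() == "A") == favoured_a
            fractions.append(chose_fav.mean())
        assert np.mean(fractions) > 0.5

    def test_seeded_determinism(self):
        d = make_session_design("during-task", "sham", "wins-first", seed=8)
        a = simulate_agent(AgentParams(0.4, 0.2, 6, 6), d, seed=9)
        b = simulate_agent(AgentParams(0.4, 0.2, 6, 6), d, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCohort:
    def test_structure_and_determinism(self, small_cohort):
        again = simulate_cohort(CohortSpec(n_subjects=6, group="during-task", seed=21))
        pd.testing.assert_frame_equal(small_cohort.trials, again.trials)
        assert small_cohort.metadata.subject_id.nunique() == 6
        # two sessions, counterbalanced stim order
        per = small_cohort.trials.groupby(["subject_id", "session"]).stim.first().unstack()
        assert set(map(tuple, per.to_numpy())) == {("sham", "real"), ("real", "sham")}

    def test_zero_injection_means_zero_true_group_difference(self):
        spec = CohortSpec(n_subjects=4, group="during-task", seed=3)
        c = simulate_cohort(spec)
        t = c.truth.merge(c.trials.drop_duplicates(["subject_id", "session"])[
            ["subject_id", "session", "stim"]], on=["subject_id", "session"])
        vol = t[t.condition == "losses-volatile"]
        by_stim = vol.groupby(["subject_id", "stim"]).alpha_loss.mean().unstack()
        assert np.allclose(by_stim["real"], by_stim["sham"])

    def test_injected_shift_moves_true_adjustment(self):
        """A -0.1 loss shift lowers the true loss adjustment by exactly 0.1."""
        base = simulate_cohort(CohortSpec(n_subjects=40, group="during-task", seed=5))
        shifted = simulate_cohort(
            CohortSpec(n_subjects=40, group="during-task", seed=5, sample_shift_loss=-0.1)
        )
        def loss_adjustment(truth):
            vol = truth[truth.condition == "losses-volatile"].groupby("subject_id").alpha_loss.mean()
            stab = truth[truth.condition == "wins-volatile"].groupby("subject_id").alpha_loss.mean()
            return (vol - stab).mean()
        diff = loss_adjustment(shifted.truth) - loss_adjustment(base.truth)
        assert diff == pytest.approx(-0.1, abs=1e-9)

    def test_infeasible_shift_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_cohort(
                CohortSpec(n_subjects=10, group="during-task", seed=1, sample_shift_loss=-0.4)
            )

    def test_stim_shift_confined_to_stimulated_blocks(self):
        c = simulate_cohort(
            CohortSpec(n_subjects=8, group="during-task", seed=9,
                       stim_shift_loss=0.1, stim_shift_win=-0.05)
        )
        t = c.truth.merge(
            c.trials.drop_duplicates(["subject_id", "session"])[["subject_id", "session", "stim"]],
            on=["subject_id", "session"],
        )
        real, sham = t[t.stim == "real"], t[t.stim == "sham"]
        merged = real.merge(sham, on=["subject_id", "block_index"], suffixes=("_r", "_s"))
        inside = merged.block_index.isin([2, 3])
        vol_loss = merged.condition_r == "losses-volatile"
        assert np.allclose(
            merged.loc[inside & vol_loss, "alpha_loss_r"]
            - merged.loc[inside & vol_loss, "alpha_loss_s"],
            0.1,
        )
        outside = ~inside
        assert np.allclose(
            merged.loc[outside, "alpha_loss_r"], merged.loc[outside, "alpha_loss_s"]
        )
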