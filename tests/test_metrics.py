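"""Stay tabulation and the learning-score contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep import (
    AgentParams,
    InvalidInputError,
    StayTable,
    TaskConfig,
    TrialRecord,
    UndefinedCellError,
    delta_scores,
    learning_scores,
    model_based_score,
    model_free_score,
    simulate_session,
    tabulate_stays,
    total_coins,
)
from twostep.metrics import CELLS


def make_log(choices, rewards, transitions, phase="drift"):
    """Hand-build a trial log; stage-2 fields are irrelevant to stay tables."""
    struct_common = {"A": 1, "B": 2}
    records = []
    for i, (c, r, t) in enumerate(zip(choices, rewards, transitions)):
        state = struct_common[c] if t == "common" else 3 - struct_common[c]
        records.append(
            TrialRecord(
                trial_index=i + 1,
                phase=phase,
                choice1=c,
                transition=t,
                state2=state,
                choice2="a",
                reward=r,
                prob_used=0.5,
            )
        )
    return records


def table_from_pct(rc, rr, uc, ur, n=100):
    return StayTable(
        n_stay={c: int(round(v * n / 100)) for c, v in zip(CELLS, (rc, rr, uc, ur))},
        n_obs={c: n for c in CELLS},
    )


class TestTabulation:
    def test_five_trial_hand_example(self):
        log = make_log(
            list("AABBB"),
            [1, 0, 1, 1, 0],
            ["common", "common", "rare", "common", "common"],
        )
        table = tabulate_stays(log)
        assert table.n_obs == {
            "rewarded_common": 2,
            "rewarded_rare": 1,
            "unrewarded_common": 1,
            "unrewarded_rare": 0,
        }
        pct = table.stay_pct
        assert pct["rewarded_common"] == 100.0
        assert pct["rewarded_rare"] == 100.0
        assert pct["unrewarded_common"] == 0.0
        assert np.isnan(pct["unrewarded_rare"])
        assert table.undefined_cells == ("unrewarded_rare",)

    def test_perfect_win_stay_lose_shift(self):
        choices, rewards, trans = ["A"], [1], ["common"]
        rng = np.random.default_rng(0)
        for i in range(60):
            choices.append(choices[-1] if rewards[-1] else ("B" if choices[-1] == "A" else "A"))
            rewards.append(int(rng.random() < 0.5))
            trans.append("common" if rng.random() < 0.7 else "rare")
        table = tabulate_stays(make_log(choices, rewards, trans))
        pct = table.stay_pct
        assert pct["rewarded_common"] == 100.0 and pct["rewarded_rare"] == 100.0
        assert pct["unrewarded_common"] == 0.0 and pct["unrewarded_rare"] == 0.0
        assert model_free_score(table) == 200.0
        assert model_based_score(table) == 0.0

    def test_counts_match_naive_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            choices = [("A", "B")[i] for i in rng.integers(0, 2, n)]
            rewards = [int(x) for x in rng.integers(0, 2, n)]
            trans = [("common", "rare")[i] for i in rng.integers(0, 2, n)]
            log = make_log(choices, rewards, trans)
            table = tabulate_stays(log)
            # oracle: explicit loop over trial pairs
            obs = {c: 0 for c in CELLS}
            stays = {c: 0 for c in CELLS}
            for t in range(1, n):
                cell = ("rewarded_" if rewards[t - 1] else "unrewarded_") + trans[t - 1]
                obs[cell] += 1
                stays[cell] += choices[t] == choices[t - 1]
            assert table.n_obs == obs and table.n_stay == stays

    def test_observation_assigned_to_phase_of_current_trial(self):
        # trial 3 is the first "stable" trial; it conditions on drift trial 2
        log = make_log(list("AAAA"), [1, 1, 1, 1], ["common"] * 4)
        records = [
            TrialRecord(
                trial_index=r.trial_index,
                phase="drift" if r.trial_index <= 2 else "stable",
                choice1=r.choice1,
                transition=r.transition,
                state2=r.state2,
                choice2=r.choice2,
                reward=r.reward,
                prob_used=r.prob_used,
            )
            for r in log
        ]
        drift = tabulate_stays(records, "drift")
        stable = tabulate_stays(records, "stable")
        assert drift.n_total == 1  # only trial 2
        assert stable.n_total == 2  # trials 3 (conditioning on drift) and 4

    def test_phase_tables_partition_whole_session(self, session_log):
        drift = tabulate_stays(session_log, "drift")
        stable = tabulate_stays(session_log, "stable")
        whole = tabulate_stays(session_log)
        for c in CELLS:
            assert drift.n_obs[c] + stable.n_obs[c] == whole.n_obs[c]
            assert drift.n_stay[c] + stable.n_stay[c] == whole.n_stay[c]
        assert whole.n_total == 299

    def test_unordered_log_rejected(self):
        log = make_log(list("AB"), [1, 0], ["common", "rare"])
        with pytest.raises(InvalidInputError):
            tabulate_stays(log[::-1])


class TestScores:
    @pytest.mark.parametrize(
        "cells,mf,mb",
        [
            ((90, 85, 40, 50), 85.0, 15.0),
            ((100, 100, 0, 0), 200.0, 0.0),
            ((100, 0, 0, 100), 0.0, 200.0),
            ((70, 70, 70, 70), 0.0, 0.0),
        ],
    )
    def test_score_formulas(self, cells, mf, mb):
        table = table_from_pct(*cells)
        assert model_free_score(table) == pytest.approx(mf)
        assert model_based_score(table) == pytest.approx(mb)

    def test_undefined_cell_raises_with_cell_name(self):
        table = StayTable(
            n_stay={c: 1 for c in CELLS},
            n_obs={**{c: 2 for c in CELLS}, "rewarded_rare": 0},
        )
        with pytest.raises(UndefinedCellError) as exc:
            model_free_score(table)
        assert "rewarded_rare" in str(exc.value)

    @given(
        pct=st.tuples(*[st.integers(0, 100) for _ in range(4)]),
        shift=st.integers(-50, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scores_are_zero_sum_contrasts(self, pct, shift):
        """Adding a constant to all four cells leaves both scores unchanged,
        and both stay within [-200, 200]."""
        table = table_from_pct(*pct, n=100)
        mf, mb = model_free_score(table), model_based_score(table)
        assert -200.0 <= mf <= 200.0 and -200.0 <= mb <= 200.0
        shifted = StayTable(
            n_stay={c: table.n_stay[c] + shift + 50 for c in CELLS},
            n_obs={c: 200 for c in CELLS},
        )
        base = StayTable(
            n_stay={c: table.n_stay[c] for c in CELLS},
            n_obs={c: 200 for c in CELLS},
        )
        delta_mf = model_free_score(shifted) - model_free_score(base)
        delta_mb = model_based_score(shifted) - model_based_score(base)
        assert delta_mf == pytest.approx(0.0, abs=1e-9)
        assert delta_mb == pytest.approx(0.0, abs=1e-9)


class TestDeltasAndCoins:
    def test_delta_is_late_minus_early(self):
        early = learning_scores(table_from_pct(80, 70, 60, 55))
        late = learning_scores(table_from_pct(85, 75, 55, 50))
        d = delta_scores(early, late)
        assert d.delta_model_free == pytest.approx(
            late.model_free - early.model_free
        )
        rev = delta_scores(late, early)
        assert rev.delta_model_free == pytest.approx(-d.delta_model_free)
        assert rev.delta_model_based == pytest.approx(-d.delta_model_based)

    def test_identical_sessions_have_zero_delta(self):
        s = learning_scores(table_from_pct(80, 70, 60, 55))
        d = delta_scores(s, s, coins_early=40, coins_late=40)
        assert d.delta_model_free == 0 and d.delta_model_based == 0
        assert d.delta_coins == 0

    def test_mismatched_phase_rejected(self):
        a = learning_scores(StayTable({c: 1 for c in CELLS}, {c: 2 for c in CELLS}, phase="drift"))
        b = learning_scores(StayTable({c: 1 for c in CELLS}, {c: 2 for c in CELLS}, phase="stable"))
        with pytest.raises(InvalidInputError):
            delta_scores(a, b)

    def test_total_coins_equals_independent_sum(self, session_log):
        for phase in ("drift", "stable", None):
            expected = sum(
                r.reward for r in session_log if phase is None or r.phase == phase
            )
            assert total_coins(session_log, phase) == expected

    def test_coin_extremes(self):
        log = make_log(list("AAAA"), [1, 1, 1, 1], ["common"] * 4)
        assert total_coins(log) == 4
        log0 = make_log(list("AAAA"), [0, 0, 0, 0], ["common"] * 4)
        assert total_coins(log0) == 0
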