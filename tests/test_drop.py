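"""Competition-drop scoring, retention filtering, z-scoring, RT drop."""

import numpy as np
import pandas as pd
import pytest

import compdrop as cd
from compdrop import ConfigurationError, DataFormatError
from compdrop.containers import CompetitionGrid

from conftest import make_drop_table


def behavior_from_configs(configs, rts=None, recalled=None):
    """Long behavior table for a single subject from configuration strings."""
    rows = []
    for item, config in enumerate(configs):
        for r, bit in enumerate(config, start=1):
            rows.append(
                {
                    "subject": 0,
                    "item": item,
                    "round": r,
                    "correct": int(bit),
                    "rt_s": rts[item][r - 1] if rts else 2.5,
                    "recalled_s3": recalled[item] if recalled else 0,
                }
            )
    return pd.DataFrame(rows)


def grid_for(behavior, probs):
    """CompetitionGrid with 1x1 grid squares holding `probs[item][round]`."""
    items = sorted(behavior["item"].unique())
    n_rounds = int(behavior["round"].max())
    values, rows = [], []
    for item in items:
        for r in range(1, n_rounds + 1):
            values.append([[probs[item][r - 1]]])
            rows.append({"subject": 0, "item": item, "round": r, "trial_type": "retrieval"})
    return CompetitionGrid(
        values=np.array(values),
        train_times=np.array([80.0]),
        test_times=np.array([0.0]),
        trials=pd.DataFrame(rows),
    )


class TestCompetitionDrop:
    def test_retention_rule_excludes_never_correct_and_r4_incorrect(self):
        behavior = behavior_from_configs(["0000", "1110", "0111", "1111"])
        probs = {i: [0.5, 0.5, 0.5, 0.5] for i in range(4)}
        table = cd.competition_drop(grid_for(behavior, probs), behavior)
        assert sorted(table.items["item"]) == [2, 3]
        assert set(table.items["configuration"]) == {"0111", "1111"}

    def test_drop_arithmetic_first_correct_minus_round4(self):
        behavior = behavior_from_configs(["0111"])
        probs = {0: [0.6, 0.8, 0.5, 0.3]}
        table = cd.competition_drop(grid_for(behavior, probs), behavior)
        # first correct round is 2: drop = 0.8 - 0.3
        assert table.drops[0, 0, 0] == pytest.approx(0.5)

    def test_constant_probabilities_give_zero_drop(self):
        behavior = behavior_from_configs(["1111", "0011"])
        probs = {0: [0.4] * 4, 1: [0.7] * 4}
        table = cd.competition_drop(grid_for(behavior, probs), behavior)
        assert np.allclose(table.drops, 0.0)

    def test_missing_behavior_for_grid_item_rejected(self):
        behavior = behavior_from_configs(["0111", "1111"])
        probs = {0: [0.5] * 4, 1: [0.5] * 4}
        grid = grid_for(behavior, probs)
        with pytest.raises(DataFormatError):
            cd.competition_drop(grid, behavior[behavior["item"] == 0])

    def test_rt_drop_column_follows_same_rule(self):
        behavior = behavior_from_configs(["0111"], rts=[[2.1, 3.0, 2.6, 2.2]])
        probs = {0: [0.5] * 4}
        table = cd.competition_drop(grid_for(behavior, probs), behavior)
        assert table.items["rt_drop"].iloc[0] == pytest.approx(3.0 - 2.2)


class TestFilterByConfiguration:
    def test_forced_0011_data_fully_retained(self):
        behavior = behavior_from_configs(["0011"] * 5)
        probs = {i: [0.5] * 4 for i in range(5)}
        table = cd.competition_drop(grid_for(behavior, probs), behavior)
        assert cd.filter_by_configuration(table, "0011").n_items == 5

    def test_match_counts_equal_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        configs = ["".join(map(str, rng.integers(0, 2, 4))) for _ in range(60)]
        configs = [c for c in configs if c[3] == "1" and "1" in c]  # retainable only
        behavior = behavior_from_configs(configs)
        probs = {i: [0.5] * 4 for i in range(len(configs))}
        table = cd.competition_drop(grid_for(behavior, probs), behavior)
        for pattern in ("0011", "0111", "1111"):
            expected = sum(c == pattern for c in configs)
            assert cd.filter_by_configuration(table, pattern).n_items == expected

    def test_no_match_warns_and_returns_empty(self):
        table = make_drop_table(n_items=10)
        with pytest.warns(UserWarning):
            out = cd.filter_by_configuration(table, "1111")
        assert out.n_items == 0

    def test_non_binary_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            cd.filter_by_configuration(make_drop_table(n_items=4), "01x1")


class TestZscoreWithinSubject:
    def test_each_subject_mean_zero_sd_one(self):
        table = make_drop_table(n_items=60, n_subjects=4, seed=6)
        z = cd.zscore_within_subject(table)
        for subject in z.items["subject"].unique():
            rows = (z.items["subject"] == subject).to_numpy()
            block = z.drops[rows]
            assert np.allclose(block.mean(axis=0), 0.0, atol=1e-12)
            assert np.allclose(block.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_two_value_hand_example_nminus1_denominator(self):
        table = make_drop_table(n_items=2, n_subjects=1, grid_shape=(1, 1), seed=7)
        table.drops[:, 0, 0] = [1.0, 3.0]
        z = cd.zscore_within_subject(table)
        assert sorted(z.drops[:, 0, 0]) == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_drop_subject_excluded(self):
        table = make_drop_table(n_items=20, n_subjects=2, seed=8)
        rows = (table.items["subject"] == 0).to_numpy()
        table.drops[rows] = 0.25
        z = cd.zscore_within_subject(table)
        assert 0 not in set(z.items["subject"])

    def test_single_item_subject_excluded(self):
        table = make_drop_table(n_items=21, n_subjects=10, seed=9)
        counts = table.items["subject"].value_counts()
        singleton = counts.index[counts == counts.min()]
        z = cd.zscore_within_subject(table)
        if (counts == 1).any():
            assert not set(singleton[counts[singleton] == 1]) & set(z.items["subject"])


class TestRtDrop:
    def test_equal_rts_give_zero(self):
        behavior = behavior_from_configs(["1111"], rts=[[2.5] * 4])
        out = cd.rt_drop(behavior)
        assert out["rt_drop"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        behavior = behavior_from_configs(["0011"], rts=[[2.0, 2.0, 3.0, 2.2]])
        out = cd.rt_drop(behavior)
        assert out["rt_drop"].iloc[0] == pytest.approx(0.8)

    def test_never_correct_excluded(self):
        behavior = behavior_from_configs(["0000", "1111"], rts=[[2.5] * 4, [2.5] * 4])
        out = cd.rt_drop(behavior)
        assert list(out["item"]) == [1]

    def test_rt_drop_null_when_rts_uncoupled_from_memory(self):
        from conftest import small_config

        # accuracy->recall coupling is silenced: it would otherwise induce an
        # indirect RT-drop association via the first-correct round index
        cfg = small_config(
            n_subjects=30, n_items_s2=40, accuracy_memory_coupling=0.0, seed=51
        )
        truth = cd.simulate_behavior(cfg)
        out = cd.rt_drop(truth.behavior_table())
        t, p = cd.rt_drop_test(out)
        assert p > 0.01  # no systematic RT-drop difference by outcome


class TestRecoveryAgainstPlantedDrop:
    def test_computed_drop_correlation_with_planted_drop_grows_with_snr(self):
        from conftest import small_config

        def recovery_r(effect):
            cfg = small_config(n_subjects=4, n_items_s2=40, effect_size=effect, seed=52)
            s1, _ = cd.simulate_session1(cfg)
            s2, truth = cd.simulate_session2(cfg)
            f1 = cd.sliding_window_features(s1)
            f2 = cd.sliding_window_features(s2)
            train_times = f1.start_times[(f1.start_times >= 120) & (f1.start_times <= 360)]
            grid = cd.transfer_by_subject(f1, f2, train_times)
            table = cd.competition_drop(grid, truth.behavior_table())
            sel = (table.test_times >= 120) & (table.test_times <= 360)
            computed = table.drops[:, :, sel].mean(axis=(1, 2))
            key = truth.items.set_index(["subject", "item"])
            planted = np.array(
                [
                    key.loc[(rec["subject"], rec["item"]), "planted_drop"]
                    for _, rec in table.items.iterrows()
                ]
            )
            return np.corrcoef(computed, planted)[0, 1]

        r_low, r_high = recovery_r(0.5), recovery_r(3.0)
        assert r_high > 0.2
        assert r_high > r_low
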