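"""Transition counts, probabilities, durations and episodes on staged epochs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepmap import hypnogram as hg
from sleepmap import synthetic as syn


def make(seq, **kw):
    return hg.Hypnogram(list(seq), **kw)


class TestCountTransitions:
    @pytest.mark.parametrize(
        "seq, expected, n_pairs",
        [
            ("WWSSW", {"WW": 1, "WS": 1, "SS": 1, "SW": 1}, 4),
            ("SSSS", {"SS": 3}, 3),
            ("WXS", {}, 0),  # both pairs touch the artifact epoch
        ],
    )
    def test_examples(self, seq, expected, n_pairs):
        counts = hg.count_transitions(make(seq))
        assert counts.n_pairs == n_pairs
        for a in "WS":
            for b in "WS":
                assert counts.count(a, b) == expected.get(a + b, 0)

    def test_window_straddling_pairs_not_counted(self):
        """Counts are additive over a partition of the day into windows."""
        hyp, _ = syn.simulate_hypnogram(seed=3)
        whole = hg.count_transitions(hyp)
        parts = [
            hg.count_transitions(hyp, hg.Window(lo, lo + 6.0)) for lo in (0, 6, 12, 18)
        ]
        total = sum(p.matrix.sum() for p in parts)
        # each window boundary drops exactly one adjacent pair
        assert whole.n_pairs - total == 3

    def test_window_outside_hypnogram_raises(self):
        with pytest.raises(hg.WindowRangeError):
            hg.count_transitions(make("WSWS"), hg.Window(0.0, 1.0))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from("WSX"), min_size=1, max_size=400))
    def test_matches_bruteforce_scan(self, seq):
        """Grid of counts equals a direct scan over adjacent pairs."""
        counts = hg.count_transitions(make(seq))
        brute = {}
        for a, b in zip(seq[:-1], seq[1:]):
            if "X" not in (a, b):
                brute[a + b] = brute.get(a + b, 0) + 1
        for a in "WS":
            for b in "WS":
                assert counts.count(a, b) == brute.get(a + b, 0)
        assert counts.n_pairs == sum(brute.values())


class TestTransitionProbability:
    def test_forced_by_definition(self):
        counts = hg.count_transitions(make("WWSSW"))
        assert hg.transition_probability(counts, "W") == 0.5
        assert hg.transition_probability(counts, "S") == 0.5

    def test_degenerate_rows_treated_as_one(self):
        counts = hg.count_transitions(make("SSSS"))
        assert hg.transition_probability(counts, "W") == 1.0
        assert hg.transition_probability(counts, "S") == 0.0
        counts = hg.count_transitions(make("WWWW"))
        assert hg.transition_probability(counts, "S") == 1.0
        assert hg.transition_probability(counts, "W") == 0.0

    def test_strict_mode_returns_nan(self):
        counts = hg.count_transitions(make("SSSS"))
        assert np.isnan(hg.transition_probability(counts, "W", degenerate="nan"))

    def test_unknown_state_raises(self):
        counts = hg.count_transitions(make("WSWS"))
        with pytest.raises(ValueError):
            hg.transition_probability(counts, "Q")

    def test_three_state_row_sums_to_one(self):
        hyp, _ = syn.simulate_three_state(n_epochs=2000, seed=4)
        counts = hg.count_transitions(hyp)
        for state in "WNR":
            row = hg.transition_probability(counts, state)
            assert set(row) == {"W", "N", "R"}
            assert all(0 <= p <= 1 for p in row.values())
            assert sum(row.values()) == pytest.approx(1.0)

    def test_parameter_recovery_three_binomial_se(self):
        p_ws, p_sw = 0.05, 0.02
        params = syn.MarkovSleepParams(p_ws, p_sw, p_ws, p_sw, n_days=3)
        hyp, _ = syn.simulate_hypnogram(params, seed=5)
        counts = hg.count_transitions(hyp)
        n_w = counts.count("W", "S") + counts.count("W", "W")
        n_s = counts.count("S", "W") + counts.count("S", "S")
        est_ws = hg.transition_probability(counts, "W")
        est_sw = hg.transition_probability(counts, "S")
        assert abs(est_ws - p_ws) < 3 * np.sqrt(p_ws * (1 - p_ws) / n_w)
        assert abs(est_sw - p_sw) < 3 * np.sqrt(p_sw * (1 - p_sw) / n_s)

    def test_bias_shrinks_with_length(self):
        """Estimator error decreases from short to long stationary chains."""
        p_ws, p_sw = 0.05, 0.02
        errors = []
        for n_days in (1, 3, 9):
            errs = []
            for seed in range(4):
                params = syn.MarkovSleepParams(p_ws, p_sw, p_ws, p_sw, n_days=n_days)
                hyp, _ = syn.simulate_hypnogram(params, seed=seed)
                counts = hg.count_transitions(hyp)
                errs.append(abs(hg.transition_probability(counts, "W") - p_ws))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]


class TestDurations:
    def test_epoch_count_times_length(self):
        hyp = make("S" * 450)
        assert hg.state_duration(hyp, None, "S") == 60.0

    def test_all_artifact_window_is_zero(self):
        hyp = make("X" * 10)
        assert hg.state_duration(hyp, None, "S") == 0.0
        assert hg.state_duration(hyp, None, "W") == 0.0

    def test_conservation_without_artifacts(self):
        hyp, _ = syn.simulate_hypnogram(seed=6)
        win = hg.Window(3.0, 17.0)
        total = hg.state_duration(hyp, win, "S") + hg.state_duration(hyp, win, "W")
        assert total == pytest.approx(14 * 60.0)


class TestEpisodes:
    def test_maximal_runs_and_mean(self):
        tab = hg.episodes(make("WSSWS"))
        sleep = tab.table[tab.table["state"] == "S"]
        assert sorted(sleep["length_epochs"]) == [1, 2]
        assert tab.mean_duration_minutes("S") == pytest.approx(1.5 * 8 / 60)

    def test_single_run_censored_both_ends(self):
        tab = hg.episodes(make("S" * 7))
        assert len(tab.table) == 1
        row = tab.table.iloc[0]
        assert row["censored_left"] and row["censored_right"]
        assert tab.mean_length_epochs("S") == 7

    def test_no_episodes_gives_nan(self):
        tab = hg.episodes(make("WWW"))
        assert np.isnan(tab.mean_duration_minutes("S"))

    def test_artifact_breaks_runs_and_reconstruction(self):
        tab = hg.episodes(make("SSXSSW"))
        sleep = tab.table[tab.table["state"] == "S"]
        assert list(sleep["length_epochs"]) == [2, 2]
        # concatenated episodes cover exactly the non-X epochs
        assert tab.table["length_epochs"].sum() == 5

    def test_geometric_run_duality(self):
        """Mean sleep bout length (epochs) x P_SW stays near 1 when stationary."""
        params = syn.MarkovSleepParams(0.05, 0.02, 0.05, 0.02, n_days=1)
        hyp, _ = syn.simulate_hypnogram(params, seed=7)
        counts = hg.count_transitions(hyp)
        p_sw = hg.transition_probability(counts, "S")
        mean_len = hg.episodes(hyp).mean_length_epochs("S")
        assert 0.9 <= mean_len * p_sw <= 1.1


class TestCollapse:
    def test_mapping(self):
        hyp3 = make("WNRN", alphabet=("W", "N", "R"))
        hyp2 = hg.collapse_three_to_two(hyp3)
        assert list(hyp2.stages) == list("WSSS")
        assert hyp2.alphabet == hg.TWO_STATE

    def test_artifacts_preserved(self):
        hyp3 = make("XXX", alphabet=("W", "N", "R"))
        assert list(hg.collapse_three_to_two(hyp3).stages) == list("XXX")

    def test_duration_conservation(self):
        hyp3, _ = syn.simulate_three_state(n_epochs=1000, seed=8)
        hyp2 = hg.collapse_three_to_two(hyp3)
        s = hg.state_duration(hyp2, None, "S")
        n = hg.state_duration(hyp3, None, "N")
        r = hg.state_duration(hyp3, None, "R")
        assert s == pytest.approx(n + r)

    def test_wrong_alphabet_raises(self):
        with pytest.raises(ValueError):
            hg.collapse_three_to_two(make("WSWS"))
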