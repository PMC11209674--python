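"""Linear models of standardized rate on transition probability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from groomcode import synthetic as syn
from groomcode.syntax import TransitionTable, count_transitions
from groomcode.transition_coding import (
    binomial_critical_count,
    cell_slope_shuffle_test,
    group_linear_fit,
    list_transitions,
    significance_counts,
    transition_observations,
    transition_probabilities_lookup,
)

from test_synthetic import uniform_exit_spec


def make_observations(cells, seed=0, n_inst=100, windows=(0.0,), slope=0.0,
                      noise=1.0):
    """Synthetic long-format observation frame with a planted slope."""
    rng = np.random.default_rng(seed)
    p_values = np.array([0.05, 0.15, 0.3, 0.5, 0.8])
    frames = []
    for uid, sl in cells.items():
        types = rng.integers(0, 5, n_inst)
        p = p_values[types]
        for w in windows:
            z = sl * p + noise * rng.standard_normal(n_inst)
            frames.append(pd.DataFrame({
                "unit_id": uid, "structure": "MI", "cell_class": "PC",
                "instance": np.arange(n_inst),
                "from_phase": "P1A",
                "to_phase": np.array(["P1A", "P1B", "P2", "P3", "P4"])[types],
                "p_trans": p, "window_center_s": w, "z": z,
            }))
    return pd.concat(frames, ignore_index=True)


class TestProbabilityLookup:
    def test_deterministic_chain_all_ones(self):
        counts = np.zeros((5, 6), dtype=int)
        counts[0, 2] = 10   # P1A -> P2 always
        counts[2, 5] = 10   # P2 -> STOP always
        lut = transition_probabilities_lookup(TransitionTable(counts))
        assert lut[("P1A", "P2")] == 1.0
        assert lut[("P2", "STOP")] == 1.0
        assert ("P1B", "P2") not in lut  # P1B never observed

    def test_uniform_chain_all_point_two(self, markov_session):
        spec = uniform_exit_spec(0.2, n_sequences=500, seed=77)
        sess = syn.generate_behavior(spec)
        lut = transition_probabilities_lookup(count_transitions([sess]))
        # generator used q = 0.2 exits and uniform 0.2 elsewhere
        vals = [v for (a, b), v in lut.items() if a != b]
        assert np.allclose(vals, 0.2, atol=0.05)

    def test_lookup_matches_generator_matrix(self, markov_session):
        table = count_transitions([markov_session])
        lut = transition_probabilities_lookup(table)
        tm = syn.DEFAULT_TRANSITION_MATRIX
        names = list(table.labels_to)
        for i, a in enumerate(table.labels_from):
            for j, b in enumerate(names):
                assert lut[(a, b)] == pytest.approx(tm[i, j], abs=0.03)


class TestGroupLinearFit:
    def test_slope_matches_closed_form_covariance_ratio(self):
        obs = make_observations({"u0": -1.5}, seed=1)
        fit = group_linear_fit(obs).iloc[0]
        x = obs["p_trans"].to_numpy()
        y = obs["z"].to_numpy()
        oracle = np.cov(x, y, ddof=0)[0, 1] / x.var()
        assert fit["slope"] == pytest.approx(oracle, abs=1e-9)

    def test_planted_slope_recovered_within_three_se(self):
        obs = make_observations({f"u{k}": -2.0 for k in range(10)}, seed=2)
        fit = group_linear_fit(obs).iloc[0]
        x = obs["p_trans"].to_numpy()
        se = 1.0 / (x.std() * np.sqrt(len(x)))
        assert abs(fit["slope"] - (-2.0)) < 3 * se

    def test_constant_p_trans_skipped(self):
        obs = make_observations({"u0": 0.0}, seed=3)
        obs["p_trans"] = 0.3
        fits = group_linear_fit(obs)
        assert fits.empty
        assert fits.attrs["skipped"].iloc[0]["reason"] == "constant_p_trans"

    def test_null_population_p_value_calibration(self):
        obs = make_observations({f"u{k}": 0.0 for k in range(5)}, seed=4,
                                windows=np.arange(40))
        fits = group_linear_fit(obs)
        assert (fits["p_value"] < 0.05).mean() < 0.15


class TestCellSlopeShuffleTest:
    def test_planted_negative_coders_detected_with_power(self):
        tests = cell_slope_shuffle_test(
            make_observations({f"u{k}": -2.0 for k in range(30)}, seed=5),
            n_shuffles=500, seed=6,
        )
        detected = tests["significant"] & (tests["sign"] == "negative")
        assert detected.mean() >= 0.9

    def test_null_cells_flagged_at_five_percent(self):
        tests = cell_slope_shuffle_test(
            make_observations({f"u{k}": 0.0 for k in range(40)}, seed=7,
                              windows=np.arange(5)),
            n_shuffles=400, seed=8,
        )
        assert tests["significant"].mean() == pytest.approx(0.05, abs=0.03)

    def test_exchangeability_yields_uniform_pvalues(self):
        """On pre-shuffled data the rank of the observed slope inside the
        shuffle distribution is uniform (KS test)."""
        rng = np.random.default_rng(9)
        obs = make_observations({f"u{k}": 0.0 for k in range(60)}, seed=10)
        ranks = []
        for uid, g in obs.groupby("unit_id"):
            x = g["p_trans"].to_numpy()
            y = g["z"].to_numpy()
            xc = x - x.mean()
            sl = xc @ (y - y.mean()) / (xc**2).sum()
            null = np.array([
                (xc[rng.permutation(len(x))] @ (y - y.mean())) / (xc**2).sum()
                for _ in range(99)
            ])
            ranks.append((null < sl).mean())
        assert stats.kstest(ranks, "uniform").pvalue > 0.01

    def test_constant_p_trans_cell_excluded(self):
        obs = make_observations({"u0": 0.0}, seed=11)
        obs["p_trans"] = 0.4
        obs["to_phase"] = "P2"
        tests = cell_slope_shuffle_test(obs, n_shuffles=50, seed=12)
        assert tests.empty

    def test_full_stack_prob_coder_archetypes_detected(self, separated_session):
        """Negative probability coders planted in spike trains come out
        significant at the transition window."""
        archs = [syn.UnitArchetype(kind="prob_coder", baseline_hz=5,
                                   slope_hz_per_prob=-15, intercept_hz=20)] * 10
        units = syn.generate_spikes(archs, separated_session, seed=13)
        obs = transition_observations(units, [separated_session],
                                      window_centers=np.array([0.0]))
        tests = cell_slope_shuffle_test(obs, n_shuffles=500, seed=14)
        hit = tests["significant"] & (tests["sign"] == "negative")
        assert hit.sum() >= 8


class TestSignificanceCounts:
    def test_critical_count_matches_brute_force(self):
        from math import comb

        def brute(n, chance, alpha):
            for k in range(n + 1):
                tail = sum(comb(n, j) * chance**j * (1 - chance) ** (n - j)
                           for j in range(k, n + 1))
                if tail <= alpha:
                    return k
            return n + 1

        for n in (20, 50, 100, 200):
            assert binomial_critical_count(n) == brute(n, 0.05, 0.001)
        assert binomial_critical_count(100) == 14

    def test_symmetric_planting_not_significant(self):
        cells = {f"u{k}": (-2.0 if k % 2 else 2.0) for k in range(30)}
        tests = cell_slope_shuffle_test(
            make_observations(cells, seed=15, windows=np.round(np.arange(-1, 1.01, 0.2), 10)),
            n_shuffles=300, seed=16,
        )
        _, comp = significance_counts(tests)
        assert comp["p_bonferroni"].iloc[0] > 0.05

    def test_negative_excess_detected(self):
        cells = {f"u{k}": (-2.0 if k % 3 else 0.0) for k in range(30)}
        tests = cell_slope_shuffle_test(
            make_observations(cells, seed=17, windows=np.round(np.arange(-1, 1.01, 0.2), 10)),
            n_shuffles=300, seed=18,
        )
        counts, comp = significance_counts(tests)
        assert (counts["n_negative"] > counts["n_positive"]).all()
        assert comp["p_raw"].iloc[0] < 0.05

    def test_counts_carry_critical_threshold(self):
        tests = cell_slope_shuffle_test(
            make_observations({f"u{k}": 0.0 for k in range(25)}, seed=19),
            n_shuffles=100, seed=20,
        )
        counts, _ = significance_counts(tests)
        assert (counts["critical_count"] == binomial_critical_count(25)).all()


class TestListTransitions:
    def test_counts_and_phases(self, tiny_session):
        df = list_transitions([tiny_session])
        assert len(df) == 3  # (P1A->P2), (P1B->P2), (P2->P3)
        assert set(zip(df["from_phase"], df["to_phase"])) == {
            ("P1A", "P2"), ("P1B", "P2"), ("P2", "P3")
        }
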