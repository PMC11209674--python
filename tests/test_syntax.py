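"""Transition statistics, bias, Markov validation, entropy, durations."""

import numpy as np
import pandas as pd
import pytest

from groomcode import synthetic as syn, syntax
from groomcode.core import PHASE_NAMES
from groomcode.syntax import (
    TransitionTable,
    binomial_outside_tail,
    count_transitions,
    duration_stats,
    exit_chi_square,
    ngram_predicted_counts,
    sequence_length_ci,
    shannon_profile,
    simulate_markov,
    transition_bias,
)

from conftest import make_session


class TestCountTransitions:
    def test_single_two_phase_sequence(self):
        sess = make_session([["P1A", "P2"]])
        t = count_transitions([sess])
        assert t.counts[0, 2] == 1          # P1A -> P2
        assert t.counts[2, 5] == 1          # P2 -> STOP
        assert t.totals[0] == 1 and t.totals[2] == 1
        assert t.n_transitions == 2

    def test_conditional_row_with_single_successor(self):
        sess = make_session([["P1A", "P2"], ["P1A", "P2"]])
        t = count_transitions([sess])
        assert t.conditional[0, 2] == 1.0
        assert t.conditional[0, [0, 1, 3, 4, 5]].sum() == 0.0

    def test_row_sums_equal_totals(self, markov_session):
        t = count_transitions([markov_session])
        np.testing.assert_array_equal(t.counts.sum(axis=1), t.totals)
        assert np.all(np.diag(t.counts[:, :5]) == 0)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="no sequences"):
            t = count_transitions([])
        assert t.counts.sum() == 0


class TestTransitionBias:
    def test_exact_independence_gives_zero_beta(self):
        counts = np.outer([40, 5, 35, 10, 10], [25, 5, 30, 10, 10, 20])
        b = transition_bias(TransitionTable(counts), n_sim=10, seed=0)
        assert np.abs(b.beta).max() < 1e-12

    def test_two_symbol_alternation_gives_log2(self):
        t = TransitionTable(np.array([[0, 10], [10, 0]]), ("A", "B"), ("A", "B"))
        b = transition_bias(t, n_sim=10, seed=0)
        assert b.beta[0, 1] == pytest.approx(np.log(2))
        assert b.beta[1, 0] == pytest.approx(np.log(2))

    def test_zero_joint_count_is_minus_infinity(self):
        counts = np.outer([40, 5, 35, 10, 10], [25, 5, 30, 10, 10, 20])
        counts[0, 1] = 0
        b = transition_bias(TransitionTable(counts), n_sim=100, seed=0)
        assert b.beta[0, 1] == -np.inf

    def test_false_positive_rate_matches_ci_level(self):
        """Under an independence generator the over/under flag rate is
        about 1 - ci_level per cell."""
        rng = np.random.default_rng(42)
        px = np.array([0.4, 0.05, 0.35, 0.1, 0.1])
        py = np.array([0.25, 0.05, 0.3, 0.1, 0.1, 0.2])
        P = np.outer(px, py)
        P /= P.sum()
        n_flag = n_cell = 0
        for r in range(30):
            counts = rng.multinomial(4000, P.ravel()).reshape(5, 6)
            b = transition_bias(TransitionTable(counts), n_sim=400,
                                ci_level=0.90, seed=r)
            n_flag += (b.flag != "none").sum()
            n_cell += b.flag.size
        assert abs(n_flag / n_cell - 0.10) < 0.03

    def test_flags_follow_ci_exclusion_of_zero(self, markov_session):
        t = count_transitions([markov_session])
        b = transition_bias(t, n_sim=300, seed=1)
        over = b.flag == "over"
        assert np.all(b.ci_low[over] > 0)
        none = b.flag == "none"
        assert np.all((b.ci_low[none] <= 0) & (b.ci_high[none] >= 0))

    def test_chain_steps_overrepresented_in_default_generator(self, markov_session):
        """The syntactic-chain transitions planted in the generator come out
        flagged as overrepresented."""
        t = count_transitions([markov_session])
        b = transition_bias(t, n_sim=500, seed=2)
        i = {n: k for k, n in enumerate(PHASE_NAMES)}
        assert b.flag[i["P1B"], i["P2"]] == "over"
        assert b.flag[i["P3"], i["P4"]] == "over"


class TestSimulateMarkov:
    def test_all_stop_rows_give_length_one(self):
        cond = np.zeros((5, 6))
        cond[:, 5] = 1.0
        lengths = simulate_markov(cond, np.full(5, 0.2), 1000, seed=0)
        assert np.all(lengths == 1)

    def test_uniform_exit_mean_length(self):
        q = 0.2
        cond = np.full((5, 6), (1 - q) / 4)
        cond[np.arange(5), np.arange(5)] = 0.0
        cond[:, 5] = q
        lengths = simulate_markov(cond, np.full(5, 0.2), 200_000, seed=1)
        se = np.sqrt((1 - q) / q**2 / lengths.size)
        assert abs(lengths.mean() - 5.0) < 3 * se

    def test_two_seeds_agree_in_distribution(self):
        cond = syn.DEFAULT_TRANSITION_MATRIX
        start = syn.DEFAULT_START_DISTRIBUTION
        h = []
        for seed in (1, 2):
            lengths = simulate_markov(cond, start, 10**6, seed=seed)
            counts = np.bincount(np.minimum(lengths, 60), minlength=61)[1:]
            h.append(counts / counts.sum())
        tv = 0.5 * np.abs(h[0] - h[1]).sum()
        assert tv < 0.01

    def test_nonterminating_chain_rejected(self):
        cond = np.zeros((5, 6))
        cond[0, 2] = 1.0   # P1A -> P2
        cond[2, 0] = 1.0   # P2 -> P1A (closed loop, no STOP)
        cond[[1, 3, 4], 5] = 1.0
        with pytest.raises(ValueError, match="STOP"):
            simulate_markov(cond, np.array([1, 0, 0, 0, 0.0]), 100, seed=0)


class TestSequenceLengthCI:
    def test_degenerate_model_band(self):
        lengths = np.ones(500 * 20, dtype=int)
        v = sequence_length_ci(lengths, observed_lengths=np.ones(500, dtype=int),
                               set_size=500, n_sets=20)
        assert v.ci_low[0] == v.ci_high[0] == 500
        assert np.all(v.ci_high[1:] == 0)
        assert v.n_outside == 0

    def test_observed_equal_to_model_mean_has_no_misses(self):
        rng = np.random.default_rng(3)
        lengths = rng.geometric(0.25, size=470 * 200)
        # an "observed" draw from the same model stays inside the band
        observed = rng.geometric(0.25, size=470)
        v = sequence_length_ci(lengths, observed, set_size=470, n_sets=200)
        assert v.n_outside <= 3
        assert 0 <= v.tail_prob <= 1

    def test_band_width_scales_with_sqrt_set_size(self):
        rng = np.random.default_rng(4)
        lengths = rng.geometric(0.25, size=400 * 400)
        v1 = sequence_length_ci(lengths[: 100 * 400], set_size=100, n_sets=400)
        v4 = sequence_length_ci(lengths, set_size=400, n_sets=400)
        # compare relative half-widths on well-populated bins
        w1 = (v1.ci_high - v1.ci_low)[:6]
        w4 = (v4.ci_high - v4.ci_low)[:6]
        ratio = (w4 / np.maximum(w1, 1e-12)).mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_insufficient_lengths_rejected(self):
        with pytest.raises(ValueError, match="longer simulation"):
            sequence_length_ci(np.ones(100), set_size=470, n_sets=2000)


class TestBinomialOutsideTail:
    def test_paper_value_18_percent(self):
        assert binomial_outside_tail(60, 5, 0.05) == pytest.approx(0.1803, abs=5e-4)

    def test_zero_outside_is_certain(self):
        assert binomial_outside_tail(37, 0, 0.05) == 1.0

    def test_matches_brute_force_pmf_summation(self):
        from math import comb

        for n, k, p in [(10, 3, 0.1), (60, 5, 0.05), (25, 7, 0.2), (100, 0, 0.01)]:
            brute = sum(
                comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
            )
            assert binomial_outside_tail(n, k, p) == pytest.approx(brute, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_outside_tail(10, 11, 0.05)
        with pytest.raises(ValueError):
            binomial_outside_tail(10, 2, 1.5)


class TestShannonProfile:
    def test_order_zero_is_log2_of_five(self, tiny_session):
        prof = shannon_profile([tiny_session], max_order=2)
        assert prof.H_bits[0] == pytest.approx(np.log2(5))

    def test_iid_uniform_sequences_are_flat_at_log2_5(self):
        rng = np.random.default_rng(11)
        seqs = []
        # iid symbols, long sequences: ~1e5 tuples
        for k in range(100):
            seqs.append([PHASE_NAMES[i] for i in rng.integers(0, 5, size=1000)])
        sess = make_session(seqs, durations=0.5, gap=1.0)
        prof = shannon_profile([sess], max_order=3)
        assert abs(prof.H_bits[1] - np.log2(5)) < 0.01
        assert abs(prof.H_bits[2] - np.log2(5)) < 0.02

    def test_first_order_markov_signature(self, markov_session):
        """H2 drops below H1 (the planted first-order dependence) and
        H3 stays within estimator bias of H2."""
        prof = shannon_profile([markov_session], max_order=4)
        assert prof.H_bits[2] < prof.H_bits[1] - 0.2
        assert abs(prof.H_bits[3] - prof.H_bits[2]) < 0.05

    def test_short_sequences_omit_high_orders(self):
        sess = make_session([["P1A", "P2"]])
        with pytest.warns(UserWarning, match="order"):
            prof = shannon_profile([sess], max_order=5)
        assert prof.order.max() == 2


class TestNgramPredictedCounts:
    def test_deterministic_chain_support(self):
        sess = make_session([["P1B", "P2", "P3", "P4"]] * 10)
        table = count_transitions([sess])
        out = ngram_predicted_counts(table, [sess], orders=(3,))
        df = out[3]
        observed_support = set(df.loc[df["observed_n"] > 0, "ngram"])
        predicted_support = set(df.loc[df["predicted_p"] > 0, "ngram"])
        assert observed_support == {"P1B-P2-P3", "P2-P3-P4"}
        assert observed_support <= predicted_support

    def test_self_consistency_rank_correlation(self, markov_session):
        table = count_transitions([markov_session])
        out = ngram_predicted_counts(table, [markov_session], orders=(3,))
        assert out[3].attrs["spearman_rho"] > 0.9

    def test_impossible_transition_has_zero_both_ways(self, markov_session):
        table = count_transitions([markov_session])
        df = ngram_predicted_counts(table, [markov_session], orders=(3,))[3]
        row = df[df["ngram"] == "P1A-P1A-P2"].iloc[0]  # self-transition: impossible
        assert row["predicted_p"] == 0.0 and row["observed_n"] == 0

    def test_unsupported_order_rejected(self, tiny_session):
        table = count_transitions([tiny_session])
        with pytest.raises(ValueError, match="order"):
            ngram_predicted_counts(table, [tiny_session], orders=(2,))


class TestExitChiSquare:
    def test_equal_exit_proportions_give_null_result(self):
        counts = np.zeros((5, 6), dtype=int)
        for i in range(5):
            counts[i, (i + 1) % 5] = 80
            counts[i, 5] = 20
        chi2, df, p = exit_chi_square(TransitionTable(counts))
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_df_is_phases_minus_one(self, markov_session):
        _, df, p = exit_chi_square(count_transitions([markov_session]))
        assert df == 4
        assert p < 0.001  # planted exit probabilities differ strongly

    def test_two_phase_table_matches_hand_computation(self):
        """Exits 10/100 vs 30/100: Pearson chi-square = 12.5 by hand
        (expected exits 20 each: 2*(100/20 + 100/80))."""
        counts = np.array([[0, 90, 10], [70, 0, 30]])
        t = TransitionTable(counts, ("A", "B"), ("A", "B", "STOP"))
        chi2, df, _ = exit_chi_square(t)
        assert df == 1
        assert chi2 == pytest.approx(12.5, abs=1e-9)


class TestDurationStats:
    def test_bonferroni_factor_is_number_of_pairs(self, markov_session):
        res = duration_stats([markov_session], include_pauses=True)
        n_pairs = len(res.ks_tests)
        assert n_pairs == 15  # 6 categories incl. STOP pauses
        row = res.ks_tests.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(
            min(1.0, row["p_raw"] * n_pairs)
        )

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(5)
        seqs = [["P1A", "P2"] for _ in range(200)]
        sess = make_session(seqs, durations=list(rng.lognormal(0, 0.3, 200)))
        res = duration_stats([sess], include_pauses=False)
        row = res.ks_tests.iloc[0]
        assert row["p_bonferroni"] > 0.05

    def test_median_ratio_two_detected_with_power(self):
        """Log-normal durations with median ratio 2, n = 500: KS significant
        at the Bonferroni-corrected 0.001 level."""
        rng = np.random.default_rng(6)
        rows = []
        for _ in range(500):
            rows.append(["P1A", "P2"])
        d = []
        for k in range(500):
            d.append(None)
        # build events by hand with per-phase durations
        from groomcode.core import BehaviorSession, GroomingSequence, Phase, PhaseEvent
        t = 0.0
        seqs = []
        for k in range(500):
            d1 = float(rng.lognormal(0.0, 0.5))
            d2 = float(rng.lognormal(np.log(2), 0.5))
            seqs.append(GroomingSequence(f"q{k}", [
                PhaseEvent(Phase.P1A, t, t + d1),
                PhaseEvent(Phase.P2, t + d1, t + d1 + d2),
            ]))
            t += d1 + d2 + 5.0
        sess = BehaviorSession("s", "a", seqs, t)
        res = duration_stats([sess], include_pauses=False)
        assert res.ks_tests.iloc[0]["p_bonferroni"] < 0.001

    def test_single_animal_skips_animal_factor(self, markov_session):
        with pytest.warns(UserWarning, match="animal factor"):
            res = duration_stats([markov_session], include_pauses=False)
        assert "C(phase)" in res.anova.index

    def test_two_way_anova_with_two_animals(self, markov_session):
        other = syn.generate_behavior(
            syn.BehaviorGeneratorSpec(n_sequences=200, seed=55,
                                      session_id="s2", animal_id="rat-02")
        )
        res = duration_stats([markov_session, other], include_pauses=False)
        assert {"C(phase)", "C(animal)"} <= set(res.anova.index)
        assert res.anova.loc["C(phase)", "PR(>F)"] < 0.001
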