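"""Boundary-cell taxonomy, proportion tests, phase-transition coding."""

import itertools

import numpy as np
import pytest
from scipy import stats

from groomcode import synthetic as syn
from groomcode.events import (
    _boundary_class,
    classify_boundary_cells,
    in_phase_anova,
    proportion_ztest,
    single_transition_preference,
    transition_event_modulation,
    upcoming_phase_preference,
)
from groomcode.peth import PETH, TRANSITION_SPEC
from groomcode.pipeline import build_boundary_peths, in_phase_rates


def make_peth(z, bin_width=0.125, n_events=20, uid="u"):
    z = np.asarray(z, float)
    n = len(z)
    centers = (np.arange(n) - n // 2 + 0.5) * bin_width
    return PETH(uid, "event", centers, z, z, n_events, 0.0, 1.0)


class TestBoundaryClassLogic:
    """The taxonomy's exclusivity constraints hold for every epoch pattern."""

    @pytest.mark.parametrize(
        "pattern", list(itertools.product([False, True], repeat=4))
    )
    def test_invariants_for_all_epoch_patterns(self, pattern):
        sig = dict(zip(("pre_onset", "post_onset", "pre_end", "post_end"), pattern))
        cls = _boundary_class(sig)
        if cls == "bracketer":
            assert sig["pre_onset"] and sig["post_end"]
        elif cls == "stopper":
            assert sig["pre_end"] and not sig["post_end"]
        elif cls == "starter":
            assert sig["pre_onset"]
            assert not (sig["pre_end"] or sig["post_end"])
        # starters and stoppers are mutually exclusive by construction
        assert not (cls == "starter" and sig["pre_end"])

    def test_all_four_epochs_significant_is_bracketer(self):
        sig = dict.fromkeys(("pre_onset", "post_onset", "pre_end", "post_end"), True)
        assert _boundary_class(sig) == "bracketer"


class TestClassifyBoundaryCells:
    def test_planted_archetypes_recovered(self, separated_session):
        n = 30
        archs = (
            [syn.UnitArchetype(kind="starter", bump_amplitude_hz=15)] * n
            + [syn.UnitArchetype(kind="stopper", bump_amplitude_hz=15)] * n
            + [syn.UnitArchetype(kind="bracketer", bump_amplitude_hz=15)] * n
        )
        units = syn.generate_spikes(archs, separated_session, seed=31)
        sp, ep = build_boundary_peths(units, [separated_session])
        profs = classify_boundary_cells(sp, ep)
        classes = {p.unit_id: p.boundary_class for p in profs}
        uids = [u.unit_id for u in units]
        for i, kind in enumerate(("starter", "stopper", "bracketer")):
            got = [classes[u] for u in uids[i * n:(i + 1) * n]]
            assert got.count(kind) >= 0.8 * n, (kind, got)

    def test_missing_peth_excluded_with_warning(self, separated_session):
        units = syn.generate_spikes([syn.UnitArchetype()] * 2, separated_session,
                                    seed=32)
        sp, ep = build_boundary_peths(units, [separated_session])
        del ep[units[0].unit_id]
        with pytest.warns(UserWarning, match="missing"):
            profs = classify_boundary_cells(sp, ep)
        assert len(profs) == 1


class TestProportionZtest:
    def test_printed_cortical_in_vs_pc_comparison(self):
        _, p = proportion_ztest(25, 58, 42, 158)
        assert round(p, 3) == 0.020

    def test_printed_mi_vs_rest_comparison(self):
        _, p = proportion_ztest(29, 191, 15, 198)
        assert round(p, 3) == 0.018

    def test_identical_proportions_give_zero(self):
        z, p = proportion_ztest(7, 20, 7, 20)
        assert z == 0.0 and p == 1.0

    def test_z_squared_equals_chi_square(self):
        for k1, n1, k2, n2 in [(25, 58, 42, 158), (3, 10, 8, 12), (50, 80, 20, 90)]:
            z, _ = proportion_ztest(k1, n1, k2, n2)
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            chi2 = stats.chi2_contingency(table, correction=False)[0]
            assert z**2 == pytest.approx(chi2, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ztest(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_ztest(11, 10, 1, 10)


class TestTransitionEventModulation:
    def _peths(self, n_mi_mod, n_mi, n_rest, seed=0, bins=151):
        rng = np.random.default_rng(seed)
        peths, structures = {}, {}
        for k in range(n_mi + n_rest):
            uid = f"u{k:03d}"
            z = rng.standard_normal(bins)
            if k < n_mi_mod:
                z[bins // 2 - 2: bins // 2 + 3] += 6.0  # bump at t=0
            peths[uid] = make_peth(z, bin_width=0.04, uid=uid)
            structures[uid] = "MI" if k < n_mi else "DLS"
        return peths, structures

    def test_planted_mi_modulation_detected(self):
        peths, structures = self._peths(n_mi_mod=15, n_mi=50, n_rest=50)
        df = transition_event_modulation(peths, structures)
        mi = df[df["structure"] == "MI"].iloc[0]
        rest = df[df["structure"] == "DLS"].iloc[0]
        assert mi["fraction"] > rest["fraction"]
        assert df.attrs["mi_vs_rest"][1] < 0.05

    def test_no_planting_is_not_significant(self):
        peths, structures = self._peths(n_mi_mod=0, n_mi=50, n_rest=50, seed=1)
        df = transition_event_modulation(peths, structures)
        assert df.attrs["mi_vs_rest"][1] > 0.05


class TestUpcomingPhasePreference:
    def _peths_by_phase(self, prefer=None, bins=151, seed=0, n_events=10):
        rng = np.random.default_rng(seed)
        out = {}
        for ph in ("P1A", "P2", "P3"):
            z = rng.standard_normal(bins) * 0.5
            if prefer == ph:
                pre = (np.arange(bins) - bins // 2 + 0.5) * 0.04
                z[(pre >= -0.2) & (pre < 0)] += 5.0
            out[ph] = make_peth(z, bin_width=0.04, n_events=n_events)
        return out

    def test_planted_preference_recovered(self):
        by_cell = {f"u{k}": self._peths_by_phase(prefer="P2", seed=k)
                   for k in range(20)}
        prefs, summary = upcoming_phase_preference(by_cell)
        recovered = [p for p in prefs if p.preferred_phase == "P2" and p.significant]
        assert len(recovered) >= 0.9 * 20
        assert summary["binomial_p"] < 0.01

    def test_two_phases_above_threshold_not_counted(self):
        by_cell = {"u0": {
            "P1A": make_peth(np.full(151, 3.0), 0.04),
            "P2": make_peth(np.full(151, 3.0), 0.04),
        }}
        prefs, _ = upcoming_phase_preference(by_cell)
        assert not prefs[0].significant

    def test_rare_phases_excluded(self):
        by_cell = {"u0": {
            "P1A": make_peth(np.zeros(151), 0.04, n_events=10),
            "P2": make_peth(np.zeros(151), 0.04, n_events=2),   # < 5 instances
        }}
        prefs, summary = upcoming_phase_preference(by_cell)
        assert summary["n_cells"] == 0  # only one usable phase left

    def test_null_population_binomial_p_not_small(self):
        by_cell = {f"u{k}": self._peths_by_phase(prefer=None, seed=100 + k)
                   for k in range(40)}
        _, summary = upcoming_phase_preference(by_cell)
        assert summary["binomial_p"] > 0.01


class TestInPhaseAnova:
    def test_planted_tuning_detected_with_power(self, separated_session):
        n = 30
        archs = [syn.UnitArchetype(kind="phase_tuned", baseline_hz=8,
                                   tuning={"P2": 2.0})] * n
        units = syn.generate_spikes(archs, separated_session, seed=41)
        rates = in_phase_rates(units, [separated_session])
        df = in_phase_anova(rates)
        assert (df["p"] < 0.001).mean() >= 0.9

    def test_identical_rates_give_f_near_one(self):
        rng = np.random.default_rng(42)
        rates = {f"u{k}": {ph: rng.poisson(5, 30).astype(float)
                           for ph in ("P1A", "P2", "P3")} for k in range(100)}
        df = in_phase_anova(rates)
        assert df["F"].mean() == pytest.approx(1.0, abs=0.3)
        assert (df["p"] < 0.001).mean() < 0.05

    def test_single_phase_cell_excluded(self):
        df = in_phase_anova({"u0": {"P1A": np.ones(10)}})
        assert df.empty


class TestSingleTransitionPreference:
    def _cell(self, prefer=None, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for pair in [("P1A", "P2"), ("P1B", "P2"), ("P2", "P3"), ("P3", "P4")]:
            z = rng.standard_normal(151) * 0.5
            if prefer == pair:
                pre = (np.arange(151) - 75 + 0.5) * 0.04
                z[(pre >= -0.2) & (pre < 0)] += 5.0
            out[pair] = make_peth(z, bin_width=0.04)
        return out

    def test_pair_specific_cell_detected_and_dissociated(self):
        """A cell responding only before P1A->P2 is found by the restricted
        analysis, and its preference names that exact pair."""
        cells = {f"u{k}": self._cell(prefer=("P1A", "P2"), seed=k) for k in range(15)}
        df = single_transition_preference(cells)
        assert (df["significant"]).mean() >= 0.9
        assert (df["preferred_transition"] == "P1A->P2").all()

    def test_uniform_response_not_flagged(self):
        cells = {"u0": {
            pair: make_peth(np.full(151, 2.5), 0.04)
            for pair in [("P1A", "P2"), ("P1B", "P2"), ("P2", "P3")]
        }}
        df = single_transition_preference(cells)
        assert not df["significant"].any()

    def test_too_few_types_excluded(self):
        cells = {"u0": {("P1A", "P2"): make_peth(np.zeros(151), 0.04),
                        ("P2", "P3"): make_peth(np.zeros(151), 0.04)}}
        df = single_transition_preference(cells)
        assert df.empty
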