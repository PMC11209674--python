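"""End-to-end orchestration: simulate -> analyze -> report.

``run_all`` executes the full pipeline on synthetic data (or on ethogram
/ spike tables read from disk), writes every result table as CSV plus a
machine-readable ``results.json`` echoing all parameters, and is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import io as gio
from . import peth as peth_mod
from . import population as pop
from . import synthetic as syn
from . import syntax
from . import transition_coding as tc
from . import waveforms as wf
from .core import BehaviorSession, Structure, Hemisphere, Unit

logger = logging.getLogger("groomcode")

STAGES = ("behavior", "syntax", "classify", "peth", "events", "population", "transcode")


@dataclass
class RunConfig:
    """All pipeline parameters with their default analysis values.

    Every field is echoed into ``results.json`` for provenance.
    """

    seed: int = 0
    # --- synthetic generation -------------------------------------------
    n_sequences: int = 300
    n_units: int = 200
    baseline_hz: float = 5.0
    bump_amplitude_hz: float = 20.0
    bump_sigma_s: float = 0.2
    prob_coder_slope_hz: float = 15.0
    # fractions of unit archetypes (remainder is null)
    frac_starter: float = 0.10
    frac_stopper: float = 0.10
    frac_bracketer: float = 0.10
    frac_transition_event: float = 0.10
    frac_phase_tuned: float = 0.10
    frac_prob_coder: float = 0.15
    # --- input files (used instead of simulation when given) ------------
    ethogram_path: str | None = None
    spikes_path: str | None = None
    units_path: str | None = None
    # --- behavior syntax -------------------------------------------------
    bias_n_sim: int = 1000
    bias_ci_level: float = 0.95
    markov_n_transitions: int = 500_000
    markov_set_size: int | None = None     # default: observed sequence count
    markov_n_sets: int = 1000
    entropy_max_order: int = 5
    # --- PETH / event coding ---------------------------------------------
    boundary_epoch_s: float = 1.0
    z_threshold: float = 2.0
    max_transition_events: int = 300       # subsample cap for PETH analyses
    # --- decoding ---------------------------------------------------------
    decode_window_s: float = 1.5
    decode_max_transitions: int = 150
    decode_max_units: int = 40
    inclusion_grid: tuple[int, ...] = (1, 2, 5, 10, 20)
    inclusion_repeats: int = 20
    # --- transition coding ------------------------------------------------
    coding_window_centers: tuple[float, float, float] = (-3.0, 3.0, 0.1)
    coding_window_width_s: float = 0.5
    n_shuffles: int = 1000
    coder_window_range_s: tuple[float, float] = (-1.0, 1.0)
    # --- stages -------------------------------------------------------------
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "inclusion_grid", "coding_window_centers",
                    "coder_window_range_s"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def default_archetypes(config: RunConfig) -> list[syn.UnitArchetype]:
    """The default synthetic unit population.

    Units cycle through the four structures and two hemispheres.
    Transition-event archetypes are planted preferentially in MI and
    negative probability coders in MI and DMS, mirroring where those
    signals were strongest in recordings; prob-coder sign alternates 2:1
    negative:positive.
    """
    n = config.n_units
    kinds: list[str] = []
    for frac, kind in [
        (config.frac_starter, "starter"),
        (config.frac_stopper, "stopper"),
        (config.frac_bracketer, "bracketer"),
        (config.frac_transition_event, "transition_event"),
        (config.frac_phase_tuned, "phase_tuned"),
        (config.frac_prob_coder, "prob_coder"),
    ]:
        kinds += [kind] * int(round(frac * n))
    kinds += ["null"] * (n - len(kinds))
    kinds = kinds[:n]

    structures = [Structure.MI, Structure.RFA, Structure.DLS, Structure.DMS]
    archetypes = []
    prob_i = 0
    for k, kind in enumerate(kinds):
        if kind == "transition_event":
            struct = Structure.MI
        elif kind == "prob_coder":
            struct = [Structure.MI, Structure.DMS][prob_i % 2]
        else:
            struct = structures[k % 4]
        sign = -1.0 if (kind == "prob_coder" and prob_i % 3 != 2) else 1.0
        if kind == "prob_coder":
            prob_i += 1
        arch = syn.UnitArchetype(
            kind=kind,
            baseline_hz=config.baseline_hz,
            bump_amplitude_hz=config.bump_amplitude_hz,
            bump_sigma_s=config.bump_sigma_s,
            tuning={"P2": 2.0} if kind == "phase_tuned" else None,
            slope_hz_per_prob=sign * config.prob_coder_slope_hz if kind == "prob_coder" else 0.0,
            intercept_hz=(config.bump_amplitude_hz if sign < 0 else 2.0)
            if kind == "prob_coder" else 0.0,
            structure=struct,
            hemisphere=Hemisphere.LEFT if k % 2 == 0 else Hemisphere.RIGHT,
            cell_class="IN" if k % 4 == 3 else "PC",
        )
        archetypes.append(arch)
    return archetypes


# ---------------------------------------------------------------------------
# event-set helpers shared by pipeline stages


def boundary_events(sessions: list[BehaviorSession]) -> tuple[np.ndarray, np.ndarray]:
    """Sequence onset and end times across sessions."""
    starts = np.array([s.start_s for sess in sessions for s in sess.sequences])
    ends = np.array([s.end_s for sess in sessions for s in sess.sequences])
    return starts, ends


def grooming_intervals(sessions: list[BehaviorSession]) -> list[tuple[float, float]]:
    return [(s.start_s, s.end_s) for sess in sessions for s in sess.sequences]


def build_boundary_peths(
    units: list[Unit], sessions: list[BehaviorSession],
    spec: peth_mod.PETHSpec = peth_mod.BOUNDARY_SPEC,
) -> tuple[dict[str, peth_mod.PETH], dict[str, peth_mod.PETH]]:
    starts, ends = boundary_events(sessions)
    start_peths = {
        u.unit_id: peth_mod.build_peth(u, starts, spec, event_type="sequence_start")
        for u in units
    }
    end_peths = {
        u.unit_id: peth_mod.build_peth(u, ends, spec, event_type="sequence_end")
        for u in units
    }
    return start_peths, end_peths


def _subsample(df: pd.DataFrame, cap: int, seed: int) -> pd.DataFrame:
    if len(df) <= cap:
        return df
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    idx = np.sort(rng.choice(len(df), size=cap, replace=False))
    return df.iloc[idx].reset_index(drop=True)


def build_transition_peths(
    units: list[Unit], sessions: list[BehaviorSession],
    cap: int, seed: int,
    spec: peth_mod.PETHSpec = peth_mod.TRANSITION_SPEC,
) -> tuple[dict[str, peth_mod.PETH], dict[str, dict[str, peth_mod.PETH]], pd.DataFrame]:
    """Pooled and upcoming-phase-conditioned transition PETHs."""
    trans = tc.list_transitions(sessions)
    trans = _subsample(trans, cap, seed)
    valid = grooming_intervals(sessions)
    pooled = {
        u.unit_id: peth_mod.build_peth(
            u, trans["t_s"].to_numpy(), spec, valid_intervals=valid,
            event_type="phase_transition",
        )
        for u in units
    }
    by_phase: dict[str, dict[str, peth_mod.PETH]] = {}
    for u in units:
        by_phase[u.unit_id] = {}
        for ph, g in trans.groupby("to_phase"):
            by_phase[u.unit_id][ph] = peth_mod.build_peth(
                u, g["t_s"].to_numpy(), spec, valid_intervals=valid,
                event_type=f"transition_to_{ph}",
            )
    return pooled, by_phase, trans


def decode_rate_tensor(
    units: list[Unit], trans: pd.DataFrame,
    window_s: float, bin_width_s: float = 0.04,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """trials x units x bins normalized rate tensor around transitions."""
    nb = int(round(2 * window_s / bin_width_s))
    edges = -window_s + np.arange(nb + 1) * bin_width_s
    centers = (edges[:-1] + edges[1:]) / 2
    t0 = trans["t_s"].to_numpy()
    abs_edges = t0[:, None] + edges[None, :]
    rates = np.empty((len(t0), len(units), nb))
    for k, u in enumerate(units):
        counts = np.diff(np.searchsorted(u.spike_times_s, abs_edges), axis=1)
        r = counts / bin_width_s
        sd = r.std()
        rates[:, k, :] = (r - r.mean()) / sd if sd > 0 else 0.0
    return rates, trans["to_phase"].to_numpy(), centers


def in_phase_rates(
    units: list[Unit], sessions: list[BehaviorSession], window_s: float = 0.44,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-unit, per-phase firing rates in the mid-phase window."""
    mids: dict[str, list[float]] = {}
    for sess in sessions:
        for seq in sess.sequences:
            for e in seq.events:
                mids.setdefault(e.phase.value, []).append((e.start_s + e.end_s) / 2)
    out: dict[str, dict[str, np.ndarray]] = {}
    for u in units:
        out[u.unit_id] = {}
        for ph, centers in mids.items():
            c = np.asarray(centers)
            counts = (
                np.searchsorted(u.spike_times_s, c + window_s / 2)
                - np.searchsorted(u.spike_times_s, c - window_s / 2)
            )
            out[u.unit_id][ph] = counts / window_s
    return out


# ---------------------------------------------------------------------------
# run_all


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write all outputs to ``outdir``.

    Returns the results bundle (also written to ``results.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    results: dict = {"config": config.to_dict(), "stages": {}}
    try:
        sessions: list[BehaviorSession] | None = None
        units: list[Unit] | None = None
        archetypes = None

        # ---- behavior --------------------------------------------------
        if config.ethogram_path:
            sessions = gio.read_ethogram_sessions(config.ethogram_path)
            logger.info("read %d session(s) from %s", len(sessions), config.ethogram_path)
        elif "behavior" in config.stages:
            spec = syn.BehaviorGeneratorSpec(
                n_sequences=config.n_sequences, seed=config.seed
            )
            sessions = [syn.generate_behavior(spec)]
            gio.write_ethogram(sessions, outdir / "ethogram.csv")
            logger.info("generated %d sequences", config.n_sequences)
        if sessions is None:
            raise ValueError(
                "no behavioral input: enable the 'behavior' stage or set ethogram_path"
            )
        needs_units = bool(set(config.stages) & {"classify", "peth", "events",
                                                 "population", "transcode"})
        if config.spikes_path and config.units_path:
            units = gio.read_units(config.spikes_path, config.units_path)
        elif needs_units:
            archetypes = default_archetypes(config)
            units = syn.generate_spikes(archetypes, sessions[0], seed=config.seed)
            wfs = syn.generate_waveforms([a.cell_class for a in archetypes],
                                         seed=config.seed)
            for u, w in zip(units, wfs):
                u.waveform = w
            gio.write_units(units, outdir / "spikes.csv", outdir / "units.csv")
            truth = pd.DataFrame({
                "unit_id": [u.unit_id for u in units],
                "kind": [a.kind for a in archetypes],
                "cell_class": [a.cell_class for a in archetypes],
            })
            gio.write_table(truth, outdir / "unit_ground_truth.csv")
            logger.info("generated %d units", len(units))

        table = syntax.count_transitions(sessions)

        # ---- syntax ------------------------------------------------------
        if "syntax" in config.stages:
            gio.write_table(table, outdir / "transitions.csv")
            bias = syntax.transition_bias(
                table, n_sim=config.bias_n_sim, ci_level=config.bias_ci_level,
                seed=config.seed,
            )
            gio.write_table(bias, outdir / "bias.csv")
            profile = syntax.shannon_profile(sessions, config.entropy_max_order)
            gio.write_table(profile, outdir / "entropy.csv")

            observed_lengths = np.array(
                [len(s) for sess in sessions for s in sess.sequences]
            )
            set_size = config.markov_set_size or observed_lengths.size
            model_lengths = syntax.simulate_markov(
                np.nan_to_num(table.conditional), table.totals / table.totals.sum(),
                max(config.markov_n_transitions, set_size * config.markov_n_sets * 10),
                seed=config.seed,
            )
            validation = syntax.sequence_length_ci(
                model_lengths, observed_lengths,
                set_size=set_size, n_sets=config.markov_n_sets,
            )
            with open(outdir / "markov_validation.json", "w") as fh:
                json.dump({
                    "length_bins": validation.length_bins.tolist(),
                    "ci_low": validation.ci_low.tolist(),
                    "ci_high": validation.ci_high.tolist(),
                    "observed": validation.observed.tolist(),
                    "n_outside": validation.n_outside,
                    "n_points": validation.n_points,
                    "tail_prob": validation.tail_prob,
                }, fh, indent=1)
            chi2, df_, p = syntax.exit_chi_square(table)
            ngrams = syntax.ngram_predicted_counts(table, sessions)
            dur = syntax.duration_stats(sessions)
            gio.write_table(dur.ks_tests, outdir / "durations.csv")
            results["stages"]["syntax"] = {
                "n_transitions": table.n_transitions,
                "exit_chi2": chi2, "exit_df": df_, "exit_p": p,
                "entropy_bits": profile.H_bits.tolist(),
                "markov_n_outside": validation.n_outside,
                "markov_tail_prob": validation.tail_prob,
                "ngram_spearman_rho": {
                    str(n): df.attrs["spearman_rho"] for n, df in ngrams.items()
                },
                "n_bias_over": int((bias.flag == "over").sum()),
                "n_bias_under": int((bias.flag == "under").sum()),
            }
            logger.info("syntax stage done")

        # ---- classify ----------------------------------------------------
        cell_classes: dict[str, str] = {}
        if "classify" in config.stages and units is not None:
            ct = wf.classify_units_by_structure(units, seed=config.seed)
            gio.write_table(ct, outdir / "cell_types.csv")
            cell_classes = dict(zip(ct["unit_id"], ct["putative_type"]))
            results["stages"]["classify"] = {
                "n_pc": int((ct["putative_type"] == "PC").sum()),
                "n_in": int((ct["putative_type"] == "IN").sum()),
                "n_unclassified": int((ct["putative_type"] == "unclassified").sum()),
            }
            logger.info("classify stage done")

        # ---- peth (boundary) ----------------------------------------------
        start_peths = end_peths = None
        if "peth" in config.stages and units is not None:
            start_peths, end_peths = build_boundary_peths(units, sessions)
            Z = np.vstack([start_peths[u.unit_id].z for u in units])
            gio.write_table(
                pd.DataFrame(
                    Z, columns=[f"{t:.3f}" for t in peth_mod.BOUNDARY_SPEC.bin_centers]
                ).assign(unit_id=[u.unit_id for u in units]),
                outdir / "peth_start.csv",
            )
            profiles = ev.classify_boundary_cells(
                start_peths, end_peths, epoch_s=config.boundary_epoch_s,
                z_threshold=config.z_threshold,
            )
            struct_of = {u.unit_id: u.structure.value for u in units}
            bc = pd.DataFrame({
                "unit_id": [p.unit_id for p in profiles],
                "structure": [struct_of[p.unit_id] for p in profiles],
                "boundary_class": [p.boundary_class for p in profiles],
            })
            gio.write_table(bc, outdir / "boundary_classes.csv")
            sig_bins, _ = peth_mod.population_bin_test(list(start_peths.values()))
            counts = bc["boundary_class"].value_counts().to_dict()
            results["stages"]["peth"] = {
                "boundary_class_counts": counts,
                "fraction_boundary_modulated": float(
                    (bc["boundary_class"] != "none").mean()
                ),
                "n_significant_population_bins_start": int(sig_bins.sum()),
            }
            logger.info("peth stage done")

        # ---- events ----------------------------------------------------------
        trans_sub = None
        pooled_tpeths = by_phase_tpeths = None
        if "events" in config.stages and units is not None:
            pooled_tpeths, by_phase_tpeths, trans_sub = build_transition_peths(
                units, sessions, config.max_transition_events, config.seed,
            )
            struct_of = {u.unit_id: u.structure.value for u in units}
            mod = ev.transition_event_modulation(pooled_tpeths, struct_of,
                                                 z_threshold=config.z_threshold)
            prefs, pref_summary = ev.upcoming_phase_preference(by_phase_tpeths)
            gio.write_table(
                pd.DataFrame({
                    "unit_id": [p.unit_id for p in prefs],
                    "preferred_phase": [p.preferred_phase for p in prefs],
                    "significant": [p.significant for p in prefs],
                }),
                outdir / "phase_preference.csv",
            )
            anova_df = ev.in_phase_anova(in_phase_rates(units, sessions), struct_of)
            proportions = {
                "transition_modulation": mod.to_dict(orient="records"),
                "mi_vs_rest": list(mod.attrs.get("mi_vs_rest", (None, None))),
                "upcoming_phase": pref_summary,
                "in_phase_anova_significant": int((anova_df["p"] < 0.001).sum()),
            }
            with open(outdir / "proportions.json", "w") as fh:
                json.dump(proportions, fh, indent=1, default=float)
            results["stages"]["events"] = proportions
            logger.info("events stage done")

        # ---- population -------------------------------------------------------
        if "population" in config.stages and units is not None:
            if start_peths is None:
                start_peths, end_peths = build_boundary_peths(units, sessions)
            Zmat = np.vstack([start_peths[u.unit_id].z for u in units]).T
            traj = pop.pca_trajectories(Zmat)
            gio.write_table(
                pd.DataFrame(traj.projections, columns=["PC1", "PC2", "PC3"]),
                outdir / "pca_projections.csv",
            )
            if trans_sub is None:
                trans_sub = _subsample(tc.list_transitions(sessions),
                                       config.max_transition_events, config.seed)
            dec_trans = _subsample(trans_sub, config.decode_max_transitions, config.seed)
            dec_units = units[: config.decode_max_units]
            rates, labels, centers = decode_rate_tensor(
                dec_units, dec_trans, config.decode_window_s
            )
            decoding = pop.lda_decode_timecourse(rates, labels, centers)
            gio.write_table(
                pd.DataFrame({
                    "bin_center_s": decoding.bin_centers_s,
                    "correct_fraction": decoding.correct_fraction,
                }),
                outdir / "decoding_timecourse.csv",
            )
            # inclusion curves from the 100 ms pre-transition window
            pre_bin = (centers >= -0.1) & (centers < 0.0)
            X_pre = rates[:, :, pre_bin].mean(axis=2)
            curves = []
            for struct in sorted({u.structure.value for u in dec_units}):
                mask = np.array([u.structure.value == struct for u in dec_units])
                curve = pop.neuron_inclusion_curve(
                    X_pre, labels, mask, list(config.inclusion_grid),
                    repeats=config.inclusion_repeats, seed=config.seed,
                )
                for i, n in enumerate(curve.n_units):
                    curves.append((struct, int(n), curve.mean_correct[i],
                                   curve.sem_correct[i], curve.chance_mean[i]))
            gio.write_table(
                pd.DataFrame(curves, columns=["structure", "n_units", "mean_correct",
                                              "sem_correct", "chance_mean"]),
                outdir / "inclusion_curves.csv",
            )
            results["stages"]["population"] = {
                "pca_explained_variance": traj.explained_variance_ratio.tolist(),
                "decoding_peak": float(decoding.correct_fraction.max()),
                "decoding_peak_time_s": float(
                    decoding.bin_centers_s[decoding.correct_fraction.argmax()]
                ),
                "decoding_chance": decoding.chance,
                "decoding_threshold": decoding.threshold,
            }
            logger.info("population stage done")

        # ---- transition coding -------------------------------------------------
        if "transcode" in config.stages and units is not None:
            lo, hi, step = config.coding_window_centers
            centers = np.round(np.arange(lo, hi + 1e-9, step), 10)
            obs = tc.transition_observations(
                units, sessions, table, centers, config.coding_window_width_s,
                cell_classes=cell_classes or None,
            )
            fits = tc.group_linear_fit(obs)
            gio.write_table(fits, outdir / "group_fits.csv")
            slopes = tc.cell_slope_shuffle_test(
                obs, n_shuffles=config.n_shuffles, seed=config.seed,
            )
            gio.write_table(slopes, outdir / "cell_slopes.csv")
            counts, comparisons = tc.significance_counts(
                slopes, window_range_s=config.coder_window_range_s,
            )
            gio.write_table(counts, outdir / "significance_counts.csv")
            near = counts[counts["window_center_s"].abs() <= 1.0]
            results["stages"]["transcode"] = {
                "n_cells_tested": int(slopes["unit_id"].nunique()),
                "max_negative_coders": int(near["n_negative"].max()) if len(near) else 0,
                "max_positive_coders": int(near["n_positive"].max()) if len(near) else 0,
                "signed_rank": comparisons.to_dict(orient="records"),
            }
            logger.info("transcode stage done")

        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=1, default=float)
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# report


def report(outdir: str | Path) -> str:
    """Human-readable summary of a results bundle."""
    outdir = Path(outdir)
    lines = ["groomcode results", "=" * 40]
    results_path = outdir / "results.json"
    if not results_path.exists():
        return "no results.json found; run the pipeline first"
    with open(results_path) as fh:
        results = json.load(fh)
    stages = results.get("stages", {})

    trans_path = outdir / "transitions.csv"
    if trans_path.exists():
        df = pd.read_csv(trans_path)
        lines += ["", "Transition counts N(Y<-X):", df.to_string(index=False)]
    else:
        lines += ["", "[behavior syntax output absent]"]
    if "syntax" in stages:
        s = stages["syntax"]
        lines += [
            f"exit chi-square: chi2={s['exit_chi2']:.1f} df={s['exit_df']} p={s['exit_p']:.2g}",
            "conditional uncertainty (bits) by order: "
            + ", ".join(f"{h:.3f}" for h in s["entropy_bits"]),
            f"sequence-length check: {s['markov_n_outside']} bins outside the 95% band "
            f"(binomial tail p={s['markov_tail_prob']:.2f})",
            f"bias flags: {s['n_bias_over']} over / {s['n_bias_under']} under",
        ]
    if "peth" in stages:
        p = stages["peth"]
        lines += ["", "Boundary-cell classes: "
                  + ", ".join(f"{k}={v}" for k, v in p["boundary_class_counts"].items()),
                  f"fraction boundary-modulated: {p['fraction_boundary_modulated']:.3f}"]
    else:
        lines += ["", "[neural boundary output absent]"]
    if "population" in stages:
        q = stages["population"]
        lines += [f"decoding peak {q['decoding_peak']:.2f} at "
                  f"t={q['decoding_peak_time_s']:+.2f} s "
                  f"(chance {q['decoding_chance']:.2f})"]
    if "transcode" in stages:
        t = stages["transcode"]
        lines += [f"P(trans) coders near transition: up to {t['max_negative_coders']} "
                  f"negative / {t['max_positive_coders']} positive of "
                  f"{t['n_cells_tested']} cells"]
    return "\n".join(lines)
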