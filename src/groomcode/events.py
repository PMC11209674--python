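"""Single-cell boundary and phase-transition coding.

Boundary-cell taxonomy (from sequence-onset and sequence-end PETHs,
|Z| > 2 within 1 s epochs):

* bracketer -- significant pre-onset AND post-end modulation (marks the
  outer boundaries of a whole sequence);
* stopper -- significant pre-end modulation without post-end modulation;
* starter -- significant pre-onset modulation without any end modulation.

Starters and stoppers are mutually exclusive by construction; a cell
significant in every epoch is a bracketer (post-end rule dominates).

Also here: the two-proportion z-test used for the population proportion
comparisons, transition-event modulation, upcoming-phase preference with
its binomial population test, the in-phase one-way ANOVA, and the
restricted single-transition-type preference analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .core import Unit
from .peth import PETH

__all__ = [
    "ModulationProfile",
    "PhasePreference",
    "classify_boundary_cells",
    "proportion_ztest",
    "transition_event_modulation",
    "upcoming_phase_preference",
    "in_phase_anova",
    "single_transition_preference",
]

EPOCHS = ("pre_onset", "post_onset", "pre_end", "post_end")


def kernel_run_length(peth: PETH) -> int:
    """Bins spanned by the smoothing kernel's FWHM (at least 1).

    Any real rate modulation, once convolved with the Gaussian kernel,
    extends over at least the kernel FWHM; requiring a supra-threshold
    run of that length rejects single-bin noise excursions without
    costing sensitivity.
    """
    if peth.spec is None:
        return 1
    fwhm = 2.355 * peth.spec.smooth_sigma_s
    return max(1, int(round(fwhm / peth.spec.bin_width_s)))


def epoch_significant(
    peth: PETH, t0: float, t1: float,
    z_threshold: float = 2.0, min_consecutive: int | None = None,
) -> bool:
    """Significant modulation within [t0, t1): at least ``min_consecutive``
    consecutive bins with |Z| above threshold.

    ``min_consecutive=1`` is the permissive single-bin criterion; the
    default (``None``) requires a run one smoothing-kernel FWHM long
    (see :func:`kernel_run_length`), which damps the false positives the
    single-bin rule accumulates over the many correlated bins of an
    epoch.
    """
    if min_consecutive is None:
        min_consecutive = kernel_run_length(peth)
    m = (peth.bin_centers_s >= t0) & (peth.bin_centers_s < t1)
    above = np.abs(peth.z[m]) > z_threshold
    if min_consecutive <= 1:
        return bool(above.any())
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= min_consecutive:
            return True
    return False


@dataclass
class ModulationProfile:
    """Epoch-wise boundary modulation and the derived class of one cell."""

    unit_id: str
    epoch_max_abs_z: dict[str, float]
    epoch_significant: dict[str, bool]
    boundary_class: str  # starter | stopper | bracketer | none


def _boundary_class(sig: dict[str, bool]) -> str:
    if sig["pre_onset"] and sig["post_end"]:
        return "bracketer"
    if sig["pre_end"] and not sig["post_end"]:
        return "stopper"
    if sig["pre_onset"] and not (sig["pre_end"] or sig["post_end"]):
        return "starter"
    return "none"


def classify_boundary_cells(
    start_peths: dict[str, PETH],
    end_peths: dict[str, PETH],
    epoch_s: float = 1.0,
    z_threshold: float = 2.0,
    min_consecutive: int | None = None,
) -> list[ModulationProfile]:
    """Assign starter / stopper / bracketer classes from boundary PETHs.

    Epoch significance requires ``min_consecutive`` consecutive bins
    (default: one smoothing-kernel FWHM worth of bins) with |Z| above
    ``z_threshold`` within the 1 s epochs [-epoch, 0) / [0, epoch)
    around sequence onset and end (see :func:`epoch_significant`).
    Units missing either PETH are excluded with a warning.
    """
    out: list[ModulationProfile] = []
    missing = sorted(set(start_peths) ^ set(end_peths))
    if missing:
        warnings.warn(f"units missing one boundary PETH, excluded: {missing}", stacklevel=2)
    for uid in sorted(set(start_peths) & set(end_peths)):
        sp, ep = start_peths[uid], end_peths[uid]
        windows = {
            "pre_onset": (sp, -epoch_s, 0.0),
            "post_onset": (sp, 0.0, epoch_s),
            "pre_end": (ep, -epoch_s, 0.0),
            "post_end": (ep, 0.0, epoch_s),
        }
        maxz = {k: p.max_abs_z(t0, t1) for k, (p, t0, t1) in windows.items()}
        sig = {
            k: epoch_significant(p, t0, t1, z_threshold, min_consecutive)
            for k, (p, t0, t1) in windows.items()
        }
        out.append(ModulationProfile(uid, maxz, sig, _boundary_class(sig)))
    return out


def proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, two_sided: bool = True
) -> tuple[float, float]:
    """Two-proportion z-test with pooled variance.

    ``z = (p1 - p2) / sqrt( p (1-p) (1/n1 + 1/n2) )`` with
    ``p = (k1 + k2) / (n1 + n2)``; two-sided normal p by default.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * ndtr(-abs(z)) if two_sided else float(ndtr(-z))
    return float(z), float(p)


def transition_event_modulation(
    peths: dict[str, PETH],
    structures: dict[str, str],
    near_window_s: float = 0.2,
    z_threshold: float = 2.0,
    reference_structure: str = "MI",
    min_cells: int = 5,
) -> pd.DataFrame:
    """Fraction of cells per structure modulated at phase transitions.

    A cell counts as transition-modulated when |Z| exceeds the threshold
    within ``+-near_window_s`` of t = 0 of its all-transitions PETH.
    The reference structure (MI) is compared against the pooled rest via
    the two-proportion z-test; the comparison is attached to the frame
    as ``df.attrs["mi_vs_rest"] = (z, p)``.
    """
    rows = []
    sig_of: dict[str, bool] = {}
    for uid, p in peths.items():
        sig_of[uid] = p.max_abs_z(-near_window_s, near_window_s + 1e-9) > z_threshold
    for struct in sorted(set(structures.values())):
        uids = [u for u in peths if structures.get(u) == struct]
        k = sum(sig_of[u] for u in uids)
        n = len(uids)
        rows.append((struct, k, n, k / n if n else float("nan"), n < min_cells))
    df = pd.DataFrame(rows, columns=["structure", "n_modulated", "n_cells",
                                     "fraction", "low_n"])
    ref = df[df["structure"] == reference_structure]
    rest = df[df["structure"] != reference_structure]
    if len(ref) == 1 and rest["n_cells"].sum() > 0 and int(ref["n_cells"].iloc[0]) > 0:
        z, p = proportion_ztest(
            int(ref["n_modulated"].iloc[0]), int(ref["n_cells"].iloc[0]),
            int(rest["n_modulated"].sum()), int(rest["n_cells"].sum()),
        )
        df.attrs["mi_vs_rest"] = (z, p)
    return df


@dataclass
class PhasePreference:
    """Pre-transition preference of one cell for a specific upcoming phase."""

    unit_id: str
    preferred_phase: str | None
    window_mean_z: dict[str, float]
    significant: bool


def _single_phase_preference(
    mean_z: dict[str, float], z_threshold: float
) -> tuple[str | None, bool]:
    above = [ph for ph, z in mean_z.items() if np.isfinite(z) and abs(z) > z_threshold]
    if len(above) == 1:
        return above[0], True
    return None, False


def upcoming_phase_preference(
    peths_by_phase: dict[str, dict[str, PETH]],
    window: tuple[float, float] = (-0.2, 0.0),
    control_window: tuple[float, float] = (-1.6, -1.4),
    z_threshold: float = 2.0,
    min_instances: int = 5,
    min_phases: int = 2,
) -> tuple[list[PhasePreference], dict]:
    """Single-upcoming-phase preference with a binomial population test.

    ``peths_by_phase[unit_id][phase]`` holds the transition PETH
    conditioned on the upcoming phase.  A cell prefers a phase when
    exactly one upcoming phase has |mean Z| above threshold in the 200 ms
    window immediately before the transition; phases with fewer than
    ``min_instances`` transitions are excluded, and cells observed under
    fewer than ``min_phases`` phases are dropped.  The chance rate is the
    same statistic evaluated in the control window 1.5 s earlier (still
    within grooming); the binomial test asks whether the number of
    preferring cells exceeds that chance rate.
    """
    prefs: list[PhasePreference] = []
    n_sig_control = 0
    n_cells = 0
    for uid in sorted(peths_by_phase):
        by_phase = {
            ph: p for ph, p in peths_by_phase[uid].items()
            if p.n_events >= min_instances
        }
        if len(by_phase) < min_phases:
            continue
        n_cells += 1
        mean_z = {ph: p.mean_z(*window) for ph, p in by_phase.items()}
        ctrl_z = {ph: p.mean_z(*control_window) for ph, p in by_phase.items()}
        preferred, significant = _single_phase_preference(mean_z, z_threshold)
        _, ctrl_sig = _single_phase_preference(ctrl_z, z_threshold)
        n_sig_control += int(ctrl_sig)
        prefs.append(PhasePreference(uid, preferred, mean_z, significant))

    k = sum(p.significant for p in prefs)
    chance = n_sig_control / n_cells if n_cells else float("nan")
    if n_cells:
        # guard a zero chance estimate with half a count
        p_chance = max(chance, 0.5 / n_cells)
        binom_p = float(stats.binomtest(k, n_cells, p_chance, alternative="greater").pvalue)
    else:
        binom_p = float("nan")
    summary = {
        "n_cells": n_cells,
        "n_significant": k,
        "chance_rate": chance,
        "binomial_p": binom_p,
    }
    return prefs, summary


def in_phase_anova(
    rates_by_phase: dict[str, dict[str, np.ndarray]],
    structures: dict[str, str] | None = None,
    min_instances: int = 5,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """One-way ANOVA of in-phase firing rate by current phase, per cell.

    ``rates_by_phase[unit_id][phase]`` holds per-instance firing rates
    measured in the mid-phase window.  Cells need at least two phases
    with ``min_instances`` instances each.  Returns per-cell F and p; the
    per-structure significant-cell counts at ``alpha`` are attached as
    ``df.attrs["structure_summary"]``.
    """
    rows = []
    for uid in sorted(rates_by_phase):
        groups = [
            np.asarray(v, dtype=float)
            for v in rates_by_phase[uid].values()
            if len(v) >= min_instances
        ]
        if len(groups) < 2:
            continue
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(
            np.concatenate(groups)
        ) == 0:
            f, p = float("nan"), float("nan")
        else:
            f, p = stats.f_oneway(*groups)
        rows.append((uid, float(f), float(p),
                     structures.get(uid) if structures else None))
    df = pd.DataFrame(rows, columns=["unit_id", "F", "p", "structure"])
    if structures:
        summary = (
            df.assign(significant=df["p"] < alpha)
            .groupby("structure")["significant"]
            .agg(["sum", "count"])
            .rename(columns={"sum": "n_significant", "count": "n_cells"})
        )
        df.attrs["structure_summary"] = summary
    return df


def single_transition_preference(
    peths_by_pair: dict[str, dict[tuple[str, str], PETH]],
    window: tuple[float, float] = (-0.2, 0.0),
    control_window: tuple[float, float] = (-1.6, -1.4),
    z_threshold: float = 2.0,
    min_instances: int = 5,
    min_types: int = 3,
) -> pd.DataFrame:
    """Cells preferring one specific phase-pair transition type.

    For each cell with at least ``min_types`` transition types (each
    observed at least ``min_instances`` times), the preferred type's mean
    pre-transition Z is compared against the median over all types; the
    cell is flagged when the difference exceeds the Z threshold.  The
    chance rate of the same statistic in the earlier control window and a
    binomial test are attached as ``df.attrs["binomial"]``.
    """
    rows = []
    n_ctrl_sig = 0
    for uid in sorted(peths_by_pair):
        by_pair = {
            pair: p for pair, p in peths_by_pair[uid].items()
            if p.n_events >= min_instances
        }
        if len(by_pair) < min_types:
            continue
        resp = {pair: p.mean_z(*window) for pair, p in by_pair.items()}
        ctrl = {pair: p.mean_z(*control_window) for pair, p in by_pair.items()}
        vals = np.array(list(resp.values()))
        best_pair = max(resp, key=lambda k: resp[k])
        excess = resp[best_pair] - float(np.median(vals))
        sig = excess > z_threshold
        cvals = np.array(list(ctrl.values()))
        n_ctrl_sig += int(cvals.max() - np.median(cvals) > z_threshold)
        rows.append((uid, f"{best_pair[0]}->{best_pair[1]}", excess, sig))
    df = pd.DataFrame(rows, columns=["unit_id", "preferred_transition",
                                     "excess_z", "significant"])
    n = len(df)
    if n:
        chance = max(n_ctrl_sig / n, 0.5 / n)
        k = int(df["significant"].sum())
        df.attrs["binomial"] = {
            "n_cells": n,
            "n_significant": k,
            "chance_rate": n_ctrl_sig / n,
            "binomial_p": float(
                stats.binomtest(k, n, chance, alternative="greater").pvalue
            ),
        }
    return df
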