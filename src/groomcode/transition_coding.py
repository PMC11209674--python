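"""Firing rate as a linear function of transition probability.

The headline neural-behavioral link: around each within-sequence phase
transition, each cell's standardized rate Z is regressed on P(trans),
the fitted conditional probability of the transition that actually
occurred.  Group-level ordinary least squares runs per
(structure x cell class) in 500 ms windows stepped by 100 ms; per-cell
slopes are tested against a null built by shuffling the transition-type
labels (1000 shuffles, empirical 95% band).  Cells with negative slopes
fire more around rare transitions; signed-rank statistics compare the
per-window counts of negative vs positive coders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BehaviorSession, Unit
from .syntax import TransitionTable

__all__ = [
    "transition_probabilities_lookup",
    "transition_observations",
    "group_linear_fit",
    "cell_slope_shuffle_test",
    "binomial_critical_count",
    "significance_counts",
    "DEFAULT_WINDOW_CENTERS",
]

#: 500 ms windows, 100 ms steps over [-3, 3] s around the transition
DEFAULT_WINDOW_CENTERS = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.1), 10)
DEFAULT_WINDOW_WIDTH_S = 0.5


def transition_probabilities_lookup(
    table: TransitionTable,
) -> dict[tuple[str, str], float]:
    """Map every (from-phase, to-symbol) pair to its fitted P(Y|X).

    Pairs never observed (zero conditional) still map to 0.0; rows with
    zero occurrences are omitted, so looking up a transition from an
    unobserved phase raises ``KeyError``.
    """
    cond = table.conditional
    out: dict[tuple[str, str], float] = {}
    for i, lf in enumerate(table.labels_from):
        if table.totals[i] == 0:
            continue
        for j, lt in enumerate(table.labels_to):
            out[(lf, lt)] = float(cond[i, j])
    return out


def list_transitions(sessions: list[BehaviorSession]) -> pd.DataFrame:
    """All within-sequence transition instances: time, from- and to-phase."""
    rows = []
    for sess in sessions:
        for seq in sess.sequences:
            evs = seq.events
            for a, b in zip(evs[:-1], evs[1:]):
                rows.append((sess.session_id, seq.sequence_id, b.start_s,
                             a.phase.value, b.phase.value))
    return pd.DataFrame(
        rows, columns=["session_id", "sequence_id", "t_s", "from_phase", "to_phase"]
    )


def transition_observations(
    units: list[Unit],
    sessions: list[BehaviorSession],
    table: TransitionTable | None = None,
    window_centers: np.ndarray = DEFAULT_WINDOW_CENTERS,
    window_width_s: float = DEFAULT_WINDOW_WIDTH_S,
    cell_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the (cell, transition instance, window) observation set.

    For every unit and every within-sequence transition, the firing rate
    in each sliding window is computed from raw spike counts and
    standardized per unit (mean/SD over all of that unit's samples, i.e.
    an in-grooming-context baseline).  Each observation carries the
    P(trans) of its transition looked up in ``table`` (fitted on
    ``sessions`` when not supplied).

    Returns a long frame with columns ``unit_id, structure, cell_class,
    instance, from_phase, to_phase, p_trans, window_center_s, z``.
    """
    from .syntax import count_transitions

    if table is None:
        table = count_transitions(sessions)
    lookup = transition_probabilities_lookup(table)
    trans = list_transitions(sessions)
    if trans.empty:
        raise ValueError("no within-sequence transitions in the supplied sessions")
    missing = {
        pair for pair in zip(trans["from_phase"], trans["to_phase"])
        if pair not in lookup
    }
    if missing:
        raise KeyError(f"transitions absent from the probability table: {sorted(missing)}")
    p_trans = np.array([lookup[p] for p in zip(trans["from_phase"], trans["to_phase"])])
    t0 = trans["t_s"].to_numpy()
    centers = np.asarray(window_centers, dtype=float)
    half = window_width_s / 2.0
    # edges for every (instance, window): shape (n_inst, n_win, 2)
    lo = t0[:, None] + centers[None, :] - half
    hi = t0[:, None] + centers[None, :] + half

    frames = []
    n_inst = len(trans)
    for u in units:
        counts = np.searchsorted(u.spike_times_s, hi) - np.searchsorted(u.spike_times_s, lo)
        rate = counts / window_width_s
        mu, sd = rate.mean(), rate.std()
        z = (rate - mu) / sd if sd > 0 else np.zeros_like(rate)
        df = pd.DataFrame({
            "unit_id": u.unit_id,
            "structure": u.structure.value,
            "cell_class": (cell_classes or {}).get(u.unit_id, "all"),
            "instance": np.repeat(np.arange(n_inst), centers.size),
            "from_phase": np.repeat(trans["from_phase"].to_numpy(), centers.size),
            "to_phase": np.repeat(trans["to_phase"].to_numpy(), centers.size),
            "p_trans": np.repeat(p_trans, centers.size),
            "window_center_s": np.tile(centers, n_inst),
            "z": z.ravel(),
        })
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def group_linear_fit(
    observations: pd.DataFrame,
    min_observations: int = 20,
) -> pd.DataFrame:
    """OLS of Z on P(trans) per (structure, cell class, window).

    P-values are reported without multiple-comparison correction.
    Group-windows with too few observations or constant P(trans) are
    skipped (flagged in the ``skipped`` frame attached as
    ``df.attrs["skipped"]``).
    """
    rows = []
    skipped = []
    for (struct, cls, center), g in observations.groupby(
        ["structure", "cell_class", "window_center_s"], sort=True
    ):
        x = g["p_trans"].to_numpy()
        y = g["z"].to_numpy()
        if len(g) < min_observations:
            skipped.append((struct, cls, center, "too_few_observations"))
            continue
        if np.ptp(x) == 0:
            skipped.append((struct, cls, center, "constant_p_trans"))
            continue
        fit = stats.linregress(x, y)
        rows.append((struct, cls, center, float(fit.slope), float(fit.intercept),
                     float(fit.pvalue), len(g)))
    df = pd.DataFrame(rows, columns=["structure", "cell_class", "window_center_s",
                                     "slope", "intercept", "p_value", "n_points"])
    df.attrs["skipped"] = pd.DataFrame(
        skipped, columns=["structure", "cell_class", "window_center_s", "reason"]
    )
    return df


def _slopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS slope of each column of Y on x (shared regressor)."""
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    return (xc @ (Y - Y.mean(axis=0))) / denom


def cell_slope_shuffle_test(
    observations: pd.DataFrame,
    n_shuffles: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    min_types: int = 3,
) -> pd.DataFrame:
    """Per-cell slope of Z on P(trans) against a shuffled null.

    The null permutes the transition-type identities across each cell's
    transition instances (one permutation per shuffle, applied to all
    windows of that cell), which permutes P(trans) against the responses
    while keeping the response set fixed.  A cell-window is significant
    when its slope falls outside the central ``level`` band of the 1000
    shuffle slopes; the sign records whether the cell fires more around
    rare (negative) or common (positive) transitions.  Cells observed
    over fewer than ``min_types`` distinct transition types, or with
    constant P(trans), are excluded.
    """
    rng = np.random.default_rng(seed)
    alpha = 1.0 - level
    rows = []
    for uid, g in observations.groupby("unit_id", sort=True):
        piv = g.pivot_table(index="instance", columns="window_center_s", values="z")
        inst = piv.index.to_numpy()
        first = g.drop_duplicates("instance").set_index("instance")
        x = first.loc[inst, "p_trans"].to_numpy(dtype=float)
        types = first.loc[inst, ["from_phase", "to_phase"]].agg("->".join, axis=1)
        if types.nunique() < min_types or np.ptp(x) == 0:
            continue
        Y = piv.to_numpy()
        xc = x - x.mean()
        denom = float((xc ** 2).sum())
        Yc = Y - Y.mean(axis=0)
        sl = (xc @ Yc) / denom
        perms = np.argsort(rng.random((n_shuffles, len(x))), axis=1)
        # sum xc^2 is permutation-invariant, so the null is one matmul
        null = (xc[perms] @ Yc) / denom
        lo = np.percentile(null, 100 * alpha / 2, axis=0)
        hi = np.percentile(null, 100 * (1 - alpha / 2), axis=0)
        for w, center in enumerate(piv.columns):
            sig = bool(sl[w] < lo[w] or sl[w] > hi[w])
            rows.append((
                uid, first["structure"].iloc[0], first["cell_class"].iloc[0],
                float(center), float(sl[w]), float(lo[w]), float(hi[w]), sig,
                "negative" if sl[w] < 0 else "positive",
            ))
    return pd.DataFrame(rows, columns=[
        "unit_id", "structure", "cell_class", "window_center_s",
        "slope", "ci_low", "ci_high", "significant", "sign",
    ])


def binomial_critical_count(n: int, chance: float = 0.05, alpha: float = 0.001) -> int:
    """Smallest k with P(X >= k) <= alpha for X ~ Binomial(n, chance).

    The horizontal threshold line for significant-coder counts: observing
    at least k significant cells out of n is itself significant at
    ``alpha`` when each cell is a false positive with rate ``chance``.
    """
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, chance) <= alpha:
            return k
    return n + 1


def significance_counts(
    tests: pd.DataFrame,
    group_cols: tuple[str, ...] = ("structure", "cell_class"),
    window_range_s: tuple[float, float] = (-1.0, 1.0),
    chance: float = 0.05,
    alpha: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window counts of negative/positive coders plus group tests.

    Returns ``(counts, comparisons)``: per (group, window) the number of
    significant negative and positive coders and the binomial critical
    count for that group size; per group a Wilcoxon signed-rank test over
    the windows inside ``window_range_s`` comparing negative vs positive
    counts, Bonferroni-corrected over groups.
    """
    group_cols = list(group_cols)
    rows = []
    for key, g in tests.groupby(group_cols + ["window_center_s"], sort=True):
        *gkey, center = key
        n_cells = g["unit_id"].nunique()
        sig = g[g["significant"]]
        n_neg = int((sig["sign"] == "negative").sum())
        n_pos = int((sig["sign"] == "positive").sum())
        rows.append((*gkey, float(center), n_cells, n_neg, n_pos,
                     binomial_critical_count(n_cells, chance, alpha)))
    counts = pd.DataFrame(rows, columns=group_cols + [
        "window_center_s", "n_cells", "n_negative", "n_positive", "critical_count",
    ])

    comp_rows = []
    groups = counts.groupby(group_cols, sort=True)
    n_groups = groups.ngroups
    for gkey, g in groups:
        w = g[(g["window_center_s"] >= window_range_s[0])
              & (g["window_center_s"] <= window_range_s[1])]
        neg, pos = w["n_negative"].to_numpy(), w["n_positive"].to_numpy()
        if len(w) < 2 or np.all(neg == pos):
            stat, p = float("nan"), 1.0
            if np.all(neg == pos):
                warnings.warn(f"group {gkey}: identical counts; signed-rank skipped",
                              stacklevel=2)
        else:
            res = stats.wilcoxon(neg, pos)
            stat, p = float(res.statistic), float(res.pvalue)
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        comp_rows.append((*gkey, stat, p, min(1.0, p * n_groups)))
    comparisons = pd.DataFrame(comp_rows, columns=group_cols + [
        "wilcoxon_stat", "p_raw", "p_bonferroni",
    ])
    return counts, comparisons
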