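"""Behavioral-sequence analytics: the Markov model of grooming syntax.

Given scored grooming sequences this module estimates the first-order
transition structure and tests how well it accounts for the data:

* transition counts ``N(Y <- X)`` and conditional probabilities
  ``P(Y|X) = N(Y<-X) / N(X)`` over the five phases plus the STOP exit;
* the transition bias ``beta = log( P(Y<-X) / (P(X) P(Y)) )`` -- the log
  ratio of a pair's joint probability to the product of its marginals --
  with simulated (parametric-resampling) confidence intervals;
* forward simulation of the fitted chain and a 95% band check of the
  sequence-length histogram, with a binomial tail probability for the
  number of out-of-band points;
* the conditional-uncertainty (Shannon information) profile ``H_i`` over
  model orders i = 0..5, whose flattening beyond i = 2 is the signature
  of first-order Markov structure;
* n-gram predicted-vs-observed counts, the exit chi-square test, and
  phase-duration statistics (pairwise KS, two-way ANOVA).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BehaviorSession, Phase, PHASE_NAMES, SYMBOL_NAMES

__all__ = [
    "TransitionTable",
    "TransitionBias",
    "EntropyProfile",
    "MarkovValidation",
    "count_transitions",
    "transition_bias",
    "simulate_markov",
    "sequence_length_ci",
    "binomial_outside_tail",
    "shannon_profile",
    "ngram_predicted_counts",
    "exit_chi_square",
    "duration_stats",
]


# ---------------------------------------------------------------------------
# transition counting


@dataclass
class TransitionTable:
    """Transition counts and conditional probabilities.

    Rows are from-symbols (the five phases), columns are to-symbols (the
    five phases plus STOP).  ``totals[i]`` is the number of occurrences of
    from-symbol i; since every phase occurrence has an observed successor
    (the next phase or STOP), row sums of ``counts`` equal ``totals``.
    """

    counts: np.ndarray
    labels_from: tuple[str, ...] = PHASE_NAMES
    labels_to: tuple[str, ...] = SYMBOL_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.labels_from), len(self.labels_to)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match labels "
                f"({len(self.labels_from)} x {len(self.labels_to)})"
            )

    @property
    def totals(self) -> np.ndarray:
        """Occurrences of each from-symbol, N(X)."""
        return self.counts.sum(axis=1)

    @property
    def conditional(self) -> np.ndarray:
        """P(Y|X) = N(Y<-X) / N(X); rows with zero total are all-NaN."""
        totals = self.totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = self.counts / totals[:, None]
        cond[totals == 0] = np.nan
        return cond

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def symbol_counts(self) -> np.ndarray:
        """Occurrence counts of every to-symbol: phases from ``totals``,
        STOP (or any purely terminal symbol) from its column sum."""
        out = np.zeros(len(self.labels_to), dtype=float)
        for j, lab in enumerate(self.labels_to):
            if lab in self.labels_from:
                out[j] = self.totals[self.labels_from.index(lab)]
            else:
                out[j] = self.counts[:, j].sum()
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.labels_to))
        df.insert(0, "from_phase", list(self.labels_from))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionTable":
        labels_from = tuple(df["from_phase"])
        labels_to = tuple(c for c in df.columns if c != "from_phase")
        return cls(df[list(labels_to)].to_numpy(), labels_from, labels_to)


def count_transitions(sessions: list[BehaviorSession]) -> TransitionTable:
    """Count all within-sequence phase transitions plus phase->STOP exits.

    Consecutive identical phases are expected to have been merged at
    ingest, so the diagonal is zero by construction.
    """
    idx_from = {lab: i for i, lab in enumerate(PHASE_NAMES)}
    idx_to = {lab: j for j, lab in enumerate(SYMBOL_NAMES)}
    counts = np.zeros((5, 6), dtype=int)
    n_seq = 0
    for sess in sessions:
        for seq in sess.sequences:
            n_seq += 1
            phases = [e.phase.value for e in seq.events]
            for a, b in zip(phases[:-1], phases[1:]):
                counts[idx_from[a], idx_to[b]] += 1
            counts[idx_from[phases[-1]], idx_to[Phase.STOP.value]] += 1
    if n_seq == 0:
        warnings.warn("no sequences supplied; transition table is all zero", stacklevel=2)
    return TransitionTable(counts)


# ---------------------------------------------------------------------------
# transition bias


@dataclass
class TransitionBias:
    """Transition-bias matrix ``beta`` with simulated CI bounds and flags.

    ``flag[i, j]`` is ``"over"`` when the simulated CI lies entirely above
    zero, ``"under"`` when entirely below, else ``"none"``.  Natural log.
    """

    beta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    flag: np.ndarray
    ci_level: float
    n_sim: int
    labels_from: tuple[str, ...] = PHASE_NAMES
    labels_to: tuple[str, ...] = SYMBOL_NAMES

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lf in enumerate(self.labels_from):
            for j, lt in enumerate(self.labels_to):
                rows.append(
                    (lf, lt, self.beta[i, j], self.ci_low[i, j],
                     self.ci_high[i, j], self.flag[i, j])
                )
        return pd.DataFrame(
            rows, columns=["from_phase", "to_phase", "beta", "ci_low", "ci_high", "flag"]
        )


def _beta_matrix(joint_counts: np.ndarray) -> np.ndarray:
    """beta = log(joint / (P(X) P(Y))) with -inf where the joint is zero.

    Marginals are the row/column marginals of the joint count matrix, so
    an exactly independent table (joint = outer product of marginals)
    yields beta identically zero.
    """
    total = joint_counts.sum(axis=(-2, -1), keepdims=True)
    p_joint = joint_counts / total
    p_x = p_joint.sum(axis=-1)
    p_y = p_joint.sum(axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(p_joint) - np.log(p_x[..., :, None] * p_y[..., None, :])
    return beta


def transition_bias(
    table: TransitionTable,
    n_sim: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> TransitionBias:
    """Transition bias with CIs from parametric resampling.

    ``beta[X, Y] = log( P(Y<-X) / (P(X) P(Y)) )`` where the numerator is
    the joint probability ``N(Y<-X) / sum N`` and the marginals ``P(X)``,
    ``P(Y)`` are the row and column marginals of the same joint (for the
    from-symbols this is exactly the occurrence frequency N(X)/sum N(X),
    since every phase occurrence contributes one transition).  Natural
    log.  The CI is the central band of ``n_sim`` recomputations of beta
    after resampling the count matrix from a multinomial at the plug-in
    probabilities with the observed number of transitions (marginals are
    re-derived from each resample).  A cell is flagged over/under-
    represented when zero lies outside its band.  No multiplicity
    correction is applied (the flags are per-cell, matching the star
    convention of the transition-matrix display).
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute bias on an all-zero transition table")

    beta = _beta_matrix(counts)

    p_joint = (counts / total).ravel()
    sim_joint = rng.multinomial(int(round(total)), p_joint, size=n_sim).reshape(
        n_sim, *counts.shape
    ).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim_beta = _beta_matrix(sim_joint)

    alpha = 1.0 - ci_level
    # map -inf (zero-count resamples) to a finite sentinel so percentile
    # interpolation stays defined, then restore the sentinel
    SENTINEL = -1e30
    sim_finite = np.where(np.isneginf(sim_beta), SENTINEL, sim_beta)
    ci_low = np.percentile(sim_finite, 100 * alpha / 2, axis=0)
    ci_high = np.percentile(sim_finite, 100 * (1 - alpha / 2), axis=0)
    ci_low[ci_low < SENTINEL / 2] = -np.inf
    ci_high[ci_high < SENTINEL / 2] = -np.inf

    flag = np.full(counts.shape, "none", dtype=object)
    flag[ci_low > 0] = "over"
    flag[ci_high < 0] = "under"
    return TransitionBias(beta, ci_low, ci_high, flag, ci_level, n_sim)


# ---------------------------------------------------------------------------
# Markov simulation and sequence-length validation


def _check_stochastic(conditional: np.ndarray) -> np.ndarray:
    cond = np.asarray(conditional, dtype=float)
    rowsums = cond.sum(axis=1)
    if np.any(np.abs(rowsums - 1) > 1e-9) or np.any(cond < -1e-12):
        raise ValueError("conditional matrix rows must be non-negative and sum to 1")
    return np.clip(cond, 0, None)


def _check_terminates(cond: np.ndarray, start: np.ndarray) -> None:
    """Error if some start-reachable phase can never reach STOP."""
    n = cond.shape[0]
    reach_stop = set(np.nonzero(cond[:, n] > 0)[0])
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if i in reach_stop:
                continue
            if any(cond[i, j] > 0 and j in reach_stop for j in range(n)):
                reach_stop.add(i)
                changed = True
    reachable = set(np.nonzero(start > 0)[0])
    frontier = list(reachable)
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if cond[i, j] > 0 and j not in reachable:
                reachable.add(j)
                frontier.append(j)
    stuck = reachable - reach_stop
    if stuck:
        raise ValueError(
            f"phases {sorted(stuck)} can never reach STOP; the chain would not terminate"
        )


def simulate_markov(
    conditional: np.ndarray,
    start_distribution: np.ndarray,
    n_transitions: int,
    seed: int | None = None,
    return_sequences: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[list[int]]]:
    """Generate sequences from a first-order chain until the transition
    budget is consumed; return the sequence lengths (phase counts).

    ``conditional`` is the (n_phases x n_phases+1) row-stochastic matrix
    whose last column is the exit-to-STOP probability.  A sequence of L
    phases consumes L transitions (L-1 internal plus the exit).
    Simulation is batched and vectorized; the whole run is reproducible
    from ``seed``.
    """
    cond = _check_stochastic(conditional)
    n_phase = cond.shape[0]
    if cond.shape[1] != n_phase + 1:
        raise ValueError("conditional must have one more column (STOP) than rows")
    start = np.asarray(start_distribution, dtype=float)
    start = start / start.sum()
    _check_terminates(cond, start)

    rng = np.random.default_rng(seed)
    cum_rows = np.cumsum(cond, axis=1)
    cum_start = np.cumsum(start)

    lengths: list[np.ndarray] = []
    sequences: list[list[int]] = []
    consumed = 0
    batch = 20000
    while consumed < n_transitions:
        state = np.searchsorted(cum_start, rng.random(batch), side="right")
        active = np.arange(batch)
        length = np.ones(batch, dtype=np.int64)
        if return_sequences:
            seqs: list[list[int]] = [[int(s)] for s in state]
        while active.size:
            u = rng.random(active.size)
            nxt = (cum_rows[state[active]] < u[:, None]).sum(axis=1)
            done = nxt == n_phase
            consumed += active.size  # each active sequence consumed one transition
            still = active[~done]
            state[still] = nxt[~done]
            length[still] += 1
            if return_sequences:
                for a, nx in zip(active[~done], nxt[~done]):
                    seqs[a].append(int(nx))
            active = still
        lengths.append(length)
        if return_sequences:
            sequences.extend(seqs)
    all_lengths = np.concatenate(lengths)
    if return_sequences:
        return all_lengths, sequences
    return all_lengths


@dataclass
class MarkovValidation:
    """95% band of per-length counts under the fitted chain, and the
    out-of-band tally of the observed histogram."""

    length_bins: np.ndarray          # integer lengths; last bin is overflow
    ci_low: np.ndarray
    ci_high: np.ndarray
    model_mean: np.ndarray
    observed: np.ndarray | None
    n_outside: int
    n_points: int
    tail_prob: float
    level: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "length": self.length_bins,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "model_mean": self.model_mean,
            }
        )
        if self.observed is not None:
            df["observed"] = self.observed
        return df


def _length_histograms(lengths: np.ndarray, max_length: int) -> np.ndarray:
    """Histogram lengths into bins 1..max_length plus an overflow bin."""
    clipped = np.minimum(lengths, max_length + 1)
    if clipped.ndim == 1:
        return np.bincount(clipped, minlength=max_length + 2)[1:]
    n_sets = clipped.shape[0]
    offset = clipped + (max_length + 2) * np.arange(n_sets)[:, None]
    flat = np.bincount(offset.ravel(), minlength=(max_length + 2) * n_sets)
    return flat.reshape(n_sets, max_length + 2)[:, 1:]


def sequence_length_ci(
    model_lengths: np.ndarray,
    observed_lengths: np.ndarray | None = None,
    set_size: int = 470,
    n_sets: int = 2000,
    level: float = 0.95,
    max_length: int = 40,
    miss_prob: float | None = None,
) -> MarkovValidation:
    """Empirical per-length-bin confidence band over simulated sets.

    The model lengths are split into ``n_sets`` disjoint sets of
    ``set_size`` lengths each (mirroring the size of the observed corpus);
    the band per integer length bin is the central ``level`` percentile
    range of the per-set counts.  If an observed length list is supplied,
    ``n_outside`` counts the bins whose observed count falls outside the
    band, and ``tail_prob`` is the binomial probability of seeing at least
    that many misses if the chain were the true generator.
    """
    model_lengths = np.asarray(model_lengths)
    needed = set_size * n_sets
    if model_lengths.size < needed:
        raise ValueError(
            f"need at least set_size*n_sets = {needed} model lengths, got "
            f"{model_lengths.size}; run a longer simulation"
        )
    sets = model_lengths[:needed].reshape(n_sets, set_size)
    hists = _length_histograms(sets, max_length)
    alpha = 1.0 - level
    ci_low = np.percentile(hists, 100 * alpha / 2, axis=0)
    ci_high = np.percentile(hists, 100 * (1 - alpha / 2), axis=0)
    model_mean = hists.mean(axis=0)
    bins = np.arange(1, max_length + 2)  # last = overflow

    observed = None
    n_outside = 0
    n_points = int(bins.size)
    if observed_lengths is not None:
        observed = _length_histograms(np.asarray(observed_lengths), max_length).astype(float)
        outside = (observed < ci_low) | (observed > ci_high)
        n_outside = int(outside.sum())
    p_miss = (1.0 - level) if miss_prob is None else miss_prob
    tail = binomial_outside_tail(n_points, n_outside, p_miss) if observed is not None else float("nan")
    return MarkovValidation(
        bins, ci_low, ci_high, model_mean, observed, n_outside, n_points, tail, level
    )


def binomial_outside_tail(n_points: int, k_outside: int, miss_prob: float = 0.05) -> float:
    """P(X >= k_outside) for X ~ Binomial(n_points, miss_prob).

    The probability of seeing at least ``k_outside`` of ``n_points``
    histogram bins outside a band that each bin independently misses with
    probability ``miss_prob``.
    """
    if not (0 <= k_outside <= n_points):
        raise ValueError("k_outside must lie in [0, n_points]")
    if not (0 <= miss_prob <= 1):
        raise ValueError("miss_prob must lie in [0, 1]")
    return float(stats.binom.sf(k_outside - 1, n_points, miss_prob))


# ---------------------------------------------------------------------------
# conditional-uncertainty (Shannon information) profile


@dataclass
class EntropyProfile:
    """Conditional-uncertainty estimates H_i over model orders.

    ``H_bits[i]`` estimates the uncertainty (bits) about the upcoming
    phase given the previous ``i - 1`` phases; order 0 is the uninformed
    log2(5).  Flatness beyond order 2 indicates that one step of history
    suffices (first-order Markov syntax).
    """

    order: np.ndarray
    H_bits: np.ndarray
    tuple_counts: dict[int, Counter]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"order": self.order, "H_bits": self.H_bits})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EntropyProfile":
        return cls(df["order"].to_numpy(), df["H_bits"].to_numpy(), {})


def _plugin_entropy(counts: np.ndarray) -> float:
    """H-hat = log2 N - (1/N) sum n_j log2 n_j over observed tuples."""
    counts = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                        dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    return float(np.log2(N) - (counts * np.log2(counts)).sum() / N)


def shannon_profile(sessions: list[BehaviorSession], max_order: int = 5) -> EntropyProfile:
    """Conditional-uncertainty profile over model orders 0..max_order.

    Tuples are formed within sequences only (never across STOP), over the
    five-phase alphabet (c = 5).  For order i >= 2 the lower-order counts
    entering the difference are re-derived by marginalizing the i-tuple
    counts over their last symbol, so both plug-in entropies share the
    same effective sample.
    """
    seqs = [
        [e.phase.value for e in seq.events]
        for sess in sessions
        for seq in sess.sequences
    ]
    orders = [0]
    H = [float(np.log2(5))]
    tuple_counts: dict[int, Counter] = {}
    for i in range(1, max_order + 1):
        counts: Counter = Counter()
        for s in seqs:
            for k in range(len(s) - i + 1):
                counts[tuple(s[k:k + i])] += 1
        if not counts:
            warnings.warn(f"no tuples of order {i}; omitting orders >= {i}", stacklevel=2)
            break
        tuple_counts[i] = counts
        if i == 1:
            H_i = _plugin_entropy(np.array(list(counts.values())))
        else:
            prefix: Counter = Counter()
            for tup, n in counts.items():
                prefix[tup[:-1]] += n
            H_i = (
                _plugin_entropy(np.array(list(counts.values())))
                - _plugin_entropy(np.array(list(prefix.values())))
            )
        orders.append(i)
        H.append(H_i)
    return EntropyProfile(np.array(orders), np.array(H), tuple_counts)


# ---------------------------------------------------------------------------
# n-gram prediction, exit test, durations


def ngram_predicted_counts(
    table: TransitionTable,
    sessions: list[BehaviorSession],
    orders: tuple[int, ...] = (3, 4, 5),
) -> dict[int, pd.DataFrame]:
    """Predicted first-order-chain probability vs observed count per n-gram.

    The predicted probability of an n-gram (w1..wn) is the marginal phase
    frequency of w1 times the product of fitted conditionals along the
    gram.  Observed counts are occurrences of the gram as a contiguous
    subsequence within sequences.  Each returned frame carries the
    Spearman rank correlation over grams with nonzero predicted
    probability in ``df.attrs["spearman_rho"]``.
    """
    for n in orders:
        if n not in (3, 4, 5):
            raise ValueError(f"order {n} unsupported; orders must be within {{3,4,5}}")
    cond = table.conditional[:, :5]
    totals = table.totals.astype(float)
    marg = totals / totals.sum()
    seqs = [
        [e.phase.value for e in seq.events]
        for sess in sessions
        for seq in sess.sequences
    ]
    idx = {lab: i for i, lab in enumerate(table.labels_from)}

    out: dict[int, pd.DataFrame] = {}
    for n in orders:
        observed: Counter = Counter()
        for s in seqs:
            for k in range(len(s) - n + 1):
                observed[tuple(s[k:k + n])] += 1
        rows = []
        for gram in itertools.product(table.labels_from, repeat=n):
            p = marg[idx[gram[0]]]
            for a, b in zip(gram[:-1], gram[1:]):
                p *= cond[idx[a], idx[b]]
            rows.append(("-".join(gram), float(p), observed.get(gram, 0)))
        df = pd.DataFrame(rows, columns=["ngram", "predicted_p", "observed_n"])
        support = df[df["predicted_p"] > 0]
        if len(support) >= 3 and support["observed_n"].nunique() > 1:
            rho, pval = stats.spearmanr(support["predicted_p"], support["observed_n"])
        else:
            rho, pval = float("nan"), float("nan")
        df.attrs["spearman_rho"] = float(rho)
        df.attrs["spearman_p"] = float(pval)
        out[n] = df
    return out


def exit_chi_square(table: TransitionTable) -> tuple[float, int, float]:
    """Chi-square test of homogeneity of exit-to-STOP proportions.

    Builds the (exits, non-exits) x phases contingency table and applies
    Pearson's chi-square without continuity correction; df = n_phases - 1.
    Phases with zero occurrences are dropped with a warning.
    """
    stop_col = table.labels_to.index(Phase.STOP.value)
    exits = table.counts[:, stop_col].astype(float)
    totals = table.totals.astype(float)
    keep = totals > 0
    if not np.all(keep):
        dropped = [lab for lab, k in zip(table.labels_from, keep) if not k]
        warnings.warn(f"phases with zero occurrences dropped from exit test: {dropped}",
                      stacklevel=2)
    exits, totals = exits[keep], totals[keep]
    if exits.size < 2:
        raise ValueError("need at least two phases with observations for the exit test")
    contingency = np.vstack([exits, totals - exits])
    chi2, p, df, _ = stats.chi2_contingency(contingency, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class DurationStats:
    """Per-phase duration distributions with pairwise KS tests and ANOVA."""

    durations: pd.DataFrame          # columns: phase, animal, duration_s
    ks_tests: pd.DataFrame           # phase_a, phase_b, ks_stat, p_raw, p_bonferroni
    anova: pd.DataFrame | None       # statsmodels ANOVA table (or None)

    def to_frame(self) -> pd.DataFrame:
        return self.ks_tests


def duration_stats(
    sessions: list[BehaviorSession],
    include_pauses: bool = True,
) -> DurationStats:
    """Phase-duration statistics: pairwise two-sample KS tests with
    Bonferroni correction and a two-way ANOVA (phase, animal).

    With ``include_pauses`` the inter-sequence pauses enter the KS
    comparisons as a sixth "STOP" category (15 pairs instead of 10); the
    ANOVA always runs on the five grooming phases only.  The animal factor
    is skipped (with a warning) when only one animal is present.
    """
    rows = []
    for sess in sessions:
        for seq in sess.sequences:
            for ev in seq.events:
                rows.append((ev.phase.value, sess.animal_id, ev.duration_s))
        if include_pauses:
            for d in sess.pause_durations_s():
                rows.append((Phase.STOP.value, sess.animal_id, d))
    durations = pd.DataFrame(rows, columns=["phase", "animal", "duration_s"])

    cats = [c for c in SYMBOL_NAMES if (durations["phase"] == c).sum() >= 2]
    pairs = list(itertools.combinations(cats, 2))
    ks_rows = []
    for a, b in pairs:
        xa = durations.loc[durations["phase"] == a, "duration_s"]
        xb = durations.loc[durations["phase"] == b, "duration_s"]
        res = stats.ks_2samp(xa, xb)
        ks_rows.append((a, b, float(res.statistic), float(res.pvalue),
                        min(1.0, float(res.pvalue) * len(pairs))))
    ks_tests = pd.DataFrame(
        ks_rows, columns=["phase_a", "phase_b", "ks_stat", "p_raw", "p_bonferroni"]
    )

    phase_only = durations[durations["phase"] != Phase.STOP.value]
    anova_table = None
    if phase_only["phase"].nunique() >= 2:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        if phase_only["animal"].nunique() >= 2:
            model = smf.ols("duration_s ~ C(phase) + C(animal)", data=phase_only).fit()
        else:
            warnings.warn("single animal: animal factor skipped in duration ANOVA",
                          stacklevel=2)
            model = smf.ols("duration_s ~ C(phase)", data=phase_only).fit()
        anova_table = sm.stats.anova_lm(model, typ=2)
    return DurationStats(durations, ks_tests, anova_table)
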