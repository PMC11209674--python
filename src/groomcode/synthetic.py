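"""Synthetic behavior and spike-train generators.

The generator emulates the statistical structure the analysis pipeline
assumes about its inputs:

* grooming sequences as a first-order Markov chain over the five phases
  with an exit-to-STOP column, log-normal phase durations, and log-normal
  inter-sequence pauses;
* spike trains as inhomogeneous Poisson processes whose rate is a
  baseline plus Gaussian bumps locked to behavioral events (sequence
  onset/end, phase transitions, preferred phases, or bumps whose
  amplitude is linear in the transition probability of the event);
* waveform shape features as draws from one of two 3-D Gaussian clusters
  (broad-spiking principal-cell-like vs narrow-spiking interneuron-like).

Everything is reproducible from a single seed; per-unit randomness is
derived from counter-based substreams (``SeedSequence(seed, unit_index)``)
so extending the unit set never reshuffles existing units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    BehaviorSession,
    GroomingSequence,
    Hemisphere,
    Phase,
    PhaseEvent,
    PHASES,
    PHASE_NAMES,
    Structure,
    Unit,
    WaveformFeatures,
)
from .syntax import TransitionTable, _check_stochastic, _check_terminates

__all__ = [
    "BehaviorGeneratorSpec",
    "UnitArchetype",
    "DEFAULT_TRANSITION_MATRIX",
    "DEFAULT_START_DISTRIBUTION",
    "DEFAULT_DURATION_PARAMS",
    "generate_behavior",
    "generate_spikes",
    "generate_waveforms",
]


# Default generative transition matrix (rows: from-phase; columns:
# P1A, P1B, P2, P3, P4, STOP).  Chosen to reproduce the qualitative
# regime of scored rat grooming: P1A and P2 dominate the phase budget,
# the syntactic-chain steps P1B->P2, P2->P3, P3->P4 are overrepresented
# relative to phase frequencies, exit probability differs strongly
# between phases (highest from P4), and mean sequence length is ~7.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        # P1A    P1B    P2     P3     P4    STOP
        [0.00, 0.02, 0.60, 0.08, 0.15, 0.15],  # from P1A
        [0.05, 0.00, 0.82, 0.04, 0.04, 0.05],  # from P1B
        [0.50, 0.03, 0.00, 0.27, 0.08, 0.12],  # from P2
        [0.25, 0.01, 0.30, 0.00, 0.34, 0.10],  # from P3
        [0.35, 0.02, 0.20, 0.08, 0.00, 0.35],  # from P4
    ]
)

#: default distribution of sequence-initial phases (paw licking starts most
#: sequences; the rapid elliptical strokes P1B start in-chain bouts)
DEFAULT_START_DISTRIBUTION = np.array([0.55, 0.08, 0.25, 0.05, 0.07])

#: per-phase log-normal duration parameters (log-median s, log-sd), chosen
#: to match the characteristic scored ranges: P1A ~1-10 s, P1B ~1 s with
#: small variance, P2 ~0.5-2 s, P3 ~1-3 s, P4 ~1-30 s
DEFAULT_DURATION_PARAMS: dict[str, tuple[float, float]] = {
    "P1A": (np.log(1.5), 0.80),
    "P1B": (np.log(1.0), 0.15),
    "P2": (np.log(0.8), 0.50),
    "P3": (np.log(1.5), 0.50),
    "P4": (np.log(3.0), 0.90),
}

#: inter-sequence pause parameters (log-median s, log-sd)
DEFAULT_PAUSE_PARAMS: tuple[float, float] = (np.log(15.0), 0.8)


@dataclass
class BehaviorGeneratorSpec:
    """Parameters of the behavioral generator.

    ``transition_matrix`` is 5 x 6 row-stochastic (columns: five phases
    plus STOP); ``duration_params`` maps each phase to the (log-median,
    log-sd) of a log-normal duration.
    """

    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_MATRIX.copy()
    )
    start_distribution: np.ndarray = field(
        default_factory=lambda: DEFAULT_START_DISTRIBUTION.copy()
    )
    duration_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_PARAMS)
    )
    pause_params: tuple[float, float] = DEFAULT_PAUSE_PARAMS
    n_sequences: int = 300
    seed: int = 0
    session_id: str = "synthetic-01"
    animal_id: str = "rat-01"
    min_duration_s: float = 0.12  # floor so events stay > 2 frames long

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (5, 6):
            raise ValueError("transition_matrix must be 5 x 6 (five phases + STOP)")
        if np.any(np.abs(tm.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition_matrix rows must sum to 1 (tol 1e-12)")
        if np.any(tm < 0):
            raise ValueError("transition_matrix entries must be non-negative")
        if np.any(tm.sum(axis=1) == 0):
            raise ValueError("a transition row has zero mass")
        sd = np.asarray(self.start_distribution, dtype=float)
        if sd.shape != (5,) or abs(sd.sum() - 1) > 1e-9 or np.any(sd < 0):
            raise ValueError("start_distribution must be a 5-vector summing to 1")
        self.transition_matrix = tm
        self.start_distribution = sd
        for name in PHASE_NAMES:
            if name not in self.duration_params:
                raise ValueError(f"duration_params missing phase {name}")


def generate_behavior(spec: BehaviorGeneratorSpec) -> BehaviorSession:
    """Sample a full behavioral session from the generator spec.

    Each sequence draws a start phase, chains phase-to-phase transitions
    until STOP, and assigns each phase a log-normal duration; sequences
    are separated by log-normal pauses (floored at the two-frame
    immobility minimum).  Bit-identical given the same spec and seed.
    """
    cond = _check_stochastic(spec.transition_matrix)
    start = spec.start_distribution / spec.start_distribution.sum()
    _check_terminates(cond, start)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    cum_rows = np.cumsum(cond, axis=1)
    cum_start = np.cumsum(start)

    sequences: list[GroomingSequence] = []
    t = 0.0
    for k in range(spec.n_sequences):
        if k > 0:
            mu, sd = spec.pause_params
            t += max(0.08, float(rng.lognormal(mu, sd)))
        state = int(np.searchsorted(cum_start, rng.random(), side="right"))
        events: list[PhaseEvent] = []
        while True:
            phase = PHASES[state]
            mu, sd = spec.duration_params[phase.value]
            dur = max(spec.min_duration_s, float(rng.lognormal(mu, sd)))
            events.append(PhaseEvent(phase, t, t + dur))
            t += dur
            nxt = int(np.searchsorted(cum_rows[state], rng.random(), side="right"))
            if nxt == 5:  # STOP
                break
            state = nxt
        sequences.append(GroomingSequence(f"seq-{k:05d}", events))
    duration = sequences[-1].end_s + 10.0 if sequences else 0.0
    return BehaviorSession(spec.session_id, spec.animal_id, sequences, duration)


# ---------------------------------------------------------------------------
# spike generation


@dataclass
class UnitArchetype:
    """Ground-truth firing archetype of a synthetic unit.

    kind
        ``null`` (homogeneous Poisson), ``starter`` (bump at sequence
        onset), ``stopper`` (bump before sequence end), ``bracketer``
        (bumps at onset and after end), ``transition_event`` (bump at
        every within-sequence phase transition), ``phase_tuned``
        (per-phase rate gain), or ``prob_coder`` (transition-locked bumps
        whose amplitude is linear in P(trans)).
    """

    kind: str = "null"
    baseline_hz: float = 5.0
    bump_amplitude_hz: float = 20.0
    bump_sigma_s: float = 0.2
    tuning: dict[str, float] | None = None       # phase -> multiplicative gain
    slope_hz_per_prob: float = 0.0               # prob_coder
    intercept_hz: float = 0.0                    # prob_coder amplitude at P(trans)=0
    boundary_offset_s: float = 0.5               # stopper lead / bracketer lag
    structure: Structure = Structure.MI
    hemisphere: Hemisphere = Hemisphere.LEFT
    cell_class: str = "PC"
    #: restrict transition_event/prob_coder bumps to one (from, to) pair;
    #: "*" wildcards either side, e.g. ("*", "P2") = any transition into P2
    pair_preference: tuple[str, str] | None = None

    KINDS = ("null", "starter", "stopper", "bracketer", "phase_tuned",
             "transition_event", "prob_coder")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if not self.baseline_hz > 0:
            raise ValueError("baseline_hz must be > 0")
        if not self.bump_sigma_s > 0:
            raise ValueError("bump_sigma_s must be > 0")


def _bump_events(
    arch: UnitArchetype, behavior: BehaviorSession,
    p_lookup: dict[tuple[str, str], float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event centers and bump amplitudes for an archetype."""
    centers: list[float] = []
    amps: list[float] = []
    for seq in behavior.sequences:
        if arch.kind == "starter":
            centers.append(seq.start_s)
            amps.append(arch.bump_amplitude_hz)
        elif arch.kind == "stopper":
            # bump in the middle of the pre-end epoch so its mass stays pre-end
            centers.append(seq.end_s - arch.boundary_offset_s)
            amps.append(arch.bump_amplitude_hz)
        elif arch.kind == "bracketer":
            centers += [seq.start_s, seq.end_s + arch.boundary_offset_s]
            amps += [arch.bump_amplitude_hz] * 2
        elif arch.kind in ("transition_event", "prob_coder"):
            phases = seq.phases
            for a, b, ev in zip(phases[:-1], phases[1:], seq.events[1:]):
                if arch.pair_preference is not None:
                    pf, pt = arch.pair_preference
                    if (pf != "*" and a.value != pf) or (pt != "*" and b.value != pt):
                        continue
                if arch.kind == "transition_event":
                    amp = arch.bump_amplitude_hz
                else:
                    if p_lookup is None:
                        raise ValueError("prob_coder archetypes need a probability lookup")
                    p = p_lookup[(a.value, b.value)]
                    amp = arch.intercept_hz + arch.slope_hz_per_prob * p
                centers.append(ev.start_s)
                amps.append(amp)
    return np.asarray(centers, dtype=float), np.asarray(amps, dtype=float)


def _rate_function(
    arch: UnitArchetype,
    behavior: BehaviorSession,
    p_lookup: dict[tuple[str, str], float] | None,
):
    """Return (rate(t) callable, rate upper bound) for thinning."""
    if arch.kind == "phase_tuned":
        tuning = arch.tuning or {}
        intervals = []
        gains = []
        for seq in behavior.sequences:
            for ev in seq.events:
                g = tuning.get(ev.phase.value, 1.0)
                if g != 1.0:
                    intervals.append((ev.start_s, ev.end_s))
                    gains.append(g)
        starts = np.array([iv[0] for iv in intervals])
        ends = np.array([iv[1] for iv in intervals])
        gains_arr = np.array(gains)

        def rate(t: np.ndarray) -> np.ndarray:
            r = np.full(t.shape, arch.baseline_hz)
            for s, e, g in zip(starts, ends, gains_arr):
                r = np.where((t >= s) & (t < e), arch.baseline_hz * g, r)
            return np.clip(r, 0.0, None)

        rmax = arch.baseline_hz * max([1.0, *gains], default=1.0)
        return rate, rmax

    centers, amps = _bump_events(arch, behavior, p_lookup)
    sigma = arch.bump_sigma_s

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full(t.shape, arch.baseline_hz)
        if centers.size:
            # sum of Gaussian bumps; evaluate only nearby events
            d = t[:, None] - centers[None, :]
            mask = np.abs(d) < 5 * sigma
            contrib = np.where(mask, amps[None, :] * np.exp(-0.5 * (d / sigma) ** 2), 0.0)
            r = r + contrib.sum(axis=1)
        return np.clip(r, 0.0, None)

    # bumps can overlap; bound by baseline + sum of amplitudes of any
    # plausible overlap cluster (conservative: 3 nearest bumps)
    if centers.size:
        amax = float(np.max(np.abs(amps)))
        rmax = arch.baseline_hz + 3 * max(amax, 0.0)
    else:
        rmax = arch.baseline_hz
    return rate, max(rmax, arch.baseline_hz)


def generate_spikes(
    archetypes: list[UnitArchetype],
    behavior: BehaviorSession,
    seed: int = 0,
    transition_table: TransitionTable | None = None,
    duration_s: float | None = None,
) -> list[Unit]:
    """Sample inhomogeneous-Poisson spike trains for each archetype.

    Thinning-based: homogeneous candidates at the archetype's rate upper
    bound are kept with probability ``rate(t) / bound``.  ``prob_coder``
    archetypes need a transition table (defaults to the table fitted on
    ``behavior`` itself) to look up each event's P(trans).  Unit ``k``
    draws from substream ``SeedSequence((seed, k))``.
    """
    if not behavior.sequences:
        return [
            Unit(f"unit-{k:04d}", a.structure, a.hemisphere, np.empty(0))
            for k, a in enumerate(archetypes)
        ]
    p_lookup = None
    if any(a.kind == "prob_coder" for a in archetypes):
        from .transition_coding import transition_probabilities_lookup
        from .syntax import count_transitions

        table = transition_table or count_transitions([behavior])
        p_lookup = transition_probabilities_lookup(table)
    T = duration_s if duration_s is not None else behavior.session_duration_s
    units: list[Unit] = []
    for k, arch in enumerate(archetypes):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
        rate, rmax = _rate_function(arch, behavior, p_lookup)
        n_cand = rng.poisson(rmax * T)
        cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        keep = rng.random(n_cand) < rate(cand) / rmax
        units.append(Unit(f"unit-{k:04d}", arch.structure, arch.hemisphere, cand[keep]))
    return units


# ---------------------------------------------------------------------------
# waveform features


#: broad-spiking (principal-cell-like) cluster: mean and covariance of
#: (valley width, peak width, peak-to-valley) in ms
PC_CLUSTER = (np.array([0.34, 0.30, 0.62]), np.diag([0.002, 0.002, 0.004]))
#: narrow-spiking (interneuron-like) cluster
IN_CLUSTER = (np.array([0.14, 0.11, 0.24]), np.diag([0.0008, 0.0008, 0.0015]))


def generate_waveforms(
    cell_classes: list[str],
    cluster_params: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    seed: int = 0,
) -> list[WaveformFeatures]:
    """Draw waveform feature triples from per-class 3-D Gaussians.

    ``cell_classes`` lists the ground-truth class ("PC" or "IN") of each
    unit.  Negative widths are resampled (truncation at zero).
    """
    params = cluster_params or {"PC": PC_CLUSTER, "IN": IN_CLUSTER}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    out: list[WaveformFeatures] = []
    for cls in cell_classes:
        mean, cov = params[cls]
        for _ in range(1000):
            x = rng.multivariate_normal(mean, cov)
            if np.all(x > 0):
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("could not sample positive waveform features")
        out.append(WaveformFeatures(*x))
    return out
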