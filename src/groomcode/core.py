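"""Core domain types for grooming-behavior and spike-train analysis.

The behavioral vocabulary is the five stereotyped rodent grooming phases
plus an absorbing STOP state:

* ``P1A`` -- repetitive licking of forepaws/whiskers (out-of-chain variant)
* ``P1B`` -- rapid bilateral elliptical strokes (in-chain variant)
* ``P2``  -- unilateral head strokes
* ``P3``  -- bilateral ear strokes
* ``P4``  -- body licking
* ``STOP`` -- immobility terminating a grooming sequence

A grooming *sequence* is an uninterrupted run of phases: each phase begins
exactly when its predecessor ends, and the sequence terminates at STOP
(at least two video frames, 80 ms, of immobility).  Times are in seconds,
0-based per session, intervals half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

#: duration of one video frame (25 fps camera)
FRAME_S = 0.04

#: minimum immobility separating two grooming sequences (two frames)
MIN_GAP_S = 2 * FRAME_S


class Phase(str, Enum):
    """One of the five grooming phases or the terminal STOP state."""

    P1A = "P1A"
    P1B = "P1B"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    STOP = "STOP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the five active grooming phases, in canonical order
PHASES: tuple[Phase, ...] = (Phase.P1A, Phase.P1B, Phase.P2, Phase.P3, Phase.P4)

#: phases plus the STOP terminator (column order of transition tables)
SYMBOLS: tuple[Phase, ...] = PHASES + (Phase.STOP,)

PHASE_NAMES: tuple[str, ...] = tuple(p.value for p in PHASES)
SYMBOL_NAMES: tuple[str, ...] = tuple(p.value for p in SYMBOLS)


class Structure(str, Enum):
    """Recorded brain structure."""

    MI = "MI"    # primary motor cortex, forelimb representation
    RFA = "RFA"  # rostral forelimb area (premotor)
    DLS = "DLS"  # dorsolateral (sensorimotor) striatum
    DMS = "DMS"  # dorsomedial (associative) striatum

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class ValidationError(ValueError):
    """Raised when an ethogram or unit table violates a structural invariant."""


def on_frame_grid(t: float, frame_s: float = FRAME_S, tol: float = 1e-9) -> bool:
    """True if ``t`` is a multiple of the video frame duration within ``tol``."""
    return abs(t - round(t / frame_s) * frame_s) <= tol


@dataclass(frozen=True)
class PhaseEvent:
    """A single labeled phase interval ``[start_s, end_s)``."""

    phase: Phase
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.phase is Phase.STOP:
            raise ValidationError("STOP is a terminator, not a phase event")
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"event {self.phase} has end_s={self.end_s} <= start_s={self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GroomingSequence:
    """A contiguous run of phase events terminated (implicitly) by STOP."""

    sequence_id: str
    events: list[PhaseEvent]

    def __post_init__(self) -> None:
        if len(self.events) < 1:
            raise ValidationError(f"sequence {self.sequence_id} is empty")
        for k in range(len(self.events) - 1):
            gap = self.events[k + 1].start_s - self.events[k].end_s
            if abs(gap) > 1e-9:
                raise ValidationError(
                    f"sequence {self.sequence_id}: events {k} and {k + 1} are not "
                    f"contiguous (gap {gap:.6g} s at t={self.events[k].end_s:.6g})"
                )

    @property
    def start_s(self) -> float:
        return self.events[0].start_s

    @property
    def end_s(self) -> float:
        return self.events[-1].end_s

    @property
    def phases(self) -> list[Phase]:
        return [e.phase for e in self.events]

    def __len__(self) -> int:
        return len(self.events)


def merge_repeated_phases(seq: GroomingSequence) -> GroomingSequence:
    """Merge consecutive identical phases into one continuous phase.

    A unilateral phase immediately repeated (e.g. P2 left then P2 right) is
    scored as a single continuous phase; applying this at ingest makes the
    transition table's diagonal zero by construction.
    """
    merged: list[PhaseEvent] = []
    for ev in seq.events:
        if merged and merged[-1].phase is ev.phase:
            merged[-1] = PhaseEvent(ev.phase, merged[-1].start_s, ev.end_s)
        else:
            merged.append(ev)
    return GroomingSequence(seq.sequence_id, merged)


@dataclass
class BehaviorSession:
    """All grooming sequences of one recording session."""

    session_id: str
    animal_id: str
    sequences: list[GroomingSequence]
    session_duration_s: float = 0.0

    def __post_init__(self) -> None:
        prev_end = None
        prev_id = None
        for seq in self.sequences:
            if prev_end is not None:
                gap = seq.start_s - prev_end
                if gap < MIN_GAP_S - 1e-9:
                    raise ValidationError(
                        f"session {self.session_id}: sequences {prev_id} and "
                        f"{seq.sequence_id} are separated by {gap:.6g} s "
                        f"(< {MIN_GAP_S} s) or overlap"
                    )
            prev_end = seq.end_s
            prev_id = seq.sequence_id
        if self.sequences and self.session_duration_s <= 0.0:
            self.session_duration_s = self.sequences[-1].end_s

    def validate_frame_grid(self, tol: float = 1e-9) -> None:
        """Check that all event times lie on the 40 ms video frame grid."""
        for seq in self.sequences:
            for ev in seq.events:
                for t in (ev.start_s, ev.end_s):
                    if not on_frame_grid(t, tol=tol):
                        raise ValidationError(
                            f"session {self.session_id}, sequence {seq.sequence_id}: "
                            f"time {t} is off the {FRAME_S * 1000:.0f} ms frame grid"
                        )

    @property
    def n_phases(self) -> int:
        return sum(len(s) for s in self.sequences)

    def pause_durations_s(self) -> list[float]:
        """Gaps between consecutive grooming sequences (STOP durations)."""
        return [
            b.start_s - a.end_s
            for a, b in zip(self.sequences[:-1], self.sequences[1:])
        ]


@dataclass(frozen=True)
class WaveformFeatures:
    """Shape features of a unit's mean spike waveform (milliseconds).

    Widths are full widths at half maximum of the valley / peak;
    ``peak_to_valley_ms`` is the time from valley minimum to peak maximum.
    """

    valley_width_ms: float
    peak_width_ms: float
    peak_to_valley_ms: float

    def __post_init__(self) -> None:
        for name in ("valley_width_ms", "peak_width_ms", "peak_to_valley_ms"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.valley_width_ms, self.peak_width_ms, self.peak_to_valley_ms]
        )


@dataclass
class Unit:
    """A single sorted unit: spike times plus anatomical metadata."""

    unit_id: str
    structure: Structure
    hemisphere: Hemisphere
    spike_times_s: np.ndarray
    waveform: WaveformFeatures | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times_s, dtype=float)
        if st.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike times must be 1-D")
        if st.size > 1 and np.any(np.diff(st) <= 0):
            warnings.warn(
                f"unit {self.unit_id}: spike times not strictly increasing; sorting",
                stacklevel=2,
            )
            st = np.unique(st)
        self.spike_times_s = st

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def mean_rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else float("nan")
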