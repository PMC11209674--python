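"""Shared fixtures: small handmade sessions plus reusable synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from groomcode.core import BehaviorSession, GroomingSequence, Phase, PhaseEvent
from groomcode import synthetic as syn


def make_session(seq_phases, durations=1.0, gap=5.0, session_id="s1", animal_id="a1"):
    """Build a session from lists of phase names, fixed durations."""
    sequences = []
    t = 0.0
    for k, phases in enumerate(seq_phases):
        events = []
        for name in phases:
            d = durations if np.isscalar(durations) else durations[k]
            events.append(PhaseEvent(Phase(name), t, t + d))
            t += d
        sequences.append(GroomingSequence(f"seq-{k}", events))
        t += gap
    return BehaviorSession(session_id, animal_id, sequences, t)


@pytest.fixture
def tiny_session():
    """Two short sequences: (P1A, P2) and (P1B, P2, P3)."""
    return make_session([["P1A", "P2"], ["P1B", "P2", "P3"]])


@pytest.fixture(scope="session")
def markov_session():
    """A moderately large generated session (fixed seed) shared read-only."""
    spec = syn.BehaviorGeneratorSpec(n_sequences=2000, seed=101)
    return syn.generate_behavior(spec)


@pytest.fixture(scope="session")
def separated_session():
    """Generated session with sequences long enough (>2 s phases) that the
    1-s boundary epochs never overlap neighboring sequences."""
    dur = {p: (np.log(2.5), 0.3) for p in ["P1A", "P1B", "P2", "P3", "P4"]}
    spec = syn.BehaviorGeneratorSpec(
        n_sequences=40, seed=5, duration_params=dur,
        pause_params=(np.log(25.0), 0.4),
    )
    return syn.generate_behavior(spec)
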