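"""Readers and writers for ethogram, spike, and result tables.

All on-disk formats are plain delimited text (CSV).  Downstream modules
consume only the in-memory types from :mod:`groomcode.core`; nothing else
in the package touches files.

Formats
-------
ethogram.csv
    ``session_id, animal_id, sequence_id, phase, start_s, end_s``
spikes.csv
    ``unit_id, spike_time_s``
units.csv
    ``unit_id, structure, hemisphere`` plus optional waveform feature
    columns ``valley_width_ms, peak_width_ms, peak_to_valley_ms``
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .core import (
    BehaviorSession,
    GroomingSequence,
    Hemisphere,
    Phase,
    PhaseEvent,
    Structure,
    Unit,
    ValidationError,
    WaveformFeatures,
    merge_repeated_phases,
)

ETHOGRAM_COLUMNS = ["session_id", "animal_id", "sequence_id", "phase", "start_s", "end_s"]

_WAVEFORM_COLUMNS = ["valley_width_ms", "peak_width_ms", "peak_to_valley_ms"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Any) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _parse_phase(value: str, row: int, path: Any) -> Phase:
    try:
        return Phase(str(value))
    except ValueError:
        allowed = ", ".join(p.value for p in Phase)
        raise ValidationError(
            f"{path}, row {row}: unknown phase label {value!r} (allowed: {allowed})"
        ) from None


def read_ethogram(
    path: str | Path,
    *,
    enforce_grid: bool = True,
    merge_repeats: bool = True,
) -> BehaviorSession:
    """Read one session's ethogram from a delimited text file.

    Parameters
    ----------
    path
        CSV file with columns ``session_id, animal_id, sequence_id, phase,
        start_s, end_s``.  All rows must belong to a single session.
    enforce_grid
        Require all times to lie on the 40 ms video-frame grid.  The grid
        is a property of the acquisition camera; switch it off for
        continuous-time synthetic data.
    merge_repeats
        Merge immediately repeated identical phases into one continuous
        phase (the scoring convention for repeated unilateral phases).

    Raises
    ------
    ValidationError
        On unknown phase labels, non-contiguous events within a sequence
        (the error names the offending row), or multiple sessions per file.
    """
    sessions = read_ethogram_sessions(
        path, enforce_grid=enforce_grid, merge_repeats=merge_repeats
    )
    if len(sessions) != 1:
        raise ValidationError(
            f"{path}: expected exactly one session, found {len(sessions)}; "
            "use read_ethogram_sessions for multi-session files"
        )
    return sessions[0]


def read_ethogram_sessions(
    path: str | Path,
    *,
    enforce_grid: bool = True,
    merge_repeats: bool = True,
) -> list[BehaviorSession]:
    """Read a (possibly multi-session) ethogram file; one session per id."""
    df = pd.read_csv(path)
    _require_columns(df, ETHOGRAM_COLUMNS, path)
    sessions: list[BehaviorSession] = []
    for session_id, sdf in df.groupby("session_id", sort=True):
        animals = sdf["animal_id"].unique()
        if len(animals) != 1:
            raise ValidationError(
                f"{path}: session {session_id} maps to several animals {list(animals)}"
            )
        sequences: list[GroomingSequence] = []
        for seq_id, qdf in sdf.groupby("sequence_id", sort=False):
            qdf = qdf.sort_values("start_s")
            events = []
            for row, rec in qdf.iterrows():
                phase = _parse_phase(rec["phase"], row, path)
                if phase is Phase.STOP:
                    raise ValidationError(
                        f"{path}, row {row}: STOP may not appear as a phase event"
                    )
                events.append(PhaseEvent(phase, float(rec["start_s"]), float(rec["end_s"])))
            try:
                seq = GroomingSequence(str(seq_id), events)
            except ValidationError as err:
                first_row = int(qdf.index[0])
                raise ValidationError(f"{path} (rows from {first_row}): {err}") from None
            if merge_repeats:
                seq = merge_repeated_phases(seq)
            sequences.append(seq)
        sequences.sort(key=lambda s: s.start_s)
        session = BehaviorSession(str(session_id), str(animals[0]), sequences)
        if enforce_grid:
            session.validate_frame_grid()
        sessions.append(session)
    return sessions


def write_ethogram(sessions: BehaviorSession | list[BehaviorSession], path: str | Path) -> None:
    """Write session(s) back to the ethogram CSV format (sorted, deterministic)."""
    if isinstance(sessions, BehaviorSession):
        sessions = [sessions]
    rows = []
    for sess in sessions:
        for seq in sess.sequences:
            for ev in seq.events:
                rows.append(
                    (sess.session_id, sess.animal_id, seq.sequence_id,
                     ev.phase.value, ev.start_s, ev.end_s)
                )
    df = pd.DataFrame(rows, columns=ETHOGRAM_COLUMNS)
    df = df.sort_values(["session_id", "start_s"], kind="mergesort")
    df.to_csv(path, index=False)


def read_units(
    spike_path: str | Path,
    meta_path: str | Path,
    *,
    strict: bool = False,
) -> list[Unit]:
    """Read spike times and unit metadata into a list of :class:`Unit`.

    Units present in the metadata but absent from the spike table receive
    empty spike trains with a warning (error in ``strict`` mode).  Unsorted
    spike times are sorted with a warning.
    """
    spikes = pd.read_csv(spike_path)
    _require_columns(spikes, ["unit_id", "spike_time_s"], spike_path)
    meta = pd.read_csv(meta_path)
    _require_columns(meta, ["unit_id", "structure", "hemisphere"], meta_path)

    by_unit = {
        str(uid): np.asarray(g["spike_time_s"], dtype=float)
        for uid, g in spikes.groupby("unit_id", sort=False)
    }
    has_waveform = all(c in meta.columns for c in _WAVEFORM_COLUMNS)

    units: list[Unit] = []
    for row, rec in meta.iterrows():
        uid = str(rec["unit_id"])
        try:
            structure = Structure(str(rec["structure"]))
        except ValueError:
            allowed = ", ".join(s.value for s in Structure)
            raise ValidationError(
                f"{meta_path}, row {row}: unknown structure {rec['structure']!r} "
                f"(allowed: {allowed})"
            ) from None
        try:
            hemisphere = Hemisphere(str(rec["hemisphere"]))
        except ValueError:
            allowed = ", ".join(h.value for h in Hemisphere)
            raise ValidationError(
                f"{meta_path}, row {row}: unknown hemisphere {rec['hemisphere']!r} "
                f"(allowed: {allowed})"
            ) from None
        st = by_unit.get(uid)
        if st is None:
            if strict:
                raise ValidationError(
                    f"{meta_path}: unit {uid} has no spikes in {spike_path} (strict mode)"
                )
            warnings.warn(f"unit {uid}: no spikes found; empty spike train", stacklevel=2)
            st = np.empty(0)
        wf = None
        if has_waveform and not rec[_WAVEFORM_COLUMNS].isna().any():
            wf = WaveformFeatures(*(float(rec[c]) for c in _WAVEFORM_COLUMNS))
        units.append(Unit(uid, structure, hemisphere, st, wf))
    return units


def write_units(units: list[Unit], spike_path: str | Path, meta_path: str | Path) -> None:
    """Write units to the spikes.csv / units.csv pair."""
    units = sorted(units, key=lambda u: u.unit_id)
    spike_frames = [
        pd.DataFrame({"unit_id": u.unit_id, "spike_time_s": u.spike_times_s})
        for u in units
    ]
    if spike_frames:
        pd.concat(spike_frames, ignore_index=True).to_csv(spike_path, index=False)
    else:  # still emit a valid header
        pd.DataFrame(columns=["unit_id", "spike_time_s"]).to_csv(spike_path, index=False)
    meta_rows = []
    for u in units:
        row: dict[str, Any] = {
            "unit_id": u.unit_id,
            "structure": u.structure.value,
            "hemisphere": u.hemisphere.value,
        }
        if u.waveform is not None:
            row.update(
                valley_width_ms=u.waveform.valley_width_ms,
                peak_width_ms=u.waveform.peak_width_ms,
                peak_to_valley_ms=u.waveform.peak_to_valley_ms,
            )
        meta_rows.append(row)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def write_table(result: Any, path: str | Path) -> None:
    """Write any tabular pipeline result to delimited text.

    Accepts a DataFrame directly or any result object exposing
    ``to_frame()``; row order is made deterministic by a stable sort on
    all columns before writing.
    """
    if isinstance(result, pd.DataFrame):
        df = result
    elif hasattr(result, "to_frame"):
        df = result.to_frame()
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__} as a table")
    df.to_csv(path, index=False)
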