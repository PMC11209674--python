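"""Peri-event time histograms: binned, smoothed, z-scored firing rates.

A PETH aligns a unit's spikes on repeated behavioral events, smooths the
spike train with a Gaussian kernel, bins it, averages over events, and
standardizes the binned rate against a baseline epoch.  Two standard
configurations mirror the two analysis regimes:

* sequence boundaries: 125 ms bins, kernel sigma 167 ms, window +-10 s,
  baseline = all bins of the window (mixed grooming/non-grooming);
* phase transitions: 40 ms bins, kernel sigma 40 ms, window +-3 s,
  baseline restricted to within-grooming bins away from sequence
  boundaries (pass the grooming intervals as ``valid_intervals``).

Smoothing-then-binning is implemented exactly for the linear operator:
each spike contributes its Gaussian kernel mass inside the bin (a
difference of normal CDFs), which is order-independent with binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .core import GroomingSequence, Unit

__all__ = [
    "PETHSpec",
    "PETH",
    "BOUNDARY_SPEC",
    "TRANSITION_SPEC",
    "build_peth",
    "population_bin_test",
    "time_warp_average",
]


@dataclass(frozen=True)
class PETHSpec:
    """Binning / smoothing / standardization parameters of a PETH."""

    bin_width_s: float = 0.125
    smooth_sigma_s: float = 0.167
    window_s: float = 10.0            # half-width; bins span [-window, +window]
    baseline: str = "full_window"     # or "valid_bins"
    exclude_center_s: float = 0.0     # exclude +-this around t=0 from the baseline

    def __post_init__(self) -> None:
        if self.smooth_sigma_s <= 0:
            raise ValueError("smooth_sigma_s must be > 0")
        n = self.window_s / self.bin_width_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_s must be a multiple of bin_width_s")
        if self.baseline not in ("full_window", "valid_bins"):
            raise ValueError(f"unknown baseline rule {self.baseline!r}")

    @property
    def bin_edges(self) -> np.ndarray:
        n = int(round(self.window_s / self.bin_width_s))
        return np.arange(-n, n + 1) * self.bin_width_s

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return (e[:-1] + e[1:]) / 2


#: sequence-boundary regime (125 ms bins, sigma 167 ms, +-10 s window)
BOUNDARY_SPEC = PETHSpec(0.125, 0.167, 10.0, "full_window")
#: phase-transition regime (40 ms bins, sigma 40 ms, +-3 s window,
#: baseline restricted to within-grooming bins)
TRANSITION_SPEC = PETHSpec(0.040, 0.040, 3.0, "valid_bins")


@dataclass
class PETH:
    """Event-aligned standardized firing rate of one unit."""

    unit_id: str
    event_type: str
    bin_centers_s: np.ndarray
    z: np.ndarray
    raw_rate_hz: np.ndarray
    n_events: int
    baseline_mean_hz: float
    baseline_sd_hz: float
    silent: bool = False
    spec: PETHSpec | None = None

    def mean_z(self, t0: float, t1: float) -> float:
        """Mean Z over bins whose centers lie in [t0, t1)."""
        m = (self.bin_centers_s >= t0) & (self.bin_centers_s < t1)
        return float(self.z[m].mean()) if m.any() else float("nan")

    def max_abs_z(self, t0: float, t1: float) -> float:
        m = (self.bin_centers_s >= t0) & (self.bin_centers_s < t1)
        return float(np.abs(self.z[m]).max()) if m.any() else float("nan")


def _smoothed_bin_mass(
    spikes: np.ndarray, edges: np.ndarray, sigma: float
) -> np.ndarray:
    """Gaussian kernel mass of each spike inside each bin, summed.

    Equivalent to convolving the spike delta train with N(0, sigma^2)
    and integrating over bins.
    """
    if spikes.size == 0:
        return np.zeros(edges.size - 1)
    z = (edges[None, :] - spikes[:, None]) / sigma
    cdf = ndtr(z)
    return np.diff(cdf, axis=1).sum(axis=0)


def build_peth(
    unit: Unit,
    event_times_s: np.ndarray,
    spec: PETHSpec,
    valid_intervals: list[tuple[float, float]] | None = None,
    recording_span: tuple[float, float] | None = None,
    event_type: str = "event",
) -> PETH:
    """Build a smoothed, binned, standardized PETH for one unit.

    Parameters
    ----------
    unit, event_times_s
        The unit and the alignment times (absolute seconds).
    spec
        Binning/smoothing/baseline parameters.
    valid_intervals
        Absolute-time intervals (e.g. grooming sequences with boundary
        epochs trimmed) restricting the baseline when the spec's rule is
        ``"valid_bins"``: a (event, bin) sample enters the averaged rate
        and the baseline only if the bin center falls inside one of the
        intervals.  ``None`` treats all bins as valid.
    recording_span
        If given, events whose full window leaves the span are dropped
        (with a count decrement) instead of zero-padded.

    The trial-averaged rate per bin is standardized with a single mean
    and SD taken over the baseline bins of the averaged PETH.  A unit
    with zero baseline SD gets ``z == 0`` and is flagged ``silent``.
    """
    events = np.sort(np.asarray(event_times_s, dtype=float))
    if recording_span is not None:
        lo, hi = recording_span
        keep = (events - spec.window_s >= lo) & (events + spec.window_s <= hi)
        if not np.all(keep):
            warnings.warn(
                f"unit {unit.unit_id}: dropped {int((~keep).sum())} events too close "
                "to the recording edge",
                stacklevel=2,
            )
        events = events[keep]
    if events.size == 0:
        raise ValueError(f"unit {unit.unit_id}: no events to align on")

    edges = spec.bin_edges
    centers = spec.bin_centers
    nbins = centers.size
    pad = 5 * spec.smooth_sigma_s

    use_mask = spec.baseline == "valid_bins" and valid_intervals is not None
    if use_mask:
        iv_starts = np.array([a for a, _ in valid_intervals])
        iv_ends = np.array([b for _, b in valid_intervals])

    rate_sum = np.zeros(nbins)
    valid_count = np.zeros(nbins)
    spikes = unit.spike_times_s
    for e in events:
        lo = np.searchsorted(spikes, e + edges[0] - pad)
        hi = np.searchsorted(spikes, e + edges[-1] + pad)
        mass = _smoothed_bin_mass(spikes[lo:hi] - e, edges, spec.smooth_sigma_s)
        if use_mask:
            abs_centers = centers + e
            inside = (
                (abs_centers[:, None] >= iv_starts[None, :])
                & (abs_centers[:, None] < iv_ends[None, :])
            ).any(axis=1)
        else:
            inside = np.ones(nbins, dtype=bool)
        rate_sum[inside] += mass[inside] / spec.bin_width_s
        valid_count[inside] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        raw_rate = rate_sum / valid_count
    raw_rate[valid_count == 0] = np.nan

    baseline_mask = valid_count > 0
    if spec.exclude_center_s > 0:
        baseline_mask &= np.abs(centers) > spec.exclude_center_s
    base = raw_rate[baseline_mask]
    mu = float(np.nanmean(base)) if base.size else float("nan")
    sd = float(np.nanstd(base)) if base.size else float("nan")

    silent = not np.isfinite(sd) or sd == 0
    if silent:
        z = np.zeros(nbins)
    else:
        z = (raw_rate - mu) / sd
        z[~np.isfinite(raw_rate)] = 0.0
    return PETH(
        unit_id=unit.unit_id,
        event_type=event_type,
        bin_centers_s=centers,
        z=z,
        raw_rate_hz=raw_rate,
        n_events=int(events.size),
        baseline_mean_hz=mu,
        baseline_sd_hz=0.0 if silent else sd,
        silent=silent,
        spec=spec,
    )


def population_bin_test(
    peths: list[PETH], alpha: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin z-test of the population mean Z against the standard normal.

    Under the null each cell's Z in a bin is N(0, 1), so the population
    mean has SD ``1/sqrt(n_cells)``.  Returns ``(significant, p)`` per
    bin; significant bins are the "diamonds" of the population displays.
    """
    if not peths:
        raise ValueError("no PETHs supplied")
    n = len(peths)
    if n < 10:
        warnings.warn(f"only {n} cells; population bin test is underpowered", stacklevel=2)
    Z = np.vstack([p.z for p in peths])
    mean = Z.mean(axis=0)
    stat = mean * np.sqrt(n)
    p = 2.0 * ndtr(-np.abs(stat))
    return p < alpha, p


def time_warp_average(
    units: list[Unit],
    sequences: list[GroomingSequence],
    bin_width_s: float = 0.125,
    pad_s: float = 2.0,
) -> dict:
    """Time-warped population average over repeats of one phase pattern.

    All sequences must share an identical phase-label pattern.  Each
    trial's per-phase interval is linearly rescaled to the median
    duration of that phase position across trials, so transition
    landmarks align exactly; ``pad_s`` of real (unwarped) time is kept
    before onset and after end.  Each unit's warped rate profile is
    standardized (its own mean/SD across warped bins) before averaging
    over trials and units.

    Returns a dict with ``t`` (warped bin centers, 0 = sequence onset),
    ``population_z`` (average standardized rate), ``unit_z`` (units x
    bins), and ``boundaries`` (warped phase-transition times).
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    pattern = [e.phase for e in sequences[0].events]
    bad = [
        s.sequence_id for s in sequences
        if [e.phase for e in s.events] != pattern
    ]
    if bad:
        raise ValueError(f"sequences with a different phase pattern: {bad}")

    n_ph = len(pattern)
    durs = np.array([[e.duration_s for e in s.events] for s in sequences])
    med = np.median(durs, axis=0)
    n_sub = np.maximum(1, np.round(med / bin_width_s).astype(int))
    n_pad = int(round(pad_s / bin_width_s))

    # warped grid: pad bins, then n_sub[k] bins per phase, then pad bins
    boundaries = np.concatenate([[0.0], np.cumsum(med)])
    t_list = [(-n_pad + 0.5 + np.arange(n_pad)) * bin_width_s]
    for k in range(n_ph):
        w = med[k] / n_sub[k]
        t_list.append(boundaries[k] + (0.5 + np.arange(n_sub[k])) * w)
    t_list.append(boundaries[-1] + (0.5 + np.arange(n_pad)) * bin_width_s)
    t = np.concatenate(t_list)
    nbins = t.size

    unit_profiles = np.zeros((len(units), nbins))
    for ui, unit in enumerate(units):
        acc = np.zeros(nbins)
        for s in sequences:
            # real-time edges matching the warped grid for this trial
            edges = [s.start_s - pad_s + np.arange(n_pad + 1) * bin_width_s]
            for k, ev in enumerate(s.events):
                w = ev.duration_s / n_sub[k]
                edges.append(ev.start_s + np.arange(1, n_sub[k] + 1) * w)
            edges.append(s.end_s + np.arange(1, n_pad + 1) * bin_width_s)
            real_edges = np.concatenate(edges)
            counts = np.diff(np.searchsorted(unit.spike_times_s, real_edges))
            widths = np.diff(real_edges)
            acc += counts / widths
        prof = acc / len(sequences)
        sd = prof.std()
        unit_profiles[ui] = (prof - prof.mean()) / sd if sd > 0 else 0.0
    return {
        "t": t,
        "population_z": unit_profiles.mean(axis=0),
        "unit_z": unit_profiles,
        "boundaries": boundaries,
        "pattern": [p.value for p in pattern],
    }
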