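"""Putative cell-type assignment from mean-waveform shape.

Units are assigned to broad-spiking principal cells (PC: pyramidal
neurons in cortex, medium spiny neurons in striatum) or narrow-spiking
interneurons (IN) by fuzzy k-means (fuzzy c-means) clustering of three
waveform features -- valley width, peak width (both full width at half
maximum) and peak-to-valley time -- with units whose maximum cluster
membership falls below a threshold (default 0.75) left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Unit, WaveformFeatures

__all__ = [
    "CellTypeAssignment",
    "extract_features",
    "fuzzy_cmeans",
    "fuzzy_kmeans_classify",
    "classify_units_by_structure",
]


@dataclass(frozen=True)
class CellTypeAssignment:
    unit_id: str
    putative_type: str     # "PC" | "IN" | "unclassified"
    membership: float      # max cluster membership in [0, 1]


class FeatureError(ValueError):
    """Raised when waveform features cannot be extracted from a trace."""


def _fwhm(t: np.ndarray, v: np.ndarray, idx: int) -> float:
    """Full width at half maximum of the extremum at ``idx``.

    The half level is half the extremum amplitude relative to the zero
    baseline; crossings are located by linear interpolation.
    """
    half = v[idx] / 2.0
    sign = np.sign(v[idx]) or 1.0
    w = sign * v  # extremum now a positive peak
    h = sign * half

    left = None
    for j in range(idx, 0, -1):
        if w[j - 1] < h <= w[j]:
            frac = (h - w[j - 1]) / (w[j] - w[j - 1])
            left = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    right = None
    for j in range(idx, len(w) - 1):
        if w[j + 1] < h <= w[j]:
            frac = (w[j] - h) / (w[j] - w[j + 1])
            right = t[j] + frac * (t[j + 1] - t[j])
            break
    if left is None or right is None:
        raise FeatureError("no half-maximum crossing within the trace")
    return float(right - left)


def extract_features(mean_waveform: np.ndarray, sample_rate_hz: float) -> WaveformFeatures:
    """Waveform shape features from a mean spike waveform.

    Expects the conventional extracellular shape: one dominant negative
    valley followed by a positive peak.  Widths are full widths at half
    maximum via linear interpolation; peak-to-valley is the time between
    the valley minimum and the subsequent peak maximum.  Times in ms.
    """
    v = np.asarray(mean_waveform, dtype=float)
    if v.ndim != 1 or v.size < 5:
        raise FeatureError("waveform must be a 1-D trace of at least 5 samples")
    if np.ptp(v) == 0:
        raise FeatureError("flat trace: no valley or peak")
    t_ms = np.arange(v.size) / sample_rate_hz * 1000.0
    i_valley = int(np.argmin(v))
    if v[i_valley] >= 0:
        raise FeatureError("no negative valley found")
    after = v[i_valley:]
    i_peak = i_valley + int(np.argmax(after))
    if i_peak == i_valley or v[i_peak] <= 0:
        raise FeatureError("no positive peak after the valley")
    return WaveformFeatures(
        valley_width_ms=_fwhm(t_ms, v, i_valley),
        peak_width_ms=_fwhm(t_ms, v, i_peak),
        peak_to_valley_ms=float(t_ms[i_peak] - t_ms[i_valley]),
    )


# ---------------------------------------------------------------------------
# fuzzy c-means


def fuzzy_cmeans(
    X: np.ndarray,
    k: int = 2,
    m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 300,
    n_restarts: int = 20,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fuzzy c-means clustering (Bezdek's algorithm).

    Minimizes ``sum_i sum_c u_ic^m ||x_i - v_c||^2`` subject to per-point
    memberships summing to one.  Runs ``n_restarts`` random
    initializations and keeps the solution with the lowest objective.

    Returns ``(centers (k, d), memberships (n, k), objective)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        centers += rng.normal(scale=1e-6, size=centers.shape)  # break duplicate points
        prev_obj = np.inf
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-300)
            # u_ic = 1 / sum_j (d_ic/d_ij)^(2/(m-1))
            ratio = d2[:, :, None] / d2[:, None, :]
            u = 1.0 / (ratio ** (1.0 / (m - 1.0))).sum(axis=2)
            um = u ** m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            obj = float((um * d2).sum())
            if prev_obj - obj < tol * max(abs(prev_obj), 1.0):
                break
            prev_obj = obj
        if best is None or obj < best[0]:
            best = (obj, centers.copy(), u.copy())
    obj, centers, u = best
    return centers, u, obj


def fuzzy_kmeans_classify(
    features: list[WaveformFeatures],
    unit_ids: list[str] | None = None,
    k: int = 2,
    fuzzifier: float = 2.0,
    threshold: float = 0.75,
    seed: int | None = None,
    standardize: bool = True,
) -> list[CellTypeAssignment]:
    """Cluster waveform features into putative PC / IN classes.

    Features are z-scored per dimension before clustering (raw scale via
    ``standardize=False``).  The cluster with the smaller mean spike
    width (valley + peak FWHM, original scale) is labeled IN -- the
    narrow-spiking interneuron convention -- and the other PC.  Units
    whose maximum membership is below ``threshold`` are unclassified.
    """
    if unit_ids is None:
        unit_ids = [f"unit-{i:04d}" for i in range(len(features))]
    X_raw = np.array([f.as_array() for f in features])
    if len(X_raw) < k:
        raise ValueError(f"need at least k={k} units, got {len(X_raw)}")
    X = X_raw.copy()
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    centers, u, _ = fuzzy_cmeans(
        X, k=k, m=fuzzifier, seed=seed,
    )
    # label by raw-scale mean width per cluster (hard assignment)
    hard = u.argmax(axis=1)
    widths = X_raw[:, 0] + X_raw[:, 1]
    mean_width = np.array([
        widths[hard == c].mean() if np.any(hard == c) else np.inf for c in range(k)
    ])
    order = np.argsort(mean_width)  # narrowest first
    label_of = {int(order[0]): "IN"}
    for c in order[1:]:
        label_of[int(c)] = "PC"

    out: list[CellTypeAssignment] = []
    for uid, memberships in zip(unit_ids, u):
        c = int(memberships.argmax())
        mship = float(memberships[c])
        ptype = label_of[c] if mship >= threshold else "unclassified"
        out.append(CellTypeAssignment(uid, ptype, mship))
    return out


def classify_units_by_structure(
    units: list[Unit],
    min_per_structure: int = 10,
    **kwargs,
) -> pd.DataFrame:
    """Per-structure fuzzy k-means classification with pooled fallback.

    Units are clustered separately within each recorded structure; any
    structure with fewer than ``min_per_structure`` waveform-bearing
    units is pooled with the rest and clustered jointly (small-sample
    stability).  Units without waveform features are unclassified.
    Returns a frame with columns unit_id, structure, putative_type,
    membership.
    """
    with_wf = [u for u in units if u.waveform is not None]
    rows: list[tuple[str, str, str, float]] = []
    for u in units:
        if u.waveform is None:
            rows.append((u.unit_id, u.structure.value, "unclassified", float("nan")))

    by_struct: dict[str, list[Unit]] = {}
    for u in with_wf:
        by_struct.setdefault(u.structure.value, []).append(u)
    pooled: list[Unit] = []
    for struct, members in sorted(by_struct.items()):
        if len(members) < min_per_structure:
            warnings.warn(
                f"structure {struct}: only {len(members)} units; pooled clustering",
                stacklevel=2,
            )
            pooled.extend(members)
        else:
            assigns = fuzzy_kmeans_classify(
                [u.waveform for u in members], [u.unit_id for u in members], **kwargs
            )
            for u, a in zip(members, assigns):
                rows.append((a.unit_id, u.structure.value, a.putative_type, a.membership))
    if pooled:
        if len(pooled) >= 2:
            assigns = fuzzy_kmeans_classify(
                [u.waveform for u in pooled], [u.unit_id for u in pooled], **kwargs
            )
            for u, a in zip(pooled, assigns):
                rows.append((a.unit_id, u.structure.value, a.putative_type, a.membership))
        else:
            for u in pooled:
                rows.append((u.unit_id, u.structure.value, "unclassified", float("nan")))
    df = pd.DataFrame(rows, columns=["unit_id", "structure", "putative_type", "membership"])
    return df.sort_values("unit_id", kind="mergesort").reset_index(drop=True)
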