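"""Population-level analyses: PCA trajectories and ensemble decoding.

The decoder follows the "pseudolinear" discriminant convention: a linear
discriminant with a pooled *diagonal* covariance (per-feature variances)
and uniform class priors.  Upcoming-phase decoding is leave-one-out over
transitions, per time bin, with features built from 11 adjacent 40 ms
bins weighted by a Gaussian window (+-220 ms ~ +-2.5 sigma) so spikes
near t = 0 dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "DecodingResult",
    "pca_trajectories",
    "DiagonalLDA",
    "lda_decode_timecourse",
    "neuron_inclusion_curve",
    "added_information",
]


# ---------------------------------------------------------------------------
# PCA trajectories


@dataclass
class PCATrajectories:
    components: np.ndarray            # units x n_components
    projections: np.ndarray           # bins x n_components
    explained_variance_ratio: np.ndarray
    kept_columns: np.ndarray          # indices of non-constant units


def pca_trajectories(peth_matrix: np.ndarray, n_components: int = 3) -> PCATrajectories:
    """Principal-component trajectories of a bins x units Z matrix.

    Each time bin is an observation, each neuron a variable.  Constant
    columns are dropped with a warning; the trajectory is the projection
    of every bin onto the first ``n_components`` components.
    """
    X = np.asarray(peth_matrix, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 units for PCA trajectories")
    keep = X.std(axis=0) > 0
    if not np.all(keep):
        warnings.warn(f"dropped {int((~keep).sum())} constant unit columns", stacklevel=2)
    X = X[:, keep]
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(X)
    return PCATrajectories(
        components=pca.components_.T,
        projections=proj,
        explained_variance_ratio=pca.explained_variance_ratio_,
        kept_columns=np.nonzero(keep)[0],
    )


# ---------------------------------------------------------------------------
# diagonal-covariance linear discriminant


class DiagonalLDA:
    """Linear discriminant with pooled diagonal covariance, uniform prior.

    Score of class c for sample x:  -sum_j (x_j - mu_cj)^2 / var_j .
    """

    def __init__(self, var_floor: float = 1e-9) -> None:
        self.var_floor = var_floor

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiagonalLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        self.var_ = resid.var(axis=0) + self.var_floor
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = X[:, None, :] - self.means_[None, :, :]
        return -(d ** 2 / self.var_[None, None, :]).sum(axis=2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]


def _loo_predict(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions with the diagonal discriminant, vectorized.

    For fold i only the held-out sample's own class statistics change;
    the class means and pooled per-feature variance are down-dated in
    closed form, so no per-fold refit is needed.  Folds whose training
    split loses a class (single-instance classes) predict among the
    remaining classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    c = classes.size
    counts = np.bincount(y_idx, minlength=c).astype(float)
    sums = np.zeros((c, d))
    np.add.at(sums, y_idx, X)
    means = sums / counts[:, None]
    resid = X - means[y_idx]
    ss = np.zeros((c, d))
    np.add.at(ss, y_idx, resid ** 2)

    n_own = counts[y_idx]                          # (n,)
    with np.errstate(divide="ignore", invalid="ignore"):
        means_own_loo = (sums[y_idx] - X) / (n_own - 1)[:, None]
        # SS of the own class without sample i
        ss_own_loo = ss[y_idx] - (n_own / np.maximum(n_own - 1, 1))[:, None] * resid ** 2
    ss_total = ss.sum(axis=0)
    ss_loo = ss_total[None, :] - ss[y_idx] + np.where(
        (n_own > 1)[:, None], ss_own_loo, 0.0
    )
    var_loo = ss_loo / (n - 1) + 1e-9               # pooled variance per fold

    diff = X[:, None, :] - means[None, :, :]        # (n, c, d)
    own = np.arange(n), y_idx
    diff[own] = np.where(
        (n_own > 1)[:, None], X - means_own_loo, np.inf
    )
    scores = -np.einsum("ncd,nd->nc", diff ** 2, 1.0 / var_loo)
    return classes[np.argmax(scores, axis=1)]


@dataclass
class DecodingResult:
    """Leave-one-out decoding accuracy per time bin."""

    bin_centers_s: np.ndarray
    correct_fraction: np.ndarray
    chance: float
    threshold: float          # chance + 2.3 SD (binomial), the p = 0.01 line
    n_transitions: int
    classes: list


def gaussian_context_weights(n_context: int = 11, sd_bins: float = 2.2) -> np.ndarray:
    """Gaussian weights over the context bins (center bin in the middle).

    Default: 11 bins of 40 ms, sd 2.2 bins (88 ms), so the +-220 ms
    context spans +-2.5 sigma.
    """
    half = n_context // 2
    x = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (x / sd_bins) ** 2)
    return w / w.sum()


def _context_features(rates: np.ndarray, b: int, weights: np.ndarray) -> np.ndarray:
    """Gaussian-weighted rate features around bin b.

    ``rates`` is trials x units x bins; out-of-range context bins are
    clipped to the edge (their weight still applies).
    """
    half = len(weights) // 2
    idx = np.clip(np.arange(b - half, b + half + 1), 0, rates.shape[2] - 1)
    return np.tensordot(rates[:, :, idx], weights, axes=([2], [0]))


def lda_decode_timecourse(
    rates: np.ndarray,
    labels: np.ndarray,
    bin_centers_s: np.ndarray,
    n_context: int = 11,
    context_sd_bins: float = 2.2,
    min_class_instances: int = 2,
) -> DecodingResult:
    """Upcoming-phase decoding accuracy as a function of time.

    Parameters
    ----------
    rates
        trials x units x bins array of (normalized) firing rates aligned
        on the transitions.
    labels
        Upcoming-phase label per trial.  Classes with fewer than
        ``min_class_instances`` trials are dropped with a warning.

    For each time bin a diagonal-covariance discriminant is fitted on the
    Gaussian-weighted 11-bin context features of all transitions but one
    and evaluated on the held-out transition (leave-one-out), cycling
    over transitions.  Chance is 1/n_classes (uniform prior); the
    significance threshold is chance + 2.3 binomial SD, corresponding to
    p = 0.01.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    drop = classes[counts < min_class_instances]
    if drop.size:
        warnings.warn(f"classes with < {min_class_instances} instances dropped: "
                      f"{list(drop)}", stacklevel=2)
        keep = ~np.isin(labels, drop)
        rates, labels = rates[keep], labels[keep]
        classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes with enough instances")
    n_trials, _, n_bins = rates.shape
    weights = gaussian_context_weights(n_context, context_sd_bins)
    correct = np.empty(n_bins)
    for b in range(n_bins):
        X = _context_features(rates, b, weights)
        pred = _loo_predict(X, labels)
        correct[b] = float(np.mean(pred == labels))
    chance = 1.0 / classes.size
    sd = np.sqrt(chance * (1 - chance) / n_trials)
    return DecodingResult(
        bin_centers_s=np.asarray(bin_centers_s),
        correct_fraction=correct,
        chance=chance,
        threshold=chance + 2.3 * sd,
        n_transitions=n_trials,
        classes=list(classes),
    )


# ---------------------------------------------------------------------------
# neuron-inclusion curves


@dataclass
class InclusionCurve:
    n_units: np.ndarray
    mean_correct: np.ndarray
    sem_correct: np.ndarray
    chance_mean: np.ndarray
    chance_sem: np.ndarray
    n_repeats: int


def _subset_loo_rate(X: np.ndarray, y: np.ndarray) -> float:
    pred = _loo_predict(X, y)
    return float(np.mean(pred == y))


def neuron_inclusion_curve(
    rates: np.ndarray,
    labels: np.ndarray,
    unit_mask: np.ndarray,
    n_grid: list[int],
    repeats: int = 100,
    seed: int | None = None,
    base_mask: np.ndarray | None = None,
) -> InclusionCurve:
    """Decoding accuracy vs number of included units from one area.

    ``rates`` is trials x units (single pre-transition window features);
    ``unit_mask`` selects the area's units.  For each n in ``n_grid``,
    ``repeats`` random subsets of n units are drawn and the leave-one-out
    correct rate averaged.  The chance curve repeats the procedure with
    all rates replaced by standard-normal surrogates, which destroys any
    label information while keeping the geometry of the estimator.
    ``base_mask`` (for added-information curves) selects units that are
    always included alongside the n sampled ones.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    chance_level = 1.0 / classes.size
    area_idx = np.nonzero(np.asarray(unit_mask))[0]
    base_idx = np.nonzero(np.asarray(base_mask))[0] if base_mask is not None else np.empty(0, int)

    n_grid = list(n_grid)
    max_n = int(area_idx.size)
    grid = [n for n in n_grid if n <= max_n]
    if len(grid) < len(n_grid):
        warnings.warn(
            f"n_grid truncated to available units ({max_n})", stacklevel=2
        )

    means, sems, cmeans, csems = [], [], [], []
    for n in grid:
        vals = np.empty(repeats)
        cvals = np.empty(repeats)
        for r in range(repeats):
            chosen = rng.choice(area_idx, size=n, replace=False) if n else np.empty(0, int)
            cols = np.concatenate([base_idx, chosen]).astype(int)
            if cols.size == 0:
                vals[r] = chance_level
                cvals[r] = chance_level
                continue
            X = rates[:, cols]
            vals[r] = _subset_loo_rate(X, labels)
            cvals[r] = _subset_loo_rate(rng.standard_normal(X.shape), labels)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(repeats) if repeats > 1 else 0.0)
        cmeans.append(cvals.mean())
        csems.append(cvals.std(ddof=1) / np.sqrt(repeats) if repeats > 1 else 0.0)
    return InclusionCurve(
        n_units=np.array(grid),
        mean_correct=np.array(means),
        sem_correct=np.array(sems),
        chance_mean=np.array(cmeans),
        chance_sem=np.array(csems),
        n_repeats=repeats,
    )


def added_information(
    rates: np.ndarray,
    labels: np.ndarray,
    unit_mask: np.ndarray,
    n_grid: list[int],
    repeats: int = 100,
    seed: int | None = None,
) -> InclusionCurve:
    """Accuracy when adding n units of one area to all other structures.

    The base ensemble is every unit outside the target area; the curve
    shows the information the target area adds on top of it.
    """
    unit_mask = np.asarray(unit_mask, dtype=bool)
    return neuron_inclusion_curve(
        rates, labels, unit_mask, n_grid, repeats=repeats, seed=seed,
        base_mask=~unit_mask,
    )
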