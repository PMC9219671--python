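"""Wavenumber feature importance and interval identification.

For a fitted discriminant model the linear score of class i at input x
expands as z . zbar_i - |zbar_i|^2 / 2 with z = (x - m) V, so the
gradient of class i's score in the original feature space is
w_i = V zbar_i.  These per-class weight vectors, normalized to the global
maximum absolute value, are the feature importances.  They are filtered
per class at the 95% absolute-weight quantile with a boundary margin,
ranked by the max-over-classes normalized magnitude, fed into an
incremental top-k refit experiment (split -> augment -> LDA -> nearest
centroid, repeated over random splits), and grouped into contiguous
wavenumber intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import ConfigurationError
from .lda import LDAModel, augment_gaussian, classify, fit_lda, project, split_train_test
from .preprocess import SpectraMatrix
from .synth import WavenumberAxis

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


@dataclass
class ImportanceProfile:
    """Per-class feature weights with optional quantile filtering."""

    axis: WavenumberAxis
    classes: tuple[str, ...]
    weights: np.ndarray  # c x p
    normalized: np.ndarray  # c x p, global max |entry| == 1
    retained_mask: Optional[np.ndarray] = None  # c x p booleans
    boundary_margin: int = 0
    quantile: Optional[float] = None

    @property
    def p(self) -> int:
        return self.weights.shape[1]

    def retained_union(self) -> np.ndarray:
        """Feature indices retained by at least one class."""
        if self.retained_mask is None:
            return np.arange(self.p)
        return np.nonzero(self.retained_mask.any(axis=0))[0]

    def eliminated_for_all(self) -> np.ndarray:
        """Feature indices retained by no class."""
        if self.retained_mask is None:
            return np.array([], dtype=int)
        return np.nonzero(~self.retained_mask.any(axis=0))[0]


@dataclass
class AccuracyCurve:
    """Mean +/- SD test accuracy versus number of top-ranked features."""

    k: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    n_repeats: int

    def smallest_k_at(self, level: float = 1.0, atol: float = 1e-12) -> Optional[int]:
        hit = np.nonzero(self.mean_accuracy >= level - atol)[0]
        return int(self.k[hit[0]]) if hit.size else None


@dataclass
class Interval:
    lo: float
    hi: float
    peak_importance: float
    feature_indices: tuple[int, ...]


@dataclass
class IntervalSet:
    """Per-class lists of non-overlapping wavenumber intervals."""

    by_class: dict  # name -> list[Interval]

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.by_class.values())


def extract_importances(model: LDAModel) -> ImportanceProfile:
    """Per-class weight vectors w_i = V zbar_i, globally normalized."""
    if model.axis is None:
        raise ConfigurationError("model carries no wavenumber axis")
    W = model.centroids @ model.V.T  # c x p
    peak = np.max(np.abs(W))
    if peak == 0:
        raise ConfigurationError("all-zero importance weights (degenerate model)")
    return ImportanceProfile(
        axis=model.axis,
        classes=model.classes,
        weights=W,
        normalized=W / peak,
    )


def filter_importances(
    profile: ImportanceProfile, q: float = 0.95, boundary_margin: int = 10
) -> ImportanceProfile:
    """Keep, per class, features whose |weight| strictly exceeds that
    class's q-quantile of |weights| (linear-interpolation quantile), and
    drop features within `boundary_margin` of either range edge."""
    if not (0.0 < q < 1.0):
        raise ConfigurationError("quantile q must lie strictly between 0 and 1")
    if boundary_margin < 0:
        raise ConfigurationError("boundary_margin must be >= 0")
    absw = np.abs(profile.weights)
    thresholds = np.quantile(absw, q, axis=1, keepdims=True)
    mask = absw > thresholds
    if boundary_margin > 0:
        mask[:, :boundary_margin] = False
        if boundary_margin < profile.p:
            mask[:, profile.p - boundary_margin :] = False
        else:
            mask[:] = False
    return replace(
        profile, retained_mask=mask, boundary_margin=boundary_margin, quantile=q
    )


def rank_features(profile: ImportanceProfile) -> np.ndarray:
    """Global feature ranking for the incremental experiment.

    Features are scored by the max-over-classes |normalized weight| and
    sorted descending, ties broken toward the lower wavenumber.  When a
    retained mask is present, the retained union comes first and the
    filtered-out remainder follows in the same order, so the ranking
    still covers all p features.
    """
    score = np.max(np.abs(profile.normalized), axis=0)
    order = np.lexsort((np.arange(profile.p), -score))  # desc score, asc index
    if profile.retained_mask is None:
        return order
    retained = set(profile.retained_union().tolist())
    first = [i for i in order if i in retained]
    rest = [i for i in order if i not in retained]
    return np.asarray(first + rest, dtype=int)


def incremental_feature_accuracy(
    M: SpectraMatrix,
    profile: ImportanceProfile,
    n_repeats: int = 20,
    k_max: int = 100,
    seed: SeedLike = 0,
    split_ratio: float = 0.5,
    augment_sigma: float = 0.05,
    augment_copies: int = 2,
    shrinkage: float = 1e-3,
    n_components: int = 2,
    convergence_level: float = 0.999,
    convergence_patience: int = 5,
) -> AccuracyCurve:
    """Accuracy of the full chain refit on the top-k features, k = 1..k_max.

    For each k the split -> augment -> LDA -> nearest-centroid chain is
    refit on `n_repeats` random stratified splits and the test-set
    accuracy recorded as mean +/- SD.  The same per-repeat split seeds are
    reused across k (common random numbers), and the sweep stops early
    once the mean accuracy stays >= `convergence_level` for
    `convergence_patience` consecutive k.
    """
    if k_max > M.p:
        raise ConfigurationError(f"k_max = {k_max} exceeds feature count p = {M.p}")
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    ranked = rank_features(profile)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(n_repeats)

    ks, means, sds = [], [], []
    streak = 0
    n_comp = n_components
    for k in range(1, k_max + 1):
        sub = M.take_features(ranked[:k])
        accs = np.empty(n_repeats)
        for r, rseed in enumerate(repeat_seeds):
            child = np.random.SeedSequence(entropy=rseed.entropy, spawn_key=rseed.spawn_key)
            split_rng, aug_rng = (np.random.default_rng(s) for s in child.spawn(2))
            train, test = split_train_test(sub, split_ratio, split_rng)
            train_aug = augment_gaussian(train, augment_sigma, augment_copies, aug_rng)
            k_comp = min(n_comp, len(sub.classes) - 1)
            model = fit_lda(train_aug, n_components=k_comp, shrinkage=shrinkage)
            pred = classify(model, project(model, test.X))
            accs[r] = float((pred == test.labels).mean())
        ks.append(k)
        means.append(accs.mean())
        sds.append(accs.std())
        streak = streak + 1 if accs.mean() >= convergence_level else 0
        if streak >= convergence_patience:
            break
    return AccuracyCurve(
        k=np.asarray(ks, dtype=int),
        mean_accuracy=np.asarray(means),
        sd_accuracy=np.asarray(sds),
        n_repeats=n_repeats,
    )


def group_runs(indices: Sequence[int], gap_tol: int = 2) -> list[list[int]]:
    """Split sorted feature indices into maximal runs with gaps <= gap_tol."""
    idx = sorted(int(i) for i in indices)
    if not idx:
        return []
    runs: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i - runs[-1][-1] <= gap_tol:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def group_intervals(
    profile: ImportanceProfile, k: int = 25, gap_tol: int = 2
) -> IntervalSet:
    """Group the top-k ranked features into per-class wavenumber intervals.

    Each selected feature is attributed to the class with the largest
    |weight| there; per class, consecutive selected features at most
    `gap_tol` grid steps apart merge into one interval, reported with its
    cm-1 bounds and the peak normalized importance inside it.
    """
    if k > profile.p:
        raise ConfigurationError(f"k = {k} exceeds feature count p = {profile.p}")
    by_class: dict = {name: [] for name in profile.classes}
    if k <= 0:
        return IntervalSet(by_class=by_class)
    top = rank_features(profile)[:k]
    owner = np.argmax(np.abs(profile.weights), axis=0)
    wn = profile.axis.values
    score = np.max(np.abs(profile.normalized), axis=0)
    for ci, name in enumerate(profile.classes):
        mine = [int(i) for i in top if owner[i] == ci]
        for run in group_runs(mine, gap_tol):
            by_class[name].append(
                Interval(
                    lo=float(wn[run[0]]),
                    hi=float(wn[run[-1]]),
                    peak_importance=float(score[run].max()),
                    feature_indices=tuple(run),
                )
            )
    return IntervalSet(by_class=by_class)
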