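"""Spectral preprocessing chain.

Five steps, in a fixed order: wavenumber-range selection (default
300-1800 cm-1), rubber-band baseline correction (lower convex hull),
cosmic-ray outlier elimination (per-wavenumber median/MAD rule with
whole-spectrum removal), per-spectrum standardization to mean 0 / SD 1,
and Savitzky-Golay smoothing (window 11, order 2, mirror edges).  The
result is a samples x features matrix ready for discriminant analysis.

Conventions: the population SD (divide by n) is used both for
standardization and for archetype SDs; smoothing runs after
standardization and rows are not re-standardized afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import ConfigurationError, DegenerateInputError
from .synth import SpectraSet, Spectrum, WavenumberAxis

STAGE_ORDER = (
    "select_range",
    "rubberband_baseline",
    "remove_outliers",
    "standardize",
    "smooth_sg",
)


@dataclass
class SpectraMatrix:
    """Samples x spectral-features matrix with labels and shared axis."""

    X: np.ndarray
    axis: WavenumberAxis
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise ConfigurationError("X must be 2-D (samples x features)")
        if self.X.shape[1] != self.axis.n_points:
            raise ConfigurationError("feature count does not match axis")
        if self.X.shape[0] != self.labels.size:
            raise ConfigurationError("label count does not match rows")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("non-finite entries in X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def class_indices(self, name: str) -> np.ndarray:
        return np.nonzero(self.labels == name)[0]

    def take_rows(self, idx: Sequence[int]) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        return SpectraMatrix(self.X[idx], self.axis, self.labels[idx], dict(self.meta))

    def take_features(self, idx: Sequence[int]) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        order = np.sort(idx)
        return SpectraMatrix(
            self.X[:, order],
            WavenumberAxis(self.axis.values[order]),
            self.labels,
            dict(self.meta),
        )


@dataclass(frozen=True)
class ArchetypeSpectrum:
    """Per-class mean spectrum with per-wavenumber SD (a QC summary)."""

    axis: WavenumberAxis
    mean: np.ndarray
    sd: np.ndarray
    n_members: int

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape or self.mean.size != self.axis.n_points:
            raise ConfigurationError("archetype mean/sd/axis lengths differ")
        if np.any(self.sd < 0):
            raise ConfigurationError("negative archetype SD")


@dataclass(frozen=True)
class PreprocessParams:
    lo: float = 300.0
    hi: float = 1800.0
    outlier_threshold: float = 8.0
    sg_window: int = 11
    sg_order: int = 2


def select_range(spectrum: Spectrum, lo: float = 300.0, hi: float = 1800.0) -> Spectrum:
    """Keep exactly the grid points with lo <= shift <= hi."""
    if lo >= hi:
        raise ConfigurationError("lo must be < hi")
    mask = (spectrum.axis.values >= lo) & (spectrum.axis.values <= hi)
    if not mask.any():
        raise DegenerateInputError(f"no axis points inside [{lo}, {hi}] cm-1")
    return Spectrum(
        axis=WavenumberAxis(spectrum.axis.values[mask]),
        intensities=spectrum.intensities[mask],
        label=spectrum.label,
        meta=dict(spectrum.meta),
    )


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain, lower hull only; x is strictly increasing."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross <= 0:  # last point lies on or above the new chord
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_baseline(spectrum: Spectrum) -> tuple[np.ndarray, Spectrum]:
    """Rubber-band baseline: the lower convex hull of (shift, intensity),
    linearly interpolated between hull vertices, subtracted from the raw
    signal.  The corrected spectrum is >= 0 with equality at hull vertices;
    both endpoints are always vertices.
    """
    if spectrum.axis.n_points < 3:
        raise DegenerateInputError("rubber-band correction needs >= 3 points")
    x, y = spectrum.axis.values, spectrum.intensities
    hull = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[hull], y[hull])
    corrected = y - baseline
    # exact zeros at vertices; clip float dust so the >= 0 contract holds
    corrected[corrected < 0] = 0.0
    return baseline, Spectrum(
        axis=spectrum.axis,
        intensities=corrected,
        label=spectrum.label,
        meta=dict(spectrum.meta),
    )


def remove_outliers(
    sset: SpectraSet, threshold: float = 8.0
) -> tuple[SpectraSet, list[int]]:
    """Eliminate whole spectra containing cosmic-ray-like outliers.

    For each wavenumber the median and MAD across spectra are computed; a
    spectrum is dropped if any of its points exceeds
    median + threshold * robust_sd at that wavenumber, with
    robust_sd = 1.4826 * MAD.  Cosmic-ray hits are single-channel and
    positive, hence the one-sided rule.

    Each column's robust SD is floored at the global robust SD of all
    deviations: after baseline correction the columns next to the range
    edges are pinned to single noisy hull vertices, so their MAD is
    near-degenerate while their tail is not, and an unfloored rule flags
    ordinary spectra there.  Planted spikes sit two orders of magnitude
    above either scale, so the floor does not affect their detection.
    """
    if len(sset) < 3:
        raise DegenerateInputError("outlier removal needs >= 3 spectra")
    Y = sset.intensity_matrix()
    med = np.median(Y, axis=0)
    dev = Y - med
    robust_sd = 1.4826 * np.median(np.abs(dev), axis=0)
    floor = 1.4826 * np.median(np.abs(dev))
    limit = med + threshold * np.maximum(robust_sd, floor)
    bad = np.nonzero((Y > limit).any(axis=1))[0]
    if bad.size == len(sset):
        raise DegenerateInputError(
            "all spectra flagged as outliers; lower the threshold aggressiveness"
        )
    keep = [s for i, s in enumerate(sset.spectra) if i not in set(bad.tolist())]
    return SpectraSet(keep), [int(i) for i in bad]


def standardize(spectrum: Spectrum) -> Spectrum:
    """Normalize a spectrum to its own mean and (population) SD."""
    y = spectrum.intensities
    sd = float(y.std())
    if sd == 0.0:
        raise DegenerateInputError("constant spectrum cannot be standardized")
    return Spectrum(
        axis=spectrum.axis,
        intensities=(y - y.mean()) / sd,
        label=spectrum.label,
        meta=dict(spectrum.meta),
    )


def smooth_sg(spectrum: Spectrum, window: int = 11, order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing with mirror-padded edges (length preserved)."""
    if window % 2 == 0:
        raise ConfigurationError("SG window must be odd")
    if order >= window:
        raise ConfigurationError("SG order must be smaller than the window")
    if spectrum.axis.n_points < window:
        raise DegenerateInputError("spectrum shorter than the SG window")
    return Spectrum(
        axis=spectrum.axis,
        intensities=savgol_filter(spectrum.intensities, window, order, mode="mirror"),
        label=spectrum.label,
        meta=dict(spectrum.meta),
    )


def compute_archetype(rows: np.ndarray, axis: WavenumberAxis) -> ArchetypeSpectrum:
    """Mean and per-wavenumber population SD over one class's spectra."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise DegenerateInputError("archetype needs >= 2 member spectra")
    return ArchetypeSpectrum(
        axis=axis,
        mean=rows.mean(axis=0),
        sd=rows.std(axis=0),
        n_members=rows.shape[0],
    )


def class_archetypes(M: SpectraMatrix) -> dict[str, ArchetypeSpectrum]:
    return {
        c: compute_archetype(M.X[M.class_indices(c)], M.axis) for c in M.classes
    }


def preprocess_pipeline(
    sset: SpectraSet, params: PreprocessParams = PreprocessParams()
) -> SpectraMatrix:
    """Apply the five preprocessing steps in their fixed order.

    Returns the preprocessed samples x features matrix; run metadata
    records the stage order, removed spectrum indices (relative to the
    input set) and the final dimensions.
    """
    selected = [select_range(s, params.lo, params.hi) for s in sset.spectra]
    corrected = [rubberband_baseline(s)[1] for s in selected]
    kept, removed = remove_outliers(SpectraSet(corrected), params.outlier_threshold)
    normalized = [standardize(s) for s in kept.spectra]
    smoothed = [
        smooth_sg(s, params.sg_window, params.sg_order) for s in normalized
    ]
    out = SpectraSet(smoothed)
    X = out.intensity_matrix()
    return SpectraMatrix(
        X=X,
        axis=out.axis,
        labels=out.labels,
        meta={
            "stage_order": list(STAGE_ORDER),
            "n_input": len(sset),
            "removed_indices": removed,
            "n": X.shape[0],
            "p": X.shape[1],
            "params": params,
        },
    )
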