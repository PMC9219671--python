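"""End-to-end orchestration: generate -> preprocess -> LDA -> importance
-> band assignment, under one seeded configuration.

One root seed fans out deterministically to per-stage child seeds (spawn
order: generate, spikes, split, augment, curve), so every stage is
independently reproducible and two runs with the same config and seed
yield identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .bands import assign_peaks, load_band_table
from .exceptions import ConfigurationError
from .importance import (
    AccuracyCurve,
    ImportanceProfile,
    IntervalSet,
    extract_importances,
    filter_importances,
    group_intervals,
    incremental_feature_accuracy,
)
from .lda import augment_gaussian, classify, evaluate, fit_lda, project, split_train_test
from .preprocess import PreprocessParams, preprocess_pipeline
from .synth import WavenumberAxis, default_profiles, generate_dataset, inject_spikes

log = logging.getLogger("serslda.pipeline")


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run.

    Defaults are the study conditions: 197 spectra over a 1024-point
    250-1900 cm-1 grid, six planted cosmic-ray spikes, 300-1800 cm-1
    selection, Savitzky-Golay window 11 / order 2, a 50:50 stratified
    split, Gaussian-noise augmentation, a 2-component discriminant model
    and the 95% importance-quantile filter.
    """

    seed: int = 0
    # synthetic data
    n_total: int = 197
    axis_points: int = 1024
    axis_lo: float = 250.0
    axis_hi: float = 1900.0
    exclusive_amplitude: float = 0.15
    n_spiked: int = 6
    spike_height: float = 20.0
    # preprocessing
    range_lo: float = 300.0
    range_hi: float = 1800.0
    outlier_threshold: float = 8.0
    sg_window: int = 11
    sg_order: int = 2
    # discriminant analysis
    split_ratio: float = 0.5
    augment_sigma: float = 0.05
    augment_copies: int = 2
    n_components: int = 2
    shrinkage: float = 1e-3
    # importance
    quantile: float = 0.95
    boundary_margin: int = 10
    curve_repeats: int = 20
    curve_k_max: int = 100
    interval_k: int = 25
    gap_tol: int = 2
    assign_tol: float = 5.0
    run_curve: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; an empty list means the config satisfies
    every stage precondition."""
    problems: list[str] = []
    if config.n_total < 3:
        problems.append("n_total must be >= 3 (one spectrum per class minimum)")
    if config.axis_points < 2:
        problems.append("axis_points must be >= 2")
    if config.axis_lo >= config.axis_hi:
        problems.append("axis_lo must be < axis_hi")
    if config.range_lo >= config.range_hi:
        problems.append("range_lo must be < range_hi")
    if config.sg_window % 2 == 0:
        problems.append("sg_window must be odd")
    if config.sg_order >= config.sg_window:
        problems.append("sg_order must be smaller than sg_window")
    if not (0.0 < config.split_ratio < 1.0):
        problems.append("split_ratio must lie strictly between 0 and 1")
    if not (0.0 < config.quantile < 1.0):
        problems.append("quantile must lie strictly between 0 and 1")
    if not (0.0 <= config.shrinkage < 1.0):
        problems.append("shrinkage must lie in [0, 1)")
    if config.n_components < 1 or config.n_components > 2:
        problems.append("n_components must be 1 or 2 for a 3-class problem")
    if config.exclusive_amplitude < 0:
        problems.append("exclusive_amplitude must be >= 0")
    if config.n_spiked < 0 or config.n_spiked > config.n_total:
        problems.append("n_spiked must lie in [0, n_total]")
    if config.spike_height <= 0:
        problems.append("spike_height must be positive")
    if config.outlier_threshold <= 0:
        problems.append("outlier_threshold must be positive")
    if config.augment_sigma < 0 or config.augment_copies < 0:
        problems.append("augmentation parameters must be >= 0")
    if config.boundary_margin < 0:
        problems.append("boundary_margin must be >= 0")
    if config.curve_repeats < 1 or config.curve_k_max < 1:
        problems.append("curve_repeats and curve_k_max must be >= 1")
    if config.interval_k < 0:
        problems.append("interval_k must be >= 0")
    if config.assign_tol <= 0:
        problems.append("assign_tol must be positive")
    return problems


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    seed: int
    config: dict
    stages: dict
    metrics: dict
    curve: Optional[dict]
    k_at_full_accuracy: Optional[int]
    intervals: dict
    versions: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: Optional[Union[str, Path]] = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    names = ("generate", "spikes", "split", "augment", "curve")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and return the run report.

    Aborts with ConfigurationError naming the offending parameters when
    the config is invalid; stage errors propagate with their own types.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("invalid config: " + "; ".join(problems))
    seeds = _stage_seeds(config.seed)

    profiles = default_profiles(exclusive_amplitude=config.exclusive_amplitude)
    axis = WavenumberAxis.uniform(config.axis_points, config.axis_lo, config.axis_hi)
    base, rem = divmod(config.n_total, len(profiles))
    counts = tuple(base + (1 if i < rem else 0) for i in range(len(profiles)))
    sset = generate_dataset(profiles, counts, seed=seeds["generate"], axis=axis)
    log.info("generated %d spectra on %d-point axis", len(sset), axis.n_points)

    sset, spiked = inject_spikes(
        sset,
        n_spectra=config.n_spiked,
        spike_height=config.spike_height,
        seed=np.random.default_rng(seeds["spikes"]),
        window=(config.range_lo, config.range_hi),
    )

    params = PreprocessParams(
        lo=config.range_lo,
        hi=config.range_hi,
        outlier_threshold=config.outlier_threshold,
        sg_window=config.sg_window,
        sg_order=config.sg_order,
    )
    M = preprocess_pipeline(sset, params)
    log.info("preprocessed: n=%d (removed %d), p=%d", M.n, len(M.meta["removed_indices"]), M.p)

    train, test = split_train_test(
        M, config.split_ratio, np.random.default_rng(seeds["split"])
    )
    train_aug = augment_gaussian(
        train,
        config.augment_sigma,
        config.augment_copies,
        np.random.default_rng(seeds["augment"]),
    )
    model = fit_lda(
        train_aug, n_components=config.n_components, shrinkage=config.shrinkage
    )
    pred = classify(model, project(model, test.X))
    metrics = evaluate(pred, test.labels)
    log.info("test accuracy %.4f on %d spectra", metrics.accuracy, test.n)

    profile = filter_importances(
        extract_importances(model), q=config.quantile, boundary_margin=config.boundary_margin
    )

    curve_dict: Optional[dict] = None
    k_full: Optional[int] = None
    if config.run_curve:
        curve = incremental_feature_accuracy(
            M,
            profile,
            n_repeats=config.curve_repeats,
            k_max=min(config.curve_k_max, M.p),
            seed=seeds["curve"],
            split_ratio=config.split_ratio,
            augment_sigma=config.augment_sigma,
            augment_copies=config.augment_copies,
            shrinkage=config.shrinkage,
            n_components=config.n_components,
        )
        k_full = curve.smallest_k_at(1.0)
        curve_dict = {
            "k": curve.k.tolist(),
            "mean_accuracy": curve.mean_accuracy.tolist(),
            "sd_accuracy": curve.sd_accuracy.tolist(),
            "n_repeats": curve.n_repeats,
        }

    interval_set = group_intervals(profile, k=config.interval_k, gap_tol=config.gap_tol)
    table = load_band_table()
    intervals_dict: dict = {}
    for name, ivals in interval_set.by_class.items():
        entries = []
        for iv in ivals:
            center = 0.5 * (iv.lo + iv.hi)
            assignment = assign_peaks([center], table, name, tol=config.assign_tol)[0]
            entries.append(
                {
                    "lo_cm1": iv.lo,
                    "hi_cm1": iv.hi,
                    "peak_importance": iv.peak_importance,
                    "n_features": len(iv.feature_indices),
                    "matched_band": assignment.table_pos,
                    "assignment": assignment.assignment,
                    "residue": assignment.residue,
                }
            )
        intervals_dict[name] = entries

    return RunReport(
        seed=config.seed,
        config=asdict(config),
        stages={
            "n_generated": len(sset),
            "n_spiked": len(spiked),
            "spiked_indices": spiked,
            "removed_indices": M.meta["removed_indices"],
            "n": M.n,
            "p": M.p,
            "n_train": train.n,
            "n_train_augmented": train_aug.n,
            "n_test": test.n,
            "stage_order": M.meta["stage_order"],
        },
        metrics=metrics.to_dict(),
        curve=curve_dict,
        k_at_full_accuracy=k_full,
        intervals=intervals_dict,
        versions={
            "serslda": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    )
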