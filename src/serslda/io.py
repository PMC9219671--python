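"""Delimited-text I/O for spectra.

Dialect: one wide CSV whose first column is `wavenumber_cm1` and whose
remaining columns are per-spectrum intensities named `<class>_<idx>`, plus
a sidecar labels CSV with columns `spectrum_id,label`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .synth import SpectraSet, Spectrum, WavenumberAxis

PathLike = Union[str, Path]


def write_spectra(sset: SpectraSet, spectra_path: PathLike, labels_path: PathLike) -> None:
    counters: dict[str, int] = {}
    data = {"wavenumber_cm1": sset.axis.values}
    ids, labels = [], []
    for s in sset.spectra:
        label = s.label if s.label is not None else "unlabelled"
        i = counters.get(label, 0)
        counters[label] = i + 1
        sid = f"{label}_{i}"
        data[sid] = s.intensities
        ids.append(sid)
        labels.append(label)
    pd.DataFrame(data).to_csv(spectra_path, index=False)
    pd.DataFrame({"spectrum_id": ids, "label": labels}).to_csv(labels_path, index=False)


def read_spectra(spectra_path: PathLike, labels_path: PathLike) -> SpectraSet:
    wide = pd.read_csv(spectra_path)
    if wide.columns[0] != "wavenumber_cm1":
        raise ConfigurationError("first column must be wavenumber_cm1")
    labels = pd.read_csv(labels_path).set_index("spectrum_id")["label"]
    axis = WavenumberAxis(wide["wavenumber_cm1"].to_numpy(dtype=float))
    spectra = []
    for sid in wide.columns[1:]:
        if sid not in labels.index:
            raise ConfigurationError(f"spectrum {sid!r} missing from labels table")
        spectra.append(
            Spectrum(
                axis=axis,
                intensities=wide[sid].to_numpy(dtype=float),
                label=str(labels.loc[sid]),
                meta={"spectrum_id": sid},
            )
        )
    return SpectraSet(spectra)
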