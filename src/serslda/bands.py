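"""Vibrational band assignment for the three ACE spectra.

Ships the full band-assignment table for angiotensin I-converting enzyme
(ACE) SERS spectra measured for the seminal-fluid, lung and heart forms of
the protein: one row per vibrational band, with the observed position in
each class's spectrum (absent where the band was not observed), the
vibrational-mode assignment, the amino acid or dipeptide it is attributed
to, the band position reported in the assignment literature, and a
literature tag.

On top of the table the module offers peak picking on archetype (mean)
spectra, nearest-band assignment of picked peaks, and class-exclusive band
queries (bands present for one class and absent for the others, globally or
in a pairwise comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import ConfigurationError

CLASS_NAMES = ("seminal", "lung", "heart")

#: Seminal-only bands as highlighted in the narrative accompanying the
#: assignment table.  The packaged table itself carries two further
#: seminal-only rows (435 and 1441 cm-1); `exclusive_bands` follows the
#: table and flags the extras -- see `EXTRA_TABLE_ONLY`.
NARRATIVE_SEMINAL_EXCLUSIVE = (453.0, 492.0, 572.0, 591.0, 683.0, 1069.0, 1095.0)

#: Table-derived seminal-only positions absent from the narrative list.
EXTRA_TABLE_ONLY = (435.0, 1441.0)

_POSITION_RANGE = (300.0, 1800.0)


@dataclass(frozen=True)
class BandTable:
    """The packaged assignment table (one row per band)."""

    df: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def positions(self, class_name: str) -> np.ndarray:
        """All positions observed for `class_name`, in table row order
        (NaN rows dropped)."""
        _check_class(class_name)
        return self.df[class_name].dropna().to_numpy(dtype=float)

    def row(self, index: int) -> pd.Series:
        return self.df.iloc[index]


@dataclass(frozen=True)
class PeakAssignment:
    """One picked peak matched (or not) against the table."""

    observed_pos: float
    matched_row: Optional[int]
    table_pos: Optional[float]
    assignment: Optional[str]
    residue: Optional[str]
    distance: Optional[float]

    @property
    def matched(self) -> bool:
        return self.matched_row is not None


def _check_class(class_name: str) -> None:
    if class_name not in CLASS_NAMES:
        raise ConfigurationError(
            f"unknown class {class_name!r}; expected one of {CLASS_NAMES}"
        )


def load_band_table() -> BandTable:
    """Load the packaged assignment table and validate its invariants."""
    with resources.files("serslda.data").joinpath("ace_band_table.csv").open() as fh:
        df = pd.read_csv(fh, dtype={c: float for c in CLASS_NAMES})
    pos = df[list(CLASS_NAMES)]
    if pos.isna().all(axis=1).any():
        raise ConfigurationError("band table row with no position in any class")
    lo, hi = _POSITION_RANGE
    values = pos.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.min() < lo or finite.max() > hi:
        raise ConfigurationError(f"band positions outside [{lo}, {hi}] cm-1")
    return BandTable(df=df)


def pick_peaks(
    intensities: np.ndarray,
    wavenumbers: np.ndarray,
    min_prominence: float = 0.05,
) -> np.ndarray:
    """Positions (cm-1) of local maxima with at least `min_prominence`.

    Typically applied to an archetype's mean spectrum.
    """
    y = np.asarray(intensities, dtype=float)
    x = np.asarray(wavenumbers, dtype=float)
    if y.shape != x.shape:
        raise ConfigurationError("intensities and wavenumbers differ in length")
    idx, _ = find_peaks(y, prominence=min_prominence)
    return x[idx]


def assign_peaks(
    peaks: Sequence[float],
    table: BandTable,
    class_name: str,
    tol: float = 5.0,
) -> list[PeakAssignment]:
    """Match each peak to the nearest band in `class_name`'s column.

    A peak is matched when the nearest position lies within `tol` cm-1;
    ties go to the smaller row index.  The result order follows the input
    order, and the matching of any one peak is independent of the others.
    """
    _check_class(class_name)
    col = table.df[class_name].to_numpy(dtype=float)
    out: list[PeakAssignment] = []
    for peak in peaks:
        dist = np.abs(col - float(peak))
        dist[~np.isfinite(dist)] = np.inf
        row = int(np.argmin(dist))  # first minimum -> smaller row index on ties
        if dist[row] <= tol:
            r = table.row(row)
            out.append(
                PeakAssignment(
                    observed_pos=float(peak),
                    matched_row=row,
                    table_pos=float(col[row]),
                    assignment=None if pd.isna(r["assignment"]) else str(r["assignment"]),
                    residue=None if pd.isna(r["residue"]) else str(r["residue"]),
                    distance=float(dist[row]),
                )
            )
        else:
            out.append(
                PeakAssignment(
                    observed_pos=float(peak),
                    matched_row=None,
                    table_pos=None,
                    assignment=None,
                    residue=None,
                    distance=None,
                )
            )
    return out


def exclusive_bands(
    table: BandTable,
    class_name: str,
    versus: Optional[str] = None,
) -> list[float]:
    """Positions present for `class_name` and absent for the other class(es).

    With `versus=None` the band must be absent in both other classes
    (globally exclusive); with `versus` set, only that one class is compared
    (pairwise mode).  The packaged table is the authority here; note that
    the narrative seminal-only list omits two table rows (see
    `EXTRA_TABLE_ONLY`) and that the narrative's pairwise heart/lung sides
    for 502/1279/1600 and 1623 cm-1 are swapped relative to the table.
    """
    _check_class(class_name)
    if versus is not None:
        _check_class(versus)
        if versus == class_name:
            raise ConfigurationError("pairwise comparison needs two distinct classes")
        others = [versus]
    else:
        others = [c for c in CLASS_NAMES if c != class_name]
    df = table.df
    mask = df[class_name].notna()
    for other in others:
        mask &= df[other].isna()
    return [float(v) for v in df.loc[mask, class_name]]
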