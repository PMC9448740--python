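"""Core in-memory containers: wavenumber axes, spectrum sets, basis libraries.

A :class:`SpectrumSet` couples a shared wavenumber axis with one intensity row
per acquired spectrum plus per-spectrum acquisition metadata (patient, biopsy,
slice, region, grid position).  A :class:`BasisLibrary` holds named reference
chemical spectra on the same kind of axis; it is the fixed factor of the
basis-restricted NMF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

#: metadata columns every SpectrumSet carries, in on-disk order
META_COLUMNS = [
    "patient_id",
    "biopsy_id",
    "timepoint",
    "slice_index",
    "region_index",
    "grid_row",
    "grid_col",
]

AXIS_MIN = 400.0
AXIS_MAX = 1900.0
MIN_AXIS_LEN = 16


def validate_axis(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis: strictly increasing, in [400, 1900] cm^-1."""
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1:
        raise ValidationError("wavenumber axis must be one-dimensional")
    if axis.size < MIN_AXIS_LEN:
        raise ValidationError(
            f"wavenumber axis needs at least {MIN_AXIS_LEN} points, got {axis.size}"
        )
    if not np.all(np.diff(axis) > 0):
        raise ValidationError("wavenumber axis must be strictly increasing")
    if axis[0] < AXIS_MIN or axis[-1] > AXIS_MAX:
        raise ValidationError(
            f"wavenumber axis must lie within [{AXIS_MIN:g}, {AXIS_MAX:g}] cm^-1, "
            f"got [{axis[0]:g}, {axis[-1]:g}]"
        )
    return axis


def trapezoid_area(y: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of each row of ``y`` over ``axis``."""
    return np.trapezoid(np.atleast_2d(y), x=axis, axis=-1)


@dataclass
class SpectrumSet:
    """A stack of Raman spectra sharing one wavenumber axis.

    Parameters
    ----------
    axis : array of float
        Raman shifts in cm^-1, strictly increasing, within [400, 1900].
    intensities : array, shape (n_spectra, n_points)
        Detector intensities, one spectrum per row.
    meta : DataFrame
        One record per spectrum with columns ``META_COLUMNS``.
    processing_state : list of str
        Names of preprocessing steps already applied, in order; no duplicates.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame
    processing_state: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.axis.size:
            raise ValidationError(
                f"intensity rows have {self.intensities.shape[1]} points but the "
                f"axis has {self.axis.size}"
            )
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns: {missing}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValidationError(
                f"{len(self.meta)} metadata records for "
                f"{self.intensities.shape[0]} spectra"
            )
        self.meta = self.meta.reset_index(drop=True)
        if len(set(self.processing_state)) != len(self.processing_state):
            raise ValidationError("processing_state contains duplicate step names")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities: np.ndarray, step: str | None = None) -> "SpectrumSet":
        """Copy with new intensities; optionally append ``step`` to the state."""
        state = list(self.processing_state)
        if step is not None:
            state.append(step)
        return SpectrumSet(self.axis, intensities, self.meta.copy(), state)

    def subset(self, indices) -> "SpectrumSet":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            self.axis,
            self.intensities[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            list(self.processing_state),
        )

    def copy(self) -> "SpectrumSet":
        return replace(
            self,
            intensities=self.intensities.copy(),
            meta=self.meta.copy(),
            processing_state=list(self.processing_state),
        )


@dataclass
class BasisLibrary:
    """Named non-negative reference chemical spectra (the fixed NMF basis).

    Each basis spectrum is normalized to unit trapezoidal area on its axis,
    matching the normalization convention applied to data spectra.
    """

    axis: np.ndarray
    names: list[str]
    spectra: np.ndarray

    #: tolerance below which small negative values are clipped rather than rejected
    NEG_TOL = 1e-9

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.names = list(self.names)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValidationError(f"duplicate chemical names: {dupes}")
        if self.spectra.shape != (len(self.names), self.axis.size):
            raise ValidationError(
                f"basis matrix shape {self.spectra.shape} does not match "
                f"{len(self.names)} names x {self.axis.size} axis points"
            )
        if np.min(self.spectra) < -self.NEG_TOL:
            raise ValidationError("basis spectra must be non-negative")
        self.spectra = np.clip(self.spectra, 0.0, None)
        areas = trapezoid_area(self.spectra, self.axis)
        if np.any(areas <= 0):
            bad = [self.names[i] for i in np.nonzero(areas <= 0)[0]]
            raise ValidationError(f"basis spectra with non-positive area: {bad}")
        self.spectra = self.spectra / areas[:, None]

    @property
    def n_chemicals(self) -> int:
        return len(self.names)

    def interpolate_to(self, axis: np.ndarray) -> "BasisLibrary":
        """Re-grid the library onto ``axis`` by linear interpolation.

        Values are clipped at 0 and each spectrum renormalized to unit area.
        A no-op (returns self) when the axes already coincide.
        """
        axis = validate_axis(axis)
        if axis.size == self.axis.size and np.array_equal(axis, self.axis):
            return self
        out = np.vstack([np.interp(axis, self.axis, row) for row in self.spectra])
        return BasisLibrary(axis, list(self.names), np.clip(out, 0.0, None))

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown chemical: {name!r}") from None
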