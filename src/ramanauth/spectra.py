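"""Core spectral data containers shared by every stage of the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a strictly increasing wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Strictly increasing grid in cm^-1.
    intensities
        Intensity values (arbitrary units), same length as the grid.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)
        if wn.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if wn.shape != y.shape:
            raise ValueError(
                f"length mismatch: {wn.shape[0]} wavenumbers vs "
                f"{y.shape[0]} intensities"
            )
        if wn.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")

    @property
    def step(self) -> float:
        """Mean grid spacing in cm^-1 (grids are uniform in practice)."""
        return float(np.mean(np.diff(self.wavenumbers)))

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, np.asarray(y, dtype=float))


@dataclass
class SpectraMatrix:
    """n spectra x p wavenumbers on one shared axis."""

    axis: np.ndarray
    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.axis.ndim != 1:
            raise ValueError("axis must be 1-D")
        if self.values.shape[1] != self.axis.size:
            raise ValueError(
                f"values have {self.values.shape[1]} columns but the axis "
                f"has {self.axis.size} points"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite intensities")
        if not self.ids:
            self.ids = [f"s{i:04d}" for i in range(self.values.shape[0])]
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("one id per row required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.axis)))

    def __len__(self) -> int:
        return self.n

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.values[i])

    def subset(self, mask: np.ndarray) -> "SpectraMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return SpectraMatrix(
            self.axis, self.values[idx], [self.ids[i] for i in idx]
        )
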