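"""The Spectrum container: one Raman trace with excitation metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Spectrum", "default_grid", "GRID_MIN", "GRID_MAX", "GRID_STEP",
           "SUPPORTED_EXCITATIONS"]

#: Default acquisition grid: 0-3400 cm-1 at 3 cm-1 spectral resolution.
GRID_MIN, GRID_MAX, GRID_STEP = 0.0, 3400.0, 3.0

SUPPORTED_EXCITATIONS = (532, 785)


def default_grid() -> np.ndarray:
    """Wavenumber axis 0..3399 cm-1 in 3 cm-1 steps (1134 points)."""
    return np.arange(GRID_MIN, GRID_MAX, GRID_STEP)


@dataclass
class Spectrum:
    """A single Raman trace.

    Attributes
    ----------
    wavenumbers : ndarray
        Strictly increasing, uniform wavenumber grid in rel. cm-1.
    intensities : ndarray
        Detector counts, same length as ``wavenumbers``.
    excitation_nm : int
        Excitation laser wavelength (532 or 785 nm).
    meta : dict
        Free-form provenance (seed, bleach seconds, profile, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    excitation_nm: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or len(w) != len(y):
            raise ValidationError("wavenumbers and intensities must be 1-D and equal length")
        if len(w) < 2:
            raise ValidationError("spectrum needs at least 2 points")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise ValidationError("wavenumber axis must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValidationError("wavenumber grid must be uniform within 1e-9 cm-1")
        if not np.all(np.isfinite(y)):
            raise ValidationError("intensities must be finite")
        if int(self.excitation_nm) not in SUPPORTED_EXCITATIONS:
            raise ValidationError(
                f"unsupported excitation {self.excitation_nm} nm; "
                f"expected one of {SUPPORTED_EXCITATIONS}")
        self.wavenumbers = w
        self.intensities = y
        self.excitation_nm = int(self.excitation_nm)

    @property
    def step(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def window_slice(self, lo: float, hi: float) -> slice:
        """Index slice covering wavenumbers in [lo, hi]."""
        if lo >= hi:
            raise ValidationError(f"empty window ({lo}, {hi})")
        if lo < self.wavenumbers[0] or hi > self.wavenumbers[-1]:
            raise ValidationError(
                f"window ({lo}, {hi}) outside grid "
                f"({self.wavenumbers[0]}, {self.wavenumbers[-1]})")
        i0 = int(np.searchsorted(self.wavenumbers, lo, side="left"))
        i1 = int(np.searchsorted(self.wavenumbers, hi, side="right"))
        return slice(i0, i1)

    def copy_with(self, intensities: np.ndarray, **meta) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        self.excitation_nm, new_meta)
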