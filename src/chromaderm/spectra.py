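"""Wavelength-indexed spectra (reflectance, irradiance, receptor sensitivity).

All downstream visual modeling works on the 300-700 nm window, the visual
range of most diurnal lizards. Spectra are stored as paired arrays of
strictly ascending wavelengths (nm) and non-negative values; resampling to
a common 1-nm grid is done by piecewise-linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumRangeError",
    "default_grid",
    "resample_spectrum",
    "flat_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

VALID_KINDS = frozenset({"reflectance", "irradiance", "sensitivity"})

#: Default modeling window and step (nm).
GRID_START = 300.0
GRID_STOP = 700.0
GRID_STEP = 1.0


class SpectrumRangeError(ValueError):
    """Requested wavelength range lies outside the measured spectrum."""


def default_grid(start: float = GRID_START, stop: float = GRID_STOP,
                 step: float = GRID_STEP) -> np.ndarray:
    """Uniform wavelength grid, inclusive of both endpoints."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function on [300, 700] nm.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly ascending sample wavelengths in nanometres.
    values : array-like
        Non-negative sample values. Reflectance is unitless (typically
        <= 1.2 for near-perfect diffuse reflectors); irradiance and
        sensitivity are in arbitrary relative units.
    kind : {"reflectance", "irradiance", "sensitivity"}
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("spectral values must be finite and non-negative")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {sorted(VALID_KINDS)}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def interp(self, wavelengths: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation at the given wavelengths (no extrapolation check)."""
        return np.interp(wavelengths, self.wavelengths_nm, self.values)


def flat_spectrum(value: float, kind: str = "reflectance",
                  grid: np.ndarray | None = None, name: str | None = None) -> Spectrum:
    """A spectrally flat spectrum at a constant value on the default grid."""
    if grid is None:
        grid = default_grid()
    return Spectrum(grid, np.full_like(np.asarray(grid, dtype=float), float(value)),
                    kind=kind, name=name)


def resample_spectrum(spectrum: Spectrum, grid_start_nm: float = GRID_START,
                      grid_stop_nm: float = GRID_STOP, step_nm: float = GRID_STEP,
                      extrapolate: str | None = None) -> Spectrum:
    """Resample a spectrum onto a uniform grid by piecewise-linear interpolation.

    Parameters
    ----------
    extrapolate : {None, "edge", "zero"}
        Policy when the requested grid extends beyond the measured range.
        ``None`` raises :class:`SpectrumRangeError`; ``"edge"`` holds the
        end values; ``"zero"`` pads with zeros.

    Values are clipped at zero (linear interpolation of non-negative data
    cannot go negative, but clipping guards resampled round-off).
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    grid = default_grid(grid_start_nm, grid_stop_nm, step_nm)
    lo, hi = spectrum.wavelengths_nm[0], spectrum.wavelengths_nm[-1]
    eps = 1e-9
    if (grid[0] < lo - eps or grid[-1] > hi + eps) and extrapolate is None:
        raise SpectrumRangeError(
            f"grid [{grid[0]}, {grid[-1]}] nm exceeds measured range [{lo}, {hi}] nm; "
            "pass extrapolate='edge' or 'zero' to allow"
        )
    if extrapolate == "zero":
        vals = np.interp(grid, spectrum.wavelengths_nm, spectrum.values,
                         left=0.0, right=0.0)
    else:  # None (in-range) or "edge": np.interp holds end values
        vals = np.interp(grid, spectrum.wavelengths_nm, spectrum.values)
    return Spectrum(grid, np.clip(vals, 0.0, None), kind=spectrum.kind,
                    name=spectrum.name)


def read_spectrum_csv(path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column CSV with header ``wavelength_nm,value``."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "wavelength_nm" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns wavelength_nm,value; got {list(df.columns)}")
    df = df.sort_values(cols["wavelength_nm"])
    return Spectrum(df[cols["wavelength_nm"]].to_numpy(),
                    df[cols["value"]].to_numpy(), kind=kind, name=str(path))


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as a two-column ``wavelength_nm,value`` CSV."""
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths_nm,
                  "value": spectrum.values}).to_csv(path, index=False)
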