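"""Spectrum containers, regridding, preprocessing and comparison metrics.

Every spectrum in irmix lives on a uniform wavenumber grid.  The default grid
has 1250 points at 4 cm⁻¹ spacing starting at 0 cm⁻¹ (0–4996 cm⁻¹), the
common representation used for simulated liquid- and gas-phase IR spectra.
Spectra are preprocessed to "probability-density-like" vectors: smoothed,
clipped to non-negative intensities and normalized to unit integrated area,
so that a mixture spectrum and its pure-component basis are directly
comparable and cumulative-distribution metrics are well defined.

Three comparison metrics are provided:

* :func:`spectral_mse` — mean squared intensity difference, the distance the
  least-squares deconvolution algorithms implicitly minimize;
* :func:`cdf` — the running cumulative intensity of a unit-area spectrum;
* :func:`avg_cdf_difference` — the mean (signed or absolute) gap between two
  cumulative spectra.  The signed mean measures net band shift: a positive
  value means the first spectrum is concentrated at lower wavenumbers
  (red-shifted) relative to the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import (
    DegenerateSpectrumError,
    IncompatibleGridsError,
    InvalidInputError,
    NotNormalizedError,
)

__all__ = [
    "WavenumberGrid",
    "RawSpectrum",
    "Spectrum",
    "DEFAULT_GRID",
    "regrid",
    "preprocess",
    "spectral_mse",
    "cdf",
    "avg_cdf_difference",
    "mean_wavenumber",
]

#: Tolerance for the unit-area check on normalized spectra.
AREA_ATOL = 1e-9


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber grid: points at ``start + i*step``, i = 0..n_points-1.

    Parameters
    ----------
    start : float
        First wavenumber in cm⁻¹.
    step : float
        Grid spacing in cm⁻¹; must be positive.
    n_points : int
        Number of grid points; at least 2.
    """

    start: float = 0.0
    step: float = 4.0
    n_points: int = 1250

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidInputError(f"grid step must be positive, got {self.step}")
        if self.n_points < 2:
            raise InvalidInputError(f"grid needs >= 2 points, got {self.n_points}")

    @property
    def wavenumbers(self) -> np.ndarray:
        """Grid wavenumbers in cm⁻¹."""
        return self.start + self.step * np.arange(self.n_points)

    @property
    def max_wavenumber(self) -> float:
        return self.start + self.step * (self.n_points - 1)

    @property
    def span(self) -> float:
        """Total covered width ``step * n_points`` in cm⁻¹.

        Each grid point carries a bin of width ``step``; the rigid-shift
        identity ``avg_cdf_difference = shift / span`` is exact for on-grid
        shifts with this convention.
        """
        return self.step * self.n_points


#: The default 0–4996 cm⁻¹, 4 cm⁻¹ grid (1250 points).
DEFAULT_GRID = WavenumberGrid()


@dataclass(frozen=True)
class RawSpectrum:
    """Pre-grid spectrum: (wavenumber, intensity) pairs as parallel arrays.

    Wavenumbers must be strictly increasing; intensities may be negative
    (raw simulation or instrument output before clipping).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or x.shape != w.shape:
            raise InvalidInputError("wavenumbers and intensities must be equal-length 1-D arrays")
        if w.size < 2:
            raise InvalidInputError("a raw spectrum needs at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise InvalidInputError("raw wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)


@dataclass(frozen=True)
class Spectrum:
    """Intensities on a uniform :class:`WavenumberGrid`.

    ``normalized=True`` asserts unit integrated area (``sum * step == 1``);
    a loose sanity check runs at construction, exact normalization is
    guaranteed by :func:`preprocess`.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size != self.grid.n_points:
            raise InvalidInputError(
                f"intensities must be 1-D of length {self.grid.n_points}, got shape {x.shape}"
            )
        if self.normalized:
            area = x.sum() * self.grid.step
            if abs(area - 1.0) > 1e-6:
                raise InvalidInputError(f"spectrum flagged normalized but area is {area}")
        object.__setattr__(self, "intensities", x)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.wavenumbers

    @property
    def area(self) -> float:
        """Rectangle-rule integrated intensity ``sum * step``."""
        return float(self.intensities.sum() * self.grid.step)

    def with_intensities(self, x: np.ndarray, normalized: bool = False) -> "Spectrum":
        return Spectrum(self.grid, x, normalized)


def _require_same_grid(a: Spectrum, b: Spectrum) -> None:
    if a.grid != b.grid:
        raise IncompatibleGridsError(f"grids differ: {a.grid} vs {b.grid}")


def regrid(raw: RawSpectrum, grid: WavenumberGrid = DEFAULT_GRID) -> Spectrum:
    """Linearly interpolate a raw spectrum onto a uniform grid.

    Grid points outside the raw spectrum's wavenumber support get intensity
    zero.  The output is *not* clipped or normalized; follow with
    :func:`preprocess`.
    """
    x = np.interp(grid.wavenumbers, raw.wavenumbers, raw.intensities, left=0.0, right=0.0)
    return Spectrum(grid, x, normalized=False)


def preprocess(
    spec: Spectrum,
    smooth_sigma: float = 0.0,
    clip: bool = True,
    normalize: bool = True,
) -> Spectrum:
    """Smooth, clip and normalize a spectrum, in that order.

    Parameters
    ----------
    smooth_sigma : float
        Gaussian smoothing width in cm⁻¹ (0 disables smoothing).  The
        discrete convolution uses reflective edge handling and a 4-sigma
        truncation, which conserves total intensity.
    clip : bool
        Clip negative intensities to zero (after smoothing).
    normalize : bool
        Divide by the rectangle-rule area ``sum * step`` so the result has
        unit integrated intensity.

    Raises
    ------
    DegenerateSpectrumError
        If normalization is requested but the (post-clip) spectrum has no
        positive area.
    """
    if smooth_sigma < 0:
        raise InvalidInputError(f"smooth_sigma must be >= 0, got {smooth_sigma}")
    x = spec.intensities
    if smooth_sigma > 0:
        x = gaussian_filter1d(x, sigma=smooth_sigma / spec.grid.step, mode="reflect", truncate=4.0)
    if clip:
        x = np.maximum(x, 0.0)
    if normalize:
        area = x.sum() * spec.grid.step
        if area <= 0:
            raise DegenerateSpectrumError("cannot normalize a spectrum with zero total intensity")
        x = x / area
        return Spectrum(spec.grid, x, normalized=True)
    return Spectrum(spec.grid, x, normalized=False)


def spectral_mse(a: Spectrum, b: Spectrum) -> float:
    """Mean squared intensity difference over the grid points."""
    _require_same_grid(a, b)
    d = a.intensities - b.intensities
    return float(np.mean(d * d))


def cdf(spec: Spectrum) -> np.ndarray:
    """Cumulative distribution of a unit-area spectrum.

    Running sum of ``intensities * step``; non-decreasing and ending at 1.
    """
    if not spec.normalized:
        raise NotNormalizedError("cdf requires a normalized spectrum")
    return raw_cdf(spec)


def raw_cdf(spec: Spectrum) -> np.ndarray:
    """Running sum of ``intensities * step`` without requiring unit area.

    Used internally to compare partial (not yet unit-area) reconstructions
    against a target spectrum.
    """
    return np.cumsum(spec.intensities) * spec.grid.step


def avg_cdf_difference(a: Spectrum, b: Spectrum, signed: bool = True) -> float:
    """Mean difference between the cumulative spectra of ``a`` and ``b``.

    With ``signed=True`` the mean of ``cdf(a) - cdf(b)`` is returned: positive
    when ``a`` is concentrated at lower wavenumbers than ``b`` (``a``
    red-shifted relative to ``b``).  With ``signed=False`` the mean absolute
    gap is returned.  For a rigid shift of Δ cm⁻¹ the signed value equals
    Δ / grid.span.
    """
    _require_same_grid(a, b)
    d = cdf(a) - cdf(b)
    if not signed:
        d = np.abs(d)
    return float(np.mean(d))


def mean_wavenumber(spec: Spectrum) -> float:
    """Intensity-weighted first moment of the spectrum, in cm⁻¹."""
    total = spec.intensities.sum()
    if total <= 0:
        raise DegenerateSpectrumError("mean wavenumber undefined for zero spectrum")
    return float(np.dot(spec.wavenumbers, spec.intensities) / total)
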