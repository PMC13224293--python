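"""IR spectra from total-dipole time series.

The IR absorbance of a simulated system follows from the autocorrelation of
its total dipole moment M(t): the spectrum is the Fourier transform C̃(ν) of
⟨M(t)·M(t+τ)⟩, multiplied by ν² to fold in the electromagnetic-field
coupling and the quantum correction of the classical line shape,

    S_qm(ν) = C̃(ν) · ν².

The autocorrelation is estimated without bias (each lag divided by its
number of valid time origins), optionally tapered with a Hann window to
suppress truncation ringing, zero-padded for fine frequency resolution, and
transformed with a real FFT.  The frequency axis is converted to wavenumber
via ν[cm⁻¹] = f / c with f in cycles per femtosecond, the result is
interpolated onto the requested wavenumber grid, clipped and normalized to
unit area like every other spectrum in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    AliasingError,
    DegenerateSpectrumError,
    InvalidInputError,
    InvalidParameterError,
)
from .spectra import RawSpectrum, Spectrum, WavenumberGrid, preprocess, regrid

__all__ = [
    "SPEED_OF_LIGHT_CM_PER_FS",
    "DipoleTrajectory",
    "dipole_autocorrelation",
    "spectrum_from_dipole",
    "gas_mixture_spectrum",
]

#: Speed of light in cm/fs; converts cycles/fs to wavenumber in cm⁻¹.
SPEED_OF_LIGHT_CM_PER_FS = 2.99792458e-5


@dataclass(frozen=True)
class DipoleTrajectory:
    """Total-dipole time series M(t) sampled at a fixed timestep.

    Parameters
    ----------
    timestep_fs : float
        Sampling interval in femtoseconds; must be positive.
    samples : ndarray of shape (n, 3)
        Dipole vectors in any consistent unit; at least 16 samples.
    temperature : float, optional
        Simulation temperature in kelvin.  Retained as metadata only: the
        thermal quantum-correction factor it would enter is absorbed into
        the combined ν² weighting.
    """

    timestep_fs: float
    samples: np.ndarray
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise InvalidInputError(f"timestep must be positive, got {self.timestep_fs}")
        m = np.asarray(self.samples, dtype=float)
        if m.ndim != 2 or m.shape[1] != 3:
            raise InvalidInputError(f"samples must have shape (n, 3), got {m.shape}")
        if m.shape[0] < 16:
            raise InvalidInputError(f"need >= 16 dipole samples, got {m.shape[0]}")
        object.__setattr__(self, "samples", m)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def nyquist_wavenumber(self) -> float:
        """Highest representable wavenumber 1/(2·c·Δt) in cm⁻¹."""
        return 1.0 / (2.0 * SPEED_OF_LIGHT_CM_PER_FS * self.timestep_fs)


def dipole_autocorrelation(traj: DipoleTrajectory, max_lag: int) -> np.ndarray:
    """Unbiased dipole autocorrelation C(τ_k) = ⟨M(t)·M(t+k)⟩, k = 0..max_lag.

    The ensemble average runs over all valid time origins for each lag
    (FFT-accelerated), divided by the number of origins so short trajectories
    are not damped artificially.
    """
    n = traj.n_samples
    if not 0 < max_lag < n:
        raise InvalidParameterError(f"max_lag must be in (0, {n}), got {max_lag}")
    m = traj.samples
    n_fft = 1 << int(np.ceil(np.log2(2 * n)))
    # sum of per-component autocorrelations == autocorrelation of the dot product
    f = np.fft.rfft(m, n=n_fft, axis=0)
    acf_full = np.fft.irfft((f * f.conj()).real.sum(axis=1), n=n_fft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return acf_full / counts


def spectrum_from_dipole(
    traj: DipoleTrajectory,
    grid: WavenumberGrid,
    max_lag: int | None = None,
    window: str = "hann",
    smooth_sigma: float = 0.0,
) -> Spectrum:
    """Quantum-corrected IR spectrum S_qm(ν) = C̃(ν)·ν² from a dipole trajectory.

    Parameters
    ----------
    max_lag : int, optional
        Longest autocorrelation lag used; defaults to half the trajectory.
    window : {"hann", "none"}
        Taper applied to the autocorrelation before the FFT.
    smooth_sigma : float
        Optional Gaussian smoothing (cm⁻¹) applied in the final
        preprocessing step.

    Raises
    ------
    AliasingError
        If the grid reaches beyond the trajectory's Nyquist wavenumber.
    DegenerateSpectrumError
        If the trajectory carries no dipole signal.
    """
    if grid.max_wavenumber >= traj.nyquist_wavenumber:
        raise AliasingError(
            f"grid extends to {grid.max_wavenumber:.1f} cm^-1 but the trajectory's "
            f"Nyquist limit is {traj.nyquist_wavenumber:.1f} cm^-1"
        )
    if not np.any(traj.samples):
        raise DegenerateSpectrumError("all-zero dipole trajectory")
    if max_lag is None:
        max_lag = traj.n_samples // 2
    acf = dipole_autocorrelation(traj, max_lag)
    if window == "hann":
        k = np.arange(max_lag + 1)
        acf = acf * 0.5 * (1.0 + np.cos(np.pi * k / max_lag))
    elif window != "none":
        raise InvalidParameterError(f"unknown window {window!r}")
    # zero-pad so the FFT frequency spacing resolves a quarter grid step
    dt = traj.timestep_fs
    needed = int(np.ceil(1.0 / (dt * SPEED_OF_LIGHT_CM_PER_FS * grid.step / 4.0)))
    n_fft = 1 << int(np.ceil(np.log2(max(needed, 2 * (max_lag + 1)))))
    # cosine transform of the even extension of C(tau):
    # C~(nu) = C(0) + 2*sum_{k>=1} C(k) cos(2 pi f k dt) = 2*Re(rfft) - C(0)
    power = 2.0 * np.fft.rfft(acf, n=n_fft).real - acf[0]
    nu = np.fft.rfftfreq(n_fft, d=dt) / SPEED_OF_LIGHT_CM_PER_FS
    raw = RawSpectrum(nu, power * nu**2)
    return preprocess(regrid(raw, grid), smooth_sigma=smooth_sigma, clip=True, normalize=True)


def gas_mixture_spectrum(spectra: list[Spectrum], mole_fractions: list[float]) -> Spectrum:
    """Mole-fraction-weighted linear combination of pure gas-phase spectra.

    In the gas phase the dipoles of distinct molecules are uncorrelated, so
    a mixture spectrum is exactly the weighted sum of its pure-component
    spectra.  Inputs must be normalized and share a grid; the fractions must
    sum to 1, so the result is unit-area by construction.
    """
    if len(spectra) != len(mole_fractions) or not spectra:
        raise InvalidParameterError("need one mole fraction per spectrum")
    fr = np.asarray(mole_fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
        raise InvalidParameterError("mole fractions must be non-negative and sum to 1")
    grid = spectra[0].grid
    x = np.zeros(grid.n_points)
    for f, s in zip(fr, spectra):
        if s.grid != grid:
            raise InvalidParameterError("all spectra must share one grid")
        if not s.normalized:
            raise InvalidParameterError("gas mixture composition requires normalized spectra")
        x += f * s.intensities
    return Spectrum(grid, x, normalized=True)
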