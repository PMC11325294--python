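"""Shared containers, constants and Fourier conventions.

Units used throughout the package:

* time / delay: femtoseconds (fs)
* spectroscopic frequency: wavenumber, cm^-1
* the two are conjugate through the speed of light ``C_CM_PER_FS``
  (cm per fs), so a trace of ``n`` samples at spacing ``dt`` transforms
  onto a wavenumber grid of spacing ``1 / (C_CM_PER_FS * n * dt)``.

Fourier conventions (fixed once, used everywhere):

* forward transform (time -> wavenumber):
  ``X(nu) = dt * sum_j x(t_j) * exp(-2*pi*i * c * nu * t_j)``,
  computed with :func:`numpy.fft.rfft` on the real trace and referenced
  to absolute time zero (the phase factor for a grid not starting at
  t = 0 is applied explicitly);
* inverse transform: Hermitian extension of the one-sided spectrum via
  :func:`numpy.fft.irfft`, i.e. kernel ``exp(+2*pi*i * c * nu * t)``.

Under these conventions a response that decays *after* the excitation
(a causal response, emitted in the wake of the pulse) has a spectrum
proportional to ``1 / (gamma + i*(nu - nu0))``, and a delayed replica at
``+tau`` carries the phase factor ``exp(-2*pi*i * c * nu * tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import hilbert

#: Speed of light in cm per femtosecond.
C_CM_PER_FS = 2.99792458e-5

#: Relative tolerance for declaring a sampling grid uniform.
GRID_RTOL = 1e-9


class FRSError(ValueError):
    """Base class for all domain errors raised by this package."""


class NonUniformGridError(FRSError):
    """A time or wavenumber axis is not uniformly sampled (or not ascending)."""


class FormatError(FRSError):
    """A file does not conform to the expected on-disk schema."""


class NyquistError(FRSError):
    """A requested spectrum does not fit inside the sampling Nyquist range."""


class CutoffError(FRSError):
    """A time-filter cutoff exceeds the unambiguous time window of the grid."""


def check_uniform_grid(x: np.ndarray, name: str = "grid") -> float:
    """Validate that *x* is uniform and ascending; return the spacing."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise NonUniformGridError(f"{name} must be a 1-d array of length >= 2")
    d = np.diff(x)
    step = float(np.mean(d))
    if step <= 0:
        raise NonUniformGridError(f"{name} must be strictly ascending")
    if np.max(np.abs(d - step)) > GRID_RTOL * abs(step):
        raise NonUniformGridError(f"{name} is not uniform to within {GRID_RTOL:g} relative")
    return step


@dataclass
class TimeTrace:
    """A uniformly sampled, real-valued EOS signal versus delay.

    Parameters
    ----------
    t
        Delay axis in fs, uniform and ascending.
    values
        Real signal amplitude (arbitrary units), same length as ``t``.
    meta
        Free-form provenance (role, day, seed, concentration, ...).
    """

    t: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise FRSError("time axis and values must have the same shape")
        check_uniform_grid(self.t, "time axis")
        if not np.all(np.isfinite(self.values)):
            raise FRSError("trace values must be finite")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Sample spacing in fs."""
        return float(self.t[1] - self.t[0])

    def envelope(self) -> np.ndarray:
        """Analytic-signal (Hilbert) envelope of the trace."""
        return np.abs(hilbert(self.values))

    def envelope_peak_time(self) -> float:
        """Delay (fs) at which the envelope peaks."""
        return float(self.t[int(np.argmax(self.envelope()))])

    def copy(self) -> "TimeTrace":
        return TimeTrace(self.t.copy(), self.values.copy(), dict(self.meta))


@dataclass
class ComplexSpectrum:
    """Spectral amplitudes on a uniform ascending wavenumber grid (cm^-1).

    ``values`` may be complex (field spectra, transfer functions) or real
    (magnitude spectra); operations that need one or the other say so.
    """

    nu: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.values = np.asarray(self.values)
        if self.nu.shape != self.values.shape:
            raise FRSError("wavenumber axis and values must have the same shape")
        check_uniform_grid(self.nu, "wavenumber axis")
        if not np.all(np.isfinite(self.values)):
            raise FRSError("spectrum values must be finite")

    @property
    def dnu(self) -> float:
        """Grid spacing in cm^-1."""
        return float(self.nu[1] - self.nu[0])

    def copy(self) -> "ComplexSpectrum":
        return ComplexSpectrum(self.nu.copy(), self.values.copy(), dict(self.meta))


def rfft_wavenumbers(n: int, dt: float) -> np.ndarray:
    """One-sided wavenumber grid (cm^-1) conjugate to ``n`` samples at ``dt`` fs."""
    return np.fft.rfftfreq(n, d=dt) / C_CM_PER_FS
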