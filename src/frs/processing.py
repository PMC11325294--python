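"""Procedures for extracting the molecular response from EOS trace pairs.

Field-resolved infrared spectroscopy (FRS) records the electric field
``S(t)`` transmitted through a sample versus delay. Three processing
routes turn a (reference, sample) pair of traces into molecular
information:

1. **Standard frequency-domain ratio** — the referenced sample response
   ``H(nu) = S_sam(nu) / S_ref(nu)``. Nominally excitation-independent,
   but the technical noise of the whole trace is carried into the
   spectrum (:func:`standard_response`).
2. **Time-domain difference** — ``S_sam(t) - S_ref(t)`` with a temporal
   filter at the excitation. Excellent noise suppression, but the
   result depends on the excitation pulse (:func:`td_difference`).
3. **Time-domain filtering (TDF)** — the time filter is applied to the
   time-domain representation ``H(t)`` of the referenced response
   itself, combining excitation independence with noise suppression
   (:func:`tdf`).

TDF exploits that the dominant multiplicative noise of the excitation
is temporally confined to the pulse: the inverse transform of ``H(nu)``
projects that noise back to the region around zero delay, where a hard
(Heaviside) or smooth (Butterworth-shaped) high-pass in time removes it
while keeping the slowly decaying molecular free-induction tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .core import (
    C_CM_PER_FS,
    ComplexSpectrum,
    CutoffError,
    FRSError,
    TimeTrace,
    check_uniform_grid,
    rfft_wavenumbers,
)

__all__ = [
    "FreqWindowSpec",
    "TimeFilterSpec",
    "SampleResponse",
    "fft_spectrum",
    "ifft_trace",
    "standard_response",
    "td_difference",
    "time_filter_weights",
    "tdf",
    "filter_magnitude_spectrum",
    "magnitude_spectrum",
    "spectral_resolution",
    "raised_cosine_window",
]


# ---------------------------------------------------------------------------
# filter specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreqWindowSpec:
    """Region of interest in wavenumber with raised-cosine edge tapers.

    The window is 1 inside ``roi = (nu_lo, nu_hi)``, falls to 0 over
    ``transition_width`` on either side, and is 0 beyond.
    """

    roi: tuple[float, float]
    transition_width: float = 50.0

    def __post_init__(self) -> None:
        lo, hi = self.roi
        if not lo < hi:
            raise FRSError("ROI must satisfy nu_lo < nu_hi")
        if self.transition_width <= 0:
            raise FRSError("transition_width must be positive")


@dataclass(frozen=True)
class TimeFilterSpec:
    """Temporal high-pass applied to ``H(t)`` or to a trace difference.

    ``heaviside`` is 0 before ``cutoff`` (fs) and 1 after; ``butterworth``
    is a smooth monotone profile ``1 / (1 + (cutoff/t)^(2*order))`` for
    t > 0 (and 0 at t <= 0); ``none`` leaves the signal untouched.
    """

    kind: Literal["heaviside", "butterworth", "none"] = "heaviside"
    cutoff: float = 0.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("heaviside", "butterworth", "none"):
            raise FRSError(f"unknown time-filter kind {self.kind!r}")
        if self.cutoff < 0:
            raise FRSError("cutoff must be >= 0")
        if self.kind == "butterworth" and self.order < 1:
            raise FRSError("butterworth order must be >= 1")


@dataclass
class SampleResponse:
    """The referenced sample response ``H(nu)`` with its ROI and offset.

    ``spectrum`` holds H on the full one-sided (rfft-like) wavenumber
    grid starting at 0; outside the tapered ROI the values equal
    ``offset`` so that ``spectrum - offset`` is compactly supported.
    ``offset`` is the complex mean of H over the valid ROI — the "1" of
    a weak transmission-like response — which TDF removes before the
    inverse transform and restores afterwards.
    """

    spectrum: ComplexSpectrum
    roi: tuple[float, float]
    offset: complex
    window: FreqWindowSpec
    td: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if abs(self.spectrum.nu[0]) > 1e-9 * self.spectrum.dnu:
            raise FRSError("SampleResponse grid must start at nu = 0")
        if not np.isfinite(self.offset):
            raise FRSError("offset must be finite")

    @property
    def nu(self) -> np.ndarray:
        return self.spectrum.nu

    def roi_mask(self, shrink: float = 0.0) -> np.ndarray:
        """Boolean mask of the ROI, optionally shrunk by ``shrink`` cm^-1."""
        lo, hi = self.roi
        return (self.nu >= lo + shrink) & (self.nu <= hi - shrink)

    @classmethod
    def from_spectrum(
        cls,
        nu: np.ndarray,
        values: np.ndarray,
        window: FreqWindowSpec | None = None,
        transition_width: float = 50.0,
    ) -> "SampleResponse":
        """Embed a spectrum on an arbitrary uniform grid into a response.

        This is the entry point for conventional (e.g. FTIR / database)
        spectra that do not come from an EOS trace pair: the data are
        placed onto a zero-origin grid of the same spacing (linear
        interpolation, ``offset`` outside the measured range), the ROI
        taper is applied, and the result can be fed to :func:`tdf`.
        """
        nu = np.asarray(nu, dtype=float)
        values = np.asarray(values)
        dnu = check_uniform_grid(nu, "wavenumber axis")
        if window is None:
            lo = nu[0] + transition_width
            hi = nu[-1] - transition_width
            if not lo < hi:
                raise FRSError("spectrum too narrow for the requested taper")
            window = FreqWindowSpec((lo, hi), transition_width)
        m = int(round(nu[-1] / dnu)) + 1
        # pad so the conjugate time grid has a power-of-two length
        n_t = 1 << int(np.ceil(np.log2(max(2 * (m - 1), 16))))
        m_pad = n_t // 2 + 1
        full_nu = np.arange(m_pad) * dnu
        roi_mask = (nu >= window.roi[0]) & (nu <= window.roi[1])
        if not roi_mask.any():
            raise FRSError("ROI does not overlap the spectrum grid")
        offset = complex(np.mean(values[roi_mask]))
        interp = np.interp(full_nu, nu, values.real, left=offset.real, right=offset.real).astype(complex)
        if np.iscomplexobj(values):
            interp += 1j * np.interp(full_nu, nu, values.imag, left=offset.imag, right=offset.imag)
        w = raised_cosine_window(full_nu, window)
        stored = offset + w * (interp - offset)
        spec = ComplexSpectrum(full_nu, stored, {"window": window})
        return cls(spectrum=spec, roi=window.roi, offset=offset, window=window)


# ---------------------------------------------------------------------------
# Fourier primitives
# ---------------------------------------------------------------------------

def fft_spectrum(trace: TimeTrace) -> ComplexSpectrum:
    """Forward transform of a real trace onto its one-sided wavenumber grid.

    ``n`` samples at spacing ``dt`` fs map to wavenumber spacing
    ``1/(c * n * dt)`` cm^-1. The spectrum is referenced to absolute
    time zero: a trace whose grid starts at ``t0 != 0`` carries the
    explicit phase factor ``exp(-2*pi*i*c*nu*t0)``. Normalization is
    ``dt * rfft`` (Riemann-sum convention), so energy satisfies
    ``sum |x|^2 dt = sum w_k |X_k|^2 dnu * c`` with one-sided doubling
    weights ``w_k`` (1 at DC/Nyquist, 2 elsewhere).
    """
    nu = rfft_wavenumbers(trace.n, trace.dt)
    vals = np.fft.rfft(trace.values) * trace.dt
    t0 = float(trace.t[0])
    if t0 != 0.0:
        vals = vals * np.exp(-2j * np.pi * C_CM_PER_FS * nu * t0)
    return ComplexSpectrum(nu, vals, {"dt": trace.dt, "t0": t0, **trace.meta})


def ifft_trace(spec: ComplexSpectrum, t0: float = 0.0) -> TimeTrace:
    """Inverse of :func:`fft_spectrum` (real signal, Hermitian extension).

    ``t0`` positions the returned grid; it must match the phase
    reference used in the forward transform for an exact round trip.
    """
    m = spec.nu.size
    if abs(spec.nu[0]) > 1e-9 * spec.dnu:
        raise FRSError("one-sided spectrum must start at nu = 0")
    n = 2 * (m - 1)
    dt = 1.0 / (C_CM_PER_FS * n * spec.dnu)
    vals = np.asarray(spec.values, dtype=complex)
    if t0 != 0.0:
        vals = vals * np.exp(+2j * np.pi * C_CM_PER_FS * spec.nu * t0)
    x = np.fft.irfft(vals, n=n) / dt
    t = t0 + np.arange(n) * dt
    return TimeTrace(t, x, dict(spec.meta))


# ---------------------------------------------------------------------------
# windows and filters
# ---------------------------------------------------------------------------

def raised_cosine_window(nu: np.ndarray, window: FreqWindowSpec) -> np.ndarray:
    """Raised-cosine ROI taper: 1 on the ROI, smooth ramps of width
    ``transition_width`` outside it, 0 beyond."""
    lo, hi = window.roi
    tw = window.transition_width
    w = np.zeros_like(nu, dtype=float)
    w[(nu >= lo) & (nu <= hi)] = 1.0
    ramp_lo = (nu > lo - tw) & (nu < lo)
    w[ramp_lo] = 0.5 * (1.0 - np.cos(np.pi * (nu[ramp_lo] - (lo - tw)) / tw))
    ramp_hi = (nu > hi) & (nu < hi + tw)
    w[ramp_hi] = 0.5 * (1.0 - np.cos(np.pi * ((hi + tw) - nu[ramp_hi]) / tw))
    return w


def time_filter_weights(filt: TimeFilterSpec, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the temporal filter profile on a time grid (fs).

    * ``heaviside``: 0 for t < cutoff, 1 for t >= cutoff;
    * ``butterworth``: 0 for t <= 0, ``1/(1 + (cutoff/t)^(2*order))``
      for t > 0 — a smooth monotone high-pass in time;
    * ``none``: all ones.
    """
    t = np.asarray(t_grid, dtype=float)
    if filt.kind == "none":
        return np.ones_like(t)
    if filt.kind == "heaviside":
        return (t >= filt.cutoff).astype(float)
    w = np.zeros_like(t)
    pos = t > 0
    if filt.cutoff == 0:
        w[pos] = 1.0
    else:
        w[pos] = 1.0 / (1.0 + (filt.cutoff / t[pos]) ** (2 * filt.order))
    return w


# ---------------------------------------------------------------------------
# the three processing procedures
# ---------------------------------------------------------------------------

def standard_response(
    sam: TimeTrace,
    ref: TimeTrace,
    window: FreqWindowSpec,
    floor_frac: float = 1e-3,
) -> SampleResponse:
    """Referenced sample response by the standard frequency-domain ratio.

    ``H(nu) = S_sam(nu)/S_ref(nu)`` is evaluated only where the
    reference has usable spectral power, ``|S_ref| >= floor_frac *
    max|S_ref|``; the division is ill-posed where the excitation has
    none. Masked points carry the offset (the complex mean of H over
    the valid ROI), and the ROI edges are tapered with a raised cosine
    so that ``H - offset`` is compactly supported — the form TDF needs.
    """
    if sam.n != ref.n or abs(sam.dt - ref.dt) > 1e-9 * ref.dt:
        raise FRSError("sample and reference must share one time grid")
    S_sam = np.fft.rfft(sam.values)
    S_ref = np.fft.rfft(ref.values)
    nu = rfft_wavenumbers(ref.n, ref.dt)
    mag = np.abs(S_ref)
    valid = mag >= floor_frac * mag.max()
    lo, hi = window.roi
    roi = (nu >= lo) & (nu <= hi)
    valid_roi = valid & roi
    if not valid_roi.any():
        raise FRSError("reference has no usable spectral support in ROI")
    ratio = np.full(nu.shape, 0.0, dtype=complex)
    ratio[valid] = S_sam[valid] / S_ref[valid]
    offset = complex(np.mean(ratio[valid_roi]))
    ratio[~valid] = offset
    w = raised_cosine_window(nu, window)
    stored = offset + w * (ratio - offset)
    meta = {"floor_frac": floor_frac, "dt": ref.dt}
    spec = ComplexSpectrum(nu, stored, meta)
    return SampleResponse(spectrum=spec, roi=window.roi, offset=offset, window=window)


def td_difference(sam: TimeTrace, ref: TimeTrace, filt: TimeFilterSpec) -> TimeTrace:
    """Time-domain difference ``S_sam - S_ref`` with a temporal filter.

    The filter is evaluated with t = 0 pinned to the reference envelope
    peak, so the cutoff is a delay behind the excitation. With
    ``kind="none"`` the raw difference is returned.
    """
    if sam.n != ref.n or np.max(np.abs(sam.t - ref.t)) > 1e-9 * ref.dt:
        raise FRSError("sample and reference must share one time grid")
    diff = sam.values - ref.values
    t_peak = ref.envelope_peak_time()
    w = time_filter_weights(filt, ref.t - t_peak)
    meta = {**sam.meta, "filter": filt.kind, "cutoff_fs": filt.cutoff}
    return TimeTrace(ref.t.copy(), diff * w, meta)


def tdf(
    resp: SampleResponse,
    filt: TimeFilterSpec,
    output: Literal["complex", "magnitude"] = "complex",
) -> ComplexSpectrum:
    """Time-domain filtering of the referenced sample response.

    Pipeline: (1) subtract the offset from H over the ROI, (2) inverse
    Fourier transform to ``H(t)``, (3) multiply by the temporal filter
    profile with t measured from the transform's zero-delay origin
    (for a Heaviside filter all t < 0 are zeroed as well), (4) forward
    transform, (5) re-add the offset. With ``output="magnitude"`` the
    modulus of the result is returned.

    For fixed filter and ROI the whole map is linear in H, which is
    what makes TDF-filtered spectra usable in linear regression for
    concentration determination.

    The cutoff is snapped to the nearest sample of the conjugate time
    grid; the snapped value is recorded in the output metadata.
    """
    nu = resp.spectrum.nu
    dnu = resp.spectrum.dnu
    m = nu.size
    n_t = 2 * (m - 1)
    dt = 1.0 / (C_CM_PER_FS * n_t * dnu)
    t_window = 1.0 / (C_CM_PER_FS * dnu)
    if filt.kind != "none" and filt.cutoff > t_window:
        raise CutoffError(
            f"cutoff {filt.cutoff:g} fs exceeds time window {t_window:g} fs"
        )
    dev = np.asarray(resp.spectrum.values, dtype=complex) - resp.offset
    h = np.fft.irfft(dev, n=n_t)
    # wraparound time axis: second half of the array holds negative delays
    idx = np.arange(n_t)
    t = idx * dt
    t[idx > n_t // 2] -= n_t * dt
    if filt.kind != "none":
        snapped = round(filt.cutoff / dt) * dt
        filt_eff = TimeFilterSpec(filt.kind, snapped, filt.order)
    else:
        snapped = 0.0
        filt_eff = filt
    w = time_filter_weights(filt_eff, t)
    filtered = np.fft.rfft(h * w) + resp.offset
    meta = {
        "filter": filt.kind,
        "cutoff_fs": snapped,
        "order": filt.order,
        "offset": resp.offset,
        "roi": resp.roi,
    }
    if output == "magnitude":
        return ComplexSpectrum(nu.copy(), np.abs(filtered), meta)
    if output != "complex":
        raise FRSError(f"unknown output kind {output!r}")
    return ComplexSpectrum(nu.copy(), filtered, meta)


def filter_magnitude_spectrum(
    nu: np.ndarray,
    values: np.ndarray,
    filt: TimeFilterSpec,
    window: FreqWindowSpec | None = None,
    transition_width: float = 50.0,
) -> np.ndarray:
    """Apply TDF to a plain (real or complex) spectrum on its own grid.

    Convenience wrapper around :meth:`SampleResponse.from_spectrum` and
    :func:`tdf` for conventional IR spectra (FTIR measurements, library
    entries): returns the filtered magnitude sampled back on ``nu``.
    """
    resp = SampleResponse.from_spectrum(nu, values, window, transition_width)
    out = tdf(resp, filt, output="magnitude")
    return np.interp(np.asarray(nu, dtype=float), out.nu, out.values.real)


def magnitude_spectrum(spec: ComplexSpectrum) -> ComplexSpectrum:
    """Pointwise modulus; the grid is unchanged."""
    return ComplexSpectrum(spec.nu.copy(), np.abs(spec.values), dict(spec.meta))


def spectral_resolution(time_window_ps: float) -> float:
    """Spectral resolution (cm^-1) of a measurement time window (ps).

    The resolution of a Fourier-transform measurement is the inverse
    of the scanned delay range: ``1 / (c * T)``.
    """
    if time_window_ps <= 0:
        raise FRSError("time window must be positive")
    t_fs = time_window_ps * 1e3
    return 1.0 / (C_CM_PER_FS * t_fs)
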