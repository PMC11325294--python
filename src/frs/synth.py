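"""Synthetic EOS measurements: pulses, molecular responses, noise, campaigns.

The generator emulates what a field-resolving spectrometer records for
an aqueous analyte solution:

* a waveform-stable few-cycle mid-IR excitation pulse with a Gaussian
  magnitude spectrum and polynomial spectral phase (GDD/TOD), optionally
  low-passed by a Gaussian detection response (:func:`synth_pulse`);
* a weak, causal molecular response built from complex Lorentzian lines
  plus an optional single cuvette-window echo (:func:`transfer_function`);
* the characteristic FRS noise structure — multiplicative noise whose
  amplitude follows the excitation envelope, on top of an additive
  detection floor (:func:`add_noise`);
* multi-day measurement campaigns with deterministic day-to-day drift
  of the pulse parameters (:func:`make_campaign`), emulating repeated
  measurements on an instrument whose configuration changes over time.

All randomness is drawn from named generators derived by seed
arithmetic, so identical specs and seeds give bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import hilbert

from .core import (
    C_CM_PER_FS,
    ComplexSpectrum,
    FRSError,
    NyquistError,
    TimeTrace,
    check_uniform_grid,
    rfft_wavenumbers,
)

__all__ = [
    "PulseSpec",
    "OscillatorModel",
    "NoiseSpec",
    "CampaignSpec",
    "Measurement",
    "CampaignDay",
    "Campaign",
    "synth_pulse",
    "transfer_function",
    "apply_response",
    "add_noise",
    "make_campaign",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PulseSpec:
    """Few-cycle excitation pulse: Gaussian spectrum + polynomial phase.

    ``center_wavenumber`` and ``bandwidth_fwhm`` are in cm^-1 (FWHM of
    the magnitude spectrum); ``gdd`` (fs^2) and ``tod`` (fs^3) are the
    group-delay and third-order dispersion about the center frequency;
    ``amplitude`` scales the peak of the field envelope;
    ``irf_bandwidth`` is "flat" for an ideal detection response or a
    Gaussian low-pass half-amplitude wavenumber.
    """

    center_wavenumber: float = 1200.0
    bandwidth_fwhm: float = 400.0
    gdd: float = 0.0
    tod: float = 0.0
    amplitude: float = 1.0
    irf_bandwidth: Union[float, str] = "flat"

    def __post_init__(self) -> None:
        if self.center_wavenumber <= 0:
            raise FRSError("center_wavenumber must be > 0")
        if self.bandwidth_fwhm <= 0:
            raise FRSError("bandwidth_fwhm must be > 0")
        if self.amplitude <= 0:
            raise FRSError("amplitude must be > 0")
        if isinstance(self.irf_bandwidth, str) and self.irf_bandwidth != "flat":
            raise FRSError("irf_bandwidth must be a wavenumber or 'flat'")


@dataclass(frozen=True)
class OscillatorModel:
    """Ground-truth analyte: Lorentzian lines and an optional etalon echo.

    Each line is ``(center cm^-1, fwhm cm^-1, strength)`` where strength
    is the dip depth per unit concentration; ``echo`` is a single
    delayed replica ``(delay fs, relative_amplitude)`` from reflections
    between the cuvette windows.
    """

    lines: tuple[tuple[float, float, float], ...] = ()
    concentration: float = 0.0
    echo: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple(tuple(l) for l in self.lines))
        for center, fwhm, _ in self.lines:
            if center <= 0 or fwhm <= 0:
                raise FRSError("line centers and widths must be > 0")
        if self.echo is not None and not abs(self.echo[1]) < 1:
            raise FRSError("echo relative amplitude must satisfy |a| < 1")

    def with_concentration(self, c: float) -> "OscillatorModel":
        return replace(self, concentration=c)


@dataclass(frozen=True)
class NoiseSpec:
    """FRS noise model: envelope-following multiplicative + additive floor.

    ``mult_rms`` is the fractional RMS of the multiplicative process
    (band-limited below ``mult_bandwidth`` cm^-1); ``add_rms`` the RMS
    of the white additive floor in trace-amplitude units.
    """

    mult_rms: float = 0.0
    mult_bandwidth: float = 2000.0
    add_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mult_rms < 0 or self.add_rms < 0:
            raise FRSError("noise RMS values must be >= 0")


@dataclass(frozen=True)
class CampaignSpec:
    """Multi-day measurement campaign with per-day pulse drift.

    ``per_day_pulse_jitter`` is the fractional 1-sigma drift applied
    multiplicatively to center wavenumber, bandwidth and amplitude;
    ``gdd_jitter_fs2`` the absolute 1-sigma drift of the GDD (spectral
    phase drift). Each day uses one drifted pulse for both the
    reference and all sample measurements of that day.
    """

    base_pulse: PulseSpec = PulseSpec()
    n_days: int = 1
    per_day_pulse_jitter: float = 0.0
    gdd_jitter_fs2: float = 0.0
    replicates_per_day: int = 1
    concentrations: tuple[float, ...] = (0.0,)
    base_seed: int = 0
    n: int = 4096
    dt: float = 2.0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.replicates_per_day < 1:
            raise FRSError("n_days and replicates_per_day must be >= 1")
        object.__setattr__(self, "concentrations", tuple(self.concentrations))


@dataclass
class Measurement:
    """One (reference, sample) trace pair with its ground truth."""

    ref: TimeTrace
    sam: TimeTrace
    day: int
    concentration: float
    replicate: int


@dataclass
class CampaignDay:
    day: int
    pulse_spec: PulseSpec
    pulse: TimeTrace  # noise-free reference of the day


@dataclass
class Campaign:
    spec: CampaignSpec
    days: list[CampaignDay]
    measurements: list[Measurement]

    def select(self, concentration: float | None = None, day: int | None = None) -> list[Measurement]:
        out = self.measurements
        if concentration is not None:
            out = [m for m in out if m.concentration == concentration]
        if day is not None:
            out = [m for m in out if m.day == day]
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def synth_pulse(spec: PulseSpec, n: int, dt: float) -> TimeTrace:
    """Synthesize a few-cycle pulse trace with envelope peak at t = 0.

    The magnitude spectrum is Gaussian with the requested center and
    FWHM; the spectral phase is the polynomial set by ``gdd``/``tod``.
    The trace is scaled so the peak of its analytic-signal envelope
    equals ``spec.amplitude``, and the time axis is chosen so that the
    envelope peak sits at t = 0.
    """
    if n < 2 or dt <= 0:
        raise FRSError("need n >= 2 samples and dt > 0")
    nu = rfft_wavenumbers(n, dt)
    nyquist = 1.0 / (2.0 * C_CM_PER_FS * dt)
    top = spec.center_wavenumber + 1.5 * spec.bandwidth_fwhm
    if top > nyquist:
        raise NyquistError(
            f"pulse spectrum extends to {top:g} cm^-1, beyond the Nyquist "
            f"wavenumber {nyquist:g} cm^-1 for dt = {dt:g} fs"
        )
    sigma = spec.bandwidth_fwhm * _FWHM_TO_SIGMA
    amp = np.exp(-0.5 * ((nu - spec.center_wavenumber) / sigma) ** 2)
    if not isinstance(spec.irf_bandwidth, str):
        if spec.irf_bandwidth <= 0:
            raise FRSError("irf_bandwidth must be positive")
        amp = amp * np.exp(-np.log(2.0) * (nu / spec.irf_bandwidth) ** 2)
    domega = 2.0 * np.pi * C_CM_PER_FS * (nu - spec.center_wavenumber)  # rad/fs
    phase = 0.5 * spec.gdd * domega**2 + spec.tod * domega**3 / 6.0
    x = np.fft.irfft(amp * np.exp(-1j * phase), n=n)
    env = np.abs(hilbert(x))
    i_peak = int(np.argmax(env))
    x = np.roll(x, n // 2 - i_peak)
    x *= spec.amplitude / env[i_peak]
    t = (np.arange(n) - n // 2) * dt
    return TimeTrace(t, x, {"role": "reference", "pulse": spec})


def transfer_function(model: OscillatorModel, grid: np.ndarray) -> ComplexSpectrum:
    """Referenced transfer function of the analyte on a wavenumber grid.

    ``H(nu) = [1 - c * sum_k s_k * L_k(nu)] * [1 + a * exp(-2*pi*i*c*nu*tau)]``

    where ``L_k`` is the causal complex Lorentzian with HWHM ``gamma_k``
    whose imaginary part peaks at exactly 1 at the line center,

    ``L_k(nu) = gamma_k / ((nu - center_k) - i*gamma_k)``,

    so the response depth is linear in concentration by construction,
    and the corresponding ``H(t) - delta(t)`` decays for t > 0 (the
    molecular field is emitted in the wake of the excitation). The echo
    factor places a single replica of relative amplitude ``a`` at delay
    ``+tau`` behind the excitation, producing spectral fringes of
    period ``1/(c*tau)``.
    """
    grid = np.asarray(grid, dtype=float)
    check_uniform_grid(grid, "wavenumber grid")
    H = np.ones(grid.shape, dtype=complex)
    for center, fwhm, strength in model.lines:
        gamma = fwhm / 2.0
        L = gamma / ((grid - center) - 1j * gamma)
        H -= model.concentration * strength * L
    if model.echo is not None:
        tau, a = model.echo
        H *= 1.0 + a * np.exp(-2j * np.pi * C_CM_PER_FS * grid * tau)
    return ComplexSpectrum(grid, H, {"model": model})


def apply_response(ref: TimeTrace, h: ComplexSpectrum) -> TimeTrace:
    """Propagate a reference trace through a sample transfer function.

    The output spectrum is ``S_ref(nu) * H(nu)``; real-valuedness is
    preserved by working on the one-sided spectrum (implicit Hermitian
    symmetry of the product). ``h`` is interpolated onto the trace's
    conjugate grid; outside its range the response is taken as 1.
    """
    if not np.all(np.isfinite(h.values)):
        raise FRSError("transfer function contains non-finite values")
    nu = rfft_wavenumbers(ref.n, ref.dt)
    hv = np.asarray(h.values, dtype=complex)
    H = np.interp(nu, h.nu, hv.real, left=1.0, right=1.0) + 1j * np.interp(
        nu, h.nu, hv.imag, left=0.0, right=0.0
    )
    sam = np.fft.irfft(np.fft.rfft(ref.values) * H, n=ref.n)
    meta = {**ref.meta, "role": "sample"}
    return TimeTrace(ref.t.copy(), sam, meta)


def _bandlimited_unit_noise(rng: np.random.Generator, n: int, dt: float, bandwidth: float) -> np.ndarray:
    """White Gaussian noise low-passed (Gaussian, half-amplitude at
    ``bandwidth`` cm^-1) and rescaled to unit RMS."""
    x = rng.standard_normal(n)
    if not np.isinf(bandwidth):
        nu = rfft_wavenumbers(n, dt)
        X = np.fft.rfft(x) * np.exp(-np.log(2.0) * (nu / bandwidth) ** 2)
        x = np.fft.irfft(X, n=n)
        rms = np.sqrt(np.mean(x**2))
        if rms > 0:
            x /= rms
    return x


def add_noise(trace: TimeTrace, noise: NoiseSpec) -> TimeTrace:
    """Add the FRS noise structure to a noise-free trace.

    Output: ``S0(t) * (1 + eps_m(t)) + eps_a(t)`` where ``eps_m`` is
    zero-mean band-limited Gaussian noise of RMS ``mult_rms`` (laser
    intensity / pointing fluctuations, whose amplitude therefore
    follows the signal envelope and is temporally confined to the
    excitation) and ``eps_a`` zero-mean white Gaussian noise of RMS
    ``add_rms`` (the detection floor). Deterministic given the seed.
    """
    rng = np.random.default_rng(noise.seed)
    eps_m = _bandlimited_unit_noise(rng, trace.n, trace.dt, noise.mult_bandwidth)
    eps_a = rng.standard_normal(trace.n)
    out = trace.values * (1.0 + noise.mult_rms * eps_m) + noise.add_rms * eps_a
    meta = {**trace.meta, "noise": noise}
    return TimeTrace(trace.t.copy(), out, meta)


def _derived_seed(*parts: int) -> int:
    """Deterministic child seed from integer coordinates, < 2**31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def make_campaign(
    spec: CampaignSpec,
    model: OscillatorModel,
    noise: NoiseSpec,
) -> Campaign:
    """Simulate a multi-day campaign of (reference, sample) pairs.

    For day ``d`` the pulse parameters are perturbed deterministically
    from ``base_seed + d``; every replicate of every concentration gets
    fresh (but reproducible) noise on both the reference and the sample
    trace. Ground truth (day, concentration, replicate, seeds) is
    recorded in each trace's metadata. A concentration of 0 yields a
    pure-solvent pair (sample = noisy copy of the reference), which the
    SNR analysis uses to estimate the noise level.
    """
    days: list[CampaignDay] = []
    measurements: list[Measurement] = []
    j = spec.per_day_pulse_jitter
    for d in range(spec.n_days):
        rng_d = np.random.default_rng([spec.base_seed, d])
        z = rng_d.standard_normal(4)
        p = spec.base_pulse
        day_pulse = replace(
            p,
            center_wavenumber=p.center_wavenumber * (1.0 + j * z[0]),
            bandwidth_fwhm=p.bandwidth_fwhm * (1.0 + j * z[1]),
            amplitude=p.amplitude * (1.0 + j * z[2]),
            gdd=p.gdd + spec.gdd_jitter_fs2 * z[3],
        )
        ref0 = synth_pulse(day_pulse, spec.n, spec.dt)
        grid = rfft_wavenumbers(spec.n, spec.dt)
        days.append(CampaignDay(day=d, pulse_spec=day_pulse, pulse=ref0))
        for ci, c in enumerate(spec.concentrations):
            if c == 0.0:
                sam0 = ref0
            else:
                H = transfer_function(model.with_concentration(c), grid)
                sam0 = apply_response(ref0, H)
            for r in range(spec.replicates_per_day):
                seed_ref = _derived_seed(spec.base_seed, d, ci, r, 0)
                seed_sam = _derived_seed(spec.base_seed, d, ci, r, 1)
                ref = add_noise(ref0, replace(noise, seed=seed_ref))
                sam = add_noise(sam0, replace(noise, seed=seed_sam))
                ref.meta.update(role="reference", day=d, concentration=c, replicate=r, seed=seed_ref)
                sam.meta.update(role="sample", day=d, concentration=c, replicate=r, seed=seed_sam)
                measurements.append(Measurement(ref=ref, sam=sam, day=d, concentration=c, replicate=r))
    return Campaign(spec=spec, days=days, measurements=measurements)
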