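"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import frs


@pytest.fixture(scope="session")
def pulse_spec() -> frs.PulseSpec:
    return frs.PulseSpec(center_wavenumber=1200.0, bandwidth_fwhm=400.0)


@pytest.fixture(scope="session")
def ref_trace(pulse_spec) -> frs.TimeTrace:
    """Noise-free transform-limited reference, 4096 samples at 2 fs."""
    return frs.synth_pulse(pulse_spec, 4096, 2.0)


@pytest.fixture(scope="session")
def analyte_model() -> frs.OscillatorModel:
    """Two-band weak absorber; 10% dip at concentration 1000."""
    return frs.OscillatorModel(lines=((1100.0, 22.0, 1.0e-4), (1310.0, 26.0, 7.0e-5)))


@pytest.fixture(scope="session")
def window() -> frs.FreqWindowSpec:
    return frs.FreqWindowSpec((900.0, 1500.0), 50.0)


@pytest.fixture(scope="session")
def noiseless_pair(ref_trace, analyte_model):
    """(ref, sam) pair propagated through the analyte at concentration 1000."""
    grid = frs.rfft_wavenumbers(ref_trace.n, ref_trace.dt)
    h = frs.transfer_function(analyte_model.with_concentration(1000.0), grid)
    sam = frs.apply_response(ref_trace, h)
    return ref_trace, sam, h


def direct_sum_tdf(resp: frs.SampleResponse, filt: frs.TimeFilterSpec) -> np.ndarray:
    """O(n^2) direct-sum oracle for the TDF pipeline.

    Implements offset removal, Hermitian extension, explicit inverse
    and forward DFT sums, and the temporal weights — no FFT calls — so
    it is an independent check of :func:`frs.tdf`.
    """
    nu = resp.spectrum.nu
    m = nu.size
    n = 2 * (m - 1)
    dnu = resp.spectrum.dnu
    dt = 1.0 / (frs.C_CM_PER_FS * n * dnu)
    dev = np.asarray(resp.spectrum.values, dtype=complex) - resp.offset
    full = np.zeros(n, dtype=complex)
    full[:m] = dev
    full[m:] = np.conj(dev[1:-1][::-1])
    j = np.arange(n)
    k = np.arange(n)
    # inverse DFT (explicit sum)
    ker_inv = np.exp(2j * np.pi * np.outer(j, k) / n)
    h = (ker_inv @ full) / n
    t = j * dt
    t = np.where(j > n // 2, t - n * dt, t)
    snapped = round(filt.cutoff / dt) * dt
    w = frs.time_filter_weights(frs.TimeFilterSpec(filt.kind, snapped, filt.order), t)
    hw = h * w
    ker_fwd = np.exp(-2j * np.pi * np.outer(k[:m], j) / n)
    return (ker_fwd @ hw) + resp.offset
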