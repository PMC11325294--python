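"""Fourier conventions, the three processing procedures, TDF invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frs
from conftest import direct_sum_tdf


_TEST_WINDOW = frs.FreqWindowSpec((300.0, 900.0), 100.0)


def _random_raw(seed: int, m: int = 257, dnu: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Random complex spectrum (flat 1 outside a noisy band)."""
    rng = np.random.default_rng(seed)
    nu = np.arange(m) * dnu
    vals = np.ones(m, dtype=complex)
    band = (nu > 300) & (nu < 900)
    vals[band] += 0.1 * (rng.standard_normal(band.sum()) + 1j * rng.standard_normal(band.sum()))
    return nu, vals


def _random_response(seed: int) -> frs.SampleResponse:
    nu, vals = _random_raw(seed)
    return frs.SampleResponse.from_spectrum(nu, vals, _TEST_WINDOW)


class TestFourierPrimitives:
    def test_round_trip_identity(self, ref_trace):
        spec = frs.fft_spectrum(ref_trace)
        back = frs.ifft_trace(spec, t0=float(ref_trace.t[0]))
        err = np.max(np.abs(back.values - ref_trace.values)) / np.max(np.abs(ref_trace.values))
        assert err < 1e-12
        assert np.allclose(back.t, ref_trace.t)

    def test_unit_impulse_has_flat_magnitude(self):
        n = 256
        vals = np.zeros(n)
        vals[0] = 1.0
        spec = frs.fft_spectrum(frs.TimeTrace(np.arange(n) * 2.0, vals))
        mags = np.abs(spec.values)
        assert np.allclose(mags, mags[0], rtol=1e-12)

    def test_parseval_with_one_sided_weights(self):
        rng = np.random.default_rng(3)
        n, dt = 1024, 2.0
        x = rng.standard_normal(n)
        trace = frs.TimeTrace(np.arange(n) * dt, x)
        spec = frs.fft_spectrum(trace)
        w = np.full(spec.nu.size, 2.0)
        w[0] = w[-1] = 1.0  # DC and Nyquist appear once in the one-sided spectrum
        lhs = np.sum(x**2) * dt
        rhs = np.sum(w * np.abs(spec.values) ** 2) * spec.dnu * frs.C_CM_PER_FS
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_spectrum_referenced_to_absolute_time_zero(self, ref_trace):
        # same waveform on a shifted grid: magnitudes equal, phases differ
        shifted = frs.TimeTrace(ref_trace.t + 500.0, ref_trace.values)
        a = frs.fft_spectrum(ref_trace)
        b = frs.fft_spectrum(shifted)
        sel = np.abs(a.values) > 1e-3 * np.abs(a.values).max()
        ratio = b.values[sel] / a.values[sel]
        expected = np.exp(-2j * np.pi * frs.C_CM_PER_FS * a.nu[sel] * 500.0)
        assert np.allclose(ratio, expected, atol=1e-9)


class TestStandardResponse:
    def test_self_reference_gives_unity(self, ref_trace, window):
        resp = frs.standard_response(ref_trace, ref_trace, window)
        assert resp.offset == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(resp.spectrum.values[resp.roi_mask()], 1.0, atol=1e-12)

    def test_delayed_sample_has_linear_phase(self, ref_trace, window):
        tau = 100.0
        grid = frs.rfft_wavenumbers(ref_trace.n, ref_trace.dt)
        h = frs.ComplexSpectrum(grid, np.exp(-2j * np.pi * frs.C_CM_PER_FS * grid * tau))
        sam = frs.apply_response(ref_trace, h)
        resp = frs.standard_response(sam, ref_trace, window)
        mask = resp.roi_mask()
        phase = np.unwrap(np.angle(resp.spectrum.values[mask]))
        slope = np.polyfit(resp.nu[mask], phase, 1)[0]
        assert slope == pytest.approx(-2 * np.pi * frs.C_CM_PER_FS * tau, rel=0.005)

    def test_inverts_apply_response_on_noiseless_data(self, noiseless_pair, window):
        ref, sam, h_true = noiseless_pair
        resp = frs.standard_response(sam, ref, window)
        mask = resp.roi_mask()
        err = np.max(np.abs(resp.spectrum.values[mask] - h_true.values[mask]))
        assert err < 1e-8 * np.max(np.abs(h_true.values[mask]))

    def test_no_spectral_support_raises(self, ref_trace):
        with pytest.raises(frs.FRSError, match="support"):
            frs.standard_response(ref_trace, ref_trace, frs.FreqWindowSpec((5000.0, 6000.0)))

    def test_grid_mismatch_raises(self, ref_trace, window):
        other = frs.TimeTrace(np.arange(512) * 2.0, np.ones(512))
        with pytest.raises(frs.FRSError):
            frs.standard_response(other, ref_trace, window)


class TestTdDifference:
    def test_identical_traces_give_zero(self, ref_trace):
        out = frs.td_difference(ref_trace, ref_trace, frs.TimeFilterSpec("none"))
        assert np.array_equal(out.values, np.zeros(ref_trace.n))

    def test_filtered_difference_equals_ground_truth_tail(self, noiseless_pair):
        ref, sam, _ = noiseless_pair
        cutoff = 650.0
        out = frs.td_difference(sam, ref, frs.TimeFilterSpec("heaviside", cutoff))
        emf = sam.values - ref.values  # ground-truth molecular field
        tail = ref.t >= cutoff
        num = np.linalg.norm(out.values[tail] - emf[tail])
        assert num < 1e-6 * np.linalg.norm(emf[tail])
        assert np.array_equal(out.values[~tail], np.zeros(np.count_nonzero(~tail)))

    def test_subtraction_is_linear(self, noiseless_pair):
        ref, sam, _ = noiseless_pair
        filt = frs.TimeFilterSpec("heaviside", 400.0)
        combo = frs.TimeTrace(ref.t, sam.values + sam.values - ref.values)
        lhs = frs.td_difference(combo, ref, filt).values
        rhs = 2.0 * frs.td_difference(sam, ref, filt).values
        assert np.allclose(lhs, rhs, atol=1e-12 * np.max(np.abs(rhs)))


class TestTimeFilterWeights:
    def test_heaviside_degenerate_cutoff(self):
        t = np.arange(0.0, 100.0, 1.0)
        assert np.array_equal(frs.time_filter_weights(frs.TimeFilterSpec("heaviside", 0.0), t),
                              np.ones_like(t))

    def test_heaviside_edge_definition(self):
        t = np.array([649.0, 650.0, 651.0])
        w = frs.time_filter_weights(frs.TimeFilterSpec("heaviside", 650.0), t)
        assert list(w) == [0.0, 1.0, 1.0]

    def test_butterworth_monotone_and_saturates(self):
        t = np.arange(0.0, 4001.0, 1.0)
        filt = frs.TimeFilterSpec("butterworth", 650.0, order=4)
        w = frs.time_filter_weights(filt, t)
        assert np.all(np.diff(w) >= 0)
        assert np.all(w[t >= 4 * 650.0] > 0.99)
        # oracle: direct evaluation of the profile
        tt = 1300.0
        assert w[int(tt)] == pytest.approx(1.0 / (1.0 + (650.0 / tt) ** 8), rel=1e-12)

    def test_zero_and_negative_times(self):
        t = np.array([-100.0, 0.0, 100.0])
        w = frs.time_filter_weights(frs.TimeFilterSpec("butterworth", 200.0, 4), t)
        assert w[0] == 0.0 and w[1] == 0.0 and 0.0 < w[2] < 1.0
        assert np.array_equal(frs.time_filter_weights(frs.TimeFilterSpec("none"), t), np.ones(3))


class TestTDF:
    def test_flat_response_is_fixed_point(self):
        nu = np.arange(513) * 4.0
        resp = frs.SampleResponse(
            spectrum=frs.ComplexSpectrum(nu, np.ones(513, dtype=complex)),
            roi=(nu[0], nu[-1]), offset=1.0 + 0.0j,
            window=frs.FreqWindowSpec((nu[0] + 1e-9, nu[-1]), 50.0))
        out = frs.tdf(resp, frs.TimeFilterSpec("heaviside", 650.0))
        assert np.max(np.abs(out.values - 1.0)) < 1e-12

    def test_no_filter_reproduces_input(self, seed=5):
        resp = _random_response(seed)
        out = frs.tdf(resp, frs.TimeFilterSpec("none"))
        err = np.max(np.abs(out.values - resp.spectrum.values))
        assert err < 1e-12 * np.max(np.abs(resp.spectrum.values))

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3),
           s1=st.integers(0, 1000), s2=st.integers(0, 1000))
    def test_tdf_is_linear(self, a, b, s1, s2):
        """The filtered deviation of a linear combination is the linear
        combination of the filtered deviations (linearity of TDF)."""
        nu, v1 = _random_raw(s1)
        _, v2 = _random_raw(s2)
        combo_vals = a * (v1 - 1.0) + b * (v2 - 1.0) + 1.0
        r1 = frs.SampleResponse.from_spectrum(nu, v1, _TEST_WINDOW)
        r2 = frs.SampleResponse.from_spectrum(nu, v2, _TEST_WINDOW)
        combo = frs.SampleResponse.from_spectrum(nu, combo_vals, _TEST_WINDOW)
        filt = frs.TimeFilterSpec("heaviside", 400.0)
        lhs = frs.tdf(combo, filt).values - 1.0
        rhs = a * (frs.tdf(r1, filt).values - 1.0) + b * (frs.tdf(r2, filt).values - 1.0)
        scale = max(np.max(np.abs(rhs)), 1.0)
        assert np.max(np.abs(lhs - rhs)) < 1e-10 * scale

    @pytest.mark.parametrize("kind,cutoff", [("heaviside", 650.0), ("butterworth", 650.0),
                                             ("heaviside", 0.0)])
    def test_matches_direct_sum_oracle(self, kind, cutoff):
        nu = np.arange(257) * 4.0
        h = frs.transfer_function(
            frs.OscillatorModel(lines=((600.0, 20.0, 1e-4),), concentration=1000.0), nu)
        resp = frs.SampleResponse.from_spectrum(nu, h.values, frs.FreqWindowSpec((400.0, 800.0), 80.0))
        filt = frs.TimeFilterSpec(kind, cutoff, 4)
        ours = frs.tdf(resp, filt).values
        oracle = direct_sum_tdf(resp, filt)
        assert np.max(np.abs(ours - oracle)) < 1e-6 * np.max(np.abs(oracle))
        # retained fraction of the response energy agrees with the oracle
        dev = np.abs(resp.spectrum.values - resp.offset) ** 2
        ret_ours = np.sum(np.abs(ours - resp.offset) ** 2) / np.sum(dev)
        ret_oracle = np.sum(np.abs(oracle - resp.offset) ** 2) / np.sum(dev)
        assert ret_ours == pytest.approx(ret_oracle, rel=1e-6)

    def test_etalon_echo_suppressed(self):
        grid = frs.rfft_wavenumbers(4096, 2.0)
        h = frs.transfer_function(frs.OscillatorModel(echo=(280.0, 0.05)), grid)
        resp = frs.SampleResponse.from_spectrum(grid, h.values, frs.FreqWindowSpec((900.0, 1500.0), 100.0))
        mask = resp.roi_mask(50.0)
        unfiltered = np.abs(resp.spectrum.values[mask])
        filtered = frs.tdf(resp, frs.TimeFilterSpec("heaviside", 700.0), output="magnitude").values[mask]
        reduction = np.ptp(unfiltered) / np.ptp(filtered)
        assert reduction >= 20.0

    def test_heaviside_energy_monotone_in_cutoff(self):
        resp = _random_response(11)
        energies = []
        for cutoff in np.arange(0.0, 1501.0, 100.0):
            out = frs.tdf(resp, frs.TimeFilterSpec("heaviside", cutoff))
            energies.append(np.sum(np.abs(out.values - resp.offset) ** 2))
        assert all(b <= a + 1e-15 for a, b in zip(energies, energies[1:]))

    def test_cutoff_beyond_time_window_raises(self):
        resp = _random_response(2)
        t_window = 1.0 / (frs.C_CM_PER_FS * resp.spectrum.dnu)
        with pytest.raises(frs.CutoffError, match="time window"):
            frs.tdf(resp, frs.TimeFilterSpec("heaviside", t_window * 1.01))

    def test_cutoff_at_window_end_yields_flat_offset(self):
        resp = _random_response(8)
        t_window = 1.0 / (frs.C_CM_PER_FS * resp.spectrum.dnu)
        out = frs.tdf(resp, frs.TimeFilterSpec("heaviside", t_window))
        assert np.max(np.abs(out.values - resp.offset)) < 1e-12

    def test_magnitude_output_and_snapping_metadata(self):
        resp = _random_response(4)
        out = frs.tdf(resp, frs.TimeFilterSpec("heaviside", 333.0), output="magnitude")
        assert not np.iscomplexobj(out.values) or np.all(out.values.imag == 0)
        dt = 1.0 / (frs.C_CM_PER_FS * 2 * (resp.spectrum.nu.size - 1) * resp.spectrum.dnu)
        assert out.meta["cutoff_fs"] == pytest.approx(round(333.0 / dt) * dt)


class TestSpectralResolution:
    def test_known_instrument_time_windows(self):
        assert round(frs.spectral_resolution(8.3), 1) == 4.0
        assert frs.spectral_resolution(5.8) == pytest.approx(5.7, abs=0.06)

    def test_monotone_vanishing_limit(self):
        res = [frs.spectral_resolution(T) for T in (1.0, 10.0, 100.0, 1000.0)]
        assert all(b < a for a, b in zip(res, res[1:]))
        assert res[-1] < 0.05

    def test_nonpositive_window_raises(self):
        with pytest.raises(frs.FRSError):
            frs.spectral_resolution(0.0)


class TestMagnitudeSpectrum:
    def test_pointwise_modulus(self):
        nu = np.arange(8) * 2.0
        theta = np.linspace(0, 3, 8)
        spec = frs.ComplexSpectrum(nu, np.exp(1j * theta))
        out = frs.magnitude_spectrum(spec)
        assert np.allclose(out.values, 1.0, atol=1e-15)
        assert np.array_equal(out.nu, nu)
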