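"""Downstream evaluations: SNR-vs-cutoff, quantification, identification.

These routines mirror how FRS spectra are actually used:

* :func:`snr_scan` maps out signal strength, noise level and SNR as a
  function of the temporal-filter cutoff, to locate the optimum — the
  delay at which the envelope-following multiplicative noise of the
  excitation has dropped to the additive detection floor
  (:func:`noise_crossover` computes that crossover from the ground
  truth of a simulated campaign);
* :func:`retrieve_concentration` projects a measured fingerprint onto
  a reference fingerprint of known concentration (one-parameter linear
  least squares), valid because the weak response — and TDF — are
  linear in concentration;
* :func:`path_calibration` rescales a measurement day by a measurement
  of a known standard, compensating cuvette path-length differences;
* :func:`cosine_identify` ranks a query spectrum against a library of
  magnitude spectra by cosine similarity after identical preprocessing
  and mean-centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .core import ComplexSpectrum, FRSError, TimeTrace
from .processing import (
    FreqWindowSpec,
    SampleResponse,
    TimeFilterSpec,
    fft_spectrum,
    filter_magnitude_spectrum,
    standard_response,
    td_difference,
    tdf,
)
from .synth import Campaign, Measurement, NoiseSpec

__all__ = [
    "SNRScanResult",
    "SpectralLibrary",
    "IdentificationResult",
    "signal_strength",
    "noise_level",
    "snr_scan",
    "noise_crossover",
    "retrieve_concentration",
    "path_calibration",
    "cosine_identify",
    "method_spectrum",
]

#: Wavenumber band (cm^-1) over which the noise level is averaged.
DEFAULT_NOISE_BAND = (1000.0, 1400.0)


@dataclass
class SNRScanResult:
    """Signal strength, noise level and SNR per temporal-filter cutoff."""

    cutoffs: np.ndarray
    signal_strength: np.ndarray
    noise_level: np.ndarray
    snr: np.ndarray
    optimal_cutoff: float
    degenerate: bool = False  # True when the noise level vanished somewhere

    def __post_init__(self) -> None:
        if not (
            len(self.cutoffs)
            == len(self.signal_strength)
            == len(self.noise_level)
            == len(self.snr)
        ):
            raise FRSError("scan arrays must have equal length")


@dataclass
class SpectralLibrary:
    """Named magnitude spectra on a common wavenumber grid."""

    grid: np.ndarray
    entries: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for name, vals in self.entries.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.grid.shape:
                raise FRSError(f"library entry {name!r} is not on the common grid")
            self.entries[name] = vals
        if len(self.entries) != len(set(self.entries)):
            raise FRSError("library names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.entries)


@dataclass
class IdentificationResult:
    """Ranked cosine similarities of a query against a library."""

    query_name: str
    ranking: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.ranking:
            raise FRSError("ranking must not be empty")
        sims = [s for _, s in self.ranking]
        if sorted(sims, reverse=True) != sims:
            raise FRSError("ranking must be sorted by descending similarity")

    @property
    def top_hit(self) -> str:
        return self.ranking[0][0]


# ---------------------------------------------------------------------------
# signal / noise figures
# ---------------------------------------------------------------------------

def signal_strength(
    values: np.ndarray,
    baseline: float = 1.0,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Maximum absolute deviation of a (filtered) spectrum from baseline.

    The baseline defaults to 1, the level of a transmission-like
    response without analyte; for filtered responses pass the recorded
    offset. ``mask`` restricts the evaluation to the ROI.
    """
    v = np.asarray(values)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    if v.size == 0:
        raise FRSError("empty ROI")
    if not np.all(np.isfinite(v)):
        raise FRSError("spectrum contains non-finite values")
    return float(np.max(np.abs(v - baseline)))


def noise_level(
    replicate_spectra: Sequence[np.ndarray],
    nu: np.ndarray,
    band: tuple[float, float] = DEFAULT_NOISE_BAND,
) -> float:
    """Replicate standard deviation, frequency-averaged over a band.

    Computes the per-wavenumber standard deviation across replicate
    spectra and averages it over ``band``. Invariant under adding any
    replicate-independent baseline.
    """
    arr = np.asarray([np.asarray(s, dtype=float) for s in replicate_spectra])
    if arr.shape[0] < 2:
        raise FRSError("need at least 2 replicates to estimate noise")
    nu = np.asarray(nu, dtype=float)
    sel = (nu >= band[0]) & (nu <= band[1])
    if not sel.any():
        raise FRSError("noise band does not overlap the grid")
    std = np.std(arr[:, sel], axis=0, ddof=1)
    return float(np.mean(std))


def snr_scan(
    measurements: Sequence[Measurement],
    cutoffs: Sequence[float],
    filter_kind: Literal["heaviside", "butterworth"] = "heaviside",
    *,
    window: FreqWindowSpec,
    floor_frac: float = 1e-3,
    order: int = 4,
    band: tuple[float, float] = DEFAULT_NOISE_BAND,
) -> SNRScanResult:
    """Scan the temporal-filter cutoff and evaluate signal, noise, SNR.

    ``measurements`` must contain analyte pairs (concentration > 0),
    from which the signal strength (maximum deviation from the offset
    of the replicate-mean filtered spectrum) is taken, and pure-solvent
    pairs (concentration == 0), from which the noise level (replicate
    scatter in ``band``) is taken — both after TDF with the given cutoff. The
    optimal cutoff is the argmax of SNR; ties break toward the smaller
    cutoff. If the noise level vanishes anywhere the scan is flagged
    degenerate and the SNR there is infinite.
    """
    analyte = [m for m in measurements if m.concentration > 0]
    solvent = [m for m in measurements if m.concentration == 0]
    if not analyte or len(solvent) < 2:
        raise FRSError("need analyte replicates and >= 2 solvent replicates")
    responses_a = [standard_response(m.sam, m.ref, window, floor_frac) for m in analyte]
    responses_s = [standard_response(m.sam, m.ref, window, floor_frac) for m in solvent]
    nu = responses_a[0].nu
    roi_mask = responses_a[0].roi_mask()
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    sig = np.empty_like(cutoffs)
    noi = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        filt = TimeFilterSpec(filter_kind, float(c), order)
        analyte_mags = [tdf(r, filt, output="magnitude").values for r in responses_a]
        baseline = float(np.mean([abs(r.offset) for r in responses_a]))
        sig[i] = signal_strength(np.mean(analyte_mags, axis=0), baseline, roi_mask)
        # offset-correct each solvent replicate (subtract its ROI mean) so the
        # scalar offset fluctuation -- which mean-centered downstream analyses
        # do not see -- does not mask the decay of the localized noise
        solvent_mags = []
        for r in responses_s:
            mag = tdf(r, filt, output="magnitude").values
            solvent_mags.append(mag - np.mean(mag[roi_mask]))
        noi[i] = noise_level(solvent_mags, nu, band)
    degenerate = bool(np.any(noi == 0))
    with np.errstate(divide="ignore"):
        snr = np.where(noi > 0, sig / np.where(noi > 0, noi, 1.0), np.inf)
    best = int(np.argmax(snr))  # argmax returns the first (smallest) maximizer
    return SNRScanResult(
        cutoffs=cutoffs,
        signal_strength=sig,
        noise_level=noi,
        snr=snr,
        optimal_cutoff=float(cutoffs[best]),
        degenerate=degenerate,
    )


def noise_crossover(pulse: TimeTrace, noise: NoiseSpec) -> float:
    """Delay (fs after the envelope peak) where multiplicative noise
    falls to the additive floor.

    Evaluates ``mult_rms * env(t) <= add_rms`` on the noise-free pulse
    and returns the first such delay behind the peak — the cutoff the
    instrument noise analysis would suggest for the time filter.
    Returns ``inf`` if the envelope never drops that far.
    """
    if noise.add_rms <= 0 or noise.mult_rms <= 0:
        raise FRSError("crossover needs both noise terms > 0")
    env = pulse.envelope()
    i_peak = int(np.argmax(env))
    level = noise.mult_rms * env[i_peak:]
    below = np.nonzero(level <= noise.add_rms)[0]
    if below.size == 0:
        return float("inf")
    return float(pulse.t[i_peak + below[0]] - pulse.t[i_peak])


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def retrieve_concentration(
    measured: np.ndarray,
    reference: np.ndarray,
    c_ref: float,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Concentration by projection onto a reference fingerprint.

    ``c_est = c_ref * <m, r> / <r, r>`` with both spectra mean-centered
    over the ROI first (offset removal); this is the one-parameter
    least-squares fit of the reference fingerprint to the measurement,
    exactly linear in the measured spectrum. Both spectra must be on
    one grid and have received identical processing.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise FRSError("measured and reference spectra must share one grid")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        m, r = m[sel], r[sel]
    m = m - np.mean(m)
    r = r - np.mean(r)
    rr = float(np.dot(r, r))
    if rr == 0.0:
        raise FRSError("reference fingerprint is empty")
    return float(c_ref * np.dot(m, r) / rr)


def path_calibration(measured_known: np.ndarray, expected: np.ndarray,
                     mask: Optional[np.ndarray] = None) -> float:
    """Scale factor of a day's path length from a known standard.

    ``s = <measured, expected> / <expected, expected>``; spectra of the
    same day are divided by ``s`` before quantification, compensating
    cuvette path-length differences between measurement days.
    """
    m = np.asarray(measured_known, dtype=float)
    e = np.asarray(expected, dtype=float)
    if m.shape != e.shape:
        raise FRSError("spectra must share one grid")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        m, e = m[sel], e[sel]
    ee = float(np.dot(e, e))
    if ee == 0.0:
        raise FRSError("expected spectrum is degenerate")
    return float(np.dot(m, e) / ee)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def cosine_identify(
    query_nu: np.ndarray,
    query_values: np.ndarray,
    lib: SpectralLibrary,
    *,
    filt: Optional[TimeFilterSpec] = None,
    window: Optional[FreqWindowSpec] = None,
    query_name: str = "query",
) -> IdentificationResult:
    """Identify a spectrum against a library by cosine similarity.

    Steps: (1) linearly interpolate the query onto the library grid
    (grid points outside the query's range are dropped from both
    vectors), (2) apply identical preprocessing — optionally TDF with
    the given filter — to query and entries, (3) mean-center each
    spectrum, (4) cosine similarity against every entry, (5) rank
    descending. The top hit is the identification.
    """
    if not lib.entries:
        raise FRSError("empty library")
    qnu = np.asarray(query_nu, dtype=float)
    qv = np.asarray(query_values, dtype=float)
    sel = (lib.grid >= qnu[0]) & (lib.grid <= qnu[-1])
    if not sel.any():
        raise FRSError("query grid does not overlap the library grid")
    grid = lib.grid[sel]
    q = np.interp(grid, qnu, qv)
    entries = {name: vals[sel] for name, vals in lib.entries.items()}
    if filt is not None:
        q = filter_magnitude_spectrum(grid, q, filt, window)
        entries = {
            name: filter_magnitude_spectrum(grid, vals, filt, window)
            for name, vals in entries.items()
        }
    q = q - np.mean(q)
    qn = float(np.linalg.norm(q))
    if qn == 0.0:
        raise FRSError("query carries no spectral contrast")
    sims = []
    for name, vals in entries.items():
        v = vals - np.mean(vals)
        vn = float(np.linalg.norm(v))
        sims.append((name, float(np.dot(q, v) / (qn * vn)) if vn > 0 else 0.0))
    sims.sort(key=lambda kv: -kv[1])
    return IdentificationResult(query_name=query_name, ranking=sims)


# ---------------------------------------------------------------------------
# end-to-end processing of one measurement
# ---------------------------------------------------------------------------

def method_spectrum(
    meas: Measurement,
    method: Literal["standard", "tddiff", "tdf"],
    window: FreqWindowSpec,
    filt: TimeFilterSpec,
    floor_frac: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run one processing procedure end to end on a measurement pair.

    Returns ``(nu, magnitude, roi_mask)`` for the chosen route:
    the unfiltered frequency-domain ratio (``standard``), the spectrum
    of the temporally filtered trace difference (``tddiff``), or the
    time-domain-filtered response (``tdf``). All three are magnitude
    spectra on the pair's conjugate wavenumber grid, comparable through
    :func:`retrieve_concentration`.
    """
    if method == "tddiff":
        diff = td_difference(meas.sam, meas.ref, filt)
        spec = fft_spectrum(diff)
        resp = standard_response(meas.sam, meas.ref, window, floor_frac)
        mask = resp.roi_mask()
        return spec.nu, np.abs(spec.values), mask
    resp = standard_response(meas.sam, meas.ref, window, floor_frac)
    mask = resp.roi_mask()
    if method == "standard":
        return resp.nu, np.abs(resp.spectrum.values), mask
    if method == "tdf":
        out = tdf(resp, filt, output="magnitude")
        return out.nu, out.values.real, mask
    raise FRSError(f"unknown method {method!r}")
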