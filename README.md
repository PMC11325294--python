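# frs — time-domain filtering for field-resolved infrared spectroscopy

Field-resolved infrared spectroscopy (FRS) records the electric field
transmitted through a sample as a function of delay, via electro-optic
sampling (EOS) of the response to a few-cycle mid-infrared pulse.
Because the excitation is ultrabrief, most of the molecular
free-induction signal — and very little of the excitation's technical
noise — lives at delays *behind* the pulse. Exploiting that separation
without making the result depend on the particular excitation pulse is
the job of this package.

It is aimed at spectroscopists who want to process EOS trace pairs
(reference = solvent, sample = analyte solution) into
instrument-independent molecular spectra, quantify analytes, and match
measurements against infrared databases — and at method developers who
need a controllable simulator of FRS measurements to test such
pipelines end to end.

## The method

From a trace pair the referenced sample response is, in the frequency
domain,

```
H(ν) = S̃_sam(ν) / S̃_ref(ν)
```

which is nominally independent of the excitation but inherits the full
technical noise of both traces. **Time-domain filtering (TDF)** removes
the part of that noise that is temporally confined to the excitation:

1. restrict H(ν) to a region of interest with smooth (raised-cosine)
   transitions and subtract the offset (the complex mean of H over the
   ROI — the "1" of a weak transmission response);
2. inverse Fourier transform to the time-domain response H(t), where
   the excitation-localized noise collapses to the region around zero
   delay;
3. multiply by a temporal high-pass w(t) — a hard Heaviside step at a
   cutoff delay, or a smooth Butterworth-shaped profile;
4. transform back and restore the offset:

```
H_filtered(ν) = F[ w(t) · F⁻¹[H(ν) − offset] ] + offset
```

TDF is linear in H, so filtered spectra remain valid inputs for linear
regression (concentration retrieval) and library matching, provided
query and reference receive the same filter. The cutoff is not free:
the multiplicative noise of the source follows the envelope of the
excitation, so the optimal cutoff is the delay at which that noise has
decayed to the additive detection floor — a quantity a simple noise
analysis provides.

The package implements, behind one consistent set of FFT conventions:

- `frs.synth` — simulation of EOS measurements: chirped Gaussian
  few-cycle pulses, weak causal Lorentzian molecular responses with an
  optional cuvette-window echo, envelope-following multiplicative plus
  additive noise, and multi-day campaigns with drifting pulse
  parameters;
- `frs.processing` — the standard frequency-domain ratio, the
  time-domain difference with temporal filter, and TDF, plus the
  filter primitives and the time-window ↔ spectral-resolution
  correspondence (1/cT);
- `frs.analysis` — signal strength / noise level / SNR versus cutoff,
  noise-crossover estimation, concentration retrieval by least-squares
  projection, path-length calibration, and cosine-similarity library
  identification;
- `frs.io` / `frs.cli` — text trace/spectrum formats, a JCAMP-DX
  reader for FTIR database spectra, and the `frs` command line
  (`simulate`, `process`, `snr-scan`, `quantify`, `identify`).

## Worked example

Simulate one measurement day (pure water and a 1000 µg/mL analyte, ten
replicates each), run the noise analysis, scan the filter cutoff, and
quantify a replicate:

```python
import numpy as np
import frs
from frs.experiments import DEFAULT_PULSE, DEFAULT_ANALYTE, DEFAULT_NOISE, DEFAULT_WINDOW

campaign = frs.make_campaign(
    frs.CampaignSpec(base_pulse=DEFAULT_PULSE, n_days=1, replicates_per_day=10,
                     concentrations=(0.0, 1000.0), base_seed=1),
    DEFAULT_ANALYTE, DEFAULT_NOISE)

crossover = frs.noise_crossover(campaign.days[0].pulse, DEFAULT_NOISE)
scan = frs.snr_scan(campaign.measurements, np.arange(0.0, 801.0, 50.0),
                    window=DEFAULT_WINDOW)

filt = frs.TimeFilterSpec("heaviside", scan.optimal_cutoff)
m = campaign.select(concentration=1000.0)[0]
resp = frs.standard_response(m.sam, m.ref, DEFAULT_WINDOW)
mag = frs.tdf(resp, filt, output="magnitude")
h = frs.transfer_function(DEFAULT_ANALYTE.with_concentration(1000.0), mag.nu)
fingerprint = frs.tdf(frs.SampleResponse.from_spectrum(mag.nu, h.values, DEFAULT_WINDOW),
                      filt, output="magnitude")
c = frs.retrieve_concentration(mag.values, fingerprint.values, 1000.0, resp.roi_mask())
```

Output:

```
noise crossover: 346 fs behind the excitation peak
SNR-optimal cutoff: 400 fs
signal 0.034, noise 1.65e-04, SNR 209 at the optimum
unfiltered SNR 19 -> gain 11.2x
retrieved concentration: 1005 ug/mL (truth 1000)
```

The noise analysis predicts where the multiplicative noise of the
excitation meets the detection floor (346 fs); the SNR scan finds its
optimum one grid step later (400 fs), where filtering has bought an
order of magnitude in SNR; quantification of a noisy replicate against
the identically filtered fingerprint recovers the concentration to
0.5%.

The same steps are available from a shell: `frs simulate`,
`frs snr-scan`, `frs process --method tdf`, `frs quantify`,
`frs identify` (see `frs --help`).

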