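# Models, conventions and design notes

This note documents what the package actually computes: the signal and
noise models behind the simulator, the exact definition of each
processing route, the numerical conventions, the study conditions used
by the bundled experiments, and the known limits of what the synthetic
tests demonstrate.

## Units and Fourier conventions

Delays are in femtoseconds, spectroscopic frequencies in wavenumbers
(cm⁻¹); they are conjugate through c = 2.99792458·10⁻⁵ cm/fs. A real
trace of n samples at spacing dt maps onto a one-sided wavenumber grid
of spacing Δν = 1/(c·n·dt). The forward transform is the Riemann-sum
rfft, `X(ν) = dt·Σ x(t)·exp(−2πi·c·ν·t)`, referenced to absolute time
zero; the inverse is the Hermitian extension (irfft), kernel
`exp(+2πi·c·ν·t)`. Under these conventions a causal response decaying
after the excitation has spectrum ∝ 1/(γ + i(ν−ν₀)), and a replica
delayed by +τ carries exp(−2πi·c·ν·τ). Round trips are exact to
~10⁻¹⁵ relative and are enforced by tests.

The spectral resolution of a scanned delay range T is 1/(c·T): 8.3 ps
↔ 4.0 cm⁻¹; 5.8 ps ↔ 5.75 cm⁻¹ (5.7 at single-decimal precision once
the rounding of the 5.8 ps window itself is taken into account).

## Signal model

**Excitation.** `synth_pulse` builds a waveform-stable few-cycle pulse
from a Gaussian magnitude spectrum (center ν₀, FWHM Δν) and a
polynomial spectral phase: group-delay dispersion (GDD, fs²) and
third-order dispersion (TOD, fs³) about ν₀. The analytic-signal
envelope peak defines t = 0 and is normalized to the requested
amplitude. An optional Gaussian low-pass in wavenumber (half
amplitude at `irf_bandwidth`) models a non-flat detection response;
the default is flat, which is a good approximation for EOS.

**Molecular response.** `transfer_function` composes the referenced
response

H(ν) = [1 − C·Σₖ sₖ·Lₖ(ν)] · [1 + a·exp(−2πi·c·ν·τ)]

with complex Lorentzians Lₖ(ν) = γₖ/((ν−ν₀ₖ) − iγₖ), γₖ = FWHM/2.
This parameterization has two deliberate properties: the imaginary
part of Lₖ peaks at exactly 1 at the line center, so `strength ×
concentration` is the response depth and H−1 is *exactly* linear in
concentration; and the sign of the (ν−ν₀) term makes the response
causal under the package's transform conventions — H(t) is emitted in
the wake of the excitation, which is the property the temporal filter
relies on. The optional echo term is a single delayed replica (first
reflection between cuvette windows) at delay +τ behind the pulse,
producing magnitude fringes of period 1/(c·τ) ≈ 119 cm⁻¹ for τ =
280 fs; higher-order reflections are out of scope. The weak-response
model is valid for low concentrations (|H−1| ≪ 1); solvent
displacement, solute–solute interaction and geometry effects are not
modeled.

**Noise.** `add_noise` implements

S_noise(t) = S₀(t)·(1 + ε_m(t)) + ε_a(t)

where ε_m is Gaussian noise low-passed below `mult_bandwidth`
(relative intensity noise and pointing of the source; its amplitude
therefore follows the signal envelope and is temporally confined to
the excitation) and ε_a is white additive noise (detector floor). The
multiplicative term rides the *full signal*, carrier included: this
matters, because the reference division of the processing chain then
cancels the pulse's spectral amplitude and phase in the noise as well,
leaving the noise in H(t) compactly localized around zero delay —
precisely the structure the time filter exploits, and the mechanism by
which the SNR optimum tracks the multiplicative/additive crossover. A
carrier-free, envelope-weighted noise term was tried and rejected: the
deconvolution imprints the conjugate chirp and ROI-edge amplification
on it, smearing it over the whole window and decoupling the SNR
optimum from the crossover delay. `mult_bandwidth` defaults to
2000 cm⁻¹ so the noise covers the full excitation band.

**Campaigns.** `make_campaign` simulates n_days measurement days. Per
day, center wavenumber, bandwidth and amplitude are jittered
multiplicatively (fractional 1σ `per_day_pulse_jitter`) and the GDD
additively (`gdd_jitter_fs2`), emulating instrument drift and
reconfiguration; one drifted pulse serves all of that day's reference
and sample traces. Every (day, concentration, replicate, role) gets
its own RNG seed derived by seed arithmetic from `base_seed`, so
campaigns are bit-reproducible. Concentration 0 produces pure-solvent
pairs used for noise estimation.

## Processing routes

**Standard ratio** (`standard_response`). H = S̃_sam/S̃_ref evaluated
where |S̃_ref| ≥ `floor_frac` (default 10⁻³) of its peak — the division
is ill-posed where the excitation has no power; masked points carry
the offset. The offset is the complex mean of H over the valid ROI.
ROI edges are tapered with raised cosines of width `transition_width`
so that H − offset is compactly supported; the stored response equals
offset + w(ν)·(H − offset).

**Time-domain difference** (`td_difference`). S_sam − S_ref with the
temporal filter evaluated relative to the reference envelope peak.
Sensitive and simple, but the result depends on the excitation pulse.

**TDF** (`tdf`). Offset subtraction → irfft to H(t) → temporal weights
→ rfft → offset restoration. For a Heaviside filter all t < cutoff
*including all negative times* is zeroed — the hard cut makes the
retained noise fraction unambiguous; the Butterworth profile
1/(1+(cutoff/t)^(2·order)) (order 4 by default; the realization is a
time-domain weight profile, not an IIR filter) is available where the
ringing of the hard cut is unwanted, and `output="magnitude"` gives
the fringe-free magnitude variant. The cutoff is snapped to the
conjugate time grid and recorded in the output metadata; a cutoff
beyond the unambiguous window 1/(c·Δν) is an error. The whole map is
linear in H for fixed filter and ROI (property-tested to 10⁻¹⁰).

Offset handling is a genuinely open design point: we subtract and
restore a *scalar* (the ROI mean), not a low-order baseline, because
in the weak-response limit H ≈ 1 + small and the mean estimates the 1;
a baseline variant would trade robustness for shape fidelity.
`SampleResponse.from_spectrum` embeds arbitrary uniform-grid spectra
(FTIR measurements, database entries) onto a zero-origin grid so the
identical filter can be applied to conventional IR data.

## Analyses

**SNR scan** (`snr_scan`). Per cutoff: signal strength = maximum
deviation from the offset of the replicate-*mean* filtered analyte
spectrum (the mean suppresses the noise bias a per-replicate maximum
would add at small cutoffs); noise level = per-wavenumber standard
deviation across pure-solvent replicates, frequency-averaged over the
band (default 1000–1400 cm⁻¹), after removing each replicate's ROI
mean. That offset correction mirrors what every downstream consumer
(retrieval, identification — both mean-center) effectively sees;
without it the scalar offset fluctuation, which no time filter can
touch, floors the noise curve and hides the crossover knee. Ties in
the SNR argmax break toward the smaller cutoff (preserving more
signal); a zero noise level flags the scan degenerate.

**Noise crossover** (`noise_crossover`). The first delay behind the
envelope peak at which mult_rms·env(t) ≤ add_rms — the cutoff a noise
analysis of the instrument would suggest.

**Quantification** (`retrieve_concentration`). c_est = c_ref·⟨m,r⟩/⟨r,r⟩
after mean-centering both spectra over the ROI: the one-parameter
least-squares fit of the reference fingerprint. The normalization by
⟨r,r⟩ is required for c_est to carry concentration units; retrieval
operates on magnitude spectra by default (complex spectra can be fed
in where phase is trustworthy). `path_calibration` returns the
analogous projection of a measured standard on its expected spectrum;
dividing a day's spectra by it compensates cuvette path-length
differences.

**Identification** (`cosine_identify`). Query interpolated to the
library grid (out-of-range points dropped from both sides), identical
TDF applied to query and entries when requested, mean-centering, then
cosine similarity, ranked descending. Similarity is invariant to
positive rescaling of either side.

## Study conditions of the bundled experiments

`frs.experiments` fixes one set of conditions, chosen to put the
simulator in the operating regime of a field-resolving spectrometer
measuring aqueous metabolite solutions:

- pulse: center 1200 cm⁻¹, FWHM 700 cm⁻¹, GDD 2000 fs² — a broadband
  fingerprint-region pulse whose envelope extends over a few hundred
  fs, standing in for the temporal pedestal of a real instrument;
- analyte: two bands (1100 and 1310 cm⁻¹, FWHM 22/26 cm⁻¹) with a 10%
  transmission dip at 1000 µg/mL — the weak-response regime of a
  sulfone-type metabolite;
- noise: 1% RMS multiplicative, additive floor 10⁻⁴ of the envelope
  peak, giving a multiplicative/additive crossover a few hundred fs
  behind the pulse;
- ROI 900–1500 cm⁻¹ with 250 cm⁻¹ transitions; noise band
  1000–1400 cm⁻¹; cutoff grid 0–800 fs in 50 fs steps (n = 4096
  samples at dt = 2 fs, i.e. an 8.2 ps window resolving ~4 cm⁻¹).

The retrieval experiment runs 10 days at 5% pulse jitter (plus 500 fs²
GDD jitter), 5 replicates each of 100 and 1000 µg/mL, and quantifies
the 100 µg/mL samples against the last day's 1000 µg/mL mean
fingerprint — so pulse dependence of a route appears as day-to-day
bias. The identification experiment measures five synthetic solvent
fingerprints (overlapping bands in 950–1450 cm⁻¹) at a query
concentration of 40, matched against a noise-free library computed at
100× that concentration; the query concentration is set so the
unfiltered route sits well below 80% correct while TDF reaches 100% —
the regime in which filtering matters.

## What the synthetic tests do and do not show

The simulator reproduces the *structure* of FRS data — causal weak
responses, envelope-confined multiplicative noise, drifting pulses,
cuvette echoes — but not everything a real instrument adds: water's
own absorption background, detector nonlinearity, delay-axis jitter
and drift within a scan, shot-noise statistics, or multi-reflection
etalons. Passing tests therefore demonstrate that the processing
chain is correct and that the claimed mechanisms (noise localization,
excitation independence, echo suppression) operate as described — not
that any particular SNR number transfers to a given spectrometer.
Quantities tied to the specific instrument datasets of the literature
(e.g. a 650 fs optimal cutoff, a 48%→100% identification gain) emerge
here with the same ordering and mechanism but at values set by the
simulation conditions above.

## Numerical details

- Grids must be uniform to 10⁻⁹ relative; time grids ascending.
- The Nyquist guard for pulse synthesis requires ν₀ + 1.5·FWHM below
  1/(2·c·dt).
- Division regularization: `floor_frac` = 10⁻³ of the reference
  spectral peak; masked points carry the offset.
- Cutoffs are snapped to the nearest conjugate-time sample; the
  snapped value is reported.
- `from_spectrum` pads the embedded grid to a power-of-two conjugate
  length; out-of-range values equal the offset, so they vanish from
  the filtered deviation.
- All randomness flows through `numpy.random.default_rng` seeded by
  explicit seed arithmetic; identical inputs give bit-identical
  outputs on one platform.
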