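# Methods

## Scope and model

pamkit converts raw WAV recordings from passive acoustic monitoring (PAM)
systems into absolute sound-pressure measurements and derives the standard
acoustic-habitat metrics from them. The underlying model is the linear
acquisition chain of a typical PAM instrument: a transducer (microphone or
hydrophone) with sensitivity *M* (dB re 1 V/µPa) converts pressure to
voltage, a pre-amplifier adds gain *G* (dB), and an ADC maps its zero-to-peak
full-scale input voltage *V* onto the audio file's full-scale code. The
combined (end-to-end) system sensitivity is

    S = M + G − 20·log10(V)   [dB re full-scale per µPa]

and calibration inverts the chain sample by sample:

    p[n] = (x[n] − x̄) · 10^(−S/20)   [µPa]

for normalized samples x ∈ [−1, 1]. *S* can instead be measured directly by
injecting a known reference signal at the transducer (pistonphone-style
end-to-end calibration) and supplied as a single number. Both air and water
domains use µPa as the working unit; only the reference pressure for dB
conversion differs (air 20 µPa, water 1 µPa).

Assumptions: the chain is linear and time-invariant up to clipping; DC
offsets are acquisition artefacts (removed per analysis segment before
scaling); frequency dependence of the chain is a separable correction curve
applied to spectrum levels, not a filter applied to the waveform.

## Metrics

All levels are decibels re p_ref (pressures) or re p_ref²/Hz (densities) or
re p_ref²·s (exposures).

- **PSD** — single-sided Welch estimate: window-compensated periodograms of
  length-N segments, divided by (fs·Σw²), doubled except at DC and Nyquist,
  averaged arithmetically in power within each output interval. Averaging K
  segments leaves the expectation unchanged and scales the estimator
  variance by 1/K (the averaged periodogram is χ²₂ᴷ/2K-distributed around
  the true density for Gaussian input).
- **Broadband SPL** — PSD power integrated over [f_lo, f_hi] per time step;
  with the full band this equals the time-domain RMS level (Parseval, exact
  for the rectangular window).
- **1/3-octave levels (TOL)** — base-ten ladder with exact centers
  fc(n) = 10^(n/10) Hz and edges fc·10^(±1/20); a PSD bin belongs to the
  band containing its center (no bin splitting). Bands narrower than one
  PSD bin and bands whose upper edge exceeds Nyquist are excluded, leaving
  a contiguous ladder labelled with preferred-number nominal centers
  (…, 63, 125, … Hz).
- **SEL** — 10·log10(Σp²Δt / (p_ref²·1 s)); for a stationary signal of
  level L over T seconds, SEL = L + 10·log10(T).
- **Level statistics** — the RMS (power-mean, L_eq-style) average
  10·log10(mean 10^(L/10)); median (L_50); histogram mode; percentiles with
  linear interpolation of order statistics; exceedance accessor L_x =
  (100−x)th percentile.
- **SPD** — per-frequency normalized histogram of dB levels (probability
  per dB); each frequency row integrates to exactly 1.
- **Impulse metrics** — zero-to-peak and peak-to-peak levels on the
  pressure waveform; pulse SEL (full window and restricted to the
  envelope); the 90% energy envelope between the 5% and 95% crossings of
  cumulative energy, whose length τ90 is the pulse duration; SNR = RMS
  level difference between pulse and noise windows, valid when ≥ 10 dB.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| window | Hann | standard Welch practice; strong sidelobe suppression |
| overlap | 0.5 | standard for Hann; dense overlaps (0.99) supported for impulsive scenes |
| scaling | density (p_ref²/Hz) | the 1-Hz-equivalent convention for PSD |
| normalization divisor | 2^(bits−1) | symmetric: the most negative code maps to exactly −1.0 |
| clip threshold | \|x\| ≥ 0.99 | catches limiter-rounded saturation, not just exact full scale |
| SPD / mode bin width | 1 dB | resolves modal structure at typical dynamic ranges without empty-bin noise |
| quantile method | linear order-statistic interpolation | the most common default, stated for reproducibility |
| multimodality flag | second histogram peak within 3 dB of the maximum density | warns when a single mode is misleading |
| SNR validity threshold | 10 dB | the accepted floor for trustworthy pulse amplitude measurements |
| envelope crossings | first sample at-or-above threshold | bias below one sample period; no sub-sample interpolation |
| frequency-response interpolation | linear in dB vs log-frequency | matches log-frequency datasheet tabulation |
| reference pressures | air 20 µPa, water 1 µPa | field conventions |

## Numerical choices

- Periodograms are computed with `scipy.signal.spectrogram` (mode `psd`,
  detrending disabled); DC removal happens once, at calibration, so that
  Parseval holds exactly for the rectangular window.
- Welch averaging groups segments by their start time into
  `average_seconds` intervals, so 60 s of 1-s segments at zero overlap
  forms exactly one 60-segment column.
- Band-edge assignment by bin center bounds the TOL reassembly error by
  one bin width; the TOL-sum-vs-broadband agreement is tested at 0.5 dB.
- Histogram mode ties break toward the lower level (argmax takes the first
  bin).
- Cumulative-energy crossings use `searchsorted` (first at-or-above);
  amplitude scaling can move a crossing by a sample or two when increments
  near the threshold are tiny (e.g. at the zero crossings of a gated
  sine) — the energy inside the envelope is unaffected to first order.
- Degenerate inputs fail loudly: empty level sets, all-zero pulse windows,
  single-column SPDs, overlapping SNR windows, bands without PSD bins.

## The synthetic generator

`pamkit.synth` produces the package's own test bed: tones that achieve a
requested SPL exactly (amplitude √2·p_ref·10^(SPL/20)), white noise with a
requested flat density (variance 10^(D/10)·p_ref²·fs/2), pink noise shaped
in the frequency domain to fall 3 dB per octave through a stated reference
frequency, decaying-sinusoid impulses scaled to an exact zero-to-peak
level, white-noise diel cycles with a daytime level offset, and mixtures.
`simulate_recorder` runs the forward chain — sensitivity scaling, optional
flat Gaussian self-noise, clipping at full scale, quantization — so the
calibration inverse can be tested end to end; generation is deterministic
given (parameters, seed).

What the generator does *not* emulate: propagation loss, flow noise,
shaped (non-flat) instrument noise floors, non-stationary biotic choruses,
or any real species' signals. Passing tests therefore demonstrate that the
signal-processing chain is correct and self-consistent on signals with
known ground truth, not that any particular habitat is well characterized
by these metrics.

The SPD noise-floor scenario is built as a low-pass-filtered pink "habitat"
whose block-wise level wanders over tens of dB (σ = 8 dB), recorded over a
flat self-noise floor: at floor-dominated high frequencies the lowest
populated level bins converge onto the mode, while signal-dominated low
frequencies keep a long lower tail — the classic signature by which an SPD
exposes an instrument's dynamic-range limit.

## Problem sizes

Test and reproduction runs use scenes of seconds to a couple of minutes at
1–48 kHz sampling (10⁵–10⁶ samples): long enough for ≥100 Welch averages
where bias is measured (the ±0.2 dB check), 60 SPD time bins, and 9+
high-frequency 1/3-octave bands for the 1-dB-step check, while the whole
suite completes in seconds. Statistical tolerances (0.1 dB round trip,
0.2 dB PSD bias, 0.5 dB band reassembly, factor-2 bands on variance
ratios) follow from quantization limits, χ² sampling spread at the chosen
number of averages, and the bin-assignment bound, respectively.

## Design choices where the design was open

- One pressure unit (µPa) in both domains, with the domain entering only
  through p_ref at dB conversion: one code path, no unit branching.
- 1/3-octave bands via PSD summation rather than time-domain filter banks:
  matches the PSD-first pipeline; ANSI-class filter banks are out of scope.
- Base-ten band numbering (fc = 10^(n/10)) rather than base-two; both
  yield the 63/125 Hz nominal labels, base-ten keeps edges exact decimals.
- Clipped segments are flagged in metadata, never dropped: exclusion
  policy belongs to the analyst.
- No background-energy subtraction before the envelope computation; the
  pulse windows are caller-supplied (automated detection is out of scope).
- Filename timestamps use strptime patterns; hour-of-day aggregation uses
  the recording's local clock with no daylight-saving handling.
- Partial final file segments are emitted by the streaming reader but the
  Welch engine only uses complete analysis segments, avoiding biased
  averages from short windows.

## Known limitations

- 24-bit WAV is read-only (written fixtures are 16-bit PCM or float-32).
- Frequency-dependent calibration corrects spectrum levels; it does not
  deconvolve the waveform, so impulse peak metrics assume a chain that is
  flat across the pulse's band (a warning is issued when the supplied
  response curve varies by more than 3 dB over the pulse's −10 dB spectral
  extent).
- The Welch engine loads one file's samples at a time; month-scale
  archives are handled per file, not by out-of-core streaming within a
  file.
- Self-noise in the simulator is spectrally flat; real instrument floors
  are shaped.
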