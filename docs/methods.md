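# Methods

This note documents the models and estimators implemented in `spikegamma`,
the choices made where the analysis conventions of the field leave room,
and what the synthetic-data generator does and does not emulate.

## The analysis problem

In hippocampal slices, bath-applied kainate (~100 nM) induces a persistent
gamma-band network oscillation recorded as a local field potential (LFP)
in stratum pyramidale of CA3, while simultaneous whole-cell recordings
capture the firing of individual fast-spiking interneurons (FSN) or
pyramidal cells (PC). Three families of quantities are derived:

1. **Spectral metrics** of the LFP — gamma power, spectral peak, and
   rhythm regularity (frequency variance);
2. **Spike–gamma coupling** — how tightly a neuron's action potentials
   lock to a preferred phase of the ongoing gamma cycle;
3. **Synaptic event statistics** — amplitude and frequency of
   postsynaptic currents (EPSC/IPSC) in voltage clamp.

Per-cell metrics are then compared across a genotype × age factorial
design. Signals are assumed acquired at 5 kHz after 1 kHz low-pass
conditioning; all defaults below are written for that regime.

## Spectral analysis

Power spectra are segment-averaged one-sided periodograms (Welch) with
density scaling, segment length 8192 samples (~0.61 Hz bins at 5 kHz),
computed on the last 60 s of the recording (the whole trace if shorter).
The averaging details beyond the segment length are conventions of this
package: a Hann taper with 50% overlap, chosen for variance reduction with
standard leakage behavior; `SpectralConfig(window="boxcar",
overlap_fraction=0)` reproduces plain disjoint-block FFT averaging.
Segments are mean-detrended individually; without this, DC leakage
contaminates the 20 Hz band edge at this bin width.

Gamma power is the trapezoidal integral of the PSD over 20–80 Hz (band
edges are interpolated, so a flat spectrum integrates exactly). The
estimator satisfies Parseval consistency — the integral over
[0, Nyquist] matches the sample variance of the detrended trace to within
a few percent on tones and white noise — which the tests assert at 5%.

**Frequency variance** is formalized here as the power-weighted variance
of frequency within the gamma band,
`Var = ∫ p(f) (f − f̄)² df / ∫ p(f) df`, i.e. the second central moment of
the in-band PSD treated as a distribution over frequency. A flat band
spectrum over [20, 80] Hz gives the uniform-distribution value
60²/12 = 300 Hz²; a pure tone gives a leakage-limited value below 1 Hz².
An alternative reading — variance of per-segment spectral peak
frequencies — is available behind
`SpectralConfig(freq_variance_mode="peak_per_segment")`; the weighted
moment is the default because it uses all in-band power rather than only
the argmax and is stable for short recordings.

Group normalization divides each value by the **mean** of the age-matched
control group (the control group itself normalizes to mean exactly 1).

## Spike–gamma coupling

The chain is: zero-phase band-pass → Hilbert phase → amplitude-threshold
spike detection → phase lookup → circular statistics.

* **Filtering.** Butterworth band-pass 20–40 Hz applied forward and
  backward (`sosfiltfilt`), so the output has no group delay and the
  effective magnitude response is the squared Butterworth response. Order
  4 per pass by default (exposed in `FilterConfig`). A 30 Hz tone passes
  with zero lag; 5 Hz and DC inputs attenuate exactly as the squared
  analytic magnitude predicts.
* **Phase convention.** The instantaneous phase is the angle of the
  analytic signal of the filtered LFP: a local maximum of the recorded
  signal maps to phase 0, a trough to ±π. Extracellular polarity is
  ambiguous in general; `FilterConfig(invert_lfp=True)` flips it, which
  shifts phase angles by π and never changes vector lengths.
* **Spike detection.** One spike per contiguous supra-threshold epoch
  (default threshold 0 mV), timestamped at the epoch maximum; epochs
  separated by less than `min_interval` (2 ms) merge, so a noisy crest
  counts once.
* **Phase lookup** is nearest-sample without interpolation: at 5 kHz
  against a ~30 Hz rhythm the per-sample phase step is ≈0.038 rad,
  negligible against biological scatter. Spikes within three low-cut
  cycles (150 ms) of either trace edge are dropped to avoid filter
  settling transients.
* **Circular statistics.** Each spike contributes a unit vector at its
  phase; the mean resultant vector gives the vector length
  r = |Σe^{iθ}|/n ∈ [0, 1] and the preferred angle. The Rayleigh test
  (Z = nr², p from the standard finite-n corrected series) gates
  inclusion at α = 0.05; fewer than `n_min = 10` spikes yields an
  excluded result carrying the reason rather than an exception, so
  selection is always explicit and auditable. Group-level preferred
  angles are circular means of per-cell angles (arithmetic averaging is
  ill-defined near ±π).

Validation is by parameter recovery: simulated spike trains with von
Mises phase preference of concentration κ should recover
r → I₁(κ)/I₀(κ). Through the full chain (simulated LFP, filtering,
Hilbert phase) the absolute bias is below 0.02 across κ ∈ [0.5, 8] at
500 spikes per cell, and preferred angles recover within 0.01 rad —
comfortably inside the 0.05 / 0.15 rad bands the tests assert.

## Synaptic event detection

The template is the unit-peak average of at least 20 onset-aligned
representative event snippets (fewer is an error; this mirrors standard
practice of refusing under-specified templates). Detection slides the
template over the trace and fits, at each offset, an optimally scaled and
offset copy by closed-form least squares; the detection statistic is the
fitted scale divided by the residual SD of the fit — the scaled-template
criterion standard in patch-clamp software. The default threshold is 3.5
(the literature's usual operating point; no published value constrains it
here).

Candidates are accepted greedily in order of criterion value; each
accepted event's fitted template is subtracted before re-scanning, which
removes the elevated criterion along the event's decay and lets partially
overlapping events (separated by at least one template rise time) both be
recovered. Deeper overlap resolution (joint fitting) is out of scope.
Amplitude is the fitted scale, signed by polarity. The statistic is
invariant to trace rescaling, and detection commutes with polarity
reversal.

At the tested operating point (fixed-amplitude events at SNR 5, criterion
3.5) recall is ≥95% with amplitude RMSE under 10%; on pure noise the
false-positive rate is far below 0.1 events/s because the criterion's
null SD shrinks with the template's effective length. With realistically
dispersed amplitudes (CV ≈ 0.3) recall is necessarily lower — events
below ~threshold × noise SD are undetectable by construction — which is a
property of the statistic, not of this implementation.

## Group statistics

For each metric the pipeline is: per-group outlier exclusion → normality
screen → two-way ANOVA → per-age control-vs-disease contrasts with
Holm–Šidák adjustment.

* **Outliers.** The ROUT procedure (Q = 1%) is defined for robust
  regression; for single-group descriptive data it degenerates to a
  robust location fit. Implemented as: residuals from the group median,
  scaled by the normalized MAD (×1.4826), converted to two-sided t tail
  probabilities and thresholded with a Benjamini–Hochberg step-up at rate
  Q. On clean Gaussian data fewer than 2% of points are flagged; a single
  gross outlier is flagged reliably. Groups under 5 values, or with zero
  spread, are left untouched. Whether to exclude per group or on the
  pooled metric is config-switchable; per group is the default.
* **Normality** is screened per genotype × age group with Shapiro–Wilk
  and reported only — the parametric pipeline is applied throughout, so
  the screen never silently switches tests.
* **ANOVA** uses Type-II sums of squares (cell n's differ throughout
  realistic cohorts; Type II is the standard choice for unbalanced
  factorial comparisons when the interaction is not the primary target).
  On balanced designs it agrees with textbook sums-of-squares formulas to
  1e-10, and its null rejection rate calibrates at α.
* **Contrasts.** Per age, a two-sided t statistic on the difference of
  genotype means over the pooled ANOVA residual variance; the Holm–Šidák
  step-down family is the set of per-age contrasts for one metric (3–4
  comparisons), matching per-figure reporting practice. Adjusted p-values
  are never below raw ones and are monotone in them.

Cells, not animals, are the default unit of analysis; the tables carry
both `cell_id` and `animal_id` so either can be selected. Animal-level
nesting (mixed models) is a known limitation, not implemented.

## Synthetic data generator

The generator provides ground truth for every estimator; its defaults are
the study conditions the analysis expects.

* **LFP**: carrier A(t)·cos(φ(t)) with φ̇ = 2π(f₀ + OU jitter). The
  Ornstein–Uhlenbeck frequency wander (SD 1.5 Hz, correlation time
  0.5 s) and a matching fractional amplitude envelope (SD 0.2) emulate
  the cycle-to-cycle irregularity of kainate-induced gamma around a 30 Hz
  center; the background is 1/f^β Gaussian noise (β = 1, band 0.5
  Hz–Nyquist) produced by spectral shaping. Defaults: 60 s at 5 kHz,
  carrier 0.05 mV, noise 0.02 mV RMS — amplitudes in the range typical of
  submerged-slice field recordings. Because the carrier phase is
  constructed, the true phase track is returned alongside the trace and
  any phase estimator can be scored against it.
* **Spikes**: an inhomogeneous Poisson process with intensity ∝
  exp(κ·cos(φ(t) − μ)) realized by thinning at the peak intensity, which
  makes the spike-phase distribution von Mises (Kolmogorov–Smirnov
  agreement at n = 2000 is asserted in the tests). A refractory dead time
  (2 ms) is enforced afterwards; because concentrated firing loses far
  more than rate×τ to dead time, the base rate is renormalized by solving
  the dead-time fixed-point equation on the actual phase track, keeping
  the realized mean rate within ~2% of target across the study's κ range.
  von Mises is adopted as the standard circular model of phase scatter,
  not as an empirical claim about FSN/PC.
* **Synaptic traces**: Poisson event times, gamma-distributed amplitudes
  (mean 30 pA, CV 0.3), difference-of-exponentials kernel with unit peak
  (rise 0.8 ms, decay 6 ms — fast EPSC-like kinetics), Gaussian recording
  noise (2 pA default). Events are kept fully inside the trace so the
  ground-truth list is exact; in the noiseless case the trace minus the
  reconstructed event sum is identically zero.
* **Cohorts**: a genotype × age design with per-group multipliers on
  carrier amplitude, κ, firing rate, event amplitude and event rate.
  Per-cell seeds derive from `SeedSequence(master_seed, spawn_key=(group,
  cell))`, so cohorts are bit-reproducible yet cells are independent.
  Spike trains are rendered into current-clamp-like voltage traces
  (Gaussian AP waveforms on a −60 mV baseline) so the spike detector is
  exercised end-to-end.

What the generator does **not** emulate: conductance-based network
dynamics (no PING mechanism, no E/I loop), spike-waveform diversity,
electrode drift and line noise, bursting statistics, and any dependence
of LFP amplitude on the recorded cell. Passing tests therefore
demonstrate estimator correctness under the stated statistical structure,
not robustness to every artifact of real recordings.

## Numerical choices and degenerate inputs

* Phases live in (−π, π]; wrapping maps −π to +π.
* A constant trace has undefined phase (error); an all-zero band has
  undefined frequency variance (error naming the band).
* Welch bins are interpolated at band edges before integration, making
  flat-spectrum integrals exact and band power monotone in band width.
* The template criterion treats a zero-residual window as a perfect match
  (infinite criterion); fitted scales at float-dust level (≤1e-9 of the
  trace peak) are rejected as subtraction residue. Both rules only matter
  for noiseless synthetic inputs.
* Problem sizes in the test suite (20 s recordings, 10–50 Monte Carlo
  seeds, 2000-draw calibrations) are chosen so the whole suite runs in a
  few minutes on one CPU while keeping Monte Carlo standard errors well
  inside the asserted bands.

## I/O

The archival format is CSV (`time_s,value`, full float precision) with a
JSON sidecar for sampling rate, units and label; write→read round-trips
bit-identically. Proprietary acquisition formats are out of scope for
this package; converting vendor files to CSV upstream keeps the analysis
surface format-agnostic.
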