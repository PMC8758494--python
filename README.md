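# spikegamma

Quantification of hippocampal gamma oscillations and neuronal
spike–gamma coupling for slice electrophysiology.

In hippocampal area CA3, bath-applied kainate induces a persistent
gamma-band (~25–35 Hz) network oscillation. Whether individual neurons —
fast-spiking interneurons (FSN) and pyramidal cells (PC) — fire at a
consistent phase of that rhythm is a sensitive functional readout: loss
of spike–gamma coupling precedes gross network breakdown in amyloid
pathology models. `spikegamma` implements the full analysis chain for
such experiments, plus a synthetic-data generator with exact ground truth
so every estimator is validated by parameter recovery.

The package is for electrophysiologists and computational neuroscientists
analyzing concomitant LFP + whole-cell recordings (or simulating them).

## What it computes

**Spectral metrics** (`spikegamma.spectral`). Segment-averaged power
spectra (8192-point segments over 60 s of LFP), gamma power by
integrating the PSD over 20–80 Hz, the spectral peak, and rhythm
regularity as the power-weighted frequency variance within the band;
values normalized to the age-matched control group mean.

**Spike–gamma coupling** (`spikegamma.coupling`). The LFP is band-pass
filtered 20–40 Hz with a zero-phase Butterworth filter (applied in both
directions), instantaneous phase is taken from the Hilbert transform
(cycle peak = 0, trough = ±π), action potentials are detected by
amplitude threshold, and each spike contributes a unit vector at its
gamma phase. The mean resultant vector yields

- **vector length** `r = |Σ e^{iθ}| / n` ∈ [0, 1] — how recurrent firing
  is at the preferred phase (1 = perfect locking, 0 = uniform), and
- **phase angle** `arg(Σ e^{iθ})` — the preferred phase of firing,

with the Rayleigh test (`Z = n r²`) gating inclusion at p < 0.05.

**Synaptic events** (`spikegamma.events`). EPSC/IPSC detection by
scaled-template matching: a unit-peak template averaged from ≥20
representative events slides along the voltage-clamp trace; the criterion
is the fitted scale over the residual SD (threshold 3.5), events are
peeled off greedily so partial overlaps resolve; amplitude and frequency
statistics follow.

**Group comparisons** (`spikegamma.group_stats`). Per-group ROUT (Q = 1%)
outlier exclusion, Shapiro–Wilk normality screen (reported), two-way
ANOVA (genotype × age, Type-II SS), and per-age control-vs-disease
contrasts with Holm–Šidák adjustment.

**Synthetic data** (`spikegamma.synth`). Gamma LFP with known
instantaneous phase (OU frequency jitter on a 1/f background), von
Mises phase-coupled spike trains of known concentration κ (so the
recovered vector length can be checked against the analytic
I₁(κ)/I₀(κ)), Poisson synaptic-event traces, and full genotype × age
cohorts with configurable effect multipliers — all bit-reproducible from
a seed.

## Worked example

```python
import spikegamma as sg

# a 30 s gamma LFP and a strongly coupled cell (kappa = 4, mu = 0.3 rad)
lfp, phase = sg.simulate_gamma_lfp(sg.GammaLfpParams(duration=30.0, seed=42))
spikes = sg.simulate_coupled_spikes(
    phase, sg.CouplingParams(mean_rate=15, kappa=4, mu=0.3, seed=1))
cell = sg.render_spike_trace(spikes, lfp.sampling_rate, seed=2)

gm = sg.gamma_metrics(lfp)
print(f"gamma power: {gm.band_power:.6f} mV^2")
print(f"peak frequency: {gm.peak_frequency:.2f} Hz")
print(f"frequency variance: {gm.frequency_variance:.2f} Hz^2")
print(sg.analyze_cell(lfp, cell).summary())
```

prints

```
gamma power: 0.001485 mV^2
peak frequency: 29.30 Hz
frequency variance: 24.20 Hz^2
CouplingResult: n=423, r=0.855, angle=+0.317 rad, Rayleigh p=6.72e-132, rate=14.10 Hz, included=True
```

The spectral peak sits at the 30 Hz carrier (to within one 0.61 Hz bin);
the frequency variance reflects the simulated rhythm jitter. The cell's
vector length 0.855 recovers the analytic von Mises value
I₁(4)/I₀(4) ≈ 0.864, the preferred angle recovers μ = 0.3 rad, and the
Rayleigh test confirms phase locking, so the cell is included.

A full study-shaped run — simulate a genotype × age cohort, analyze every
cell, and compare groups — is one call (`spikegamma.run`) or one command:

```bash
spikegamma run --config examples/demo_run.yaml --out scratch/demo
```

The report directory contains per-cell metrics (`cells.csv`), per-metric
cohort tables and group summaries, the ANOVA + Holm–Šidák comparisons
(`comparisons.json`), and an inclusion ledger naming every excluded cell
and why. The other subcommands (`simulate`, `spectral`, `couple`,
`events`, `compare`) expose each stage on single files.

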