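"""Synthetic electrophysiology with known ground truth.

Emulates the statistical structure of kainate-induced gamma recordings in
hippocampal slices so every analysis stage can be validated by parameter
recovery:

* an LFP whose gamma carrier is ``A(t) * cos(phi(t))`` with the
  instantaneous frequency wandering around a 25-35 Hz center as an
  Ornstein-Uhlenbeck process, on a 1/f^beta noise background — and whose
  true phase track is returned alongside the trace;
* spike trains whose gamma-phase distribution is von Mises with known
  concentration ``kappa`` and preferred angle ``mu``, produced by thinning
  a Poisson process against the true phase track;
* voltage-clamp traces containing double-exponential postsynaptic-current
  events at Poisson times;
* full genotype x age cohorts with per-group multipliers on the coupling,
  power and synaptic parameters, seeded reproducibly per cell.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal, special

from .core import ParameterError, PhaseSeries, SpikeTrain, TimeSeries, wrap_phase

__all__ = [
    "GammaLfpParams",
    "CouplingParams",
    "SynapticTraceParams",
    "CohortDesign",
    "CellRecord",
    "simulate_gamma_lfp",
    "simulate_coupled_spikes",
    "simulate_synaptic_trace",
    "simulate_cohort",
    "render_spike_trace",
    "psc_kernel",
]


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class GammaLfpParams:
    """Gamma-band LFP generator settings.

    ``carrier_freq`` is the rhythm center (Hz), ``freq_jitter_sd`` the
    stationary SD of a slow Ornstein-Uhlenbeck wander of the instantaneous
    frequency, ``amp_jitter_sd`` the fractional SD of a matching amplitude
    envelope, and ``noise_exponent`` the beta of the 1/f^beta background.
    """

    duration: float = 60.0
    sampling_rate: float = 5000.0
    carrier_freq: float = 30.0
    carrier_amp: float = 0.05
    amp_jitter_sd: float = 0.2
    freq_jitter_sd: float = 1.5
    jitter_tau: float = 0.5
    noise_exponent: float = 1.0
    noise_amp: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")
        if self.sampling_rate < 4 * self.carrier_freq:
            raise ParameterError("sampling_rate must be >= 4 x carrier_freq")
        if min(self.amp_jitter_sd, self.freq_jitter_sd, self.noise_amp) < 0:
            raise ParameterError("jitter SDs and noise_amp must be >= 0")
        if self.carrier_amp < 0:
            raise ParameterError("carrier_amp must be >= 0")
        if not self.jitter_tau > 0:
            raise ParameterError("jitter_tau must be > 0")


@dataclass(frozen=True)
class CouplingParams:
    """Phase-coupled spike generator settings (von Mises modulation)."""

    mean_rate: float = 15.0
    kappa: float = 4.0
    mu: float = 0.0
    refractory: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rate < 0:
            raise ParameterError("mean_rate must be >= 0")
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        if not (-np.pi < self.mu <= np.pi):
            raise ParameterError("mu must lie in (-pi, pi]")
        if self.refractory < 0:
            raise ParameterError("refractory must be >= 0")


@dataclass(frozen=True)
class SynapticTraceParams:
    """Voltage-clamp trace generator: Poisson events, difference-of-
    exponentials kernel with unit peak, Gaussian recording noise."""

    event_rate: float = 2.0
    amp_mean: float = 30.0
    amp_cv: float = 0.3
    rise_tau: float = 0.0008
    decay_tau: float = 0.006
    noise_sd: float = 2.0
    duration: float = 60.0
    sampling_rate: float = 5000.0
    polarity: str = "inward"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ParameterError("must have decay_tau > rise_tau > 0")
        if not self.amp_mean > 0:
            raise ParameterError("amp_mean must be > 0")
        if self.event_rate < 0 or self.noise_sd < 0 or self.amp_cv < 0:
            raise ParameterError("event_rate, noise_sd, amp_cv must be >= 0")
        if self.polarity not in ("inward", "outward"):
            raise ParameterError("polarity must be 'inward' or 'outward'")
        if not self.duration > 0 or not self.sampling_rate > 0:
            raise ParameterError("duration and sampling_rate must be > 0")


#: parameter names an effect multiplier may target
EFFECT_KEYS = ("carrier_amp", "kappa", "mean_rate", "amp_mean", "event_rate")


@dataclass(frozen=True)
class CohortDesign:
    """A genotype x age factorial design with per-group effect multipliers.

    ``groups`` lists ``(genotype, age, n_cells)``; ``effects`` maps
    ``(genotype, age)`` to multipliers on any of ``carrier_amp``, ``kappa``,
    ``mean_rate``, ``amp_mean``, ``event_rate`` (unlisted groups and keys
    default to 1.0).
    """

    groups: Sequence[tuple[str, str, int]]
    effects: Mapping[tuple[str, str], Mapping[str, float]] = field(default_factory=dict)
    lfp: GammaLfpParams = field(default_factory=GammaLfpParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    synaptic: SynapticTraceParams = field(default_factory=SynapticTraceParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        labels = [(g, a) for g, a, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ParameterError(f"duplicate group labels in design: {labels}")
        if not labels:
            raise ParameterError("design must contain at least one group")
        for g, a, n in self.groups:
            if n < 1:
                raise ParameterError(f"group {(g, a)}: n_cells must be >= 1")
        for key, mults in self.effects.items():
            if key not in labels:
                raise ParameterError(f"effect for unknown group {key}")
            for name, m in mults.items():
                if name not in EFFECT_KEYS:
                    raise ParameterError(f"unknown effect key {name!r}")
                if not m > 0:
                    raise ParameterError(f"multiplier for {name} must be > 0")


# ---------------------------------------------------------------------------
# generators


def _shaped_noise(n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent Gaussian noise via spectral shaping, band 0.5 Hz-Nyquist."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    band = freqs >= 0.5
    gain[band] = freqs[band] ** (-exponent / 2.0)
    noise = np.fft.irfft(spec * gain, n=n)
    scale = noise.std()
    if scale == 0:
        return np.zeros(n)
    return noise * (rms / scale)


def _ou_path(n: int, dt: float, tau: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with SD `sd`, correlation time `tau`."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    eps = np.empty(n)
    eps[0] = sd * rng.standard_normal()
    eps[1:] = innov_sd * rng.standard_normal(n - 1)
    # AR(1) recursion x[i] = a x[i-1] + eps[i], vectorized
    x = signal.lfilter([1.0], [1.0, -a], eps)
    return x


def simulate_gamma_lfp(params: GammaLfpParams) -> tuple[TimeSeries, PhaseSeries]:
    """Simulate a gamma-band LFP and its ground-truth carrier phase.

    The carrier is ``A(t) cos(phi(t))`` with
    ``dphi/dt = 2 pi (f0 + OU jitter)``, so the true phase (peak = 0,
    trough = +/-pi) is known at every sample and can score any phase
    estimator. Background is 1/f^beta noise.

    Returns
    -------
    (TimeSeries, PhaseSeries)
        The trace (mV) and the wrapped true phase of the carrier.
    """
    fs, n = params.sampling_rate, int(round(params.duration * params.sampling_rate))
    dt = 1.0 / fs
    rng = np.random.default_rng(params.seed)
    freq = params.carrier_freq + _ou_path(n, dt, params.jitter_tau, params.freq_jitter_sd, rng)
    # phase accrued up to (not including) each sample; sample 0 sits at the peak
    phi = 2.0 * np.pi * np.concatenate(([0.0], np.cumsum(freq[:-1]) * dt))
    envelope = params.carrier_amp * np.clip(
        1.0 + _ou_path(n, dt, params.jitter_tau, params.amp_jitter_sd, rng), 0.0, None
    )
    carrier = envelope * np.cos(phi)
    noise = _shaped_noise(n, fs, params.noise_exponent, params.noise_amp, rng)
    ts = TimeSeries(samples=carrier + noise, sampling_rate=fs, units="mV", label="lfp")
    phase = PhaseSeries(phases=wrap_phase(phi), sampling_rate=fs)
    return ts, phase


def simulate_coupled_spikes(phase: PhaseSeries, params: CouplingParams) -> SpikeTrain:
    """Spike train phase-locked to a gamma phase track.

    An inhomogeneous Poisson process with intensity proportional to
    ``exp(kappa * cos(phase - mu))`` is realized by thinning a homogeneous
    process at the peak intensity; the base rate is renormalized against
    the empirical phase occupancy (and the expected refractory loss) so
    the realized mean rate matches ``mean_rate`` within a couple of
    percent. Refractoriness is enforced afterwards as a dead time.
    """
    if len(phase) == 0:
        raise ParameterError("phase track is empty")
    duration = phase.duration
    if params.mean_rate == 0:
        return SpikeTrain(times=np.empty(0), duration=duration)
    rng = np.random.default_rng(params.seed)
    mod = np.exp(params.kappa * np.cos(phase.phases - params.mu))
    mean_mod = mod.mean()
    # renormalize the base rate for dead-time loss: with a refractory period
    # the realized rate is E[lambda(t) P(no spike in the preceding tau)],
    # P ~ exp(-integral of lambda over the window). Concentrated modulation
    # (large kappa) loses far more than rate*tau, so solve by fixed point.
    base = params.mean_rate
    if params.refractory > 0 and params.mean_rate > 0:
        dt = 1.0 / phase.sampling_rate
        win = max(int(round(params.refractory * phase.sampling_rate)), 1)
        shape = mod / mean_mod
        cum = np.concatenate(([0.0], np.cumsum(shape) * dt))
        window_int = cum[win:] - cum[:-win]  # integral of shape over trailing tau
        lam_shape = shape[win - 1 :][: window_int.size]
        for _ in range(6):
            realized = float(np.mean(base * lam_shape * np.exp(-base * window_int)))
            if realized <= 0:
                break
            base *= params.mean_rate / realized
    lam_max = base * mod.max() / mean_mod

    times: list[float] = []
    t = rng.exponential(1.0 / lam_max)
    last = -np.inf
    while t < duration:
        idx = min(int(t * phase.sampling_rate), len(phase) - 1)
        accept = rng.random() < (base * mod[idx] / mean_mod) / lam_max
        if accept and t - last >= params.refractory:
            times.append(t)
            last = t
        t += rng.exponential(1.0 / lam_max)
    return SpikeTrain(times=np.asarray(times), duration=duration)


def psc_kernel(params: SynapticTraceParams) -> np.ndarray:
    """Unit-peak difference-of-exponentials postsynaptic-current kernel.

    Signed by polarity: inward currents deflect negative. Truncated at
    8 decay time constants.
    """
    fs = params.sampling_rate
    n = max(int(round(8.0 * params.decay_tau * fs)), 2)
    t = np.arange(n) / fs
    shape = np.exp(-t / params.decay_tau) - np.exp(-t / params.rise_tau)
    shape /= shape.max()
    return -shape if params.polarity == "inward" else shape


def simulate_synaptic_trace(
    params: SynapticTraceParams,
) -> tuple[TimeSeries, dict[str, np.ndarray]]:
    """Simulate a voltage-clamp trace of postsynaptic currents.

    Events occur at Poisson times with gamma-distributed amplitudes
    (mean ``amp_mean``, CV ``amp_cv``); each contributes
    ``amplitude x unit-peak kernel`` so trace extrema equal event
    amplitudes in the noiseless case.

    Returns the trace (pA) and a ground-truth dict with ``times`` (onset,
    seconds) and ``amplitudes`` (pA, positive magnitudes).
    """
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    rng = np.random.default_rng(params.seed)
    n_events = rng.poisson(params.event_rate * params.duration)
    kernel = psc_kernel(params)
    # keep every event fully inside the trace so ground truth is exact
    latest = max(params.duration - len(kernel) / fs, 0.0)
    onsets = np.sort(rng.uniform(0.0, latest, size=n_events))
    if params.amp_cv > 0:
        shape = 1.0 / params.amp_cv**2
        amps = rng.gamma(shape, params.amp_mean / shape, size=n_events)
    else:
        amps = np.full(n_events, params.amp_mean)
    trace = np.zeros(n)
    for t_on, a in zip(onsets, amps):
        i = int(round(t_on * fs))
        seg = kernel[: n - i]
        trace[i : i + len(seg)] += a * seg
    trace += params.noise_sd * rng.standard_normal(n)
    ts = TimeSeries(samples=trace, sampling_rate=fs, units="pA", label="synaptic")
    return ts, {"times": onsets, "amplitudes": amps}


# ---------------------------------------------------------------------------
# whole-cell voltage rendering (for spike detection end-to-end tests)


def render_spike_trace(
    spikes: SpikeTrain,
    sampling_rate: float,
    *,
    baseline: float = -60.0,
    ap_peak: float = 30.0,
    ap_width: float = 0.001,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> TimeSeries:
    """Render spike times as a current-clamp voltage trace.

    Each action potential is a Gaussian-shaped depolarization of half-width
    ``ap_width`` rising from ``baseline`` (mV) to ``ap_peak``; membrane
    noise is white Gaussian. Crude electrically, but it gives the spike
    detector a realistic supra-threshold waveform with exact ground truth.
    """
    n = int(round(spikes.duration * sampling_rate))
    rng = np.random.default_rng(seed)
    v = np.full(n, baseline) + noise_sd * rng.standard_normal(n)
    half = int(round(3 * ap_width * sampling_rate))
    tt = (np.arange(-half, half + 1)) / sampling_rate
    wave = (ap_peak - baseline) * np.exp(-0.5 * (tt / ap_width) ** 2)
    for t_sp in spikes.times:
        i = int(round(t_sp * sampling_rate))
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        v[lo:hi] += wave[half - (i - lo) : half + (hi - i)]
    return TimeSeries(samples=v, sampling_rate=sampling_rate, units="mV", label="cell")


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CellRecord:
    """One simulated cell: traces, ground truth, and factor labels."""

    genotype: str
    age: str
    cell_id: str
    animal_id: str
    lfp: TimeSeries
    true_phase: PhaseSeries
    spikes: SpikeTrain
    cell_trace: TimeSeries
    synaptic: TimeSeries
    synaptic_truth: dict
    true_params: dict


def _cell_seed(master_seed: int, group_index: int, cell_index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(group_index, cell_index))
    return int(ss.generate_state(1)[0] % (2**31))


def theoretical_vector_length(kappa: float) -> float:
    """Mean resultant length of a von Mises sample: I1(kappa)/I0(kappa)."""
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def simulate_cohort(design: CohortDesign) -> list[CellRecord]:
    """Simulate every cell of a genotype x age design.

    Per-cell seeds derive deterministically from ``master_seed`` and the
    (group, cell) indices, so cohorts are reproducible yet cells are
    independent. Each record carries the generating parameters as ground
    truth for recovery tests.
    """
    records: list[CellRecord] = []
    for gi, (genotype, age, n_cells) in enumerate(design.groups):
        mults = dict(design.effects.get((genotype, age), {}))
        lfp_p = replace(
            design.lfp, carrier_amp=design.lfp.carrier_amp * mults.get("carrier_amp", 1.0)
        )
        coup_p = replace(
            design.coupling,
            kappa=design.coupling.kappa * mults.get("kappa", 1.0),
            mean_rate=design.coupling.mean_rate * mults.get("mean_rate", 1.0),
        )
        syn_p = replace(
            design.synaptic,
            amp_mean=design.synaptic.amp_mean * mults.get("amp_mean", 1.0),
            event_rate=design.synaptic.event_rate * mults.get("event_rate", 1.0),
        )
        for ci in range(n_cells):
            seed = _cell_seed(design.master_seed, gi, ci)
            lfp, phase = simulate_gamma_lfp(replace(lfp_p, seed=seed))
            spikes = simulate_coupled_spikes(phase, replace(coup_p, seed=seed + 1))
            cell_trace = render_spike_trace(spikes, lfp_p.sampling_rate, seed=seed + 2)
            syn, syn_truth = simulate_synaptic_trace(replace(syn_p, seed=seed + 3))
            records.append(
                CellRecord(
                    genotype=genotype,
                    age=age,
                    cell_id=f"{genotype}_{age}_c{ci:02d}",
                    animal_id=f"{genotype}_{age}_a{ci // 2:02d}",
                    lfp=lfp,
                    true_phase=phase,
                    spikes=spikes,
                    cell_trace=cell_trace,
                    synaptic=syn,
                    synaptic_truth=syn_truth,
                    true_params={
                        "carrier_amp": lfp_p.carrier_amp,
                        "kappa": coup_p.kappa,
                        "mu": coup_p.mu,
                        "mean_rate": coup_p.mean_rate,
                        "amp_mean": syn_p.amp_mean,
                        "event_rate": syn_p.event_rate,
                        "vector_length": theoretical_vector_length(coup_p.kappa),
                        "seed": seed,
                    },
                )
            )
    return records
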