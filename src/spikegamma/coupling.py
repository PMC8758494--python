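"""Spike-gamma phase coupling.

The chain: band-pass the LFP 20-40 Hz with a zero-phase (forward-backward)
Butterworth filter, take the instantaneous phase from the Hilbert
transform (peak of the cycle = 0, trough = +/-pi), detect action
potentials in the concomitant current-clamp trace by amplitude threshold,
read off the gamma phase at each spike, and summarize the spike-phase
distribution by the mean resultant vector: its length measures how
recurrent firing is at the preferred angle (1 = perfect locking,
0 = uniform), its argument is the preferred phase of firing. Cells are
included in group analyses only when the Rayleigh test rejects circular
uniformity at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ParameterError, PhaseSeries, SpikeTrain, TimeSeries, wrap_phase

__all__ = [
    "FilterConfig",
    "SpikeDetectConfig",
    "CouplingConfig",
    "CouplingResult",
    "bandpass_filter",
    "detect_spikes",
    "instantaneous_phase",
    "spike_phase_angles",
    "resultant_vector",
    "rayleigh_test",
    "coupling_statistics",
    "circular_mean",
    "analyze_cell",
]


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase Butterworth band-pass settings (order is per pass; the
    forward-backward application squares the magnitude response)."""

    low_cut: float = 20.0
    high_cut: float = 40.0
    order: int = 4
    invert_lfp: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ParameterError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ParameterError("order must be >= 1")


@dataclass(frozen=True)
class SpikeDetectConfig:
    """Amplitude-threshold action-potential detection settings."""

    threshold: float = 0.0
    min_interval: float = 0.002
    alignment: str = "peak"

    def __post_init__(self) -> None:
        if self.min_interval < 0:
            raise ParameterError("min_interval must be >= 0")
        if self.alignment not in ("peak", "threshold_crossing"):
            raise ParameterError("alignment must be 'peak' or 'threshold_crossing'")


@dataclass(frozen=True)
class CouplingConfig:
    """Inclusion and edge-handling settings for per-cell coupling."""

    alpha: float = 0.05
    n_min: int = 10
    edge_cycles: float = 3.0  # filter settling margin, in cycles of low_cut


@dataclass(frozen=True)
class CouplingResult:
    """Per-cell spike-gamma coupling summary.

    ``vector_length`` is |sum exp(i theta)| / n over spike phase angles
    (each spike contributes a unit vector); ``phase_angle`` is the
    argument of that resultant; ``included`` is the Rayleigh gate at the
    stated alpha. When fewer than ``n_min`` spikes are available the
    result is excluded with a reason rather than raising.
    """

    n_spikes: int
    vector_length: float
    phase_angle: float
    rayleigh_p: float
    firing_rate: float
    included: bool
    alpha: float = 0.05
    exclusion_reason: str | None = None

    def summary(self) -> str:
        if self.exclusion_reason:
            return (
                f"CouplingResult: excluded ({self.exclusion_reason}); "
                f"n={self.n_spikes}, rate={self.firing_rate:.2f} Hz"
            )
        return (
            f"CouplingResult: n={self.n_spikes}, r={self.vector_length:.3f}, "
            f"angle={self.phase_angle:+.3f} rad, Rayleigh p={self.rayleigh_p:.3g}, "
            f"rate={self.firing_rate:.2f} Hz, included={self.included}"
        )

    def to_dict(self) -> dict:
        return {
            "n_spikes": self.n_spikes,
            "vector_length": self.vector_length,
            "phase_angle": self.phase_angle,
            "rayleigh_p": self.rayleigh_p,
            "firing_rate": self.firing_rate,
            "included": self.included,
            "alpha": self.alpha,
            "exclusion_reason": self.exclusion_reason,
        }


def bandpass_filter(ts: TimeSeries, cfg: FilterConfig | None = None) -> TimeSeries:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    Output has the same length and rate as the input and no group delay;
    the effective magnitude response is the squared Butterworth response.
    """
    cfg = cfg or FilterConfig()
    nyq = ts.sampling_rate / 2.0
    if cfg.high_cut >= nyq:
        raise ParameterError(
            f"high_cut {cfg.high_cut} Hz must be below Nyquist {nyq} Hz"
        )
    x = -ts.samples if cfg.invert_lfp else ts.samples
    sos = signal.butter(
        cfg.order, [cfg.low_cut, cfg.high_cut], btype="bandpass",
        fs=ts.sampling_rate, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, x)
    return ts.with_samples(filtered, label=f"{ts.label}|bp{cfg.low_cut:g}-{cfg.high_cut:g}")


def detect_spikes(ts: TimeSeries, cfg: SpikeDetectConfig | None = None) -> SpikeTrain:
    """Amplitude-threshold spike detection on a current-clamp trace.

    One spike per contiguous supra-threshold epoch; epochs separated by
    less than ``min_interval`` are merged (a noisy crest crossing the
    threshold twice counts once). Spikes are timestamped at the
    within-epoch maximum (``alignment='peak'``) or at the first crossing.
    """
    cfg = cfg or SpikeDetectConfig()
    above = ts.samples > cfg.threshold
    if not np.any(above):
        return SpikeTrain(times=np.empty(0), duration=ts.duration)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(ts)]))

    min_gap = int(round(cfg.min_interval * ts.sampling_rate))
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    idx = []
    for s, e in merged:
        if cfg.alignment == "peak":
            idx.append(s + int(np.argmax(ts.samples[s:e])))
        else:
            idx.append(s)
    times = np.asarray(idx, dtype=float) / ts.sampling_rate
    return SpikeTrain(times=times, duration=ts.duration)


def instantaneous_phase(filtered: TimeSeries) -> PhaseSeries:
    """Instantaneous phase via the Hilbert transform.

    The input must be band-limited (output of :func:`bandpass_filter`).
    The phase is the angle of the analytic signal, so a local maximum of
    the filtered LFP maps to 0 and a local minimum to +/-pi.
    """
    x = filtered.samples
    if np.ptp(x) == 0:
        raise ParameterError("phase undefined for a constant trace")
    analytic = signal.hilbert(x)
    phases = wrap_phase(np.angle(analytic))
    return PhaseSeries(phases=phases, sampling_rate=filtered.sampling_rate, t0=filtered.t0)


def spike_phase_angles(phase: PhaseSeries, spikes: SpikeTrain) -> np.ndarray:
    """Gamma phase at each spike time (nearest sample, no interpolation).

    At 5 kHz against a 30 Hz rhythm the per-sample phase step is ~0.038
    rad, so nearest-sample lookup is negligible against biological
    scatter. Raises listing any spike outside the phase-series span.
    """
    if len(spikes) == 0:
        return np.empty(0)
    return phase.at_times(spikes.times)


def resultant_vector(angles: np.ndarray) -> tuple[float, float]:
    """Mean resultant vector of unit vectors at the given angles.

    Returns ``(length, angle)`` with length in [0, 1]; each spike is
    assigned a vector of length 1 and the resultant is normalized by n.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ParameterError("no angles supplied")
    z = np.exp(1j * angles).mean()
    return float(np.abs(z)), float(wrap_phase(np.angle(z)))


def circular_mean(angles: np.ndarray) -> float:
    """Circular mean angle (the resultant direction); used for group-level
    preferred phase, where arithmetic averaging is ill-defined near +/-pi."""
    return resultant_vector(angles)[1]


def rayleigh_test(angles: np.ndarray) -> float:
    """Rayleigh test of circular uniformity.

    Statistic ``Z = n r^2`` with the standard finite-n corrected series
    for the p-value:

        p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clipped into (0, 1].
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 2:
        raise ParameterError("Rayleigh test needs at least 2 angles")
    r, _ = resultant_vector(angles)
    Z = n * r * r
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def coupling_statistics(
    angles: np.ndarray,
    duration: float,
    cfg: CouplingConfig | None = None,
) -> CouplingResult:
    """Summarize spike phase angles as a :class:`CouplingResult`.

    Fewer than ``n_min`` spikes yields an excluded result carrying the
    reason (mirroring the study's practice of logging, not silently
    dropping, recordings that fail selection).
    """
    cfg = cfg or CouplingConfig()
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if not duration > 0:
        raise ParameterError("duration must be > 0")
    rate = n / duration
    if n < cfg.n_min:
        return CouplingResult(
            n_spikes=n, vector_length=float("nan"), phase_angle=float("nan"),
            rayleigh_p=float("nan"), firing_rate=rate, included=False,
            alpha=cfg.alpha, exclusion_reason=f"n < n_min ({n} < {cfg.n_min})",
        )
    r, angle = resultant_vector(angles)
    p = rayleigh_test(angles)
    return CouplingResult(
        n_spikes=n, vector_length=r, phase_angle=angle, rayleigh_p=p,
        firing_rate=rate, included=p < cfg.alpha, alpha=cfg.alpha,
    )


def analyze_cell(
    lfp: TimeSeries,
    cell_trace: TimeSeries,
    filter_cfg: FilterConfig | None = None,
    detect_cfg: SpikeDetectConfig | None = None,
    coupling_cfg: CouplingConfig | None = None,
) -> CouplingResult:
    """Full per-cell chain: filter -> Hilbert phase -> detect -> angles ->
    coupling statistics.

    The LFP and cell trace must share duration and sampling rate. Spikes
    within the filter settling margin (``edge_cycles`` cycles of the low
    cut) of either trace edge are dropped before phase lookup.
    """
    filter_cfg = filter_cfg or FilterConfig()
    detect_cfg = detect_cfg or SpikeDetectConfig()
    coupling_cfg = coupling_cfg or CouplingConfig()
    if abs(lfp.sampling_rate - cell_trace.sampling_rate) > 1e-9:
        raise ParameterError(
            f"sampling-rate mismatch: LFP {lfp.sampling_rate} Hz vs "
            f"cell {cell_trace.sampling_rate} Hz"
        )
    if len(lfp) != len(cell_trace):
        raise ParameterError(
            f"length mismatch: LFP {len(lfp)} vs cell {len(cell_trace)} samples"
        )
    phase = instantaneous_phase(bandpass_filter(lfp, filter_cfg))
    spikes = detect_spikes(cell_trace, detect_cfg)
    margin = coupling_cfg.edge_cycles / filter_cfg.low_cut
    keep = (spikes.times >= margin) & (spikes.times <= lfp.duration - margin)
    angles = spike_phase_angles(
        phase, SpikeTrain(times=spikes.times[keep], duration=lfp.duration)
    )
    return coupling_statistics(angles, duration=lfp.duration, cfg=coupling_cfg)
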