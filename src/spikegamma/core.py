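"""Shared time-series data model.

Every analysis stage consumes and produces these containers, never raw
files: :class:`TimeSeries` for uniformly sampled voltage/current traces,
:class:`SpikeTrain` for action-potential times, and :class:`PhaseSeries`
for instantaneous-phase tracks.

Conventions: time is in seconds with ``t0 = 0`` at the first sample and
0-based sample indexing, so sample ``k`` lives at ``t0 + k / sampling_rate``.
Phase is in radians in ``(-pi, pi]`` with the oscillation peak at 0 and the
trough at +/-pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_UNITS = ("mV", "pA", "arbitrary")


class ParameterError(ValueError):
    """Invalid parameter or malformed domain object."""


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    wrapped = -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) + np.pi
    return wrapped if np.ndim(phi) else float(wrapped)


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled trace.

    Parameters
    ----------
    samples : ndarray
        Finite real values; mV for voltage, pA for current.
    sampling_rate : float
        Samples per second (Hz), > 0.
    t0 : float
        Time of the first sample, seconds.
    units : str
        One of ``mV``, ``pA``, ``arbitrary``.
    label : str
        Free-text channel label.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    units: str = "mV"
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.units not in VALID_UNITS:
            raise ParameterError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the trace: n / sampling_rate, seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, *, label: str | None = None) -> "TimeSeries":
        out = replace(self, samples=np.asarray(samples, dtype=float))
        if label is not None:
            out = replace(out, label=label)
        return out


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered action-potential times extracted from a current-clamp trace."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ParameterError("spike times must be 1-D")
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ParameterError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ParameterError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        """Mean firing rate over the source duration, Hz."""
        return self.times.size / self.duration


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase per sample; peak of the cycle = 0, trough = +/-pi."""

    phases: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    convention: str = field(default="peak=0,trough=±π")

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", phases)
        if phases.ndim != 1 or phases.size < 1:
            raise ParameterError("phases must be a non-empty 1-D array")
        if not np.all(np.isfinite(phases)):
            raise ParameterError("phases must be finite")
        if np.any(phases <= -np.pi) or np.any(phases > np.pi):
            raise ParameterError("phases must lie in (-pi, pi]")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be > 0")

    def __len__(self) -> int:
        return self.phases.size

    @property
    def duration(self) -> float:
        return self.phases.size / self.sampling_rate

    def at_times(self, times: np.ndarray) -> np.ndarray:
        """Phase at the nearest sample to each requested time.

        Raises :class:`ParameterError` listing any times outside the span.
        """
        times = np.asarray(times, dtype=float)
        bad = (times < self.t0) | (times >= self.t0 + self.duration)
        if np.any(bad):
            raise ParameterError(
                f"times outside phase-series span: {times[bad].tolist()}"
            )
        idx = np.rint((times - self.t0) * self.sampling_rate).astype(int)
        return self.phases[np.clip(idx, 0, self.phases.size - 1)]
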