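"""Template-based detection of postsynaptic currents.

A template is the unit-peak average of at least 20 representative event
snippets. Detection slides the template along the trace, fitting at each
offset an optimally scaled-and-offset copy by least squares; the
detection statistic is the fitted scale divided by the SD of the fit
residual — the standard scaled-template criterion of patch-clamp
software. Events are positions where the criterion exceeds a threshold
(default 3.5), separated by at least one template rise time; after a
first pass the fitted events are subtracted and the trace re-scanned
once, so partially overlapping events can both be recovered. The fitted
scale is the event amplitude (the template has unit peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ParameterError, TimeSeries

__all__ = [
    "EventTemplate",
    "DetectedEvents",
    "build_template",
    "detect_events",
    "event_statistics",
]

MIN_SOURCE_EVENTS = 20


@dataclass(frozen=True)
class EventTemplate:
    """Unit-peak average event waveform, aligned at onset."""

    waveform: np.ndarray
    sampling_rate: float
    n_source_events: int
    polarity: str

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        if w.ndim != 1 or w.size < 2:
            raise ParameterError("template waveform must be 1-D with length >= 2")
        if not np.isclose(np.max(np.abs(w)), 1.0):
            raise ParameterError("template must have unit peak magnitude")
        if self.n_source_events < MIN_SOURCE_EVENTS:
            raise ParameterError(
                f"template requires >= {MIN_SOURCE_EVENTS} averaged source events, "
                f"got {self.n_source_events}"
            )
        if self.polarity not in ("inward", "outward"):
            raise ParameterError("polarity must be 'inward' or 'outward'")

    @property
    def rise_time(self) -> float:
        """Onset-to-peak time of the template, seconds."""
        return int(np.argmax(np.abs(self.waveform))) / self.sampling_rate


@dataclass(frozen=True)
class DetectedEvents:
    """Detected events: onset times, fitted amplitudes, criterion values."""

    times: np.ndarray
    amplitudes: np.ndarray
    criterion_values: np.ndarray
    threshold: float
    polarity: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        c = np.asarray(self.criterion_values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "criterion_values", c)
        if not (t.shape == a.shape == c.shape):
            raise ParameterError("times, amplitudes, criterion_values must match")
        if t.size and np.any(np.diff(t) <= 0):
            raise ParameterError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def build_template(
    snippets,
    sampling_rate: float,
    polarity: str = "inward",
    baseline_samples: int = 0,
) -> EventTemplate:
    """Average >= 20 onset-aligned event snippets into a unit-peak template.

    ``baseline_samples`` > 0 subtracts the per-snippet median of that many
    leading samples (for snippets carrying a pre-onset baseline margin);
    the default assumes snippets start at onset, already at baseline.
    """
    snippets = [np.asarray(s, dtype=float) for s in snippets]
    if len(snippets) < MIN_SOURCE_EVENTS:
        raise ParameterError(
            f"need >= {MIN_SOURCE_EVENTS} representative events to build a template, "
            f"got {len(snippets)}"
        )
    lengths = {len(s) for s in snippets}
    if len(lengths) != 1:
        raise ParameterError(f"snippets must share one length, got lengths {sorted(lengths)}")
    stack = np.stack(snippets)
    if baseline_samples > 0:
        stack = stack - np.median(stack[:, :baseline_samples], axis=1, keepdims=True)
    mean = stack.mean(axis=0)
    peak = np.max(np.abs(mean))
    if peak == 0:
        raise ParameterError("averaged snippet is identically zero")
    return EventTemplate(
        waveform=mean / peak,
        sampling_rate=sampling_rate,
        n_source_events=len(snippets),
        polarity=polarity,
    )


def _criterion_profile(x: np.ndarray, tpl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled-template criterion and fitted scale at every window offset.

    At offset k the model is ``x[k:k+L] ~ scale * tpl + offset``; closed-form
    least squares via rolling sums, computed with FFT correlation.
    """
    L = tpl.size
    sum_t = tpl.sum()
    sum_t2 = float(tpl @ tpl)
    ones = np.ones(L)
    sum_y = signal.fftconvolve(x, ones[::-1], mode="valid")
    sum_y2 = signal.fftconvolve(x * x, ones[::-1], mode="valid")
    sum_ty = signal.fftconvolve(x, tpl[::-1], mode="valid")
    denom = sum_t2 - sum_t * sum_t / L
    scale = (sum_ty - sum_t * sum_y / L) / denom
    offset = (sum_y - scale * sum_t) / L
    sse = (
        sum_y2
        + scale**2 * sum_t2
        + L * offset**2
        - 2.0 * (scale * sum_ty + offset * sum_y - scale * offset * sum_t)
    )
    sse = np.clip(sse, 0.0, None)
    sd = np.sqrt(sse / (L - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        # a zero-residual window is a perfect match: infinite criterion
        exact = np.where(scale > 0, np.inf, np.where(scale < 0, -np.inf, 0.0))
        crit = np.where(sd > 0, scale / sd, exact)
    return crit, scale


def detect_events(
    ts: TimeSeries,
    template: EventTemplate,
    criterion_threshold: float = 3.5,
) -> DetectedEvents:
    """Detect events in a voltage-clamp trace by scaled-template matching.

    Detections are accepted greedily in order of criterion value; each
    accepted event's fitted template is subtracted before the trace is
    re-scanned, so partially overlapping events (separated by at least
    one template rise time) are both recovered. Amplitudes are the fitted
    scales (pA; negative for inward polarity).
    """
    if abs(ts.sampling_rate - template.sampling_rate) > 1e-9:
        raise ParameterError(
            f"sampling-rate mismatch: trace {ts.sampling_rate} Hz vs "
            f"template {template.sampling_rate} Hz"
        )
    tpl = template.waveform
    if len(ts) < tpl.size + 1:
        raise ParameterError("trace shorter than template")
    L = tpl.size
    min_sep = max(int(round(template.rise_time * ts.sampling_rate)), 1)

    # greedy peel-off: accept the best criterion peak, subtract its fitted
    # template, recompute the criterion locally (only positions within one
    # template length of the subtraction change), repeat. Peeling removes
    # the elevated criterion along an accepted event's decay, so overlapping
    # events are resolved without cascades of spurious detections.
    x = ts.samples.astype(float).copy()
    crit, scale = _criterion_profile(x, tpl)
    blocked = np.zeros(crit.size, dtype=bool)
    # fitted scales at float-arithmetic dust level are subtraction residue,
    # not events; the floor scales with the trace (keeps equivariance)
    atol = 1e-9 * float(np.max(np.abs(ts.samples)))
    found: dict[int, tuple[float, float]] = {}  # onset idx -> (scale, criterion)
    while True:
        avail = np.where(blocked | (np.abs(scale) <= atol), -np.inf, crit)
        p = int(np.argmax(avail))
        if not avail[p] >= criterion_threshold:
            break
        found[p] = (float(scale[p]), float(crit[p]))
        seg = tpl[: len(x) - p]
        x[p : p + len(seg)] -= scale[p] * seg
        blocked[max(p - min_sep + 1, 0) : p + min_sep] = True
        lo = max(p - L + 1, 0)
        hi = min(p + L, crit.size)  # exclusive, position range to refresh
        c_loc, s_loc = _criterion_profile(x[lo : hi - 1 + L], tpl)
        crit[lo:hi] = c_loc
        scale[lo:hi] = s_loc

    idx = np.array(sorted(found), dtype=int)
    scales = np.array([found[i][0] for i in idx])
    crits = np.array([found[i][1] for i in idx])
    # signed amplitude: fitted scale times the template's signed peak, so
    # inward events report negative pA
    peak_sign = np.sign(tpl[int(np.argmax(np.abs(tpl)))])
    return DetectedEvents(
        times=idx / ts.sampling_rate,
        amplitudes=scales * peak_sign,
        criterion_values=crits,
        threshold=criterion_threshold,
        polarity=template.polarity,
    )


def event_statistics(ev: DetectedEvents, duration: float) -> dict:
    """Mean absolute amplitude (pA) and event frequency (Hz).

    An empty event set reports frequency 0 and amplitude NaN.
    """
    if not duration > 0:
        raise ParameterError("duration must be > 0")
    n = len(ev)
    return {
        "n_events": n,
        "mean_amplitude": float(np.mean(np.abs(ev.amplitudes))) if n else float("nan"),
        "frequency": n / duration,
    }
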