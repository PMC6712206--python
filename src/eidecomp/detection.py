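"""Detection of stimulus-evoked responses and action potentials.

Response onset uses the 8x-baseline-SD rule: a response is detected when the
signal deviates from the pre-stimulus baseline mean by more than ``k_sd``
baseline standard deviations within the first ``search_ms`` after the
stimulus. The latency is the first such crossing (after an optional
stimulus-artifact blanking period) and the peak is the extremum of the
signal, in the polarity of the crossing, after the latency.

Spikes are local maxima with a minimum prominence (rise above the
surrounding troughs) and a minimum absolute peak level, equivalent to the
classic MATLAB ``peakdet`` usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core_io import BaselineWindow, Sweep
from .errors import ParameterError, RangeError, UndefinedThresholdError


@dataclass
class EventDetection:
    detected: bool
    latency_ms: float | None = None
    peak_amplitude: float | None = None
    peak_time_ms: float | None = None
    threshold_used: float = 0.0
    baseline_sd: float = 0.0
    polarity: int = 0  # +1 upward crossing, -1 downward, 0 none


@dataclass
class SpikeTrain:
    spike_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_peaks_mV: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times_ms = np.asarray(self.spike_times_ms, dtype=float)
        self.spike_peaks_mV = np.asarray(self.spike_peaks_mV, dtype=float)
        if self.spike_times_ms.size != self.spike_peaks_mV.size:
            raise ParameterError("times and peaks must have equal length")
        if np.any(np.diff(self.spike_times_ms) <= 0):
            raise ParameterError("spike times must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.spike_times_ms.size)


def detect_response(
    trace: Sweep,
    baseline: BaselineWindow | None = None,
    k_sd: float = 8.0,
    search_ms: float = 30.0,
    artifact_blank_ms: float = 0.5,
    peak_window_ms: float | None = None,
    two_sided: bool = True,
) -> EventDetection:
    """Threshold-crossing response detection.

    A response is detected where ``|signal - baseline mean|`` (or the signed
    deviation if ``two_sided=False``) exceeds ``k_sd * baseline_sd`` in
    ``(artifact_blank_ms, search_ms]``. If the baseline is noiseless
    (SD = 0) any nonzero deviation counts; a fully flat trace with SD = 0
    has no definable threshold and raises.
    """
    tb = trace.timebase
    baseline = baseline or BaselineWindow()
    if tb.end_ms < search_ms:
        raise RangeError("trace does not cover the search window")
    bl = trace.values[tb.window_slice(baseline.start_ms, baseline.end_ms)]
    mu = float(bl.mean())
    sd = float(bl.std(ddof=0))
    thresh = k_sd * sd

    dev = trace.values - mu
    t = tb.times()
    in_search = (t > artifact_blank_ms) & (t <= search_ms)
    sig = np.abs(dev) if two_sided else dev
    crossing = in_search & (sig > thresh)

    if sd == 0 and not np.any(np.abs(dev[in_search]) > 0):
        raise UndefinedThresholdError(
            "baseline SD is 0 and the trace never deviates from baseline"
        )
    if not np.any(crossing):
        return EventDetection(False, threshold_used=thresh, baseline_sd=sd)

    i0 = int(np.argmax(crossing))
    polarity = 1 if dev[i0] >= 0 else -1
    latency = float(t[i0])

    end = peak_window_ms if peak_window_ms is not None else search_ms
    win = (t >= latency) & (t <= end)
    seg = dev[win]
    j = int(np.argmax(seg)) if polarity > 0 else int(np.argmin(seg))
    idx = np.flatnonzero(win)[j]
    return EventDetection(
        True,
        latency_ms=latency,
        peak_amplitude=float(dev[idx]),
        peak_time_ms=float(t[idx]),
        threshold_used=thresh,
        baseline_sd=sd,
        polarity=polarity,
    )


def detect_spikes(voltage: Sweep, prominence_mV: float = 20.0,
                  min_peak_mV: float = -10.0) -> SpikeTrain:
    """Local-maximum spike detection with prominence and level criteria."""
    if prominence_mV <= 0:
        raise ParameterError("prominence must be positive")
    idx, props = find_peaks(voltage.values, prominence=prominence_mV,
                            height=min_peak_mV)
    t = voltage.timebase.times()
    return SpikeTrain(t[idx], voltage.values[idx])


def first_spike_latency(train: SpikeTrain) -> float | None:
    """Time of the first spike, or None for an empty train."""
    if train.count == 0:
        return None
    return float(train.spike_times_ms[0])


def spike_density(trains, bin_ms: float = 1.0,
                  window_ms: tuple[float, float] = (0.0, 50.0),
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per time bin pooled across trains.

    Returns ``(counts, bin_edges)``; the counts sum to the total number of
    spikes inside the window.
    """
    if bin_ms <= 0:
        raise ParameterError("bin_ms must be positive")
    lo, hi = window_ms
    edges = np.arange(lo, hi + bin_ms * 0.5, bin_ms)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_ms)
    all_times = np.concatenate(
        [tr.spike_times_ms for tr in trains] or [np.empty(0)]
    )
    all_times = all_times[(all_times >= lo) & (all_times < edges[-1])]
    counts, _ = np.histogram(all_times, bins=edges)
    return counts, edges
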