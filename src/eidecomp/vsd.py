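"""Photodiode-array voltage-sensitive dye (VSD) processing.

The instrument records the change in light absorption ΔA(t) on each of 464
photodiodes at 1 kHz, together with the per-diode absolute light level Amax.
Membrane depolarization appears as a positive ΔA/Amax signal. The processing
chain is:

    normalize (ΔA / Amax)
    -> subtract instrumentation offset (mean over 100 ms pre-stimulus)
    -> average >= 3 artifact-free repeats
    -> 2-D Gaussian spatial filter (sigma = one inter-diode distance, 150 µm)
    -> 5 ms running-average temporal filter
    -> ROI average over selected diodes and peak of the first positive
       deflection.

Every step is linear, so the chain is linear; both filters are weight-
normalized and preserve the spatial/temporal mean. The diode geometry is
irregular (hexagonal packing), so the spatial filter is a distance-based
Gaussian kernel over diode coordinates rather than a grid convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import TimeBase
from .errors import DataError, ParameterError, RangeError


@dataclass
class DiodeArrayRecording:
    """Frames (n_diodes x n_samples) of ΔA plus per-diode Amax and geometry.

    ``frames`` may hold a stack of repeats as (n_repeats, n_diodes,
    n_samples); all operations broadcast over the leading axis.
    """

    frames: np.ndarray
    amax: np.ndarray
    coords_um: np.ndarray
    timebase: TimeBase
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.amax = np.asarray(self.amax, dtype=float)
        self.coords_um = np.asarray(self.coords_um, dtype=float)
        n_diodes = self.frames.shape[-2]
        if self.frames.shape[-1] != self.timebase.n_samples:
            raise DataError("frames do not match the timebase")
        if self.amax.shape != (n_diodes,):
            raise DataError("amax must be one value per diode")
        if self.coords_um.shape != (n_diodes, 2):
            raise DataError("coords must be (n_diodes, 2)")
        if np.any(self.amax <= 0):
            raise DataError("amax must be positive for every diode")

    @property
    def n_diodes(self) -> int:
        return int(self.frames.shape[-2])


@dataclass
class RoiMask:
    """Set of diode indices forming a region of interest."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != np.unique(self.indices).size:
            raise ParameterError("ROI indices must be unique")


@dataclass
class VsdResponse:
    trace: np.ndarray
    timebase: TimeBase
    peak_amplitude: float
    peak_time_ms: float
    label: str = ""


def normalize(rec: DiodeArrayRecording) -> np.ndarray:
    """Fractional signal ΔA/Amax per diode (depolarization positive)."""
    if np.any(rec.amax <= 0):
        raise DataError("amax must be positive")
    return rec.frames / rec.amax[..., :, None]


def subtract_offset(frames: np.ndarray, timebase: TimeBase,
                    pre_window_ms: float = 100.0) -> np.ndarray:
    """Remove the per-diode instrumentation offset (mean over the
    pre-stimulus window)."""
    if timebase.t0_ms > -pre_window_ms + 1e-9:
        # tolerate shorter recordings by shrinking to the available span
        if timebase.t0_ms >= 0:
            raise RangeError("no pre-stimulus samples for offset estimation")
        pre_window_ms = -timebase.t0_ms
    sl = timebase.window_slice(-pre_window_ms, 0.0)
    frames = np.asarray(frames, dtype=float)
    return frames - frames[..., sl].mean(axis=-1, keepdims=True)


def average_repeats(frames: np.ndarray) -> np.ndarray:
    """Mean over the leading repeat axis of a (n_repeats, n_diodes, n_t)
    stack (>= 3 repeats in the standard protocol)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise DataError("expected a (n_repeats, n_diodes, n_t) stack")
    return frames.mean(axis=0)


def spatial_filter(frames: np.ndarray, coords_um: np.ndarray,
                   sigma_um: float = 150.0) -> np.ndarray:
    """Gaussian spatial smoothing over the irregular diode layout.

    Each diode's value becomes a Gaussian-weighted average over all diodes,
    weights ``exp(-d^2 / (2 sigma^2))`` normalized to sum 1 per target diode
    (DC preserving). Default sigma is one inter-diode distance (~150 µm).
    """
    if sigma_um <= 0:
        raise ParameterError("sigma must be positive")
    coords = np.asarray(coords_um, dtype=float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-d2 / (2.0 * sigma_um**2))
    w /= w.sum(axis=1, keepdims=True)
    return w @ np.asarray(frames, dtype=float)


def temporal_filter(frames: np.ndarray, timebase: TimeBase,
                    window_ms: float = 5.0) -> np.ndarray:
    """Centered running average; the window truncates (shrinks) at the
    edges so constant traces pass unchanged."""
    n_win = max(int(round(window_ms / timebase.dt_ms)), 1)
    if n_win % 2 == 0:
        n_win += 1  # keep the window centered
    frames = np.asarray(frames, dtype=float)
    half = n_win // 2
    csum = np.cumsum(frames, axis=-1)
    n_t = frames.shape[-1]
    idx_hi = np.minimum(np.arange(n_t) + half, n_t - 1)
    idx_lo = np.arange(n_t) - half - 1
    hi = csum[..., idx_hi]
    lo = np.where(idx_lo >= 0, csum[..., np.maximum(idx_lo, 0)], 0.0)
    counts = idx_hi - np.maximum(idx_lo, -1)
    return (hi - lo) / counts


def roi_response(frames: np.ndarray, timebase: TimeBase, mask: RoiMask,
                 search_window_ms: tuple[float, float] = (0.0, 200.0),
                 onset_k_sd: float = 8.0) -> VsdResponse:
    """Average the masked diodes and quantify the first positive deflection.

    A deflection is a maximal run of positive samples inside the search
    window; the first run whose peak exceeds ``onset_k_sd`` times the
    pre-stimulus SD of the ROI trace is the response (brief noise blips are
    skipped; with a noiseless baseline any positive run qualifies). The
    peak is the run maximum; the undershoot after the deflection is not
    analyzed. Falls back to the window maximum if no run qualifies.
    """
    if mask.indices.size == 0:
        raise ParameterError("ROI mask is empty")
    frames = np.asarray(frames, dtype=float)
    trace = frames[mask.indices].mean(axis=0)
    t = timebase.times()
    lo, hi = search_window_ms
    hi = min(hi, timebase.end_ms)
    in_win = np.flatnonzero((t >= lo) & (t <= hi))

    sd = trace[t < 0].std() if np.any(t < 0) else 0.0
    thresh = onset_k_sd * sd

    pos = trace[in_win] > 0
    # maximal runs of positive samples within the window
    bounds = np.flatnonzero(np.diff(np.concatenate(([0], pos.view(np.int8),
                                                    [0]))))
    for s, e in zip(bounds[::2], bounds[1::2]):
        run = in_win[s:e]
        j = run[np.argmax(trace[run])]
        if trace[j] > thresh:
            return VsdResponse(trace, timebase, float(trace[j]),
                               float(t[j]), mask.label)
    j = in_win[np.argmax(trace[in_win])]
    return VsdResponse(trace, timebase, float(trace[j]), float(t[j]),
                       mask.label)


def process_chain(rec: DiodeArrayRecording, mask: RoiMask,
                  sigma_um: float = 150.0, tavg_ms: float = 5.0,
                  pre_window_ms: float = 100.0,
                  search_window_ms: tuple[float, float] = (0.0, 200.0),
                  ) -> VsdResponse:
    """Full standard chain: normalize -> offset -> (average repeats) ->
    spatial filter -> temporal filter -> ROI response."""
    f = normalize(rec)
    f = subtract_offset(f, rec.timebase, pre_window_ms)
    if f.ndim == 3:
        f = average_repeats(f)
    f = spatial_filter(f, rec.coords_um, sigma_um)
    f = temporal_filter(f, rec.timebase, tavg_ms)
    return roi_response(f, rec.timebase, mask, search_window_ms)
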