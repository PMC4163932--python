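"""Slow-wave-coupled spindle detection.

Spindles are transient 8–20 Hz bursts nested at the peaks of the slow
oscillation.  Detection follows a filter–rectify–smooth–z-score scheme: the
trace is zero-phase band-pass filtered to 8–20 Hz, rectified, smoothed with a
71 ms boxcar (one 14 Hz cycle) and z-scored over the recording period.
Supra-threshold (≥ 2 SD) envelope runs become candidate events; a candidate
is kept only when its envelope peak falls within ±0.25 s of a slow-wave peak
(equivalently: the two peaks lie within 0.5 s of each other), and each
slow-wave peak keeps at most its strongest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .preprocess import bandpass

__all__ = [
    "SpindleParams",
    "SpindleEvent",
    "SpindleDetector",
    "slow_wave_peaks",
    "spindle_envelope",
    "detect_spindles",
    "spindle_rate",
    "normalized_spindle_rate",
    "kernel_length_ms",
]


def kernel_length_ms(freq: float = 14.0) -> int:
    """Smoothing-kernel length in ms: one cycle of ``freq``, ms-rounded (71 ms at 14 Hz)."""
    return int(round(1000.0 / freq))


@dataclass(frozen=True)
class SpindleParams:
    """Detection settings.

    ``kernel_freq`` sets the boxcar length to one cycle (71 ms at the 14 Hz
    default); ``proximity`` is the maximum |spindle peak − slow-wave peak|
    separation; ``peak_min_separation`` suppresses sub-cycle duplicates among
    slow-wave peaks.
    """

    slow_band: tuple[float, float] = (0.1, 3.0)
    spindle_band: tuple[float, float] = (8.0, 20.0)
    kernel_freq: float = 14.0
    z_thresh: float = 2.0
    proximity: float = 0.25
    peak_min_separation: float = 0.4
    peak_prominence_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.proximity <= 0 or self.z_thresh <= 0 or self.kernel_freq <= 0:
            raise ValueError("proximity, z_thresh and kernel_freq must be positive")

    @property
    def kernel_len_ms(self) -> int:
        return kernel_length_ms(self.kernel_freq)


@dataclass
class SpindleEvent:
    """One detected burst: envelope peak, associated slow-wave peak and the
    supra-threshold onset/offset, all in seconds from period start."""

    channel: str
    peak_time: float
    slow_peak_time: float
    onset: float
    offset: float
    z_peak: float


def slow_wave_peaks(x: Sequence[float], fs: float, params: SpindleParams | None = None) -> np.ndarray:
    """Times (s) of slow-wave crests.

    Crests are positive local maxima of the slow-band-filtered signal,
    separated by at least ``peak_min_separation`` and with a prominence of
    at least ``peak_prominence_sd`` slow-band standard deviations — small
    ripples above zero near a trough are not crests.
    """
    params = params or SpindleParams()
    x = np.asarray(x, dtype=float)
    min_len = int(fs / params.slow_band[1]) + 1  # one cycle of the band's upper edge
    if len(x) < min_len:
        raise ValueError("signal shorter than one slow cycle")
    slow = bandpass(x, fs, params.slow_band)
    distance = max(1, int(round(params.peak_min_separation * fs)))
    prominence = params.peak_prominence_sd * slow.std()
    idx, _ = sps.find_peaks(slow, height=0.0, distance=distance,
                            prominence=prominence if prominence > 0 else None)
    return idx / fs


def spindle_envelope(x: Sequence[float], fs: float, params: SpindleParams | None = None) -> np.ndarray:
    """Z-scored rectified-and-smoothed 8–20 Hz envelope, same length as ``x``."""
    params = params or SpindleParams()
    x = np.asarray(x, dtype=float)
    n_kernel = max(1, int(round(params.kernel_len_ms / 1000.0 * fs)))
    if len(x) <= n_kernel:
        raise ValueError("signal shorter than the smoothing kernel")
    filtered = bandpass(x, fs, params.spindle_band, order=4)
    rectified = np.abs(filtered)
    kernel = np.ones(n_kernel) / n_kernel
    smooth = np.convolve(rectified, kernel, mode="same")
    sd = smooth.std()
    if sd == 0:
        raise ValueError("flat envelope: cannot z-score")
    return (smooth - smooth.mean()) / sd


def detect_spindles(
    x: Sequence[float],
    fs: float,
    params: SpindleParams | None = None,
    channel: str = "",
) -> list[SpindleEvent]:
    """Detect slow-wave-coupled spindles in one channel.

    Returns time-ordered events; at most one per slow-wave peak (the highest
    envelope z wins when several candidates couple to the same peak).
    """
    params = params or SpindleParams()
    x = np.asarray(x, dtype=float)
    sw_peaks = slow_wave_peaks(x, fs, params)
    z = spindle_envelope(x, fs, params)

    above = z >= params.z_thresh
    if not above.any() or len(sw_peaks) == 0:
        return []
    # contiguous supra-threshold runs
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(z)]

    best: dict[float, SpindleEvent] = {}
    for s, e in zip(starts, ends):
        peak_idx = s + int(np.argmax(z[s:e]))
        peak_time = peak_idx / fs
        nearest = sw_peaks[int(np.argmin(np.abs(sw_peaks - peak_time)))]
        if abs(peak_time - nearest) > params.proximity:
            continue
        event = SpindleEvent(
            channel=channel,
            peak_time=peak_time,
            slow_peak_time=float(nearest),
            onset=s / fs,
            offset=e / fs,
            z_peak=float(z[peak_idx]),
        )
        kept = best.get(event.slow_peak_time)
        if kept is None or event.z_peak > kept.z_peak:
            best[event.slow_peak_time] = event
    return sorted(best.values(), key=lambda ev: ev.peak_time)


def spindle_rate(events: Sequence[SpindleEvent] | int, duration: float) -> float:
    """Events per minute over a period of ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    count = events if isinstance(events, (int, np.integer)) else len(events)
    return 60.0 * count / duration


def normalized_spindle_rate(rate: float, pct_slow: float) -> float:
    """Spindles per minute of slow-wave time: rate / (pct_slow / 100)."""
    if pct_slow <= 0:
        raise ValueError("pct_slow must be positive to normalize the spindle rate")
    return rate / (pct_slow / 100.0)


class SpindleDetector(BaseEstimator):
    """sklearn-style detector: ``fit(x)`` runs detection on one channel.

    Attributes after fitting: ``events_`` (list of SpindleEvent), ``rate_``
    (per minute) and ``envelope_`` (z-scored envelope).
    """

    def __init__(
        self,
        fs: float = 2020.0,
        slow_band: tuple[float, float] = (0.1, 3.0),
        spindle_band: tuple[float, float] = (8.0, 20.0),
        kernel_freq: float = 14.0,
        z_thresh: float = 2.0,
        proximity: float = 0.25,
        peak_min_separation: float = 0.4,
    ):
        self.fs = fs
        self.slow_band = slow_band
        self.spindle_band = spindle_band
        self.kernel_freq = kernel_freq
        self.z_thresh = z_thresh
        self.proximity = proximity
        self.peak_min_separation = peak_min_separation

    def _params(self) -> SpindleParams:
        return SpindleParams(
            slow_band=tuple(self.slow_band),
            spindle_band=tuple(self.spindle_band),
            kernel_freq=self.kernel_freq,
            z_thresh=self.z_thresh,
            proximity=self.proximity,
            peak_min_separation=self.peak_min_separation,
        )

    def fit(self, X, y=None) -> "SpindleDetector":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a single channel as a 1-D array or single column")
        params = self._params()
        self.envelope_ = spindle_envelope(x, self.fs, params)
        self.events_ = detect_spindles(x, self.fs, params)
        self.rate_ = spindle_rate(self.events_, len(x) / self.fs)
        return self
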