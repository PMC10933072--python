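"""Gait event detection: pressure peaks, stance landmarks, stride intervals.

The stride-interval time series — the input to the entropy analysis — is
defined as the time between adjacent peaks of the fused hindfoot pressure
trace (one heel-loading peak per stride).  Stance-phase morphology is
summarized by five landmarks on the whole-foot total: contact start, the
loading (first) peak, the mid-stance valley, the push-off (second) peak and
contact end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .core import REGIONS, RegionalSignal
from .errors import (
    InsufficientEventsError,
    InvalidParameterError,
    MorphologyError,
)

__all__ = [
    "DetectorParams",
    "StrideSeries",
    "StanceLandmarks",
    "detect_peaks",
    "stride_intervals",
    "segment_stance",
    "split_contacts",
    "amplitude_pressure_ratio",
]


@dataclass(frozen=True)
class DetectorParams:
    """Peak-detection and segmentation parameters.

    ``nominal_stride_s`` sets the minimum peak separation to half a stride
    (prevents the two stance sub-peaks from being double-counted);
    ``min_prominence_frac`` is the required peak prominence as a fraction of
    the trace range; ``smooth_window`` (samples) enables an optional moving
    average before peak detection, off (0) by default;
    ``contact_threshold_frac`` defines contact onset/offset as a fraction of
    the peak pressure.
    """

    nominal_stride_s: float = 1.1
    min_prominence_frac: float = 0.2
    smooth_window: int = 0
    contact_threshold_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.nominal_stride_s <= 0:
            raise InvalidParameterError("nominal_stride_s must be positive")
        if not 0 < self.min_prominence_frac <= 1:
            raise InvalidParameterError("min_prominence_frac must be in (0, 1]")
        if self.smooth_window < 0:
            raise InvalidParameterError("smooth_window must be >= 0")
        if not 0 < self.contact_threshold_frac < 1:
            raise InvalidParameterError("contact_threshold_frac must be in (0, 1)")


@dataclass
class StrideSeries:
    """Ordered stride durations in seconds, the series analyzed for entropy."""

    intervals: np.ndarray
    source: str
    fs_hz: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise InvalidParameterError("all stride intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    def to_csv(self, path: str | Path) -> None:
        lines = ["interval_s"] + [f"{v:.17g}" for v in self.intervals]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class StanceLandmarks:
    """Sample indices of the stance-phase morphology within one contact."""

    stance_start_idx: int
    first_peak_idx: int
    valley_idx: int
    second_peak_idx: int
    stance_end_idx: int

    def __post_init__(self) -> None:
        ordered = (
            self.stance_start_idx
            <= self.first_peak_idx
            < self.valley_idx
            < self.second_peak_idx
            <= self.stance_end_idx
        )
        if not ordered:
            raise MorphologyError(f"landmarks out of order: {self}")


def _smooth(trace: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return trace
    kernel = np.ones(window) / window
    return np.convolve(trace, kernel, mode="same")


def detect_peaks(
    trace: np.ndarray,
    fs_hz: float,
    min_separation_s: float = 0.5,
    min_prominence_frac: float = 0.2,
) -> np.ndarray:
    """Indices of local maxima with fraction-of-range prominence.

    Peaks must have prominence >= ``min_prominence_frac * (max - min)`` of
    the trace and be at least ``min_separation_s`` apart.  A constant or
    too-short trace yields an empty result (not an error), so the detector
    composes cleanly with downstream event counting.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        return np.array([], dtype=int)
    if fs_hz <= 0:
        raise InvalidParameterError("fs_hz must be positive")
    span = float(trace.max() - trace.min())
    if span == 0:
        return np.array([], dtype=int)
    distance = max(int(round(min_separation_s * fs_hz)), 1)
    peaks, _ = find_peaks(trace, prominence=min_prominence_frac * span, distance=distance)
    return peaks.astype(int)


def stride_intervals(
    regional: RegionalSignal, params: DetectorParams | None = None
) -> StrideSeries:
    """Stride-interval series from adjacent hindfoot pressure peaks.

    Intervals are ``(peak[i+1] - peak[i]) / fs`` in seconds.  Requires at
    least two detectable hindfoot peaks.
    """
    params = params or DetectorParams()
    trace = _smooth(regional.hindfoot, params.smooth_window)
    peaks = detect_peaks(
        trace,
        regional.fs_hz,
        min_separation_s=0.5 * params.nominal_stride_s,
        min_prominence_frac=params.min_prominence_frac,
    )
    if peaks.size < 2:
        raise InsufficientEventsError(
            f"need >= 2 hindfoot peaks to form stride intervals, found {peaks.size}"
        )
    intervals = np.diff(peaks) / regional.fs_hz
    return StrideSeries(
        intervals=intervals, source="hindfoot", fs_hz=regional.fs_hz, peak_indices=peaks
    )


def split_contacts(
    total: np.ndarray,
    contact_threshold_frac: float = 0.05,
    min_duration_samples: int = 5,
) -> list[tuple[int, int]]:
    """(start, end) index ranges of contact episodes in a total-pressure trace.

    A contact episode is a maximal run of samples at or above
    ``contact_threshold_frac`` times the global peak; runs shorter than
    ``min_duration_samples`` are discarded as noise blips.
    """
    total = np.asarray(total, dtype=float)
    if total.size == 0 or total.max() <= 0:
        return []
    above = total >= contact_threshold_frac * total.max()
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[0::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_duration_samples]


def segment_stance(
    total: np.ndarray,
    contact_threshold_frac: float = 0.05,
    min_prominence_frac: float = 0.2,
) -> StanceLandmarks:
    """Landmarks of a single contact episode on the whole-foot total trace.

    The stance window is bounded by threshold crossings at
    ``contact_threshold_frac`` of the episode peak; within it the two most
    prominent local maxima are the loading and push-off peaks and the
    minimum between them is the mid-stance valley.  Raises
    :class:`MorphologyError` when no double peak is present (e.g. an
    all-zero swing segment).
    """
    total = np.asarray(total, dtype=float)
    if total.size < 5 or total.max() <= 0:
        raise MorphologyError("segment contains no contact (all zero or too short)")
    threshold = contact_threshold_frac * total.max()
    above = np.flatnonzero(total >= threshold)
    start, end = int(above[0]), int(above[-1])
    window = total[start : end + 1]
    span = float(window.max() - window.min())
    peaks, props = find_peaks(window, prominence=min_prominence_frac * span)
    if peaks.size < 2:
        raise MorphologyError(
            f"expected a double-peaked stance, found {peaks.size} prominent peak(s)"
        )
    # two most prominent peaks, in temporal order
    order = np.argsort(props["prominences"])[::-1][:2]
    p1, p2 = sorted(int(peaks[i]) for i in order)
    valley = p1 + int(np.argmin(window[p1 : p2 + 1]))
    return StanceLandmarks(
        stance_start_idx=start,
        first_peak_idx=start + p1,
        valley_idx=start + valley,
        second_peak_idx=start + p2,
        stance_end_idx=end,
    )


def amplitude_pressure_ratio(
    regional: RegionalSignal,
    weight_kg: float,
    contact_threshold_frac: float = 0.05,
) -> dict[str, float]:
    """Per-region amplitude-pressure ratio: mean peak pressure over body weight.

    For each region the peak amplitude is taken within every contact episode
    (episodes found on the total trace), averaged across episodes, and
    divided by the subject's weight.  Doubling every pressure sample doubles
    every ratio; the ratio is the cross-speed loading measure.
    """
    if weight_kg <= 0:
        raise InvalidParameterError("weight_kg must be positive")
    contacts = split_contacts(regional.total, contact_threshold_frac)
    if not contacts:
        raise InsufficientEventsError("no contact episodes found in total trace")
    ratios = {}
    for region in REGIONS:
        trace = regional.region(region)
        peaks = [float(trace[a:b].max()) for a, b in contacts]
        ratios[region] = float(np.mean(peaks)) / weight_kg
    return ratios
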