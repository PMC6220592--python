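"""Fluorescence trace processing: extraction, detrending, transient detection.

The processing chain mirrors standard in vivo GCaMP analysis:

1. ``extract_trace`` — average pixels in an ROI per frame, subtract a
   background ROI.
2. ``detrend`` — remove slow drift by subtracting, at every time point, the
   8th percentile of the fluorescence distribution in a +/-15 s window.
3. ``estimate_baseline`` — iterative sigma-clipping replaces manual selection
   of transient-free stretches; yields baseline mean mu and SD sigma.
4. ``detect_transients`` — a calcium transient is a contiguous run of frames
   exceeding mu + 4 sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    EstimationFailedError,
    IncompatibleInputsError,
    InvalidConfigError,
    InvalidRoiError,
)

__all__ = [
    "FluorescenceTrace",
    "DetrendParams",
    "BaselineEstimate",
    "TransientEvent",
    "extract_trace",
    "detrend",
    "estimate_baseline",
    "detect_transients",
    "to_dff",
    "event_frequency",
    "peak_times_s",
]

TRACE_STATES = ("raw", "background_subtracted", "detrended", "dff")


@dataclass(frozen=True)
class FluorescenceTrace:
    """One ROI's fluorescence time series.

    Parameters
    ----------
    values
        Fluorescence samples (a.u. or ΔF/F). Must be finite, length >= 1.
    frame_interval_s
        Seconds per frame (e.g. 0.242 for spine imaging, 0.390 for
        population imaging).
    roi_id
        Identifier of the source ROI.
    state
        Processing state, one of ``raw``, ``background_subtracted``,
        ``detrended``, ``dff``.
    """

    values: np.ndarray
    frame_interval_s: float
    roi_id: str = "roi"
    state: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise InvalidConfigError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise InvalidConfigError("trace contains non-finite values")
        if not (np.isfinite(self.frame_interval_s) and self.frame_interval_s > 0):
            raise InvalidConfigError("frame_interval_s must be positive")
        if self.state not in TRACE_STATES:
            raise InvalidConfigError(f"unknown trace state {self.state!r}")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        """Frame-center time stamps in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval_s


@dataclass(frozen=True)
class DetrendParams:
    """Sliding-percentile detrend parameters: +/-15 s window, 8th percentile."""

    half_window_s: float = 15.0
    percentile: float = 8.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.half_window_s) and self.half_window_s > 0):
            raise InvalidConfigError("half_window_s must be positive")
        if not (0 < self.percentile < 100):
            raise InvalidConfigError("percentile must lie in (0, 100)")


@dataclass(frozen=True)
class BaselineEstimate:
    """Baseline mean/SD from transient-free frames plus the frames used."""

    mu: float
    sigma: float
    quiet_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidConfigError("sigma must be nonnegative")


@dataclass(frozen=True)
class TransientEvent:
    """One detected Ca2+ transient (frame indices, inclusive offset)."""

    onset_frame: int
    peak_frame: int
    offset_frame: int
    peak_value: float
    label: str = "unclassified"

    def __post_init__(self) -> None:
        if not (self.onset_frame <= self.peak_frame <= self.offset_frame):
            raise InvalidConfigError("event frames must satisfy onset <= peak <= offset")

    def with_label(self, label: str) -> "TransientEvent":
        return replace(self, label=label)


def extract_trace(
    stack: np.ndarray,
    roi,
    background,
    frame_interval_s: float = 0.390,
) -> FluorescenceTrace:
    """Average an ROI per frame and subtract the background ROI average.

    ``stack`` is T x Y x X (or T x Z x Y x X with voxel ROIs); ``roi`` and
    ``background`` are Roi objects (or boolean masks) that must be disjoint
    and within bounds.
    """
    stack = np.asarray(stack)
    roi_mask = _as_mask(roi, stack.shape[1:])
    bg_mask = _as_mask(background, stack.shape[1:])
    if not roi_mask.any() or not bg_mask.any():
        raise InvalidRoiError("ROI masks must be non-empty")
    if np.any(roi_mask & bg_mask):
        raise InvalidRoiError("ROI and background masks overlap")
    flat = stack.reshape(stack.shape[0], -1)
    roi_mean = flat[:, roi_mask.ravel()].mean(axis=1)
    bg_mean = flat[:, bg_mask.ravel()].mean(axis=1)
    roi_id = getattr(roi, "id", "roi")
    return FluorescenceTrace(
        roi_mean - bg_mean, frame_interval_s, roi_id=roi_id, state="background_subtracted"
    )


def _as_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != tuple(shape):
            raise InvalidRoiError("mask shape does not match stack frame shape")
        return roi
    # Roi object with a to_mask method
    return roi.to_mask(shape)


def detrend(trace: FluorescenceTrace, params: DetrendParams | None = None) -> FluorescenceTrace:
    """Subtract the sliding-window 8th percentile from each sample.

    At frame t, the percentile is taken over all frames within
    ``half_window_s`` of t; windows are truncated (never padded) at the
    recording edges. Equivalent to a per-frame brute-force re-computation.
    """
    params = params or DetrendParams()
    v = trace.values
    n = v.size
    w = int(round(params.half_window_s / trace.frame_interval_s))
    baseline = np.empty(n)
    full = 2 * w + 1
    if w > 0 and n >= full:
        windows = sliding_window_view(v, full)
        baseline[w : n - w] = np.percentile(windows, params.percentile, axis=1)
        edges = list(range(w)) + list(range(n - w, n))
    else:
        edges = list(range(n))
    for t in edges:
        lo, hi = max(0, t - w), min(n, t + w + 1)
        baseline[t] = np.percentile(v[lo:hi], params.percentile)
    return FluorescenceTrace(
        v - baseline, trace.frame_interval_s, roi_id=trace.roi_id, state="detrended"
    )


def estimate_baseline(
    trace: FluorescenceTrace,
    clip_k: float = 3.0,
    max_iter: int = 10,
    min_quiet_frac: float = 0.10,
) -> BaselineEstimate:
    """Estimate baseline mean/SD by iterative one-sided sigma clipping.

    Starting from all frames, frames exceeding mu + clip_k * sigma are
    dropped and (mu, sigma) recomputed, until convergence or ``max_iter``
    passes. Replaces manual selection of transient-free regions.
    """
    if clip_k <= 0 or max_iter < 1:
        raise InvalidConfigError("clip_k must be > 0 and max_iter >= 1")
    v = trace.values
    mask = np.ones(v.size, dtype=bool)
    for _ in range(max_iter):
        mu = float(v[mask].mean())
        sigma = float(v[mask].std())
        new_mask = v <= mu + clip_k * sigma
        if new_mask.sum() < max(2, int(np.ceil(min_quiet_frac * v.size))):
            raise EstimationFailedError(
                "fewer than the minimum fraction of quiet frames remain; "
                "trace may be one long transient"
            )
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    mu = float(v[mask].mean())
    sigma = float(v[mask].std())
    return BaselineEstimate(mu=mu, sigma=sigma, quiet_mask=mask)


def detect_transients(
    trace: FluorescenceTrace,
    baseline: BaselineEstimate,
    k_sigma: float = 4.0,
    merge_gap: int = 1,
) -> list[TransientEvent]:
    """Detect transients as runs of frames above mu + k_sigma * sigma.

    Runs separated by fewer than ``merge_gap`` sub-threshold frames are
    merged. Peak is the earliest maximum within a run. When sigma is zero
    (noiseless trace) the threshold falls back to mu + a tiny epsilon so
    that any frame above baseline is flagged.
    """
    if k_sigma < 0:
        raise InvalidConfigError("k_sigma must be nonnegative")
    v = trace.values
    if baseline.sigma > 0:
        thr = baseline.mu + k_sigma * baseline.sigma
    else:
        thr = baseline.mu + 1e-9 * max(1.0, abs(baseline.mu))
    above = v > thr
    events: list[TransientEvent] = []
    runs = _runs(above)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    for start, end in merged:
        seg = v[start : end + 1]
        peak = start + int(np.argmax(seg))  # argmax returns earliest maximum
        events.append(
            TransientEvent(
                onset_frame=start,
                peak_frame=peak,
                offset_frame=end,
                peak_value=float(v[peak]),
            )
        )
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def to_dff(trace: FluorescenceTrace, baseline: BaselineEstimate) -> FluorescenceTrace:
    """Normalize to ΔF/F = (F - mu) / mu when mu > 0.

    Traces with a nonpositive baseline are returned unchanged (in
    subtracted units) with a warning, since the ratio is meaningless there.
    """
    if baseline.mu <= 0:
        warnings.warn(
            f"ROI {trace.roi_id}: baseline mu <= 0, keeping subtracted units",
            RuntimeWarning,
            stacklevel=2,
        )
        return trace
    return FluorescenceTrace(
        (trace.values - baseline.mu) / baseline.mu,
        trace.frame_interval_s,
        roi_id=trace.roi_id,
        state="dff",
    )


def event_frequency(events, duration_s: float) -> float:
    """Event count divided by recording duration, in Hz."""
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be positive")
    return len(events) / duration_s


def peak_times_s(events, frame_interval_s: float) -> np.ndarray:
    """Peak times at frame centers, in seconds."""
    if frame_interval_s <= 0:
        raise IncompatibleInputsError("frame_interval_s must be positive")
    return np.array([(e.peak_frame + 0.5) * frame_interval_s for e in events])
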