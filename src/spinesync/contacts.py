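"""Microglia-on-spine contact detection from two-channel Z-stacks.

A contact is red/green fluorescence overlap within the spine ROI; a frame
counts as a real contact only when the overlap is present in at least two
Z sections (the >= 2-Z rule), which rejects chance overlap confined to a
single optical section. Flagged frames are merged into contact epochs and
summarized as contacts per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibleInputsError, InvalidConfigError

__all__ = [
    "ContactEpoch",
    "threshold_channel",
    "detect_contacts",
    "flags_to_epochs",
    "contact_rate",
]


@dataclass(frozen=True)
class ContactEpoch:
    """One contact interval (inclusive frame bounds) with per-frame Z-support.

    ``z_support`` holds, for each frame of the epoch, the number of Z
    sections with three-way (spine ROI & red & green) overlap. Frames
    bridged by gap merging may have support below the detection minimum.
    """

    spine_id: str
    start_frame: int
    end_frame: int
    z_support: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise InvalidConfigError("epoch must satisfy start <= end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, frame_interval_s: float) -> float:
        return self.n_frames * frame_interval_s


def threshold_channel(
    stack: np.ndarray, method: str = "percentile", level: float = 99.0
) -> np.ndarray:
    """Binarize one channel of a T x Z x Y x X stack.

    ``percentile`` computes the threshold per frame over the frame's voxels
    (robust to slow bleaching); ``fixed`` applies one absolute level.
    A voxel is foreground when its intensity strictly exceeds the threshold.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise IncompatibleInputsError("channel stack must be T x Z x Y x X")
    if method == "percentile":
        if not (0 < level < 100):
            raise InvalidConfigError("percentile level must lie in (0, 100)")
        thr = np.percentile(stack.reshape(stack.shape[0], -1), level, axis=1)
        return stack > thr[:, None, None, None]
    if method == "fixed":
        if level < 0:
            raise InvalidConfigError("fixed threshold must be nonnegative")
        return stack > level
    raise InvalidConfigError(f"unknown threshold method {method!r}")


def detect_contacts(
    red_mask: np.ndarray,
    green_mask: np.ndarray,
    spine_roi,
    min_z: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag frames where spine/red/green overlap spans >= ``min_z`` Z sections.

    ``spine_roi`` is a (Z, Y, X) boolean mask or an Roi of voxels. Returns
    ``(flags, z_support)``: per-frame booleans and per-frame counts of Z
    sections containing at least one overlapping voxel.
    """
    red_mask = np.asarray(red_mask, dtype=bool)
    green_mask = np.asarray(green_mask, dtype=bool)
    if red_mask.shape != green_mask.shape or red_mask.ndim != 4:
        raise IncompatibleInputsError("red and green masks must share a TxZxYxX shape")
    if min_z < 1:
        raise InvalidConfigError("min_z must be >= 1")
    if isinstance(spine_roi, np.ndarray):
        spine = spine_roi.astype(bool)
    else:
        spine = spine_roi.to_mask(red_mask.shape[1:])
    if spine.shape != red_mask.shape[1:]:
        raise IncompatibleInputsError("spine ROI shape must match the stack's Z,Y,X")
    overlap = red_mask & green_mask & spine[None]
    z_support = overlap.any(axis=(2, 3)).sum(axis=1)
    return z_support >= min_z, z_support


def flags_to_epochs(
    flags: np.ndarray,
    max_gap_frames: int = 2,
    spine_id: str = "spine0",
    z_support: np.ndarray | None = None,
) -> list[ContactEpoch]:
    """Merge flagged frames into epochs, bridging gaps <= ``max_gap_frames``."""
    flags = np.asarray(flags, dtype=bool)
    if flags.ndim != 1 or flags.size < 1:
        raise InvalidConfigError("flags must be a non-empty 1-D boolean array")
    if max_gap_frames < 0:
        raise InvalidConfigError("max_gap_frames must be nonnegative")
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    merged: list[list[int]] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if merged and s - merged[-1][1] - 1 <= max_gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        ContactEpoch(
            spine_id=spine_id,
            start_frame=s,
            end_frame=e,
            z_support=None if z_support is None else np.asarray(z_support)[s : e + 1],
        )
        for s, e in merged
    ]


def contact_rate(epochs: list[ContactEpoch], duration_s: float) -> float:
    """Contacts per hour over a recording of ``duration_s`` seconds."""
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be positive")
    return len(epochs) * 3600.0 / duration_s
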