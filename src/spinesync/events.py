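"""Classify spine transients as local synaptic vs back-propagating (BP).

A back-propagating action potential invades the dendrite and every spine on
it, so it appears as near-simultaneous transients in the spine and its
parent dendrite; a local synaptic event produces a spine transient only.
Classification therefore matches spine event peaks against dendrite event
peaks within a coincidence window (default +/-1 frame).

Also computes per-epoch (before / during / after microglial contact) event
frequencies and the contacted-vs-noncontacted basal-rate comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibleInputsError, InvalidConfigError
from .traces import TransientEvent
from . import stats

__all__ = [
    "EpochSet",
    "classify_spine_events",
    "epoch_frequencies",
    "compare_contacted_vs_noncontacted",
]


@dataclass(frozen=True)
class EpochSet:
    """Before / during / after intervals in seconds, non-overlapping."""

    before: tuple[float, float]
    during: tuple[float, float]
    after: tuple[float, float]

    def __post_init__(self) -> None:
        spans = [self.before, self.during, self.after]
        for s, e in spans:
            if not e > s:
                raise InvalidConfigError("each epoch must have positive duration")
        for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
            if e1 > s2:
                raise InvalidConfigError("epochs must be ordered and non-overlapping")

    @classmethod
    def around_contact(
        cls, contact_start_s: float, contact_end_s: float, recording_duration_s: float
    ) -> "EpochSet":
        """Equal-length before/after windows abutting the contact epoch.

        Windows are truncated at the recording edges; the contact epoch must
        leave room for nonzero before and after spans.
        """
        length = contact_end_s - contact_start_s
        before = (max(0.0, contact_start_s - length), contact_start_s)
        after = (contact_end_s, min(recording_duration_s, contact_end_s + length))
        return cls(before=before, during=(contact_start_s, contact_end_s), after=after)


def classify_spine_events(
    spine_events: list[TransientEvent],
    dendrite_events: list[TransientEvent],
    coincidence_frames: int = 1,
    spine_frame_interval_s: float | None = None,
    dendrite_frame_interval_s: float | None = None,
) -> list[TransientEvent]:
    """Label each spine event ``bp`` or ``local`` by dendritic coincidence.

    A spine event is ``bp`` when an unmatched dendrite event peak lies within
    ``coincidence_frames`` of its peak; each dendrite event can support at
    most one spine event. Matching is greedy in spine-peak order, choosing
    the nearest available dendrite peak (the earlier one on ties).
    """
    if (
        spine_frame_interval_s is not None
        and dendrite_frame_interval_s is not None
        and not np.isclose(spine_frame_interval_s, dendrite_frame_interval_s)
    ):
        raise IncompatibleInputsError("spine and dendrite traces must share a frame interval")
    if coincidence_frames < 0:
        raise InvalidConfigError("coincidence_frames must be nonnegative")
    dend_peaks = sorted((e.peak_frame, i) for i, e in enumerate(dendrite_events))
    used: set[int] = set()
    labeled = []
    for ev in sorted(spine_events, key=lambda e: e.peak_frame):
        best = None
        for frame, idx in dend_peaks:
            if idx in used:
                continue
            dist = abs(frame - ev.peak_frame)
            if dist <= coincidence_frames and (best is None or dist < best[0]):
                best = (dist, frame, idx)
        if best is not None:
            used.add(best[2])
            labeled.append(ev.with_label("bp"))
        else:
            labeled.append(ev.with_label("local"))
    return labeled


def epoch_frequencies(
    events: list[TransientEvent],
    epochs: EpochSet,
    frame_interval_s: float,
) -> dict[str, tuple[float, float, float]]:
    """Per-label (f_before, f_during, f_after) event frequencies in Hz.

    An event belongs to an epoch when its peak time (frame center) lies in
    [start, end). Returns entries for every label present plus ``all``.
    """
    if frame_interval_s <= 0:
        raise InvalidConfigError("frame_interval_s must be positive")
    out: dict[str, tuple[float, float, float]] = {}
    labels = sorted({e.label for e in events}) + ["all"]
    for label in labels:
        sel = events if label == "all" else [e for e in events if e.label == label]
        freqs = []
        for start, end in (epochs.before, epochs.during, epochs.after):
            span = end - start
            if span <= 0:
                raise InvalidConfigError("epoch has nonpositive duration")
            t = np.array([(e.peak_frame + 0.5) * frame_interval_s for e in sel])
            n = int(((t >= start) & (t < end)).sum()) if t.size else 0
            freqs.append(n / span)
        out[label] = tuple(freqs)
    return out


def compare_contacted_vs_noncontacted(
    basal_rates_contacted, basal_rates_noncontacted
) -> stats.StatResult:
    """Rank-sum comparison of basal transient rates by contact status.

    Tests whether spines that later receive a microglial contact already
    have a different basal rate than spines that never do.
    """
    a = np.asarray(basal_rates_contacted, dtype=float)
    b = np.asarray(basal_rates_noncontacted, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidConfigError("both groups must be non-empty")
    return stats.compare(a, b, design="unpaired", family="rank")
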