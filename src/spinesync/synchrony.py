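"""Pairwise neuronal synchrony from binned transient-peak trains.

Each neuron's transient peak times are grouped into 242-ms bins; the
correlation coefficient (C.C.) between two neurons is the Pearson
correlation of their binary bin-occupancy vectors. Synchrony structure is
summarized as the mean C.C. of nearby pairs (within 100 um) and as the
Pearson relationship between C.C. and inter-neuron distance, whose fitted
``r`` is negative when nearby neurons fire together more than distant ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    EmptySelectionError,
    IncompatibleInputsError,
    InsufficientDataError,
    InvalidConfigError,
    UndefinedFitError,
)
from . import stats
from .traces import TransientEvent

__all__ = [
    "BinnedEventTrain",
    "PairCorrelation",
    "DistanceSynchronyFit",
    "bin_peaks",
    "pairwise_cc",
    "mean_cc_within",
    "cc_vs_distance",
    "per_animal_slope_test",
]

DEFAULT_BIN_WIDTH_S = 0.242


@dataclass(frozen=True)
class BinnedEventTrain:
    """Event-bin occupancy for one neuron at fixed bin width."""

    bins: np.ndarray
    bin_width_s: float = DEFAULT_BIN_WIDTH_S
    neuron_id: str = "n"

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0:
            raise InvalidConfigError("bin_width_s must be positive")
        object.__setattr__(self, "bins", np.asarray(self.bins))


@dataclass(frozen=True)
class PairCorrelation:
    """C.C. and centroid distance for one unordered neuron pair."""

    id_a: str
    id_b: str
    cc: float
    distance_um: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise InvalidConfigError("distance must be nonnegative")
        if not -1.0 - 1e-12 <= self.cc <= 1.0 + 1e-12:
            raise InvalidConfigError("cc must lie in [-1, 1]")


@dataclass(frozen=True)
class DistanceSynchronyFit:
    """Pearson r/p and least-squares slope of C.C. against distance."""

    r: float
    p: float
    n_pairs: int
    slope_per_um: float
    degenerate: bool = False


def bin_peaks(
    events: list[TransientEvent],
    frame_interval_s: float,
    duration_s: float,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    neuron_id: str = "n",
    binary: bool = True,
) -> BinnedEventTrain:
    """Group transient peak times (frame centers) into fixed-width bins.

    Bin index is ``floor(peak_time / bin_width_s)``; occupancy is binary by
    default (>= 1 peak in the bin), or a count with ``binary=False``. The
    242-ms default matches the acquisition bin width even for 390-ms
    population frames.
    """
    if bin_width_s <= 0 or duration_s <= 0 or frame_interval_s <= 0:
        raise InvalidConfigError("bin width, duration and frame interval must be positive")
    n_bins = int(math.ceil(duration_s / bin_width_s))
    counts = np.zeros(n_bins, dtype=np.int64)
    for e in events:
        t = (e.peak_frame + 0.5) * frame_interval_s
        if not (0 <= t < duration_s):
            raise InvalidConfigError("peak time outside [0, duration_s)")
        counts[int(t // bin_width_s)] += 1
    bins = (counts > 0).astype(np.int8) if binary else counts
    return BinnedEventTrain(bins=bins, bin_width_s=bin_width_s, neuron_id=neuron_id)


def pairwise_cc(
    trains: list[BinnedEventTrain], positions_um: np.ndarray
) -> list[PairCorrelation]:
    """Pearson C.C. for every unordered neuron pair, with centroid distance.

    Pairs where either train is constant (all-zero or all-one) get cc = 0
    with ``degenerate=True`` rather than NaN, keeping pair tables complete.
    """
    positions_um = np.asarray(positions_um, dtype=float)
    if len(trains) != positions_um.shape[0]:
        raise IncompatibleInputsError("one position per train is required")
    lengths = {t.bins.size for t in trains}
    if len(lengths) > 1:
        raise IncompatibleInputsError("all trains must have equal length")
    mat = np.array([t.bins for t in trains], dtype=float)
    sd = mat.std(axis=1)
    centered = mat - mat.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / mat.shape[1]
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc_mat = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    pairs = []
    n = len(trains)
    for i in range(n):
        for j in range(i + 1, n):
            degenerate = sd[i] == 0 or sd[j] == 0
            cc = 0.0 if degenerate else float(np.clip(cc_mat[i, j], -1.0, 1.0))
            dist = float(np.linalg.norm(positions_um[i] - positions_um[j]))
            pairs.append(
                PairCorrelation(
                    id_a=trains[i].neuron_id,
                    id_b=trains[j].neuron_id,
                    cc=cc,
                    distance_um=dist,
                    degenerate=degenerate,
                )
            )
    return pairs


def mean_cc_within(pairs: list[PairCorrelation], max_distance_um: float = 100.0) -> float:
    """Mean C.C. over pairs separated by at most ``max_distance_um``."""
    sel = [p.cc for p in pairs if p.distance_um <= max_distance_um]
    if not sel:
        raise EmptySelectionError(f"no pairs within {max_distance_um} um")
    return float(np.mean(sel))


def cc_vs_distance(pairs: list[PairCorrelation]) -> DistanceSynchronyFit:
    """Pearson r, two-sided p and least-squares slope of C.C. on distance."""
    if len(pairs) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    cc = np.array([p.cc for p in pairs])
    d = np.array([p.distance_um for p in pairs])
    if np.ptp(d) == 0:
        raise UndefinedFitError("distances have zero variance")
    if np.ptp(cc) == 0:
        return DistanceSynchronyFit(r=0.0, p=1.0, n_pairs=len(pairs), slope_per_um=0.0,
                                    degenerate=True)
    res = sps.linregress(d, cc)
    return DistanceSynchronyFit(
        r=float(res.rvalue), p=float(res.pvalue), n_pairs=len(pairs),
        slope_per_um=float(res.slope),
    )


def per_animal_slope_test(fits: list[DistanceSynchronyFit]):
    """Average per-animal r values and test them against zero.

    ``fits`` holds one distance-synchrony fit per animal. Returns
    ``(mean_r, sem_r, StatResult)`` with a one-sample t-test of the r values
    against 0, mirroring per-mouse slope averaging.
    """
    if len(fits) < 2:
        raise InsufficientDataError("need fits from at least 2 animals")
    r = np.array([f.r for f in fits], dtype=float)
    mean_r = float(r.mean())
    sem_r = float(r.std(ddof=1) / np.sqrt(r.size))
    result = stats.one_sample(r, popmean=0.0)
    return mean_r, sem_r, result
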