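"""ROI definition via neighbor-correlation of pixel time series.

Active cells are found by correlating each pixel's fluorescence time series
with its 4-neighbors: pixels inside a responsive cell co-fluctuate, so the
mean neighbor correlation is high at the cell and near zero in background.
Thresholding the correlation image and keeping connected components within
plausible soma area bounds yields the ROIs. Note the procedure can only find
cells that actually fluoresce; silent cells are invisible to it.

Spine and dendrite ROIs are expected to be supplied by the user (drawn
masks); this module does not auto-segment spines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import InsufficientDataError, InvalidConfigError, InvalidRoiError

__all__ = ["Roi", "CorrelationImage", "correlation_image", "segment_somata", "background_roi"]


@dataclass(frozen=True)
class Roi:
    """A region of interest: a set of (y, x) pixels or (z, y, x) voxels."""

    id: str
    kind: str  # soma | spine | dendrite | background
    pixels: frozenset
    centroid_um: tuple

    @classmethod
    def from_pixels(cls, id: str, kind: str, pixels, pixel_size_um: float = 1.0) -> "Roi":
        pixels = frozenset(tuple(int(c) for c in p) for p in pixels)
        if not pixels:
            raise InvalidRoiError("ROI mask must be non-empty")
        arr = np.array(sorted(pixels), dtype=float)
        # centroid of the trailing two axes (y, x) in micrometres, x first
        cy, cx = arr[:, -2].mean(), arr[:, -1].mean()
        return cls(id=id, kind=kind, pixels=pixels,
                   centroid_um=(cx * pixel_size_um, cy * pixel_size_um))

    @classmethod
    def from_mask(cls, id: str, kind: str, mask: np.ndarray, pixel_size_um: float = 1.0) -> "Roi":
        return cls.from_pixels(id, kind, zip(*np.nonzero(mask)), pixel_size_um)

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    def to_mask(self, shape) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        pts = sorted(self.pixels)
        for p in pts:
            if len(p) != len(shape) or any(c < 0 or c >= s for c, s in zip(p, shape)):
                raise InvalidRoiError(f"ROI {self.id} exceeds stack bounds")
        idx = tuple(np.array([p[d] for p in pts]) for d in range(len(shape)))
        mask[idx] = True
        return mask


@dataclass(frozen=True)
class CorrelationImage:
    """Per-pixel mean Pearson correlation with available 4-neighbors."""

    values: np.ndarray


def correlation_image(stack: np.ndarray) -> CorrelationImage:
    """Mean temporal Pearson correlation of each pixel with its 4-neighbors.

    Border pixels average over the neighbors that exist; any pair involving
    a constant-in-time pixel contributes correlation 0 (never NaN).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidConfigError("stack must be T x Y x X")
    T = stack.shape[0]
    if T < 10:
        raise InsufficientDataError("correlation image needs at least 10 frames")
    x = stack - stack.mean(axis=0)
    norm = np.sqrt((x**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norm > 0, x / norm, 0.0)
    # correlation with the right neighbor and the lower neighbor
    corr_x = (u[:, :, :-1] * u[:, :, 1:]).sum(axis=0)
    corr_y = (u[:, :-1, :] * u[:, 1:, :]).sum(axis=0)
    H, W = stack.shape[1:]
    total = np.zeros((H, W))
    count = np.zeros((H, W))
    total[:, :-1] += corr_x
    total[:, 1:] += corr_x
    count[:, :-1] += 1
    count[:, 1:] += 1
    total[:-1, :] += corr_y
    total[1:, :] += corr_y
    count[:-1, :] += 1
    count[1:, :] += 1
    values = np.clip(total / count, -1.0, 1.0)
    return CorrelationImage(values=values)


def segment_somata(
    cimg: CorrelationImage,
    threshold: float = 0.3,
    area_bounds_um2: tuple[float, float] = (30.0, 300.0),
    pixel_size_um: float = 0.830,
) -> list[Roi]:
    """Threshold the correlation image and keep components within area bounds.

    Components of ``{cimg >= threshold}`` (4-connectivity) whose area in um^2
    falls in ``area_bounds_um2`` become soma ROIs. The area gate stands in
    for the visual confirmation step of the original semi-automated
    procedure. IDs are assigned in raster order of each component's top-left
    pixel.
    """
    if not (0 < threshold < 1):
        raise InvalidConfigError("threshold must lie in (0, 1)")
    lo, hi = area_bounds_um2
    if lo >= hi:
        raise InvalidConfigError("area bounds must satisfy min < max")
    fg = cimg.values >= threshold
    labels = measure.label(fg, connectivity=1)
    comps = []
    px_area = pixel_size_um**2
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if not (lo <= ys.size * px_area <= hi):
            continue
        top_left = (ys.min(), xs[ys == ys.min()].min())
        comps.append((top_left, list(zip(ys.tolist(), xs.tolist()))))
    comps.sort(key=lambda c: c[0])
    return [
        Roi.from_pixels(f"roi{i:03d}", "soma", pixels, pixel_size_um)
        for i, (_, pixels) in enumerate(comps)
    ]


def background_roi(rois: list[Roi], shape, pixel_size_um: float = 0.830, margin_px: int = 2) -> Roi:
    """Pixels away from every ROI (by ``margin_px``), for background subtraction."""
    from scipy.ndimage import binary_dilation

    occupied = np.zeros(shape, dtype=bool)
    for roi in rois:
        occupied |= roi.to_mask(shape)
    occupied = binary_dilation(occupied, iterations=margin_px) if occupied.any() else occupied
    bg = ~occupied
    if not bg.any():
        raise InvalidRoiError("no background pixels remain")
    return Roi.from_mask("background", "background", bg, pixel_size_um)
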