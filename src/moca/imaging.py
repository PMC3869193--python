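"""Droplet ROI location, transmission extraction, microcolony counting.

The native data model is one bright-field field of view per droplet (stacks
of shape ``(n_droplets, n_frames, H, W)``).  Light transmission — the mean
gray level over a measurement disk slightly smaller than the hydrophilic
spot — serves as the growth proxy: the lower the transmission, the larger
the population.  Pixel convention: 0-based (row, col), pixel centers at
integer coordinates, radii in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from ._disks import disk_mask
from .scene import DropletLayout

__all__ = [
    "DropletROI",
    "DropletTimeSeries",
    "DetectionError",
    "locate_droplets",
    "extract_transmission",
    "count_microcolonies",
]

#: Fraction of the ROI radius actually averaged; excludes the droplet rim,
#: where the hydrophilic/hydrophobic boundary produces edge artifacts.
DEFAULT_SHRINK = 0.9


class DetectionError(RuntimeError):
    """Droplet detection failed on a frame (no usable bright region)."""


@dataclass(frozen=True)
class DropletROI:
    """Circular region of interest for one droplet within its frame."""

    droplet_id: int
    center: tuple[float, float]  # (row, col) pixels
    radius_px: float
    shrink_factor: float = DEFAULT_SHRINK

    def measurement_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the shrunk measurement disk, clipped to ``shape``."""
        return disk_mask(shape, self.center, self.shrink_factor * self.radius_px)


@dataclass
class DropletTimeSeries:
    """Raw mean-transmission time series for one droplet."""

    droplet_id: int
    times_h: np.ndarray
    raw_mean_intensity: np.ndarray
    pixel_count: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.raw_mean_intensity, dtype=float)
        if t.ndim != 1 or len(t) != len(v):
            raise ValueError("times and intensities must be 1-D and equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.times_h = t
        self.raw_mean_intensity = v


def _detect_one(frame: np.ndarray, droplet_id: int) -> DropletROI:
    """Detect the bright spot disk in a single frame.

    Thresholds at the frame's 75th intensity percentile, keeps the largest
    connected component, and fits center = centroid, radius = sqrt(area/π).
    """
    thr = np.percentile(frame, 75)
    fg = frame >= thr
    if fg.all():
        raise DetectionError(
            f"droplet {droplet_id}: frame has no contrast (uniform intensity)"
        )
    lbl = measure.label(fg, connectivity=2)
    if lbl.max() == 0:
        raise DetectionError(f"droplet {droplet_id}: no bright region found")
    areas = np.bincount(lbl.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    area = float(areas[best - 1])
    if area < 0.05 * frame.size:
        raise DetectionError(
            f"droplet {droplet_id}: largest bright component covers "
            f"{100 * area / frame.size:.1f}% of the frame (< 5%)"
        )
    ys, xs = np.nonzero(lbl == best)
    center = (float(ys.mean()), float(xs.mean()))
    radius = float(np.sqrt(area / np.pi))
    return DropletROI(droplet_id=droplet_id, center=center, radius_px=radius)


def locate_droplets(
    stack: np.ndarray,
    layout: DropletLayout | None = None,
    mode: str = "grid",
) -> list[DropletROI]:
    """One ROI per droplet from a ``(n_droplets, n_frames, H, W)`` stack.

    ``grid`` mode places the ROI from the layout geometry (the frame is
    centered on its droplet's spot); ``detect`` mode finds the bright spot
    disk in each droplet's first frame.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError("expected a stack of shape (n_droplets, n_frames, H, W)")
    n_droplets = stack.shape[0]
    if mode == "grid":
        if layout is None:
            raise ValueError("grid mode requires a DropletLayout")
        if stack.shape[2:] != layout.frame_shape:
            raise ValueError(
                f"stack frames {stack.shape[2:]} do not match the layout frame "
                f"shape {layout.frame_shape}"
            )
        return [
            DropletROI(
                droplet_id=d, center=layout.frame_center, radius_px=layout.spot_radius_px
            )
            for d in range(n_droplets)
        ]
    if mode == "detect":
        return [_detect_one(stack[d, 0], d) for d in range(n_droplets)]
    raise ValueError(f"mode must be 'grid' or 'detect', got {mode!r}")


def extract_transmission(
    stack: np.ndarray,
    rois: list[DropletROI],
    times_h,
) -> list[DropletTimeSeries]:
    """Reduce each droplet's frames to its mean transmission over time.

    Per frame, the mean gray level over the ROI's shrunk measurement disk;
    pixels outside the disk never contribute.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError("expected a stack of shape (n_droplets, n_frames, H, W)")
    times = np.asarray(times_h, dtype=float)
    if len(times) != stack.shape[1]:
        raise ValueError("times length does not match the number of frames")
    out = []
    shape = stack.shape[2:]
    for roi in rois:
        mask = roi.measurement_mask(shape)
        npx = int(mask.sum())
        if npx == 0:
            raise ValueError(
                f"droplet {roi.droplet_id}: empty measurement disk for frame "
                f"shape {shape}"
            )
        means = stack[roi.droplet_id][:, mask].mean(axis=1)
        out.append(
            DropletTimeSeries(
                droplet_id=roi.droplet_id,
                times_h=times,
                raw_mean_intensity=means.astype(float),
                pixel_count=npx,
            )
        )
    return out


def count_microcolonies(
    frame: np.ndarray,
    roi: DropletROI,
    min_area: int = 20,
    rel_threshold: float = 0.85,
):
    """Count distinct dark microcolonies within a droplet's measurement disk.

    Pixels darker than ``rel_threshold`` × the median in-disk intensity are
    segmented into 8-connected components; components smaller than
    ``min_area`` pixels are discarded.  The median-relative threshold makes
    the count insensitive to per-droplet illumination differences.

    Returns ``(count, centroids)`` with centroids as (row, col) tuples;
    a blank droplet returns ``(0, [])``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    mask = roi.measurement_mask(frame.shape)
    if not mask.any():
        raise ValueError("empty measurement disk")
    med = float(np.median(frame[mask]))
    fg = (frame < rel_threshold * med) & mask
    lbl = measure.label(fg, connectivity=2)
    centroids = []
    for region in measure.regionprops(lbl):
        if region.area >= min_area:
            centroids.append(tuple(region.centroid))
    return len(centroids), centroids
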