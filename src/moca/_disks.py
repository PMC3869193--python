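"""Disk geometry helpers shared by the scene renderer and the extractor.

Pixel convention: 0-based (row, col) coordinates, pixel centers at integer
positions, radii in pixels.
"""

from __future__ import annotations

import math

import numpy as np

_STAMP_STEP = 0.05
_STAMP_CACHE: dict[int, tuple[np.ndarray, float]] = {}


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius`` of ``center``."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def coverage_stamp(radius: float) -> tuple[np.ndarray, int]:
    """Area-exact antialiased coverage of a disk of ``radius``, centered.

    Returns ``(cov, half)`` where ``cov`` is a (2·half+1)² array of per-pixel
    coverage fractions in [0, 1] summing exactly to π·radius², so a disk
    smaller than a pixel still contributes its true area.  Stamp shapes are
    cached on a radius grid of 0.05 px; the per-call area scaling is exact.
    """
    key = max(1, int(round(radius / _STAMP_STEP)))
    cached = _STAMP_CACHE.get(key)
    if cached is None:
        rq = key * _STAMP_STEP
        half = int(math.ceil(rq + 0.5))
        ax = np.arange(-half, half + 1, dtype=np.float32)
        dist = np.sqrt(ax[:, None] ** 2 + ax[None, :] ** 2)
        cov = np.clip(rq + 0.5 - dist, 0.0, 1.0)
        s = float(cov.sum())
        if len(_STAMP_CACHE) < 4096:
            _STAMP_CACHE[key] = (cov, s)
        cached = (cov, s)
    cov, s = cached
    scale = math.pi * radius * radius / s
    out = cov * scale
    if scale > 1.0:
        np.minimum(out, 1.0, out=out)
    return out, (out.shape[0] - 1) // 2


def disk_coverage_patch(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Antialiased, area-normalized coverage of an arbitrary disk, clipped
    to an array of ``shape``.  Returns ``(cov, (row_slice, col_slice))``."""
    h, w = shape
    r_out = radius + 0.5
    y0 = max(int(math.floor(center[0] - r_out)), 0)
    y1 = min(int(math.ceil(center[0] + r_out)) + 1, h)
    x0 = max(int(math.floor(center[1] - r_out)), 0)
    x1 = min(int(math.ceil(center[1] + r_out)) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return np.zeros((0, 0), dtype=np.float32), (slice(0, 0), slice(0, 0))
    yy = np.arange(y0, y1, dtype=np.float32) - center[0]
    xx = np.arange(x0, x1, dtype=np.float32) - center[1]
    dist = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    s = float(cov.sum())
    if s > 0:
        target = math.pi * radius * radius
        # unclipped area of the analytic disk; rescale only the AA excess
        scale = min(target / s, 1.0) if target < s else 1.0
        cov *= scale
    return cov, (slice(y0, y1), slice(x0, x1))


def disk_overlap_area(d, r1, r2):
    """Area of intersection of two disks with center distance ``d``.

    Vectorized over broadcastable inputs; handles containment (one disk
    inside the other) and disjoint disks.
    """
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    d, r1, r2 = np.broadcast_arrays(d, r1, r2)
    out = np.zeros(d.shape, dtype=float)

    small = np.minimum(r1, r2)
    big = np.maximum(r1, r2)
    contained = d <= big - small
    out[contained] = np.pi * small[contained] ** 2

    lens = (~contained) & (d < r1 + r2) & (small > 0)
    if np.any(lens):
        dd = d[lens]
        a = r1[lens]
        b = r2[lens]
        ca = np.clip((dd**2 + a**2 - b**2) / (2 * dd * a), -1.0, 1.0)
        cb = np.clip((dd**2 + b**2 - a**2) / (2 * dd * b), -1.0, 1.0)
        seg = a**2 * np.arccos(ca) + b**2 * np.arccos(cb)
        kern = np.clip(
            (-dd + a + b) * (dd + a - b) * (dd - a + b) * (dd + a + b), 0.0, None
        )
        out[lens] = seg - 0.5 * np.sqrt(kern)
    return out if out.ndim else float(out)
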