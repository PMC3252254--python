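"""Hard-constraint seed initialization from a prior mask.

Caudate seeds C are an erosion of the prior region R0; background seeds B
are the complement of its dilation: C = Erode_ke(R0), B = P \\ Dilate_kd(R0).
Both use a Euclidean disk structuring element. C and B are disjoint by
construction (C ⊆ R0 ⊆ Dilate_kd(R0) = P \\ B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask


@dataclass(frozen=True)
class SeedSet:
    """Disjoint caudate (C) and background (B) pixel index sets on one slice."""

    cau: np.ndarray  # boolean grid, True where p in C
    back: np.ndarray  # boolean grid, True where p in B
    degenerate: bool = False  # True if a fallback was needed

    def __post_init__(self) -> None:
        if self.cau.shape != self.back.shape:
            raise ValueError("seed grids must share one shape")
        if np.any(self.cau & self.back):
            raise ValueError("caudate and background seeds must be disjoint")

    @property
    def shape(self):
        return self.cau.shape


def disk_footprint(radius: int) -> np.ndarray:
    """Rasterized Euclidean disk: offsets with ||(dy,dx)|| <= radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def _erode(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=disk_footprint(radius))


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=disk_footprint(radius))


def init_seeds(prior: BinaryMask | np.ndarray, ke: int, kd: int) -> SeedSet:
    """Derive seeds from a 2-D prior mask by erosion (C) and dilation (B).

    If erosion empties C (prior thinner than 2*ke, frequent at the caudate
    tail), retry with ke-1 down to 1; as a last resort seed the prior's
    innermost pixel (distance-transform argmax). Such slices are flagged
    ``degenerate``. An empty B (prior dilation covering the whole grid) is
    also flagged.
    """
    r0 = prior.astype_bool() if isinstance(prior, BinaryMask) else np.asarray(prior).astype(bool)
    if r0.ndim != 2:
        raise ValueError("init_seeds expects a 2-D prior")
    if not r0.any():
        raise ValueError("prior mask is empty on this slice")

    degenerate = False
    cau = _erode(r0, ke)
    if not cau.any():
        degenerate = True
        for k in range(ke - 1, 0, -1):
            cau = _erode(r0, k)
            if cau.any():
                break
        if not cau.any():
            dist = ndimage.distance_transform_edt(r0)
            cau = np.zeros_like(r0)
            cau[np.unravel_index(np.argmax(dist), r0.shape)] = True

    back = ~_dilate(r0, kd)
    if not back.any():
        degenerate = True
    return SeedSet(cau=cau, back=back, degenerate=degenerate)
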