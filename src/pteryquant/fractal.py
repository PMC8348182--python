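"""Box-counting fractal dimension of lesion masks and their outlines.

Two irregularity measures are used for the healing scar: the area fractal
dimension (AFD), the box-counting dimension of the filled lesion mask (2.0 in
the regular, plane-filling limit), and the perimeter fractal dimension (PFD),
the box-counting dimension of the one-pixel inner boundary (1.0 for a smooth
outline).  Counts are taken on a single grid anchored at the top-left of the
mask's bounding box over a fixed ladder of box sizes, and the dimension is
the slope of the ordinary least-squares fit of log(count) against
log(1/size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kinetics import LinearTrend, fit_linear_trend
from .segmentation import BinaryMask

#: Default box-size ladder (pixels).
DEFAULT_BOX_SIZES = (2, 3, 4, 6, 8, 12, 16, 32, 64)


@dataclass
class FractalEstimate:
    kind: str  # "area" or "perimeter"
    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    dimension: float
    r2: float


def outline(mask: BinaryMask) -> BinaryMask:
    """Inner 8-connected boundary, one pixel thick.

    A foreground pixel belongs to the outline when at least one of its
    4-neighbors (including the virtual outside of the frame) is background.
    An empty mask yields an empty outline.
    """
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def box_count(mask: BinaryMask, sizes=DEFAULT_BOX_SIZES) -> np.ndarray:
    """Number of s x s grid cells containing foreground, per box size.

    The grid is anchored at the top-left corner of the mask's bounding box
    (single offset, no offset minimization).
    """
    if not mask.any():
        raise ValueError("mask is empty")
    sizes = np.asarray(sizes, dtype=int)
    if np.any(sizes < 1):
        raise ValueError("box sizes must be >= 1")
    rr, cc = np.nonzero(mask)
    cropped = mask[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
    h, w = cropped.shape
    counts = np.empty(sizes.size, dtype=int)
    for i, s in enumerate(sizes):
        s = int(s)
        ph, pw = (-h) % s, (-w) % s
        padded = np.pad(cropped, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts[i] = int(blocks.any(axis=(1, 3)).sum())
    return counts


def fractal_dimension(counts, sizes, kind: str = "area") -> FractalEstimate:
    """Box-counting dimension from (size, count) pairs.

    The dimension is the OLS slope of log(count) versus log(1/size); the r2
    of that log-log fit is reported as a diagnostic.
    """
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if sizes.size != counts.size:
        raise ValueError("sizes and counts must have equal length")
    if sizes.size < 3:
        raise ValueError("need at least 3 (size, count) pairs")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    trend = fit_linear_trend(np.log(1.0 / sizes), np.log(counts))
    return FractalEstimate(
        kind=kind,
        box_sizes=tuple(int(s) for s in sizes),
        counts=tuple(int(c) for c in counts),
        dimension=trend.slope,
        r2=trend.r2,
    )


def estimate_fractal(mask: BinaryMask, kind: str = "area", sizes=DEFAULT_BOX_SIZES) -> FractalEstimate:
    """Convenience: box-count a mask (or its outline) and fit the dimension."""
    if kind == "perimeter":
        target = outline(mask)
    elif kind == "area":
        target = mask
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return fractal_dimension(box_count(target, sizes), sizes, kind=kind)


def trend(days, dimensions) -> LinearTrend:
    """OLS time trend of a fractal dimension over days."""
    return fit_linear_trend(days, dimensions)
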