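"""Conversion of RGB micrographs into lesion / eyeball / vessel binary masks.

The lesion is revealed by sodium fluorescein under black light and appears as
a bright green object on a darker, red-dominant eyeball.  Segmentation runs in
the HSB (hue-saturation-brightness) colour space with all three channels on a
0-255 integer scale: pixels are gated by a fixed hue window covering the
fluorescein-green band and by a saturation window, and the brightness cut is
found automatically with Otsu's method on the gated brightness histogram,
floored at a fixed minimum so dim green texture never enters the mask.

All masks are plain boolean numpy arrays using 8-connectivity for component
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import color, filters, measure, restoration, transform

# A binary mask is a 2-D boolean array; connected components use 8-connectivity.
BinaryMask = np.ndarray

#: Physical pixel calibration of the acquisition setup (mm per pixel).
DEFAULT_MM_PER_PX = 2.61e-3


class SegmentationError(RuntimeError):
    """Raised when a frame cannot be segmented (e.g. no foreground at all)."""


@dataclass
class ImageMeta:
    """Acquisition metadata attached to a micrograph."""

    animal: str = ""
    group: str = ""
    day: int = 0
    eye: str = "left"  # "left" (lesioned) or "right" (contralateral control)


@dataclass
class CalibratedImage:
    """An 8-bit RGB raster with physical calibration and acquisition metadata."""

    pixels: np.ndarray
    mm_per_px: float = DEFAULT_MM_PER_PX
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class HSBWindow:
    """Colour-threshold window on the 0-255 HSB scale.

    The defaults are the fluorescein-green window: hue 55-110 (~78-155 deg),
    any saturation, brightness at least 48.  ``brightness_method`` selects how
    the brightness cut is made: ``"fixed"`` uses ``b_min``/``b_max`` directly,
    ``"otsu_within_gate"`` computes Otsu's threshold on the brightness
    histogram of the hue/saturation-gated pixels and floors it at ``b_min``.
    """

    h_min: int = 55
    h_max: int = 110
    s_min: int = 0
    s_max: int = 255
    b_min: int = 48
    b_max: int = 255
    brightness_method: str = "otsu_within_gate"

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.h_min, self.h_max, "h"),
            (self.s_min, self.s_max, "s"),
            (self.b_min, self.b_max, "b"),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"invalid {name} window [{lo}, {hi}]")
        if self.brightness_method not in ("fixed", "otsu_within_gate"):
            raise ValueError(f"unknown brightness_method {self.brightness_method!r}")


#: The default lesion window (fluorescein-green band, Otsu brightness cut).
FLUORESCEIN_WINDOW = HSBWindow()


def rgb_to_hsb(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB raster to H, S, B rasters, each on a 0-255 scale.

    Hue is the standard circular hue rescaled so that 360 deg -> 256 bins:
    pure green (0, 255, 0) maps to H = 85; S and B are the usual saturation
    and value (max channel) rescaled to 0-255.
    """
    px = np.asarray(pixels)
    if px.ndim == 3 and px.shape[2] == 3:
        pass
    elif isinstance(pixels, CalibratedImage):  # pragma: no cover - convenience
        px = pixels.pixels
    else:
        raise ValueError("expected an (H, W, 3) RGB array")
    hsv = color.rgb2hsv(px)
    h = np.round(hsv[..., 0] * 255.0).astype(np.uint8)
    s = np.round(hsv[..., 1] * 255.0).astype(np.uint8)
    b = np.round(hsv[..., 2] * 255.0).astype(np.uint8)
    return h, s, b


def otsu_threshold_from_counts(counts: np.ndarray) -> int:
    """Otsu threshold ``t`` for a 256-bin histogram of integer values.

    The returned convention is *foreground = value >= t*, i.e. ``t`` is the
    smallest value assigned to the bright class.  With fewer than two distinct
    populated bins there is nothing to separate and 0 is returned (everything
    passes).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    populated = np.flatnonzero(counts)
    if populated.size < 2:
        return 0
    t = filters.threshold_otsu(hist=(counts, np.arange(counts.size)))
    # skimage's convention is foreground = value > t; shift to >=.
    return int(t) + 1


def segment_eye_roi(image: CalibratedImage) -> BinaryMask:
    """Segment the whole eyeball as the region of interest.

    Otsu's threshold on overall brightness, keep the largest 8-connected
    bright component, fill its holes.  This ROI is the denominator of the
    percent-damaged-area computation and the photometry region.
    """
    _, _, b = rgb_to_hsb(image.pixels)
    if b.max() == b.min():
        raise SegmentationError("blank frame: no brightness contrast")
    t = filters.threshold_otsu(b)
    fg = b > t
    if not fg.any():
        raise SegmentationError("no foreground after thresholding")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    roi = labels == largest
    return ndimage.binary_fill_holes(roi)


def segment_lesion(
    image: CalibratedImage,
    window: HSBWindow | None = None,
    eye_roi: Optional[BinaryMask] = None,
) -> BinaryMask:
    """Segment the fluorescein-stained lesion inside the eye ROI.

    Pixels pass when hue and saturation fall inside the window gates and the
    brightness passes the configured cut (fixed window or Otsu-within-gate,
    floored at ``b_min``).  All connected components passing the gates are
    kept; fluorescein staining can fragment a lesion into several blobs and
    their union is the lesion.
    """
    window = window or FLUORESCEIN_WINDOW
    if eye_roi is None:
        eye_roi = segment_eye_roi(image)
    if not eye_roi.any():
        raise ValueError("eye_roi is empty")
    h, s, b = rgb_to_hsb(image.pixels)
    gate = (
        (h >= window.h_min)
        & (h <= window.h_max)
        & (s >= window.s_min)
        & (s <= window.s_max)
        & eye_roi
    )
    if window.brightness_method == "fixed":
        b_lo = window.b_min
    else:
        gated_b = b[gate]
        if gated_b.size == 0:
            warnings.warn("no pixels pass the hue/saturation gate; empty lesion mask")
            return np.zeros_like(eye_roi)
        counts = np.bincount(gated_b, minlength=256)
        b_lo = max(otsu_threshold_from_counts(counts), window.b_min)
    return gate & (b >= b_lo) & (b <= window.b_max)


def _rolling_ball_background(img: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background estimate, computed on a shrunken copy.

    For large radii the ball is rolled on a downscaled image with a
    proportionally smaller radius and the background is rescaled back, the
    standard speed-up for this operation.
    """
    shrink = max(1, int(radius // 8))
    if shrink == 1:
        return restoration.rolling_ball(img, radius=radius)
    small = transform.rescale(img, 1.0 / shrink, anti_aliasing=True, preserve_range=True)
    bg_small = restoration.rolling_ball(small, radius=max(1.0, radius / shrink))
    return transform.resize(bg_small, img.shape, preserve_range=True)


def segment_vessels(
    image: CalibratedImage,
    eye_roi: BinaryMask,
    bg_radius_px: int = 50,
    lesion_mask: Optional[BinaryMask] = None,
) -> BinaryMask:
    """Segment blood vessels from the green channel inside the eye ROI.

    The green channel is contrast-stretched (saturating 0.35% of ROI pixels
    per tail), a rolling-ball background of the given radius is subtracted,
    and the positive residual is binarized with Otsu's threshold.  The
    threshold is additionally floored at mean + 3 sd of the residual so a
    vessel-free eye yields an (almost) empty mask instead of thresholded
    noise.  Lesion pixels, which are also green-bright, are excluded from
    both the statistics and the mask.
    """
    if not eye_roi.any():
        raise ValueError("eye_roi is empty")
    stats_roi = eye_roi if lesion_mask is None else eye_roi & ~lesion_mask
    if not stats_roi.any():
        return np.zeros_like(eye_roi)
    g = image.pixels[..., 1].astype(np.float64)
    vals = g[stats_roi]
    p_lo, p_hi = np.percentile(vals, (0.35, 99.65))
    if p_hi <= p_lo:
        p_hi = p_lo + 1.0
    stretched = np.clip((g - p_lo) / (p_hi - p_lo) * 255.0, 0.0, 255.0)
    stretched[~eye_roi] = 0.0
    bg = _rolling_ball_background(stretched, float(bg_radius_px))
    residual = np.clip(stretched - bg, 0.0, None)
    res_roi = residual[stats_roi]
    if res_roi.max() <= 0:
        return np.zeros_like(eye_roi)
    t_otsu = filters.threshold_otsu(res_roi)
    # noise floor from the lower 90% of residuals, so a dense vessel bed does
    # not inflate its own threshold
    body = res_roi[res_roi <= np.percentile(res_roi, 90)]
    floor = body.mean() + 3.0 * body.std()
    return (residual > max(t_otsu, floor)) & stats_roi
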