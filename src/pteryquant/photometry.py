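"""Ocular opacity and angiogenesis indices from red/green channel analysis.

Opacity is measured indirectly as the red-channel luminosity of the eyeball:
the mode (peak) of the 256-bin red histogram inside the eye ROI.  A healthy
crystalline eye is a dark saturated red; an opaque scarred eye drifts toward
pink, so the luminosity mode tracks the loss of crystallinity.  The opacity
delta is the left-eye minus right-eye luminosity, using the intact
contralateral eye as the internal reference.

Angiogenesis is quantified as the foreground pixel count of the segmented
vessel tree, converted to microns of vessel (pixels x mm/px x 1000), and
normalized by the mean vessel extent of the basal (healthy) group to give a
dimensionless angiogenesis index IA = u_day / u_basal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import BinaryMask, CalibratedImage


@dataclass
class OpacityRecord:
    lum_left: int
    lum_right: int

    @property
    def delta_opacity(self) -> int:
        return self.lum_left - self.lum_right


@dataclass
class AngiogenesisRecord:
    vessel_px: int
    vessel_um: float
    ia: float


def red_luminosity(image: CalibratedImage, roi: BinaryMask) -> int:
    """Mode of the red-channel histogram over the ROI (256 integer bins).

    Ties are broken toward the lower bin.
    """
    if not roi.any():
        raise ValueError("roi is empty")
    red = image.pixels[..., 0][roi]
    counts = np.bincount(red, minlength=256)
    return int(np.argmax(counts))


def delta_opacity(lum_left: float, lum_right: float) -> float:
    """Opacity delta: left-eye minus right-eye red luminosity."""
    for v in (lum_left, lum_right):
        if not (0 <= v <= 255):
            raise ValueError("luminosities must lie in [0, 255]")
    return lum_left - lum_right


def vessel_um(vessel_px: int, mm_per_px: float) -> float:
    """Vessel extent in microns: foreground pixel count x mm/px x 1000."""
    if vessel_px < 0 or mm_per_px <= 0:
        raise ValueError("invalid vessel count or calibration")
    return vessel_px * mm_per_px * 1000.0


def angiogenesis_index(vessel_um_day: float, basal_mean_um: float) -> float:
    """Angiogenesis index IA = u_day / u_basal.

    ``basal_mean_um`` is the mean vessel extent (um) over the basal group's
    images; by construction the basal group's own mean IA is 1.
    """
    if basal_mean_um <= 0:
        raise ValueError("basal mean must be positive")
    return vessel_um_day / basal_mean_um


def opacity_area_index(delta_opacity: float, pct_damaged: float) -> float:
    """Index relating opacity to relative damaged area: delta / pct.

    Undefined for a fully healed eye (pct_damaged = 0); callers should report
    it as missing in that case.
    """
    if pct_damaged <= 0:
        raise ValueError("pct_damaged must be positive (healed eye: report missing)")
    return delta_opacity / pct_damaged
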