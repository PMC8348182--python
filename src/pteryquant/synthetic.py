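"""Synthetic eye micrographs and longitudinal lesion series with ground truth.

No micrographs of the murine pterygium model are publicly available, so every
downstream stage is exercised on generated scenes with known truth.  A scene
is an elliptical eyeball on a dark background: the interior is red-dominant
with its red-channel mode encoding opacity, a fraction of interior pixels
carries a dim desaturated-green iris texture (which also makes the
Otsu-within-gate brightness cut of the segmenter well posed), a bright
fluorescein-green lesion blob with controllable area and outline roughness
sits on the cornea, and a connected branching vessel tree of controllable
total length runs through the eye in a yellow-green outside the fluorescein
hue band.

Lesion outlines follow a radial star polygon
r(theta) = r0 * (1 + irregularity * sum_n a_n cos(n theta + phi_n)),
a_n proportional to 1/n for n = 2..16, normalized so that irregularity is the
RMS radial perturbation in units of 0.25 * r0; r0 is rescaled so the expected
enclosed area matches the request.  Longitudinal series follow
y = A * exp(k * t) with multiplicative lognormal noise of a stated CV.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw
from skimage.morphology import disk

from .segmentation import BinaryMask

# Scene palette (8-bit RGB).  The lesion colour has hue ~82/255 (fluorescein
# green), the iris texture hue ~71 at brightness 30 (below the segmenter's
# brightness floor of 48), the vessels hue ~26 (yellow-green, outside the
# 55-110 lesion hue gate) with a bright green channel for vessel extraction.
BACKGROUND_RGB = (8, 6, 5)
LESION_RGB = (46, 217, 33)
TEXTURE_RGB = (18, 30, 12)
VESSEL_RGB = (200, 150, 30)
EYE_GREEN = 40
EYE_BLUE = 40
TEXTURE_FRACTION = 0.10

_HARMONICS = np.arange(2, 17)
_AMPLITUDES = 1.0 / _HARMONICS
# RMS of sum a_n cos(...) with independent phases is sqrt(sum a_n^2 / 2);
# rescale so irregularity = 1 gives an RMS radial perturbation of 0.25 r0.
_AMPLITUDES = _AMPLITUDES * (0.25 / np.sqrt(np.sum(_AMPLITUDES**2) / 2.0))


@dataclass
class EyeSceneParams:
    """Parameters of one synthetic eye scene."""

    image_width: int = 320
    image_height: int = 240
    eye_center: tuple[int, int] = (120, 160)  # (row, col)
    eye_radii: tuple[int, int] = (75, 100)  # (row, col) semi-axes
    red_luminosity_mode: int = 120
    lesion_area_px: float = 3000.0
    lesion_irregularity: float = 0.8
    vessel_total_length_px: float = 1200.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.eye_center
        ar, ac = self.eye_radii
        if ar <= 0 or ac <= 0:
            raise ValueError("eye radii must be positive")
        if not (ar <= r <= self.image_height - 1 - ar and ac <= c <= self.image_width - 1 - ac):
            raise ValueError("eye ellipse must fit inside the frame")
        if not (0 <= self.red_luminosity_mode <= 255):
            raise ValueError("red_luminosity_mode must lie in [0, 255]")
        if self.lesion_area_px < 0 or self.lesion_irregularity < 0:
            raise ValueError("lesion area and irregularity must be non-negative")
        if self.lesion_area_px > np.pi * ar * ac:
            raise ValueError("lesion_area_px exceeds the eye area")
        if self.vessel_total_length_px < 0 or self.noise_sd < 0:
            raise ValueError("vessel length and noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Per-scene truth: masks and the scalar quantities they encode."""

    lesion_mask: BinaryMask
    vessel_mask: BinaryMask
    true_red_mode: int
    true_lesion_area_px: int = field(init=False)
    true_lesion_perimeter_px: float = field(init=False)
    true_vessel_px: int = field(init=False)

    def __post_init__(self) -> None:
        from .morphometry import perimeter_px

        self.true_lesion_area_px = int(self.lesion_mask.sum())
        self.true_lesion_perimeter_px = perimeter_px(self.lesion_mask)
        self.true_vessel_px = int(self.vessel_mask.sum())


@dataclass
class DecaySeriesParams:
    """Parameters of a longitudinal lesion-area series y = A * exp(k * t)."""

    amplitude: float  # A, pixels^2
    rate: float  # k, per day; negative = healing
    days: tuple[int, ...] = (3, 7, 10, 15)
    replicate_count: int = 6
    multiplicative_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        if self.replicate_count < 1:
            raise ValueError("need at least one replicate")
        if self.multiplicative_noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def generate_lesion_mask(
    area_px: float,
    irregularity: float,
    seed: int,
    shape: tuple[int, int] | None = None,
    center: tuple[int, int] | None = None,
) -> BinaryMask:
    """Rasterize one star-polygon lesion blob of the requested area.

    The blob is a single 8-connected (indeed simply connected) component; the
    base radius is rescaled so the expected enclosed area of the perturbed
    outline equals ``area_px``, keeping the realized pixel count within a few
    percent of the request across irregularity levels.
    """
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    if irregularity < 0:
        raise ValueError("irregularity must be non-negative")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=_HARMONICS.size)
    # E[r^2] = r0^2 (1 + irr^2 * sum a_n^2 / 2); compensate so E[area] = area_px.
    var_term = irregularity**2 * np.sum(_AMPLITUDES**2) / 2.0
    r0 = np.sqrt(area_px / (np.pi * (1.0 + var_term)))
    theta = np.linspace(0.0, 2.0 * np.pi, 1440, endpoint=False)
    pert = np.sum(
        _AMPLITUDES[:, None] * np.cos(_HARMONICS[:, None] * theta[None, :] + phases[:, None]),
        axis=0,
    )
    radius = r0 * np.clip(1.0 + irregularity * pert, 0.05, None)
    if shape is None:
        pad = int(np.ceil(radius.max())) + 2
        shape = (2 * pad + 1, 2 * pad + 1)
        center = (pad, pad)
    if center is None:
        center = (shape[0] // 2, shape[1] // 2)
    rows = center[0] + radius * np.sin(theta)
    cols = center[1] + radius * np.cos(theta)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


def generate_vessel_mask(
    total_length_px: float,
    seed: int,
    shape: tuple[int, int],
    roi: BinaryMask,
) -> BinaryMask:
    """Draw a connected branching vessel tree of roughly the given centerline length.

    A recursive random walk starts at the ROI margin and heads inward,
    branching with fixed probability; trunk segments are 3 px wide, branches
    1 px.  If the tree dies before reaching the target length, a new branch
    is seeded from a random already-drawn point, so the tree stays connected.
    """
    mask = np.zeros(shape, dtype=bool)
    if total_length_px <= 0:
        return mask
    rng = np.random.default_rng(seed)
    rr, cc = np.nonzero(roi)
    if rr.size == 0:
        return mask
    r_mid, c_mid = rr.mean(), cc.mean()
    trunk = np.zeros(shape, dtype=bool)
    twigs = np.zeros(shape, dtype=bool)
    visited: list[tuple[float, float, float]] = []

    def _start_point() -> tuple[float, float, float]:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        dr, dc = rr.max() - r_mid, cc.max() - c_mid
        r = r_mid + 0.85 * dr * np.sin(ang)
        c = c_mid + 0.85 * dc * np.cos(ang)
        heading = np.arctan2(r_mid - r, c_mid - c)
        return r, c, heading

    centerline = np.zeros(shape, dtype=bool)
    drawn = 0
    step = 6.0
    stack = [(*_start_point(), 0)]  # (row, col, heading, depth)
    while drawn < total_length_px:
        if not stack:
            if visited:
                r, c, _ = visited[rng.integers(len(visited))]
                stack.append((r, c, rng.uniform(0.0, 2.0 * np.pi), 1))
            else:
                stack.append((*_start_point(), 0))
        r, c, heading, depth = stack.pop()
        for _ in range(rng.integers(6, 14)):
            heading += rng.normal(0.0, 0.35)
            r2 = r + step * np.sin(heading)
            c2 = c + step * np.cos(heading)
            ir, ic = int(round(r2)), int(round(c2))
            if not (0 <= ir < shape[0] and 0 <= ic < shape[1]) or not roi[ir, ic]:
                break
            line_r, line_c = draw.line(int(round(r)), int(round(c)), ir, ic)
            (trunk if depth == 0 else twigs)[line_r, line_c] = True
            # only newly covered pixels count, weighted by stroke width, so
            # the realized foreground stays proportional to the request even
            # when branches revisit drawn territory
            new_px = int(np.count_nonzero(~centerline[line_r, line_c]))
            drawn += new_px * (3 if depth == 0 else 1)
            centerline[line_r, line_c] = True
            visited.append((r2, c2, heading))
            r, c = r2, c2
            if rng.random() < 0.15 and depth < 2:
                stack.append((r, c, heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2), depth + 1))
            if drawn >= total_length_px:
                break
    mask = ndimage.binary_dilation(trunk, structure=disk(1)) | twigs
    return mask & roi


def generate_eye_image(params: EyeSceneParams) -> tuple["CalibratedImage", GroundTruth]:
    """Render one synthetic eye scene and its ground truth.

    Inside the eye, outside lesion and vessels, the red-channel mode equals
    ``red_luminosity_mode`` (exactly so at noise_sd = 0); lesion pixels carry
    the fluorescein-green hue accepted by the default segmentation window;
    vessel pixels form one connected tree.  Deterministic for a fixed seed.
    """
    from .segmentation import CalibratedImage

    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = BACKGROUND_RGB

    eye = np.zeros((h, w), dtype=bool)
    err, ecc = draw.ellipse(*params.eye_center, *params.eye_radii, shape=(h, w))
    eye[err, ecc] = True
    img[eye] = (params.red_luminosity_mode, EYE_GREEN, EYE_BLUE)

    # Dim desaturated-green iris texture on a fraction of interior pixels.
    texture = eye & (rng.random((h, w)) < TEXTURE_FRACTION)
    img[texture] = TEXTURE_RGB

    inner = np.zeros((h, w), dtype=bool)
    irr_, icc_ = draw.ellipse(
        *params.eye_center,
        max(1, int(params.eye_radii[0] * 0.92)),
        max(1, int(params.eye_radii[1] * 0.92)),
        shape=(h, w),
    )
    inner[irr_, icc_] = True

    vessel_seed, lesion_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    vessels = generate_vessel_mask(params.vessel_total_length_px, vessel_seed, (h, w), inner)
    img[vessels] = VESSEL_RGB

    if params.lesion_area_px > 0:
        lesion = generate_lesion_mask(
            params.lesion_area_px,
            params.lesion_irregularity,
            lesion_seed,
            shape=(h, w),
            center=params.eye_center,
        )
        lesion &= eye
        img[lesion] = LESION_RGB
        vessels &= ~lesion
    else:
        lesion = np.zeros((h, w), dtype=bool)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = CalibratedImage(pixels)
    truth = GroundTruth(lesion, vessels, params.red_luminosity_mode)
    return image, truth


def generate_decay_series(params: DecaySeriesParams) -> list[list[tuple[int, float]]]:
    """Per-replicate (day, area) series following y = A * exp(k * t).

    With ``multiplicative_noise_cv = 0`` the series is exact; otherwise each
    value is multiplied by a lognormal factor exp(eps), eps ~ N(0, sigma)
    with sigma = sqrt(ln(1 + cv^2)) so the factor has the stated coefficient
    of variation and zero mean on the log scale (unbiased rate recovery).
    """
    rng = np.random.default_rng(params.seed)
    days = np.asarray(params.days, dtype=float)
    clean = params.amplitude * np.exp(params.rate * days)
    sigma = np.sqrt(np.log(1.0 + params.multiplicative_noise_cv**2))
    series = []
    for _ in range(params.replicate_count):
        if sigma > 0:
            vals = clean * np.exp(rng.normal(0.0, sigma, size=days.size))
        else:
            vals = clean.copy()
        series.append(list(zip((int(d) for d in params.days), (float(v) for v in vals))))
    return series
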