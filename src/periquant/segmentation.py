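"""Colour- and intensity-based segmentation of calibrated section images.

Bone is stained with Alizarin Red, so bone segmentation works in HSV space
with a red hue window (wrapping around 0°) plus saturation/value floors —
hue isolates the stain robustly under brightness noise.  The implant
cross-section is the darkest large connected component.  CD31-positive
fluorescence is a plain intensity threshold on the target channel, with
Otsu's method as the default threshold.

The study's per-case manual parameter adjustment is reproduced as explicit
per-image parameter overrides (see :mod:`periquant.io`), never interactive
state, so every run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage import color as skcolor
from skimage import filters, measure, morphology

from .calibration import CalibratedImage


class SegmentationError(ValueError):
    """Unsupported input for a segmentation routine."""


class DetectionError(RuntimeError):
    """No structure satisfying the detection rule (unusable section)."""


@dataclass
class SegmentationParams:
    """Thresholding and clean-up parameters.

    ``hue_center_deg``/``hue_window_deg`` define the stain hue window
    ``[center − window, center + window]`` on the colour circle (degrees,
    wrap-around at 0°).  ``morphology_radius`` > 0 applies a disc opening
    before component filtering; ``min_component_area`` removes connected
    components (8-connectivity) below the given pixel count.  The defaults
    leave both clean-up steps off so that a noise-free image segments
    pixel-exactly.
    """

    color_space: str = "hsv"
    hue_center_deg: float = 350.0
    hue_window_deg: float = 40.0
    min_saturation: float = 0.30
    min_value: float = 0.15
    implant_value_max: float = 0.35
    implant_min_area_px: int = 100
    morphology_radius: int = 0
    min_component_area: int = 0

    def __post_init__(self) -> None:
        if self.color_space not in ("hsv", "rgb"):
            raise ValueError("color_space must be 'hsv' or 'rgb'")
        if not 0 < self.hue_window_deg <= 180:
            raise ValueError("hue_window_deg must be in (0, 180]")
        if self.morphology_radius < 0 or self.min_component_area < 0:
            raise ValueError("clean-up parameters must be >= 0")

    def override(self, **kwargs) -> "SegmentationParams":
        """Return a copy with per-image replacements applied."""
        return replace(self, **kwargs)


def _as_unit_float(pixels: np.ndarray) -> np.ndarray:
    """Scale integer rasters to [0, 1]; floats are assumed already scaled."""
    if np.issubdtype(pixels.dtype, np.floating):
        return pixels.astype(np.float64)
    info = np.iinfo(pixels.dtype)
    return pixels.astype(np.float64) / info.max


def _cleanup(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.morphology_radius > 0:
        mask = morphology.opening(
            mask, morphology.disk(params.morphology_radius)
        )
    if params.min_component_area > 0:
        mask = morphology.remove_small_objects(
            mask, max_size=params.min_component_area - 1, connectivity=2
        )
    return mask


def segment_bone(
    image: CalibratedImage,
    params: Optional[SegmentationParams] = None,
    implant_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binary mask of stain-positive (bone) pixels.

    Pixels inside the configured colour window are kept, the optional disc
    opening and small-component removal are applied, and any supplied
    implant mask is excluded.
    """
    params = params or SegmentationParams()
    if image.n_channels != 3:
        raise SegmentationError(
            "bone segmentation needs a 3-channel colour image"
        )
    rgb = _as_unit_float(image.pixels)
    if params.color_space == "hsv":
        hsv = skcolor.rgb2hsv(rgb)
        hue_deg = hsv[:, :, 0] * 360.0
        delta = np.abs(
            (hue_deg - params.hue_center_deg + 180.0) % 360.0 - 180.0
        )
        mask = (
            (delta <= params.hue_window_deg)
            & (hsv[:, :, 1] >= params.min_saturation)
            & (hsv[:, :, 2] >= params.min_value)
        )
    else:  # red-dominance rule in raw RGB
        r, g, b = rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2]
        mask = (r >= params.min_value) & (r - np.maximum(g, b)
                                          >= params.min_saturation * r)
    if implant_mask is not None:
        mask &= ~np.asarray(implant_mask, dtype=bool)
    return _cleanup(mask, params)


def segment_implant(
    image: CalibratedImage, params: Optional[SegmentationParams] = None
) -> np.ndarray:
    """Binary mask of the implant cross-section.

    The implant is the largest connected near-black component whose area
    exceeds ``implant_min_area_px``; a tie in area is broken by the
    top-left-most centroid (row, then column).  Exactly one component is
    returned.
    """
    params = params or SegmentationParams()
    pix = _as_unit_float(image.pixels)
    value = pix if pix.ndim == 2 else pix.max(axis=2)
    dark = value <= params.implant_value_max
    labels = measure.label(dark, connectivity=2)
    candidates = []
    for region in measure.regionprops(labels):
        if region.area >= params.implant_min_area_px:
            candidates.append(
                (-region.area, region.centroid[0], region.centroid[1],
                 region.label)
            )
    if not candidates:
        raise DetectionError(
            "no dark component of at least "
            f"{params.implant_min_area_px} px found (section unusable)"
        )
    candidates.sort()
    return labels == candidates[0][3]


def segment_cd31(
    image: CalibratedImage,
    threshold: Optional[float] = None,
    target_channel: str = "target",
) -> np.ndarray:
    """Binary mask of target-channel pixels at or above ``threshold``.

    ``threshold=None`` selects Otsu's threshold on the target channel.
    """
    if target_channel not in image.channel_semantics:
        raise SegmentationError(
            f"image has no {target_channel!r} channel: "
            f"{image.channel_semantics}"
        )
    chan = image.channel(target_channel)
    if threshold is None:
        threshold = filters.threshold_otsu(chan)
    return np.asarray(chan) >= threshold
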