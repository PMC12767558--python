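"""Synthetic phantoms with exact ground truth.

The histology phantom emulates a stained cross-section through a titanium
disc press-fitted into a trephine defect: a dark 7 × 1 mm implant rectangle
centred in the canvas, a 5 mm defect band centred on it, reddish
(Alizarin-like) bone blobs planted per periimplant zone to hit requested
area fractions exactly (to pixel quantisation), and a requested fraction of
the implant-surface ring covered by a contiguous bone collar.  Because the
generator computes its own truth masks and evaluates the truth metrics with
the same definitions the measurement code uses, every downstream estimator
can be tested against exact ground truth.

The fluorescence phantom emulates a two-channel (nuclear + target)
725 × 543 μm field with a planted CD31-positive area.

All randomness flows through one ``numpy.random.default_rng(seed)`` in a
fixed order, so identical spec + seed reproduces the image and truth
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import geometry, metrics
from .calibration import CalibratedImage, DEFAULT_PIXEL_AREA_UM2

MM_TO_UM = 1000.0


class PhantomSpecError(ValueError):
    """Invalid phantom specification."""


@dataclass
class ColorModel:
    """Mean RGB (0–255) and per-class spread for each tissue class.

    ``spread`` is a per-pixel Gaussian SD applied within a class before the
    global additive noise; the default 0 keeps classes exactly uniform so a
    noise-free phantom segments pixel-exactly.
    """

    bone_rgb: tuple[float, float, float] = (185.0, 40.0, 70.0)
    background_rgb: tuple[float, float, float] = (195.0, 200.0, 210.0)
    implant_rgb: tuple[float, float, float] = (25.0, 25.0, 30.0)
    spread: float = 0.0


@dataclass
class PhantomSpec:
    """Geometry, bone-placement and appearance parameters of a phantom.

    ``bone_fraction_per_layer`` gives the target bone-area fraction for the
    immediate, intermediate and remote 100 μm layers plus the remainder of
    the defect beyond 300 μm.  ``contact_fraction`` is the fraction of
    implant-surface pixels covered by bone.  The implant may be wider than
    the defect (the study's press-fit geometry: 7 mm disc in a 5 mm
    trephine cavity).
    """

    pixel_area: float = DEFAULT_PIXEL_AREA_UM2
    implant_width_mm: float = 7.0
    implant_thickness_mm: float = 1.0
    defect_width_mm: float = 5.0
    canvas_margin_mm: float = 0.6
    bone_fraction_per_layer: tuple[float, float, float, float] = (
        0.55, 0.45, 0.40, 0.35,
    )
    contact_fraction: float = 0.5
    color_model: ColorModel = field(default_factory=ColorModel)
    noise_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_area <= 0:
            raise PhantomSpecError("pixel_area must be > 0")
        for name in ("implant_width_mm", "implant_thickness_mm",
                     "defect_width_mm", "canvas_margin_mm"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be > 0")
        fracs = (*self.bone_fraction_per_layer, self.contact_fraction)
        if len(self.bone_fraction_per_layer) != 4:
            raise PhantomSpecError(
                "bone_fraction_per_layer needs 4 entries (3 layers + rest)"
            )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise PhantomSpecError("all fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")

    @property
    def pitch_um(self) -> float:
        return math.sqrt(self.pixel_area)


@dataclass
class FluorescencePhantomSpec:
    """Two-channel fluorescence field with a planted positive area."""

    field_width_um: float = 725.0
    field_height_um: float = 543.0
    planted_positive_area_um2: float = 20000.0
    nucleus_count: int = 150
    pixel_area: float = DEFAULT_PIXEL_AREA_UM2
    noise_sd: float = 200.0
    seed: int = 0

    #: 16-bit channel levels; the positive/background midpoint is the
    #: natural recovery threshold.
    target_background: int = 2000
    target_positive: int = 30000
    nuclear_background: int = 500
    nuclear_positive: int = 20000

    def validate(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise PhantomSpecError("field dimensions must be > 0")
        if self.pixel_area <= 0:
            raise PhantomSpecError("pixel_area must be > 0")
        if self.planted_positive_area_um2 < 0:
            raise PhantomSpecError("planted area must be >= 0")
        if self.planted_positive_area_um2 > (
            self.field_width_um * self.field_height_um
        ):
            raise PhantomSpecError("planted area exceeds the field area")
        if self.nucleus_count < 0 or self.noise_sd < 0:
            raise PhantomSpecError("nucleus_count and noise_sd must be >= 0")

    @property
    def midpoint_threshold(self) -> float:
        return 0.5 * (self.target_background + self.target_positive)


@dataclass
class PhantomTruth:
    """Ground-truth masks and metric values for one phantom.

    Truth metric values are evaluated from the truth masks with the metric
    definitions of :mod:`periquant.metrics`, so truth is self-consistent by
    construction.
    """

    masks: geometry.MaskSet
    true_bone_area_mm2: float
    true_bone_density_pct: float
    true_bic_pct: float
    true_layer_areas_mm2: tuple[float, float, float]
    true_cd31_area_um2: Optional[float] = None


def _fill_zone_to_target(
    bone: np.ndarray,
    zone: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    min_radius: int = 3,
    max_radius: int = 10,
    avoid: Optional[np.ndarray] = None,
) -> None:
    """Add seeded random discs inside ``zone`` until the bone count equals
    ``round(fraction * |zone|)`` exactly; the final disc is trimmed pixel by
    pixel in a fixed order.  Pre-existing bone (the contact collar) counts
    toward the target and is never removed; if it already exceeds the
    target the zone is left as is.  Pixels in ``avoid`` (the surface ring)
    are only used when the target cannot be met without them, so the
    planted contact fraction stays exact whenever geometrically possible.
    """
    zone = np.asarray(zone, dtype=bool)
    n_zone = int(np.count_nonzero(zone))
    if n_zone == 0:
        return
    target = int(round(fraction * n_zone))
    current = int(np.count_nonzero(bone & zone))
    if current >= target:
        return
    allowed = zone if avoid is None else zone & ~np.asarray(avoid, bool)
    addable = int(np.count_nonzero(allowed & ~bone))
    stage_target = min(target, current + addable)
    h, w = bone.shape
    yy_zone, xx_zone = np.nonzero(allowed)
    n_allowed = yy_zone.size
    stale = 0
    while current < stage_target:
        i = rng.integers(0, n_allowed)
        cy, cx = int(yy_zone[i]), int(xx_zone[i])
        r = int(rng.integers(min_radius, max_radius + 1))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        patch = disc & allowed[y0:y1, x0:x1] & ~bone[y0:y1, x0:x1]
        n_new = int(np.count_nonzero(patch))
        if n_new == 0:
            stale += 1
            if stale > 200:  # nearly full zone: finish deterministically
                ys, xs = np.nonzero(allowed & ~bone)
                need = stage_target - current
                bone[ys[:need], xs[:need]] = True
                current = stage_target
            continue
        stale = 0
        excess = current + n_new - stage_target
        if excess > 0:
            ys, xs = np.nonzero(patch)
            keep = n_new - excess
            patch = np.zeros_like(patch)
            patch[ys[:keep], xs[:keep]] = True
            n_new = keep
        bone[y0:y1, x0:x1] |= patch
        current += n_new
    if current < target and avoid is not None:
        # forced overflow onto the avoided pixels (extreme fill requests)
        _fill_zone_to_target(bone, zone, fraction, rng,
                             min_radius, max_radius, avoid=None)


def _plant_contact_collar(
    bone: np.ndarray,
    surface: np.ndarray,
    implant: np.ndarray,
    contact_fraction: float,
    rng: np.random.Generator,
) -> None:
    """Cover ``round(contact_fraction·|surface|)`` surface pixels with bone
    as one contiguous run along the perimeter (random seeded start)."""
    ys, xs = np.nonzero(surface)
    n = ys.size
    k = int(round(contact_fraction * n))
    if k == 0:
        return
    iy, ix = np.nonzero(implant)
    cy, cx = iy.mean(), ix.mean()
    order = np.argsort(np.arctan2(ys - cy, xs - cx), kind="stable")
    start = int(rng.integers(0, n))
    picked = order[(start + np.arange(k)) % n]
    bone[ys[picked], xs[picked]] = True


def generate_histology_phantom(
    spec: PhantomSpec,
) -> tuple[CalibratedImage, PhantomTruth]:
    """Render one stained cross-section phantom and its exact truth."""
    spec.validate()
    pitch = spec.pitch_um
    margin_px = int(round(spec.canvas_margin_mm * MM_TO_UM / pitch))
    imp_w = int(round(spec.implant_width_mm * MM_TO_UM / pitch))
    imp_h = int(round(spec.implant_thickness_mm * MM_TO_UM / pitch))
    width = imp_w + 2 * margin_px
    height = imp_h + 2 * margin_px
    if imp_w <= 0 or imp_h <= 0 or width <= imp_w or height <= imp_h:
        raise geometry.GeometryError(
            "canvas cannot hold the implant plus margins"
        )

    implant = np.zeros((height, width), dtype=bool)
    implant[margin_px:margin_px + imp_h, margin_px:margin_px + imp_w] = True

    defect = geometry.define_defect_roi(
        implant, spec.defect_width_mm, spec.pixel_area
    )
    surface = geometry.implant_surface(implant, defect)
    zones = geometry.periimplant_layers(implant, defect, spec.pixel_area)

    rng = np.random.default_rng(spec.seed)
    bone = np.zeros_like(implant)
    _plant_contact_collar(bone, surface, implant, spec.contact_fraction, rng)
    regions = [zones == 1, zones == 2, zones == 3,
               defect & (zones == 0) & ~implant]
    for region, frac in zip(regions, spec.bone_fraction_per_layer):
        _fill_zone_to_target(bone, region, frac, rng, avoid=surface)

    cm = spec.color_model
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = cm.background_rgb
    img[bone] = cm.bone_rgb
    img[implant] = cm.implant_rgb
    if cm.spread > 0:
        img += rng.normal(0.0, cm.spread, size=img.shape)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = CalibratedImage(
        pixels=np.clip(img, 0, 255).round().astype(np.uint8),
        pixel_area=spec.pixel_area,
        channel_semantics=("R", "G", "B"),
    )

    masks = geometry.MaskSet(
        implant=implant, defect=defect, bone=bone, zones=zones,
        surface=surface,
    )
    truth = PhantomTruth(
        masks=masks,
        true_bone_area_mm2=metrics.bone_area(bone, defect, spec.pixel_area),
        true_bone_density_pct=metrics.bone_density(
            bone, defect, spec.pixel_area
        ),
        true_bic_pct=metrics.bic(implant, bone, defect),
        true_layer_areas_mm2=tuple(
            metrics.layer_bone_areas(bone, zones, spec.pixel_area)
        ),
    )
    return image, truth


def generate_fluorescence_phantom(
    spec: FluorescencePhantomSpec,
) -> tuple[CalibratedImage, PhantomTruth]:
    """Render a two-channel (nuclear, target) field with a planted
    positive-signal area; the planted pixel count matches the requested
    area to within one pixel-area unit."""
    spec.validate()
    pitch = math.sqrt(spec.pixel_area)
    # floor keeps the raster inside the physical field, so a full-field
    # request saturates every pixel
    width = int(spec.field_width_um / pitch)
    height = int(spec.field_height_um / pitch)
    n_field = width * height
    target = int(round(spec.planted_positive_area_um2 / spec.pixel_area))
    target = min(target, n_field)

    rng = np.random.default_rng(spec.seed)
    positive = np.zeros((height, width), dtype=bool)
    full = np.ones_like(positive)
    _fill_zone_to_target(positive, full, target / n_field if n_field else 0.0,
                         rng, min_radius=2, max_radius=8)
    # _fill_zone_to_target rounds its own target; force the exact count.
    assert int(np.count_nonzero(positive)) == target

    nuclear = np.full((height, width), float(spec.nuclear_background))
    for _ in range(spec.nucleus_count):
        cy = int(rng.integers(0, height))
        cx = int(rng.integers(0, width))
        r = int(rng.integers(1, 3))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, height)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, width)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        nuclear[y0:y1, x0:x1][(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = (
            spec.nuclear_positive
        )
    target_chan = np.full(
        (height, width), float(spec.target_background)
    )
    target_chan[positive] = spec.target_positive
    stack = np.stack([nuclear, target_chan], axis=2)
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    image = CalibratedImage(
        pixels=np.clip(stack, 0, 65535).round().astype(np.uint16),
        pixel_area=spec.pixel_area,
        channel_semantics=("nuclear", "target"),
    )

    empty = np.zeros_like(positive)
    masks = geometry.MaskSet(
        implant=empty, defect=empty, bone=empty,
        zones=np.zeros_like(positive, dtype=np.uint8), surface=empty,
        cd31=positive,
    )
    truth = PhantomTruth(
        masks=masks,
        true_bone_area_mm2=0.0,
        true_bone_density_pct=0.0,
        true_bic_pct=0.0,
        true_layer_areas_mm2=(0.0, 0.0, 0.0),
        true_cd31_area_um2=metrics.cd31_area(positive, spec.pixel_area),
    )
    return image, truth


def generate_paired_cohort(
    n_units: int,
    n_conditions: int,
    effect_sizes: Optional[np.ndarray] = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 50.0,
    between_unit_sd: float = 10.0,
) -> np.ndarray:
    """Paired measurements for ``n_units`` exchangeable units under
    ``n_conditions`` within-unit conditions.

    Entry ``(i, j) = baseline_i + effect_sizes[j] + ε_ij`` with
    ``baseline_i ~ N(baseline_mean, between_unit_sd²)`` and
    ``ε_ij ~ N(0, noise_sd²)``.  The between-unit spread mimics per-animal
    baselines; paired tests difference it away.
    """
    if n_units < 2 or n_conditions < 2:
        raise ValueError("need at least 2 units and 2 conditions")
    if effect_sizes is None:
        effect_sizes = np.zeros(n_conditions)
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    if effect_sizes.shape != (n_conditions,):
        raise ValueError("effect_sizes must have length n_conditions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, between_unit_sd, size=(n_units, 1))
    noise = rng.normal(0.0, noise_sd, size=(n_units, n_conditions))
    return baseline + effect_sizes[None, :] + noise
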