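"""Outcome metrics computed from aligned binary masks.

All areas are obtained by pixel counting followed by unit conversion with
the physical pixel area (μm²/pixel): bone formation (BF, mm²), bone density
(BD, % of the trephine defect), bone–implant contact (BIC, % of the
one-pixel implant surface ring covered by bone), per-layer bone areas for
the three 100 μm periimplant bands, and CD31-positive area (μm²).
Per-disc aggregation averages 3–4 cross-sections per implant disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import geometry


class MetricError(ValueError):
    """Raised when a metric is undefined for the supplied masks."""


@dataclass
class SectionMetrics:
    """Per-cross-section outcomes.

    ``layer_areas_mm2`` is ordered (immediate, intermediate, remote).
    """

    section_id: str
    bone_area_mm2: float
    bone_density_pct: float
    bic_pct: float
    layer_areas_mm2: tuple[float, float, float]
    cd31_area_um2: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bone_density_pct <= 100.0:
            raise ValueError("bone density must be within [0, 100] %")
        if not 0.0 <= self.bic_pct <= 100.0:
            raise ValueError("BIC must be within [0, 100] %")
        if self.bone_area_mm2 < 0 or any(a < 0 for a in self.layer_areas_mm2):
            raise ValueError("areas must be non-negative")


@dataclass
class DiscSummary:
    """Per-disc mean ± sample SD over that disc's cross-sections.

    ``sd`` entries are 0 with ``single_section=True`` when only one section
    is available (SD undefined).  3–4 sections per disc is the expected
    regime; other counts are accepted but flagged via ``n_sections``.
    """

    n_sections: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    single_section: bool = False


def _check_aligned(*masks: np.ndarray) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise MetricError(f"masks are not aligned: shapes {shapes}")


def bone_area(
    bone: np.ndarray, region: np.ndarray, pixel_area: float
) -> float:
    """Bone area inside ``region`` in mm² (pixel count × μm²/px × 1e-6)."""
    bone = np.asarray(bone, dtype=bool)
    region = np.asarray(region, dtype=bool)
    _check_aligned(bone, region)
    return float(np.count_nonzero(bone & region)) * pixel_area * 1e-6


def bone_density(
    bone: np.ndarray, defect: np.ndarray, pixel_area: float
) -> float:
    """Bone density: bone pixels as % of the defect ROI."""
    bone = np.asarray(bone, dtype=bool)
    defect = np.asarray(defect, dtype=bool)
    _check_aligned(bone, defect)
    n_defect = np.count_nonzero(defect)
    if n_defect == 0:
        raise MetricError("defect mask is empty; bone density undefined")
    return 100.0 * np.count_nonzero(bone & defect) / n_defect


def bic(
    implant: np.ndarray, bone: np.ndarray, defect: np.ndarray
) -> float:
    """Bone–implant contact in %.

    The implant mask is enlarged by one pixel (8-connectivity), limited to
    the trephine defect, and intersected with the bone mask; BIC is the
    bone-occupied fraction of that surface ring.
    """
    implant = np.asarray(implant, dtype=bool)
    bone = np.asarray(bone, dtype=bool)
    defect = np.asarray(defect, dtype=bool)
    _check_aligned(implant, bone, defect)
    surface = geometry.implant_surface(implant, defect)
    n_surface = np.count_nonzero(surface)
    if n_surface == 0:
        raise MetricError(
            "implant surface is empty inside the defect; BIC undefined"
        )
    return 100.0 * np.count_nonzero(surface & bone) / n_surface


def layer_bone_areas(
    bone: np.ndarray,
    zones: np.ndarray,
    pixel_area: float,
    n_layers: int = 3,
) -> tuple[float, ...]:
    """Bone area (mm²) inside each periimplant distance band."""
    bone = np.asarray(bone, dtype=bool)
    zones = np.asarray(zones)
    _check_aligned(bone, zones)
    return tuple(
        bone_area(bone, zones == k, pixel_area) for k in range(1, n_layers + 1)
    )


def cd31_area(positive: np.ndarray, pixel_area: float) -> float:
    """CD31-positive area in μm² (pixel count × μm²/px)."""
    positive = np.asarray(positive, dtype=bool)
    return float(np.count_nonzero(positive)) * pixel_area


def section_metrics(
    masks: geometry.MaskSet,
    pixel_area: float,
    section_id: str = "",
) -> SectionMetrics:
    """Compute the full per-section metric record from a mask family."""
    cd31 = (
        cd31_area(masks.cd31, pixel_area) if masks.cd31 is not None else None
    )
    return SectionMetrics(
        section_id=section_id,
        bone_area_mm2=bone_area(masks.bone, masks.defect, pixel_area),
        bone_density_pct=bone_density(masks.bone, masks.defect, pixel_area),
        bic_pct=bic(masks.implant, masks.bone, masks.defect),
        layer_areas_mm2=tuple(
            layer_bone_areas(masks.bone, masks.zones, pixel_area)
        ),
        cd31_area_um2=cd31,
    )


_SCALAR_FIELDS = ("bone_area_mm2", "bone_density_pct", "bic_pct")


def aggregate_disc(sections: Sequence[SectionMetrics]) -> DiscSummary:
    """Mean and sample SD (n−1) per metric across a disc's cross-sections.

    A single section yields mean = value and SD reported as 0 with the
    ``single_section`` flag set.
    """
    if len(sections) == 0:
        raise ValueError("aggregate_disc requires at least one section")
    single = len(sections) == 1

    def _agg(values: np.ndarray) -> tuple[float, float]:
        mean = float(np.mean(values))
        sd = 0.0 if single else float(np.std(values, ddof=1))
        return mean, sd

    summary = DiscSummary(n_sections=len(sections), single_section=single)
    for name in _SCALAR_FIELDS:
        mean, sd = _agg(np.array([getattr(s, name) for s in sections]))
        summary.mean[name] = mean
        summary.sd[name] = sd
    for k, layer in enumerate(("immediate", "intermediate", "remote")):
        mean, sd = _agg(np.array([s.layer_areas_mm2[k] for s in sections]))
        summary.mean[f"layer_{layer}_mm2"] = mean
        summary.sd[f"layer_{layer}_mm2"] = sd
    cd31_vals = [s.cd31_area_um2 for s in sections if s.cd31_area_um2 is not None]
    if cd31_vals:
        arr = np.array(cd31_vals)
        summary.mean["cd31_area_um2"] = float(arr.mean())
        summary.sd["cd31_area_um2"] = (
            0.0 if len(arr) == 1 else float(arr.std(ddof=1))
        )
    return summary
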