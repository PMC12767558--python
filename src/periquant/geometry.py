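"""Analysis-region construction around the implant cross-section.

Three regions drive all downstream metrics:

* the **trephine-defect ROI** — the cross-section of the 5 mm cylindrical
  cavity, modelled as a vertical band of the defect width centred on the
  implant and spanning the image rows, minus the implant body;
* the **implant surface** — the one-pixel ring obtained by dilating the
  implant mask with a 3×3 (8-connected) structuring element, subtracting the
  implant, and clipping to the defect;
* the **periimplant layers** — three concentric 100 μm distance bands
  (immediate, intermediate, remote) measured by the exact Euclidean distance
  transform on pixel centres, clipped to the defect.

Distance bins are half-open, ``(k−1)·t < d ≤ k·t``, so the bands partition
the 300 μm band exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .calibration import pitch_from_area

#: 3×3 all-ones structuring element = 8-connectivity.
SQUARE_3X3 = np.ones((3, 3), dtype=bool)


class GeometryError(ValueError):
    """Raised when a mask configuration makes a region undefined."""


@dataclass
class MaskSet:
    """Aligned binary masks plus the labelled periimplant zones.

    ``zones`` uses labels 0 (outside), 1 (immediate), 2 (intermediate),
    3 (remote).
    """

    implant: np.ndarray
    defect: np.ndarray
    bone: np.ndarray
    zones: np.ndarray
    surface: np.ndarray
    cd31: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.implant, self.defect, self.bone,
                                    self.zones, self.surface)}
        if len(shapes) != 1:
            raise ValueError(f"masks are not aligned: shapes {shapes}")

    def validate(self) -> None:
        """Assert the structural invariants of the mask family."""
        if np.any(self.implant & self.defect):
            raise ValueError("defect ROI must exclude the implant body")
        if np.any((self.zones > 0) & ~self.defect):
            raise ValueError("zones must lie inside the defect")
        if np.any(self.surface & ~self.defect):
            raise ValueError("surface must lie inside the defect")
        if np.any(self.surface & self.implant):
            raise ValueError("surface must exclude the implant")
        if np.any(self.implant & self.bone):
            raise ValueError("implant and bone masks overlap")


def define_defect_roi(
    implant: np.ndarray, defect_width_mm: float, pixel_area: float
) -> np.ndarray:
    """Trephine-defect ROI: a band of ``defect_width_mm`` centred on the implant.

    The band is centred on the implant centroid column, spans every image
    row, and excludes the implant body itself.
    """
    implant = np.asarray(implant, dtype=bool)
    if defect_width_mm <= 0:
        raise ValueError("defect_width_mm must be > 0")
    if not implant.any():
        raise GeometryError("implant mask is empty")
    width_px = int(round(defect_width_mm * 1000.0 / pitch_from_area(pixel_area)))
    _, cols = np.nonzero(implant)
    center = cols.mean()
    start = int(round(center - width_px / 2.0))
    stop = start + width_px
    start = max(start, 0)
    stop = min(stop, implant.shape[1])
    roi = np.zeros_like(implant)
    roi[:, start:stop] = True
    roi &= ~implant
    return roi


def implant_surface(implant: np.ndarray, defect: np.ndarray) -> np.ndarray:
    """One-pixel surface ring: ``(dilate(implant, 3×3) \\ implant) ∩ defect``."""
    implant = np.asarray(implant, dtype=bool)
    defect = np.asarray(defect, dtype=bool)
    if implant.shape != defect.shape:
        raise ValueError("implant and defect masks must share a shape")
    if not implant.any():
        raise GeometryError("implant mask is empty")
    dilated = ndimage.binary_dilation(implant, structure=SQUARE_3X3)
    return dilated & ~implant & defect


def periimplant_layers(
    implant: np.ndarray,
    defect: np.ndarray,
    pixel_area: float,
    layer_thickness_um: float = 100.0,
    n_layers: int = 3,
) -> np.ndarray:
    """Label concentric distance bands around the implant inside the defect.

    A non-implant defect pixel gets label ``k`` (1-based) iff its
    centre-to-centre Euclidean distance ``d`` to the nearest implant pixel
    satisfies ``(k−1)·t < d ≤ k·t`` with ``t = layer_thickness_um``.
    """
    implant = np.asarray(implant, dtype=bool)
    defect = np.asarray(defect, dtype=bool)
    if layer_thickness_um <= 0:
        raise ValueError("layer_thickness_um must be > 0")
    if not implant.any():
        raise GeometryError("implant mask is empty")
    pitch = pitch_from_area(pixel_area)
    dist = ndimage.distance_transform_edt(~implant, sampling=pitch)
    zones = np.zeros(implant.shape, dtype=np.uint8)
    for k in range(1, n_layers + 1):
        band = (dist > (k - 1) * layer_thickness_um) & (
            dist <= k * layer_thickness_um
        )
        zones[band & defect & ~implant] = k
    return zones


def build_mask_set(
    implant: np.ndarray,
    bone: np.ndarray,
    pixel_area: float,
    defect_width_mm: float,
    layer_thickness_um: float = 100.0,
    n_layers: int = 3,
    cd31: Optional[np.ndarray] = None,
) -> MaskSet:
    """Assemble the full region family from implant and bone masks."""
    defect = define_defect_roi(implant, defect_width_mm, pixel_area)
    surface = implant_surface(implant, defect)
    zones = periimplant_layers(
        implant, defect, pixel_area, layer_thickness_um, n_layers
    )
    bone = np.asarray(bone, dtype=bool) & ~np.asarray(implant, dtype=bool)
    ms = MaskSet(implant=np.asarray(implant, dtype=bool), defect=defect,
                 bone=bone, zones=zones, surface=surface, cd31=cd31)
    ms.validate()
    return ms
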