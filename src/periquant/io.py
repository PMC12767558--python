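"""File I/O and configuration.

Physical calibration always comes from configuration, never from image
metadata: TIFF resolution tags are unreliable across scanners, and requiring
an explicit μm²/pixel keeps every run bit-reproducible.  CSV is the single
tabular interchange format.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibratedImage


class CalibrationError(ValueError):
    """Missing or invalid physical calibration."""


class ImageReadError(IOError):
    """Unsupported or unreadable image file."""


def read_image(
    path: str | Path,
    pixel_area: Optional[float],
    channel_semantics: Optional[Sequence[str]] = None,
) -> CalibratedImage:
    """Read a TIFF or PNG into a :class:`CalibratedImage`.

    ``pixel_area`` is mandatory: a missing calibration is a hard error, no
    default is silently applied.  Bit depths of 8 and 16 are preserved
    without rescaling.
    """
    path = Path(path)
    if pixel_area is None:
        raise CalibrationError(
            f"no pixel_area calibration supplied for {path.name}; "
            "calibration must come from the run configuration"
        )
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            pixels = tifffile.imread(path)
        elif suffix == ".png":
            pixels = iio.imread(path)
        else:
            raise ImageReadError(f"unsupported image format: {path.name}")
    except (OSError, ValueError) as exc:
        raise ImageReadError(f"cannot read {path}: {exc}") from exc
    if pixels.dtype not in (np.uint8, np.uint16):
        raise ImageReadError(
            f"{path.name}: unsupported bit depth {pixels.dtype}; "
            "expected 8- or 16-bit"
        )
    # channel-first multi-page TIFF -> channel-last
    if pixels.ndim == 3 and pixels.shape[0] in (2, 3, 4) and (
        pixels.shape[0] < min(pixels.shape[1:])
    ):
        pixels = np.moveaxis(pixels, 0, -1)
    if channel_semantics is None:
        n = 1 if pixels.ndim == 2 else pixels.shape[2]
        channel_semantics = (
            ("R", "G", "B") if n == 3
            else ("nuclear", "target") if n == 2
            else tuple(f"ch{i}" for i in range(n))
        )
    return CalibratedImage(
        pixels=pixels,
        pixel_area=float(pixel_area),
        channel_semantics=tuple(channel_semantics),
    )


def write_image(path: str | Path, image: CalibratedImage) -> None:
    """Write the raster to TIFF or PNG (calibration travels in config)."""
    path = Path(path)
    pixels = image.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        if pixels.ndim == 3 and pixels.shape[2] == 2:
            pixels = np.moveaxis(pixels, -1, 0)  # pages per channel
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 single-channel PNG."""
    iio.imwrite(
        Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255))
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 mask PNG back to boolean."""
    return np.asarray(iio.imread(Path(path))) > 0


def write_labeled_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write a small-integer label raster (e.g., zone labels) as PNG."""
    iio.imwrite(Path(path), np.asarray(labels, dtype=np.uint8))


_SECTION_HEADER = (
    "# One row per cross-section. Units: bone_area_mm2 and layer areas in "
    "mm^2; bone_density_pct and bic_pct in %; cd31_area_um2 in um^2.\n"
)


def write_section_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write the per-section metrics table with a unit-documenting header."""
    with open(path, "w") as fh:
        fh.write(_SECTION_HEADER)
        df.to_csv(fh, index=False, float_format="%.6g")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
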