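"""Image and table I/O shared by the analysis pipelines.

All pipelines consume single-channel grayscale TIFFs. Spatial calibration
(pixels per mm for curvature images, pixels per µm for section images) is
never read from TIFF tags: microscope/camera calibration is external, so the
caller supplies it and it travels with the pixel data as a
:class:`CalibratedImage`.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("hairmorph")

__all__ = [
    "CalibratedImage",
    "ImageReadError",
    "read_grayscale_tiff",
    "write_csv",
    "write_run_metadata",
]


class ImageReadError(Exception):
    """Raised when a TIFF cannot be read or converted to grayscale."""


@dataclass
class CalibratedImage:
    """A 2-D grayscale intensity grid plus its spatial calibration.

    Parameters
    ----------
    pixels
        2-D array of intensities (uint8/uint16 or float).
    resolution
        Pixels per unit length; must be positive.
    unit
        Unit tag for the resolution, ``"px/mm"`` (longitudinal images)
        or ``"px/um"`` (section images).
    image_id
        Identifier, conventionally the filename stem. Used as the join key
        between estimate and truth tables.
    """

    pixels: np.ndarray
    resolution: float
    unit: str = "px/mm"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def read_grayscale_tiff(
    path: str | Path,
    resolution: float,
    unit: str = "px/mm",
) -> CalibratedImage:
    """Read a TIFF as a calibrated grayscale image.

    8- and 16-bit single-channel images pass through unchanged. RGB(A)
    images are converted by luminance with a logged warning. Anything
    unreadable raises :class:`ImageReadError` naming the file.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt / not a TIFF
        raise ImageReadError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        logger.warning("%s is RGB; converting to grayscale by luminance", path.name)
        rgb = arr[..., :3].astype(float)
        arr = (0.2125 * rgb[..., 0] + 0.7154 * rgb[..., 1] + 0.0721 * rgb[..., 2])
    if arr.ndim != 2:
        raise ImageReadError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return CalibratedImage(arr, resolution=resolution, unit=unit, image_id=path.stem)


def write_csv(records: pd.DataFrame | Iterable[dict], schema: Sequence[str], path: str | Path) -> Path:
    """Write records as CSV with an enforced column schema.

    The schema is validated before any bytes are written; a mismatch raises
    ``ValueError``. Empty record sets produce a header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if len(df) == 0:
        df = pd.DataFrame(columns=list(schema))
    missing = [c for c in schema if c not in df.columns]
    extra = [c for c in df.columns if c not in schema]
    if missing or extra:
        raise ValueError(f"record columns do not match schema (missing={missing}, extra={extra})")
    path = Path(path)
    df = df[list(schema)]
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_run_metadata(out_dir: str | Path, config: dict) -> Path:
    """Write a JSON run-metadata file (config, seed, version) next to outputs."""
    from hairmorph import __version__

    out = Path(out_dir) / "run_metadata.json"
    payload = {
        "hairmorph_version": __version__,
        "python": platform.python_version(),
        **config,
    }
    out.write_text(json.dumps(payload, indent=2, default=str))
    return out
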