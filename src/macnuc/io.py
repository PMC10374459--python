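"""File I/O: masks, images, tables, and run configuration.

Masks are single-channel PNG/TIFF rasters (any nonzero pixel is
foreground) or RGBA PNGs from tracing tools, where any non-transparent
pixel is foreground. All tables are CSV with a header row and units
embedded in the column names (e.g. ``volume_um3``). Configuration is a
flat key-value file (YAML subset).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .volume import SilhouetteMask

__all__ = [
    "RunConfig",
    "read_mask",
    "write_mask",
    "write_puncta_tiff",
    "read_puncta_tiff",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    pixel_size_um: float = 1.0
    frame_interval_min: float = 5.0
    coalescence_threshold: int = 3
    window_min: tuple[float, float] = (270.0, 480.0)
    min_seed_depth_um: float = 2.0
    puncta_sigma_um: float = 0.25
    puncta_min_d_um: float = 0.75
    puncta_max_d_um: float = 10.0
    puncta_intensity_floor: Optional[float] = None
    seed: int = 0
    n_cells: int = 11
    peak_fold_change: float = 1.35
    noise_sd: float = 0.05
    output_dir: str = "macnuc_out"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.coalescence_threshold < 1:
            raise ValueError("coalescence_threshold must be >= 1")
        if self.min_seed_depth_um <= 0:
            raise ValueError("min_seed_depth_um must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a flat key-value mapping")
        if "window_min" in data:
            data["window_min"] = tuple(data["window_min"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["window_min"] = list(self.window_min)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def read_mask(
    path: str | Path,
    pixel_size_um: float,
    cell_id: Optional[str] = None,
    frame: Optional[int] = None,
) -> SilhouetteMask:
    """Read a PNG/TIFF mask; nonzero (or non-transparent) is foreground.

    Multi-frame stacks are rejected: each timepoint is one file.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        fg = arr > 0
    elif arr.ndim == 3 and arr.shape[-1] == 4:
        fg = arr[..., 3] > 0  # RGBA: traced on transparent background
    elif arr.ndim == 3 and arr.shape[-1] in (2, 3):
        fg = np.any(arr > 0, axis=-1)
    else:
        raise ValueError(
            f"{path}: expected a single-frame mask, got shape {arr.shape}"
        )
    return SilhouetteMask(raster=fg, pixel_size_um=pixel_size_um,
                          cell_id=cell_id, frame=frame)


def write_mask(path: str | Path, mask: SilhouetteMask | np.ndarray) -> None:
    """Write a binary mask as 8-bit (0 background, 255 foreground)."""
    raster = mask.raster if isinstance(mask, SilhouetteMask) else np.asarray(mask) > 0
    iio.imwrite(path, (raster.astype(np.uint8)) * 255)


def write_puncta_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a (2, ny, nx) two-channel image as 16-bit TIFF."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[0] != 2:
        raise ValueError("expected a (2, ny, nx) image")
    tifffile.imwrite(path, np.clip(img, 0, 65535).astype(np.uint16))


def read_puncta_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"{path}: expected a (2, ny, nx) TIFF, got {arr.shape}")
    return arr.astype(float)
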