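"""Core image carriers shared by every stage of the pipeline.

The universal unit of data is a single-channel 2-D intensity grid with a
physical pixel size (:class:`ImagePlane`).  Per-cell analysis operates on a
binary :class:`CellMask` derived from the receptor stain, and texture scoring
operates on one or more :class:`TexturePatch` regions inside that mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["ImagePlane", "CellMask", "TexturePatch", "bilinear_sample"]


@dataclass
class ImagePlane:
    """One channel's 2-D intensity grid with its pixel size in micrometres.

    Parameters
    ----------
    data:
        2-D array of intensities; stored as float64.
    pixel_size_um:
        Physical edge length of one pixel in micrometres (> 0).
    channel:
        Optional channel name (e.g. ``"ddr1"``, ``"collagen"``, ``"py"``).
    """

    data: np.ndarray
    pixel_size_um: float
    channel: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"ImagePlane requires a 2-D grid, got ndim={self.data.ndim}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def um_to_px(self, length_um: float) -> float:
        """Convert a physical length in μm to pixels."""
        return length_um / self.pixel_size_um

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size_um


@dataclass
class CellMask:
    """Binary per-cell region used for all per-cell quantification."""

    grid: np.ndarray
    source_channel: str = "ddr1"
    background_level: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("CellMask grid must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return not self.grid.any()


@dataclass
class TexturePatch:
    """A segmented region of interest inside a cell, scored for texture."""

    grid: np.ndarray
    parent_cell: int = 0
    patch_id: int = 1
    pixels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("TexturePatch grid must be 2-D")
        # (n, 2) array of in-patch (row, col) indices, cached for line sampling
        self.pixels = np.argwhere(self.grid)

    @property
    def area_px(self) -> int:
        return int(self.pixels.shape[0])


def bilinear_sample(data: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinearly interpolate ``data`` at fractional (row, col) positions."""
    return map_coordinates(
        np.asarray(data, dtype=np.float64),
        np.vstack([rows, cols]),
        order=1,
        mode="nearest",
    )
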