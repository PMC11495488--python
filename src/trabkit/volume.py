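"""Voxel volume container and multi-page TIFF I/O.

A :class:`VoxelVolume` is the substrate every stage of the pipeline operates
on: a 3-D scalar grid with an isotropic physical voxel size.  Grid axes
(slice, row, column) map to world axes (Z, Y, X).  Because plain TIFF tags
carry no standard 3-D spacing, the voxel size travels in a JSON sidecar
written next to the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "read_stack", "write_stack"]

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.bool_)


@dataclass
class VoxelVolume:
    """3-D image with physical scale.

    Parameters
    ----------
    values
        Array of shape (nz, ny, nx); axis order slice/row/column = Z/Y/X.
    voxel_size
        Edge length of one cubic voxel in micrometres (> 0).
    origin
        World position (x, y, z) of voxel index (0, 0, 0), in voxel units.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if any(s < 2 for s in self.values.shape):
            raise ValueError(f"grid extents must be >= 2 per axis, got {self.values.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        """True when the volume holds only two (or fewer) intensity levels
        drawn from {0, 1} / {0, 255} / {False, True}."""
        if self.values.dtype == bool:
            return True
        u = np.unique(self.values)
        return len(u) <= 2 and set(u.tolist()) <= {0, 1, 255}

    def foreground_fraction(self) -> float:
        """Fraction of nonzero voxels (BV/TV of the whole grid)."""
        return float(np.count_nonzero(self.values)) / self.values.size

    def world_coords(self, index_points: np.ndarray) -> np.ndarray:
        """Map (z, y, x) index triples to world (x, y, z) points in voxels."""
        p = np.atleast_2d(index_points)
        return p[:, ::-1] + self.origin


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (one page per Z slice) plus a
    JSON sidecar with the voxel size and origin.

    Binary volumes are stored as 0/255 uint8; uint8/uint16 grayscale pass
    through unchanged.
    """
    path = Path(path)
    vals = volume.values
    if vals.dtype == bool:
        vals = vals.astype(np.uint8) * 255
    elif vals.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported dtype for TIFF export: {vals.dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vals, photometric="minisblack")
    meta = {
        "voxel_size_um": volume.voxel_size,
        "origin": volume.origin.tolist(),
        "shape": list(vals.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    """Read a multi-page TIFF stack.

    The voxel size comes from the JSON sidecar when present, else from the
    ``voxel_size`` argument (required otherwise).  Pages of unequal shape or
    unsupported bit depth raise a :class:`ValueError` naming the page.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing TIFF file: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = [p.shape for p in tif.pages]
        for i, s in enumerate(shapes):
            if s != shapes[0]:
                raise ValueError(f"ragged stack: page {i} has shape {s}, expected {shapes[0]}")
        for i, p in enumerate(tif.pages):
            if p.dtype not in (np.uint8, np.uint16):
                raise ValueError(f"unsupported bit depth on page {i}: {p.dtype}")
        vals = tif.asarray()
    if vals.ndim == 2:
        vals = vals[None]
    origin = np.zeros(3)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = float(meta["voxel_size_um"])
        origin = np.asarray(meta.get("origin", [0, 0, 0]), dtype=float)
    if voxel_size is None:
        raise ValueError("voxel_size not found in sidecar and not supplied")
    return VoxelVolume(values=vals, voxel_size=voxel_size, origin=origin)
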