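"""Articular-head ROI extraction, Otsu binarization, and purification.

The preprocessing chain isolates a maximal cortex-free spherical region in
the oriented articular head, thresholds it with Otsu's criterion, and
removes floating particles / enclosed cavities before morphometry:

1. :func:`interior_box` — axis-aligned box whose faces touch the innermost
   cortical voxels along the six axis rays from the head center;
2. :func:`expand_sphere` — sphere grown from the box center until one voxel
   short of the nearest cortical voxel;
3. :func:`otsu_threshold` — between-class-variance maximization on the ROI
   histogram only;
4. :func:`purify` — keep the largest 26-connected bone component and fill
   marrow cavities (6-connected background) sealed off from the ROI border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume

__all__ = [
    "SphericalROI",
    "SegmentedROI",
    "interior_box",
    "expand_sphere",
    "otsu_threshold",
    "purify",
    "segment_roi",
]


@dataclass
class SphericalROI:
    """Sphere in voxel coordinates of the oriented frame."""

    center: np.ndarray  # (x, y, z)
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        nz, ny, nx = shape
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        cx, cy, cz = self.center
        return ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) <= self.radius ** 2

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        nz, ny, nx = shape
        cx, cy, cz = self.center
        for c, n in ((cx, nx), (cy, ny), (cz, nz)):
            if c - self.radius < 0 or c + self.radius > n - 1:
                raise ValueError("sphere extends outside the volume grid")


@dataclass
class SegmentedROI:
    """Binarized spherical region: bone / marrow partition of the sphere."""

    roi: SphericalROI
    foreground: np.ndarray  # bone, same shape as source volume
    background: np.ndarray  # marrow, restricted to the sphere
    otsu_threshold: float
    voxel_size: float  # µm

    def __post_init__(self) -> None:
        sphere = self.roi.mask(self.foreground.shape)
        if np.any(self.foreground & self.background):
            raise ValueError("foreground and background masks overlap")
        if not np.array_equal(self.foreground | self.background, sphere):
            raise ValueError("foreground and background must partition the sphere")


def interior_box(cortical_mask: np.ndarray, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box inside the cortical shell.

    From the head ``center`` (x, y, z voxels), march along each of the six
    axis directions until the first cortical voxel; the box face sits one
    voxel inside it.  Returns (lower, upper) inclusive voxel bounds in
    (x, y, z) order.

    Raises if a ray leaves the grid without meeting cortex (open shell).
    """
    if not np.any(cortical_mask):
        raise ValueError("cortical mask is empty")
    nz, ny, nx = cortical_mask.shape
    cx, cy, cz = (int(round(v)) for v in np.asarray(center, dtype=float))
    if cortical_mask[cz, cy, cx]:
        raise ValueError("head center lies inside cortical bone")

    def march(axis_vals: np.ndarray, start: int, step: int) -> int:
        i = start
        n = len(axis_vals)
        while 0 <= i < n:
            if axis_vals[i]:
                return i - step  # innermost non-cortical voxel
            i += step
        raise ValueError("open cortex: no cortical voxel along an axis ray")

    xline = cortical_mask[cz, cy, :]
    yline = cortical_mask[cz, :, cx]
    zline = cortical_mask[:, cy, cx]
    lower = np.array([march(xline, cx, -1), march(yline, cy, -1), march(zline, cz, -1)])
    upper = np.array([march(xline, cx, +1), march(yline, cy, +1), march(zline, cz, +1)])
    if np.any(upper < lower):
        raise ValueError("degenerate interior box")
    return lower, upper


def expand_sphere(box: tuple[np.ndarray, np.ndarray],
                  cortical_mask: np.ndarray,
                  min_radius: float = 3.0) -> SphericalROI:
    """Maximal cortex-free sphere centered on the interior box.

    radius = (Euclidean distance from the box center to the nearest cortical
    voxel) − 1, additionally capped so the sphere stays inside the grid.
    """
    lower, upper = box
    center = (np.asarray(lower, float) + np.asarray(upper, float)) / 2.0
    # exact Euclidean distance from the (possibly half-voxel) center to the
    # nearest cortical voxel
    zz, yy, xx = np.nonzero(cortical_mask)
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    radius = float(np.sqrt(d2.min())) - 1.0
    nz, ny, nx = cortical_mask.shape
    for c, n in ((center[0], nx), (center[1], ny), (center[2], nz)):
        radius = min(radius, c, (n - 1) - c)
    if radius < min_radius:
        raise ValueError(f"ROI radius {radius:.1f} voxels is too small to contain trabeculae")
    roi = SphericalROI(center=center, radius=radius)
    if np.any(cortical_mask & roi.mask(cortical_mask.shape)):
        raise ValueError("cortical voxel inside the expanded sphere")
    return roi


def otsu_threshold(values: np.ndarray, nbins: int | None = None) -> float:
    """Otsu's threshold of an intensity sample.

    Maximizes the between-class variance over the histogram (256 bins for
    8-bit input, native integer bins otherwise); when a range of thresholds
    attains the maximum, the midpoint of that range is returned.  Voxels
    with intensity strictly greater than the threshold are foreground.
    """
    values = np.asarray(values).ravel()
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("constant image: Otsu threshold undefined")
    if nbins is None:
        nbins = 256 if values.dtype == np.uint8 else int(hi) - int(lo) + 1
    counts, edges = np.histogram(values, bins=nbins, range=(float(lo), float(hi) + 1e-9))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)
    best = np.flatnonzero(np.isclose(sigma_b, sigma_b.max(), rtol=0, atol=1e-12))
    return float((centers[best[0]] + centers[best[-1]]) / 2.0)


_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


def purify(mask: np.ndarray, roi_mask: np.ndarray | None = None) -> np.ndarray:
    """Remove floating particles and sealed cavities.

    Keeps only the largest 26-connected foreground component, then fills
    every 6-connected background component that has no path to the ROI
    border (the grid border, or the complement of ``roi_mask`` when given).
    Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty foreground: nothing to purify")
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()
    else:
        mask = mask.copy()

    background = ~mask
    if roi_mask is not None:
        outside = ~np.asarray(roi_mask, dtype=bool)
    else:
        outside = np.zeros_like(mask)
        outside[0], outside[-1] = True, True
        outside[:, 0], outside[:, -1] = True, True
        outside[:, :, 0], outside[:, :, -1] = True, True
        outside &= background
    bg_labels, nb = ndimage.label(background, structure=_CONN6)
    open_ids = np.unique(bg_labels[outside & background])
    open_ids = open_ids[open_ids > 0]
    keep_open = np.isin(bg_labels, open_ids)
    cavity = background & ~keep_open
    mask[cavity] = True
    return mask


def segment_roi(volume: VoxelVolume, roi: SphericalROI,
                do_purify: bool = True) -> SegmentedROI:
    """Binarize a grayscale volume inside a spherical ROI by Otsu's
    criterion and (optionally) purify the bone phase."""
    sphere = roi.mask(volume.shape)
    vals = volume.values[sphere]
    thr = otsu_threshold(vals)
    fg = (volume.values > thr) & sphere
    if do_purify and np.any(fg):
        fg = purify(fg, roi_mask=sphere)
        fg &= sphere
    bg = sphere & ~fg
    return SegmentedROI(roi=roi, foreground=fg, background=bg,
                        otsu_threshold=thr, voxel_size=volume.voxel_size)
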