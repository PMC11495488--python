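"""Trabecular morphometry of a segmented spherical ROI.

Implements the univariate metric suite and the fabric tensor:

* BV/TV — bone voxels over total sphere voxels;
* MIL fabric tensor — mean intercept lengths over a quasi-uniform set of
  hemisphere directions, fitted as the quadratic form 1/MIL(n)^2 = n^T M n;
  its principal axes give the primary trabecular orientation and its radii
  the degree of anisotropy DA = 1 - r3/r1;
* TbTh / TbSp — Hildebrand–Rüegsegger model-independent local thickness
  (largest inscribed sphere) of the bone and marrow phases;
* TbN — struts per mm, by the plate model (BV/TV ÷ TbTh) or directly from
  intercept counts;
* azimuth / plunge — the primary eigenvector expressed as axial compass
  direction and dip, plus the folding transform used before ordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .segmentation import SegmentedROI

__all__ = [
    "FabricTensor",
    "TrabecularMetrics",
    "bone_volume_fraction",
    "mil_fabric",
    "mil_directional",
    "degree_of_anisotropy",
    "local_thickness",
    "trabecular_number",
    "eigenvector_to_azimuth_plunge",
    "fold_azimuth",
    "compute_all_metrics",
    "hemisphere_directions",
]


# ---------------------------------------------------------------------------
# Fabric tensor


@dataclass
class FabricTensor:
    """MIL ellipsoid fitted over the sampled directions.

    ``matrix`` is the symmetric positive-definite quadratic form M with
    1/MIL(n)^2 = n^T M n; radii r1 >= r2 >= r3 are 1/sqrt(eigenvalues),
    and ``axes`` holds the matching unit eigenvectors as rows (e1, e2, e3).
    """

    matrix: np.ndarray
    radii: np.ndarray
    axes: np.ndarray
    n_directions: int
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("fabric matrix must be symmetric")
        if np.any(self.radii <= 0) or np.any(np.diff(self.radii) > 1e-12):
            raise ValueError("radii must be positive and sorted descending")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal")

    @property
    def primary_axis(self) -> np.ndarray:
        return self.axes[0]


def hemisphere_directions(n: int, seed: int = 0) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere: a golden-spiral
    lattice, rotated by a seeded random rotation for sampling-bias control."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return dirs @ q.T


def _orthobasis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def mil_directional(segmented: SegmentedROI, n_directions: int = 512,
                    line_spacing: float = 2.0, seed: int = 0,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Directional intercept statistics over the ROI sphere.

    For each direction, parallel test lines at ``line_spacing`` (voxels) are
    cast through the sphere and sampled at one-voxel steps; marrow-to-bone
    transitions between consecutive in-sphere samples are counted as
    intercepts.  Returns (directions, mil, crossings, lengths) where
    MIL = total line length × BV/TV ÷ crossings, in voxels.
    """
    fg = segmented.foreground
    roi = segmented.roi
    bvtv = bone_volume_fraction(segmented)
    directions = hemisphere_directions(n_directions, seed)
    R = roi.radius
    cx, cy, cz = roi.center
    nz, ny, nx = fg.shape

    offsets = np.arange(-R, R + line_spacing, line_spacing)
    t = np.arange(-R, R + 1.0, 1.0)
    aa, bb = np.meshgrid(offsets, offsets, indexing="ij")
    ab2 = (aa.ravel() ** 2 + bb.ravel() ** 2)
    keep = ab2 <= R * R
    aa, bb, ab2 = aa.ravel()[keep], bb.ravel()[keep], ab2[keep]
    inside = (ab2[:, None] + t[None, :] ** 2) <= R * R  # (L, T)
    pair_inside = inside[:, :-1] & inside[:, 1:]

    mil = np.empty(n_directions)
    crossings = np.empty(n_directions)
    lengths = np.empty(n_directions)
    fgi = np.ascontiguousarray(fg, dtype=np.uint8)
    for k, d in enumerate(directions):
        u, v = _orthobasis(d)
        # world (x, y, z) sample points for all lines of this direction
        base = (cx + aa[:, None] * u[0] + bb[:, None] * v[0],
                cy + aa[:, None] * u[1] + bb[:, None] * v[1],
                cz + aa[:, None] * u[2] + bb[:, None] * v[2])
        px = np.rint(base[0] + t[None, :] * d[0]).astype(np.intp)
        py = np.rint(base[1] + t[None, :] * d[1]).astype(np.intp)
        pz = np.rint(base[2] + t[None, :] * d[2]).astype(np.intp)
        np.clip(px, 0, nx - 1, out=px)
        np.clip(py, 0, ny - 1, out=py)
        np.clip(pz, 0, nz - 1, out=pz)
        vals = fgi[pz, py, px]
        up = pair_inside & (vals[:, :-1] == 0) & (vals[:, 1:] == 1)
        c = int(up.sum())
        if c == 0:
            raise ValueError(
                "a test direction produced zero bone intercepts; use a larger "
                "ROI or coarser line spacing")
        length = float(pair_inside.sum())  # one voxel per in-sphere step
        crossings[k] = c
        lengths[k] = length
        mil[k] = length * bvtv / c
    return directions, mil, crossings, lengths


def mil_fabric(segmented: SegmentedROI, n_directions: int = 512,
               line_spacing: float = 2.0, seed: int = 0) -> FabricTensor:
    """Fit the MIL fabric tensor.

    Least-squares fit of 1/MIL(n)^2 = n^T M n over the sampled directions;
    eigendecomposition of M yields ellipsoid radii (descending) and the
    principal axes.  Deterministic for a fixed seed.
    """
    if n_directions < 64:
        raise ValueError("n_directions must be >= 64 for a stable tensor fit")
    if not np.any(segmented.foreground) or not np.any(segmented.background):
        raise ValueError("MIL requires both bone and marrow voxels in the ROI")
    directions, mil, _, _ = mil_directional(segmented, n_directions, line_spacing, seed)
    n = directions
    design = np.column_stack([
        n[:, 0] ** 2, n[:, 1] ** 2, n[:, 2] ** 2,
        2 * n[:, 0] * n[:, 1], 2 * n[:, 0] * n[:, 2], 2 * n[:, 1] * n[:, 2],
    ])
    y = 1.0 / mil ** 2
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    m = np.array([[coef[0], coef[3], coef[4]],
                  [coef[3], coef[1], coef[5]],
                  [coef[4], coef[5], coef[2]]])
    evals, evecs = np.linalg.eigh(m)
    if np.any(evals <= 0):
        raise ValueError("fabric fit is not positive definite; increase n_directions")
    radii = 1.0 / np.sqrt(evals)  # ascending evals -> descending radii
    order = np.argsort(radii)[::-1]
    return FabricTensor(matrix=m, radii=radii[order], axes=evecs.T[order],
                        n_directions=n_directions, seed=seed)


def degree_of_anisotropy(fabric: FabricTensor) -> float:
    """DA = 1 - r3/r1, in [0, 1): 0 for isotropy, toward 1 for full
    alignment."""
    return float(1.0 - fabric.radii[2] / fabric.radii[0])


# ---------------------------------------------------------------------------
# Scalar metrics


def bone_volume_fraction(segmented: SegmentedROI) -> float:
    """Foreground voxels over all voxels inside the sphere."""
    n_fg = int(np.count_nonzero(segmented.foreground))
    n_total = n_fg + int(np.count_nonzero(segmented.background))
    if n_total == 0:
        raise ValueError("empty ROI")
    return n_fg / n_total


def local_thickness(mask: np.ndarray, voxel_size: float,
                    radius_step: float = 0.5) -> tuple[np.ndarray, float]:
    """Model-independent local thickness (Hildebrand–Rüegsegger).

    The thickness at a voxel is the diameter of the largest sphere that
    contains the voxel and fits entirely inside the structure, computed by
    greyscale openings over the inscribed-sphere radius ladder (radii
    quantized at ``radius_step`` voxels).  Returns the thickness map in
    voxels and the foreground mean in mm (voxel_size is in µm).
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask: local thickness undefined")
    # crop to the mask bounding box for speed
    nz_idx = np.nonzero(mask)
    lo = [max(int(i.min()) - 1, 0) for i in nz_idx]
    hi = [int(i.max()) + 2 for i in nz_idx]
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    dt = ndimage.distance_transform_edt(sub)
    # floor-quantize the radius ladder: each rung r must satisfy r <= dt at
    # its generating voxels, otherwise the largest spheres are never painted
    radii = np.unique(np.floor(dt[sub] / radius_step) * radius_step)
    radii = radii[radii > 0]
    lt_sub = np.zeros(sub.shape, dtype=np.float32)
    for r in radii:  # ascending: larger spheres overwrite
        centers = dt >= r
        if not centers.any():
            continue
        reach = ndimage.distance_transform_edt(~centers) <= r
        lt_sub[reach & sub] = 2.0 * r
    lt = np.zeros(mask.shape, dtype=np.float32)
    lt[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = lt_sub
    mean_mm = float(lt[mask].mean()) * voxel_size * 1e-3
    return lt, mean_mm


def trabecular_number(segmented: SegmentedROI, method: str = "plate_model",
                      tbth_mm: float | None = None,
                      mil_kwargs: dict[str, Any] | None = None) -> float:
    """Struts per mm.

    plate_model: TbN = (BV/TV) / TbTh.  intercept: mean over MIL test
    directions of intercepts per mm of line.
    """
    if method == "plate_model":
        if tbth_mm is None:
            _, tbth_mm = local_thickness(segmented.foreground, segmented.voxel_size)
        if tbth_mm <= 0:
            raise ValueError("TbTh is zero; plate-model TbN undefined")
        return bone_volume_fraction(segmented) / tbth_mm
    if method == "intercept":
        kw = mil_kwargs or {}
        _, _, crossings, lengths = mil_directional(segmented, **kw)
        per_voxel = np.mean(crossings / lengths)
        return float(per_voxel / (segmented.voxel_size * 1e-3))
    raise ValueError(f"unknown TbN method {method!r}")


# ---------------------------------------------------------------------------
# Orientation angles


def eigenvector_to_azimuth_plunge(e1: np.ndarray) -> tuple[float, float]:
    """Axial unit vector -> (azimuth, plunge) in degrees.

    The axis sign is canonicalized to a non-negative Z component (axes are
    sign-free); plunge is the angle between the axis and the X–Y plane in
    [0, 90], azimuth is measured from +X toward +Y in [0, 360).  A vertical
    axis has undefined azimuth and returns 0 by convention.
    """
    e = np.asarray(e1, dtype=float)
    norm = np.linalg.norm(e)
    if norm < 1e-12:
        raise ValueError("zero vector has no orientation")
    e = e / norm
    if e[2] < 0 or (e[2] == 0 and (e[0] < 0 or (e[0] == 0 and e[1] < 0))):
        e = -e
    plunge = float(np.degrees(np.arcsin(np.clip(e[2], -1.0, 1.0))))
    if abs(plunge - 90.0) < 1e-9 or np.hypot(e[0], e[1]) < 1e-12:
        return 0.0, 90.0
    azimuth = float(np.degrees(np.arctan2(e[1], e[0]))) % 360.0
    return azimuth, plunge


def fold_azimuth(x: float | np.ndarray) -> float | np.ndarray:
    """Fold an azimuth onto [0, 90] via ||x - 180| - 90|.

    Antipodal and mirror-symmetric compass directions map to the same value,
    so nearby axial orientations with distant raw angles (e.g. 359 and 1)
    are paired before correlation/ordination.
    """
    return np.abs(np.abs(np.asarray(x, dtype=float) - 180.0) - 90.0) if np.ndim(x) else abs(abs(float(x) - 180.0) - 90.0)


# ---------------------------------------------------------------------------
# Composition


@dataclass
class TrabecularMetrics:
    """The univariate metric vector of one ROI."""

    bvtv: float
    da: float
    tbth: float  # mm
    tbsp: float  # mm
    tbn: float   # per mm
    azimuth: float  # degrees [0, 360)
    plunge: float   # degrees [0, 90]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.bvtv <= 1.0:
            raise ValueError("bvtv outside [0, 1]")
        if self.tbth <= 0 or self.tbsp <= 0 or self.tbn <= 0:
            raise ValueError("tbth, tbsp, tbn must be positive")
        if not 0.0 <= self.plunge <= 90.0 or not 0.0 <= self.azimuth < 360.0:
            raise ValueError("orientation angles out of range")

    def as_row(self) -> dict[str, Any]:
        row = {k: getattr(self, k) for k in
               ("bvtv", "da", "tbth", "tbsp", "tbn", "azimuth", "plunge")}
        row.update(self.provenance)
        return row


def compute_all_metrics(segmented: SegmentedROI, n_directions: int = 512,
                        line_spacing: float = 2.0, seed: int = 0,
                        tbn_method: str = "plate_model") -> TrabecularMetrics:
    """Run the full metric suite on one segmented ROI."""
    bvtv = bone_volume_fraction(segmented)
    fabric = mil_fabric(segmented, n_directions=n_directions,
                        line_spacing=line_spacing, seed=seed)
    da = degree_of_anisotropy(fabric)
    _, tbth = local_thickness(segmented.foreground, segmented.voxel_size)
    _, tbsp = local_thickness(segmented.background, segmented.voxel_size)
    tbn = trabecular_number(
        segmented, method=tbn_method, tbth_mm=tbth,
        mil_kwargs={"n_directions": n_directions,
                    "line_spacing": line_spacing, "seed": seed})
    azimuth, plunge = eigenvector_to_azimuth_plunge(fabric.primary_axis)
    return TrabecularMetrics(
        bvtv=bvtv, da=da, tbth=tbth, tbsp=tbsp, tbn=tbn,
        azimuth=azimuth, plunge=plunge,
        provenance={"n_directions": n_directions, "line_spacing": line_spacing,
                    "mil_seed": seed, "tbn_method": tbn_method})
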