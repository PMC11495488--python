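"""Standardized bone orientation from anatomical landmarks.

Every specimen is brought into a common anatomical frame before ROI
extraction so fabric orientations are comparable across individuals:

* the metaphysis-midpoint axis maps to +Z (proximal up),
* the chord between the two lateral head–neck contact points, orthogonalized
  against Z, maps to ±Y,
* the X sign is chosen so the articular surface points toward −X.

Left elements are mirrored across the Y–Z plane to stand in for missing
right elements.  Landmarks are supplied (from metadata or the synthetic
generator); automated anatomical landmarking is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import VoxelVolume

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "orientation_transform",
    "apply_transform",
    "transform_points",
    "mirror_element",
]


@dataclass
class LandmarkSet:
    """Five anatomical points in voxel (x, y, z) world coordinates."""

    proximal_metaphysis_midpoint: np.ndarray
    distal_metaphysis_midpoint: np.ndarray
    lateral_contact_a: np.ndarray
    lateral_contact_b: np.ndarray
    articular_surface_point: np.ndarray

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        axis = self.proximal_metaphysis_midpoint - self.distal_metaphysis_midpoint
        if np.linalg.norm(axis) < 1e-9:
            raise ValueError("proximal and distal metaphysis midpoints coincide")
        chord = self.lateral_contact_a - self.lateral_contact_b
        if np.linalg.norm(chord) < 1e-9:
            raise ValueError("lateral contact points coincide")
        z = axis / np.linalg.norm(axis)
        residual = chord - (chord @ z) * z
        if np.linalg.norm(residual) < 1e-6 * np.linalg.norm(chord):
            raise ValueError("lateral contact chord is collinear with the metaphysis axis")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LandmarkSet":
        """Build from a landmark CSV table with columns
        (landmark_name, x, y, z)."""
        lut = {r.landmark_name: np.array([r.x, r.y, r.z]) for r in table.itertuples()}
        return cls(**{k: lut[k] for k in cls.__dataclass_fields__})

    def points(self) -> np.ndarray:
        return np.stack([getattr(self, n) for n in self.__dataclass_fields__])


@dataclass
class RigidTransform:
    """p' = rotation @ p + translation, in world (x, y, z) voxel coordinates.

    The rotation is orthonormal with det +1, except transforms produced by
    mirroring, which carry det −1.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal within 1e-9")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def orientation_transform(landmarks: LandmarkSet) -> RigidTransform:
    """Rigid rotation bringing the landmarks into the standard frame.

    The returned transform has zero translation: it rotates about the world
    origin, mapping the metaphysis axis onto +Z and the lateral chord onto
    ±Y, with the X sign fixed so the articular point lies at negative X
    relative to the midpoint of the lateral contacts.
    """
    z = landmarks.proximal_metaphysis_midpoint - landmarks.distal_metaphysis_midpoint
    z = z / np.linalg.norm(z)
    chord = landmarks.lateral_contact_a - landmarks.lateral_contact_b
    y = chord - (chord @ z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    head_ref = 0.5 * (landmarks.lateral_contact_a + landmarks.lateral_contact_b)
    if (landmarks.articular_surface_point - head_ref) @ x > 0:
        # flip X and Y together to keep the rotation proper
        x, y = -x, -y
    rotation = np.stack([x, y, z])  # rows are the new axes
    assert np.isclose(np.linalg.det(rotation), 1.0, atol=1e-9)
    return RigidTransform(rotation)


def transform_points(points: np.ndarray, t: RigidTransform) -> np.ndarray:
    return t.apply(points)


def apply_transform(volume: VoxelVolume, t: RigidTransform,
                    interpolation: str = "nearest", pad: int = 2) -> VoxelVolume:
    """Resample a volume under a rigid transform.

    The output grid is the axis-aligned bounding box of the transformed
    input corners plus ``pad`` voxels per side; its ``origin`` records the
    world position of its first voxel.  Binary volumes must use nearest
    interpolation (trilinear would invent intermediate intensities).
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"interpolation must be nearest or trilinear, got {interpolation!r}")
    if interpolation == "trilinear" and volume.is_binary:
        raise ValueError("trilinear interpolation requested on a binary volume; use nearest")
    nz, ny, nx = volume.shape
    # world coordinates of the 8 grid corners
    corners = np.array([[x, y, z] for x in (0, nx - 1) for y in (0, ny - 1)
                        for z in (0, nz - 1)], dtype=float) + volume.origin
    tc = t.apply(corners)
    # snap near-integer bounds before floor/ceil so exact rotations (90-deg
    # turns, identity) do not grow the grid through float fuzz
    lo = np.floor(tc.min(axis=0) + 1e-6) - pad
    hi = np.ceil(tc.max(axis=0) - 1e-6) + pad
    out_shape = (int(hi[2] - lo[2]) + 1, int(hi[1] - lo[1]) + 1, int(hi[0] - lo[0]) + 1)

    inv = t.inverse()
    oz, oy, ox = np.meshgrid(np.arange(out_shape[0], dtype=np.float32),
                             np.arange(out_shape[1], dtype=np.float32),
                             np.arange(out_shape[2], dtype=np.float32), indexing="ij")
    world = np.stack([ox.ravel() + lo[0], oy.ravel() + lo[1], oz.ravel() + lo[2]], axis=1)
    src = inv.apply(world) - volume.origin  # world (x,y,z) -> input voxel coords
    coords = np.stack([src[:, 2], src[:, 1], src[:, 0]])  # to (z,y,x) index order
    order = 0 if interpolation == "nearest" else 1
    vals = ndimage.map_coordinates(volume.values.astype(np.float32), coords,
                                   order=order, mode="constant", cval=0.0)
    out = vals.reshape(out_shape)
    if volume.values.dtype == bool:
        out = out > 0.5
    else:
        out = np.rint(out).astype(volume.values.dtype)
    return VoxelVolume(out, voxel_size=volume.voxel_size, origin=lo)


def mirror_element(volume: VoxelVolume) -> VoxelVolume:
    """Reflect across the Y–Z plane (X axis flipped); an involution.

    Used to substitute a mirrored left element for a missing right one.  The
    reflection is realized as an in-grid flip of the X (column) axis, which
    equals X negation followed by a translation back into the grid.
    """
    return VoxelVolume(volume.values[:, :, ::-1].copy(),
                       voxel_size=volume.voxel_size, origin=volume.origin)


def mirror_points(points: np.ndarray, nx: int) -> np.ndarray:
    """Landmark counterpart of :func:`mirror_element` on an nx-wide grid."""
    p = np.atleast_2d(points).astype(float).copy()
    p[:, 0] = (nx - 1) - p[:, 0]
    return p
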