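"""Shared fixtures: small phantoms and segmented ROIs built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from trabkit import PhantomSpec, SegmentedROI, SphericalROI, generate_rod_phantom
from trabkit.volume import VoxelVolume


def inscribed_roi(shape: tuple[int, int, int], margin: float = 3.0) -> SphericalROI:
    """Largest sphere that fits the grid with a safety margin."""
    center = (np.array(shape, dtype=float)[::-1] - 1) / 2.0
    radius = min(shape) / 2.0 - margin
    return SphericalROI(center=center, radius=radius)


def segment_binary(volume: VoxelVolume, roi: SphericalROI | None = None) -> SegmentedROI:
    """Wrap an already-binary volume as a SegmentedROI on its inscribed
    sphere (threshold is nominal: the mask is the segmentation)."""
    roi = roi or inscribed_roi(volume.shape)
    sphere = roi.mask(volume.shape)
    fg = volume.values.astype(bool) & sphere
    return SegmentedROI(roi=roi, foreground=fg, background=sphere & ~fg,
                        otsu_threshold=0.5, voxel_size=volume.voxel_size)


@pytest.fixture(scope="session")
def iso_phantom():
    """Isotropic rod lattice, 64³, BV/TV 0.3."""
    spec = PhantomSpec(shape=(64, 64, 64), target_bvtv=0.3, strut_radius=3.0,
                       kappa=0.0, seed=101)
    return generate_rod_phantom(spec)


@pytest.fixture(scope="session")
def aligned_phantom():
    """Strongly Z-aligned rod lattice, 64³, BV/TV 0.3."""
    spec = PhantomSpec(shape=(64, 64, 64), target_bvtv=0.3, strut_radius=3.0,
                       mean_axis=(0.0, 0.0, 1.0), kappa=200.0, seed=102)
    return generate_rod_phantom(spec)


@pytest.fixture(scope="session")
def aligned_seg(aligned_phantom):
    vol, _ = aligned_phantom
    return segment_binary(vol)


@pytest.fixture(scope="session")
def iso_seg(iso_phantom):
    vol, _ = iso_phantom
    return segment_binary(vol)
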