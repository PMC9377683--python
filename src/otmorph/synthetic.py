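"""Synthetic density maps with known ground truth.

Everything the solver and metrics need can be exercised without downloading
deposited maps: sums of Gaussian blobs, rasterization of atom coordinates
(one unit-mass Gaussian per atom, the standard way simulated maps are built
from structural-morphing frames), and a parametric two-state "open/closed"
fixture — a ring body with arms that swing outward — whose intermediate
states form a ground-truth displacement trajectory for metric tests.

All generators are deterministic functions of their arguments; there is no
hidden randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .density import DensityMap

__all__ = ["BlobSpec", "blob_map", "atoms_to_map", "two_state_fixture"]


@dataclass
class BlobSpec:
    """One isotropic Gaussian blob in voxel coordinates."""

    center: tuple  # (x, y, z) voxels
    sigma: float  # standard deviation, voxels
    weight: float = 1.0  # total mass

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.weight > 0:
            raise ValueError("weight must be positive")


def _axis_profile(n: int, center: float, sigma: float, cut: float) -> np.ndarray:
    x = np.arange(n, dtype=np.float64) - center
    g = np.exp(-(x**2) / (2.0 * sigma * sigma)) / (math.sqrt(2.0 * math.pi) * sigma)
    g[np.abs(x) > cut] = 0.0
    return g


def blob_map(shape, blobs, voxel_size: float = 1.0, truncation: float = 4.0) -> DensityMap:
    """Sum of isotropic Gaussian blobs, each truncated at ``truncation``·σ.

    Each blob integrates to its weight (to ~1e-3 relative for blobs in the
    grid interior; truncation and edge clipping account for the rest).
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError(f"shape must be three dims >= 8, got {shape}")
    data = np.zeros(shape)
    for blob in blobs:
        c = np.asarray(blob.center, dtype=np.float64)
        if np.any(c < 0) or np.any(c > np.array(shape) - 1):
            raise ValueError(f"blob center {tuple(c)} outside grid {shape}")
        cut = truncation * blob.sigma
        profiles = [
            _axis_profile(shape[ax], c[ax], blob.sigma, cut) for ax in range(3)
        ]
        data += blob.weight * (
            profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
        )
    return DensityMap(data=data, voxel_size=voxel_size, label="synthetic blobs")


def atoms_to_map(
    coords,
    shape,
    voxel_size: float,
    sigma: float = 1.5,
    origin=None,
) -> DensityMap:
    """Rasterize atom coordinates as one unit-mass Gaussian per atom.

    ``coords`` and ``sigma`` are in Å.  By default the origin is placed so
    the coordinate bounding box is centred in the grid; pass ``origin``
    explicitly to pin the frame (e.g. to rasterize a whole trajectory into
    one common grid).  The default σ of 1.5 Å is a typical width for
    mimicking intermediate-resolution maps from atomic models.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a nonempty (n, 3) array of Å positions")
    shape = tuple(int(n) for n in shape)
    if not voxel_size > 0:
        raise ValueError("voxel_size must be positive")
    if origin is None:
        bbox_mid = (coords.min(axis=0) + coords.max(axis=0)) / 2.0
        origin = bbox_mid - (np.array(shape) - 1) / 2.0 * voxel_size
    origin = np.asarray(origin, dtype=np.float64)
    vox = (coords - origin) / voxel_size
    hi = np.array(shape) - 1
    bad = np.where(np.any((vox < 0) | (vox > hi), axis=1))[0]
    if bad.size:
        raise ValueError(f"atom {bad[0]} lies outside the map box after placement")
    blobs = [BlobSpec(center=tuple(v), sigma=sigma / voxel_size) for v in vox]
    out = blob_map(shape, blobs, voxel_size=voxel_size)
    out.origin = origin
    out.label = "synthetic atoms"
    return out


def _arm_direction(phi: float, tilt: float) -> np.ndarray:
    # unit vector tilted away from +z by `tilt`, azimuth phi in the xy plane
    return np.array(
        [math.sin(tilt) * math.cos(phi), math.sin(tilt) * math.sin(phi), math.cos(tilt)]
    )


def two_state_fixture(
    shape=(60, 60, 60),
    n_arms: int = 8,
    opening: float = 0.0,
    n_ring: int = 16,
    n_segments: int = 6,
    segment_length: float | None = None,
    max_tilt_deg: float = 65.0,
    ring_sigma: float = 1.8,
    arm_sigma: float = 1.8,
) -> DensityMap:
    """Ring body with blob-chain arms that swing outward as ``opening`` grows.

    At ``opening=0`` the arms stand vertically (closed, compact); at
    ``opening=1`` each arm is tilted ``max_tilt_deg`` outward (open, spread).
    The same blobs are present at every opening, only displaced, so total
    intensity is constant along the ground-truth trajectory — exactly the
    situation displacement interpolation should reproduce and cross-fading
    should not.

    The default geometry caricatures a group II chaperonin barrel: eight
    arms (the 8-fold symmetric apical protrusions) as thick as the ring
    wall, carrying roughly half the structure's mass, with arm length about
    a third of the box — on the 60³ working grid to which γ = 1 is matched.
    ``segment_length`` defaults to 5% of the smallest box edge so the
    geometry scales with the grid.
    """
    shape = tuple(int(n) for n in shape)
    if n_arms < 2:
        raise ValueError("n_arms must be >= 2")
    if not 0.0 <= opening <= 1.0:
        raise ValueError("opening must be in [0, 1]")
    cx, cy = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    z0 = 0.35 * shape[2]
    ring_radius = 0.18 * min(shape[:2])
    if segment_length is None:
        segment_length = 0.05 * min(shape)
    blobs = []
    for j in range(n_ring):
        phi = 2.0 * math.pi * j / n_ring
        blobs.append(
            BlobSpec(
                center=(cx + ring_radius * math.cos(phi), cy + ring_radius * math.sin(phi), z0),
                sigma=ring_sigma,
                weight=1.0,
            )
        )
    tilt = math.radians(max_tilt_deg) * opening
    for j in range(n_arms):
        phi = 2.0 * math.pi * j / n_arms
        base = np.array(
            [cx + ring_radius * math.cos(phi), cy + ring_radius * math.sin(phi), z0]
        )
        direction = _arm_direction(phi, tilt)
        for k in range(1, n_segments + 1):
            blobs.append(
                BlobSpec(center=tuple(base + k * segment_length * direction), sigma=arm_sigma)
            )
    out = blob_map(shape, blobs)
    # renormalize to the blob count: open-state arm tips graze the box edge
    # and lose a little truncated tail mass, but the ground-truth trajectory
    # must conserve mass exactly (same blobs, displaced)
    out.data *= len(blobs) / out.data.sum()
    out.label = f"two-state fixture (opening={opening:g})"
    return out
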