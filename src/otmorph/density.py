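"""Density-map containers and MRC2014 I/O.

A cryo-EM map is a 3D scalar field on a regular voxel lattice, stored on disk
in the MRC2014/CCP4 format.  :class:`DensityMap` is the in-memory form used
everywhere in this package: data in (x, y, z) axis order regardless of the
file's MAPC/MAPR/MAPS permutation, a voxel edge length in Å and the physical
position of voxel (0, 0, 0).  :class:`ProbabilityField` is a map normalized to
unit mass — the measure the transport solver operates on — remembering the
original total intensity so outputs can be rescaled back to map units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

from .errors import (
    AnisotropicVoxelWarning,
    DegenerateInputError,
    GridMismatchError,
    MapDataError,
    MapFormatError,
)

__all__ = [
    "DensityMap",
    "ProbabilityField",
    "read_map",
    "write_map",
    "to_probability",
    "resample",
]


@dataclass
class DensityMap:
    """A 3D density map on a regular voxel grid.

    Parameters
    ----------
    data
        Voxel intensities, shape (nx, ny, nz), any real values.
    voxel_size
        Edge length of a voxel in Å.  A scalar or a length-3 sequence;
        anisotropic edges are stored but trigger a warning, and the mean
        edge is used wherever a single physical length is needed.
    origin
        Physical coordinate (Å) of the centre of voxel (0, 0, 0).
    label
        Free-text provenance note.
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise MapDataError(f"expected a 3D field, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise MapDataError(f"all dimensions must be >= 2, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise MapDataError("map contains non-finite voxel values")
        vs = np.asarray(self.voxel_size, dtype=np.float64)
        if vs.ndim == 0:
            vs = np.full(3, float(vs))
        if vs.shape != (3,):
            raise ValueError("voxel_size must be a scalar or length-3 sequence")
        if np.any(vs <= 0):
            raise ValueError(f"voxel_size must be positive, got {vs}")
        if not np.allclose(vs, vs[0], rtol=1e-6):
            warnings.warn(
                f"anisotropic voxel size {vs}; mean edge used for physical units",
                AnisotropicVoxelWarning,
                stacklevel=2,
            )
        self.voxel_size = vs
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_edge(self) -> float:
        """Mean voxel edge in Å (the single physical length scale)."""
        return float(self.voxel_size.mean())

    def total_mass(self) -> float:
        return float(self.data.sum())

    def with_data(self, data: np.ndarray, label: str | None = None) -> "DensityMap":
        """New map on the same grid with replaced intensities."""
        return DensityMap(
            data=data,
            voxel_size=self.voxel_size.copy(),
            origin=self.origin.copy(),
            label=self.label if label is None else label,
        )


@dataclass
class ProbabilityField:
    """A nonnegative 3D field of unit total mass (a discrete measure).

    ``source_mass`` is the total intensity of the originating map after
    clamping, so barycenters expressed as probabilities can be rescaled back
    to the intensity scale of the inputs.
    """

    data: np.ndarray
    source_mass: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ProbabilityField requires a 3D field")
        if np.any(self.data < 0):
            raise ValueError("ProbabilityField must be elementwise nonnegative")
        total = self.data.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ProbabilityField must sum to 1, got {total!r}")
        if not self.source_mass > 0:
            raise ValueError("source_mass must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def read_map(path) -> DensityMap:
    """Read an MRC2014/CCP4 volume (modes 0/1/2/6).

    Axis order is normalized to (x, y, z) whatever the header's
    MAPC/MAPR/MAPS says; voxel size comes from CELLA / grid sampling and the
    origin from the ORIGIN header words.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC map {path}: {exc}") from exc
    data = np.array(ccp4.grid, copy=True).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise MapDataError(f"map {path} contains non-finite voxels")
    spacing = np.asarray(ccp4.grid.spacing, dtype=np.float64)
    if np.any(spacing <= 0):  # header with zero cell: fall back to 1 Å
        spacing = np.ones(3)
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=np.float64)
    return DensityMap(data=data, voxel_size=spacing, origin=origin, label=str(path))


def write_map(density: DensityMap, path) -> None:
    """Write a map as MRC2014 mode 2 (float32) with voxel size and origin."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(density.data, dtype=np.float32))
    nx, ny, nz = density.shape
    vs = density.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vs[0], ny * vs[1], nz * vs[2], 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(word, float(value))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write MRC map {path}: {exc}") from exc


def to_probability(density: DensityMap, negative: str = "clamp") -> ProbabilityField:
    """Turn a map into a unit-mass measure.

    Negative intensities (routine in sharpened maps) are clamped to zero by
    default — transport needs a nonnegative measure; ``negative="error"``
    rejects them instead.  An all-zero / all-negative map has no mass to
    transport and raises :class:`DegenerateInputError`.
    """
    if negative not in ("clamp", "error"):
        raise ValueError("negative must be 'clamp' or 'error'")
    data = density.data
    if negative == "error" and np.any(data < 0):
        raise MapDataError("map has negative intensities and negative='error'")
    clamped = np.maximum(data, 0.0)
    total = clamped.sum()
    if not total > 0:
        raise DegenerateInputError("map has no positive intensity; cannot normalize")
    return ProbabilityField(data=clamped / total, source_mass=float(total))


def resample(density: DensityMap, target_shape) -> DensityMap:
    """Trilinear resampling onto ``target_shape`` over the same physical box.

    The voxel size is rescaled so the physical extent is preserved, and the
    output is renormalized so total intensity exactly matches the input —
    the transport stage requires mass conservation, so interpolation error
    in the total is scaled out.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or min(target_shape) < 2:
        raise ValueError(f"target shape must be three dims >= 2, got {target_shape}")
    src_shape = np.array(density.shape, dtype=np.float64)
    dst_shape = np.array(target_shape, dtype=np.float64)
    if tuple(density.shape) == target_shape:
        return density.with_data(density.data.copy())
    # cell-centred sampling: target voxel j covers the same box fraction as
    # source coordinate (j + 1/2) * (src/dst) - 1/2
    scale = src_shape / dst_shape
    axes = [
        (np.arange(n) + 0.5) * s - 0.5 for n, s in zip(target_shape, scale)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        density.data, np.stack(coords), order=1, mode="nearest"
    )
    total_in = density.data.sum()
    total_out = out.sum()
    if total_in != 0 and total_out != 0:
        out *= total_in / total_out
    new_vs = density.voxel_size * scale
    # keep the physical corner of the box fixed; origin marks a voxel centre
    corner = density.origin - density.voxel_size / 2.0
    new_origin = corner + new_vs / 2.0
    return DensityMap(data=out, voxel_size=new_vs, origin=new_origin, label=density.label)


def require_same_grid(a: DensityMap, b: DensityMap) -> None:
    """Raise :class:`GridMismatchError` unless the two maps share a grid."""
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shapes differ: {a.shape} vs {b.shape}")
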