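"""Map and trajectory comparison metrics.

RMSD over voxels, binarized volume difference Δ_Vol, symmetric voxel
difference Δ_Voxel, and L2 distance matrices with best-match assignment of
trajectory frames to reference maps.  RMSD and the L2 norm differ only by a
factor √n (n = voxel count of the common grid), so best matches under either
are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .density import DensityMap
from .errors import DegenerateInputError, GridMismatchError
from .interpolate import Trajectory

__all__ = [
    "BinaryMap",
    "MatchResult",
    "rmsd",
    "binarize",
    "delta_vol",
    "delta_voxel",
    "l2_matrix",
]


def _data(x) -> np.ndarray:
    if isinstance(x, DensityMap):
        return x.data
    return np.asarray(x, dtype=np.float64)


def _check_same(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shapes differ: {a.shape} vs {b.shape}")


@dataclass
class BinaryMap:
    """A map thresholded at a fraction of its own maximum."""

    bits: np.ndarray
    threshold_fraction: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")

    @property
    def volume(self) -> int:
        """Occupied volume in voxels: the count of true bits."""
        return int(self.bits.sum())


@dataclass
class MatchResult:
    """L2 distances between reference maps (rows) and trajectory frames."""

    l2: np.ndarray  # (n_refs, n_frames)
    best_t: np.ndarray  # per reference: t of the nearest frame
    best_index: np.ndarray  # per reference: index of the nearest frame

    def to_tsv(self, path, reference_ids=None) -> None:
        """One row per reference: id, best_t, best_index, then the L2 row."""
        n_refs, n_frames = self.l2.shape
        ids = reference_ids or [f"ref_{r}" for r in range(n_refs)]
        with Path(path).open("w") as fh:
            cols = "\t".join(f"l2_{k}" for k in range(n_frames))
            fh.write(f"reference\tbest_t\tbest_index\t{cols}\n")
            for r in range(n_refs):
                row = "\t".join(f"{x:.8g}" for x in self.l2[r])
                fh.write(f"{ids[r]}\t{self.best_t[r]:.6f}\t{self.best_index[r]}\t{row}\n")


def rmsd(x, y) -> float:
    """Root-mean-square voxel difference √(Σ(Xᵢ−Yᵢ)²/n) over the full grid."""
    a, b = _data(x), _data(y)
    _check_same(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def binarize(x, threshold_fraction: float = 0.01) -> BinaryMap:
    """Threshold a map at ``threshold_fraction`` of its own maximum.

    Voxel i is set iff Xᵢ > fraction · max(X), strictly — a constant map
    binarizes to all-zero bits.  Default fraction 1%.
    """
    a = _data(x)
    peak = a.max()
    if not peak > 0:
        raise DegenerateInputError("map maximum must be positive to binarize")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    return BinaryMap(bits=a > threshold_fraction * peak, threshold_fraction=threshold_fraction)


def delta_vol(x, y, threshold_fraction: float = 0.01) -> int:
    """|Vol(X) − Vol(Y)| after binarizing each map at its own maximum."""
    return abs(binarize(x, threshold_fraction).volume - binarize(y, threshold_fraction).volume)


def delta_voxel(x, y, threshold_fraction: float = 0.01) -> float:
    """Fraction of voxels where exactly one binarized map is occupied.

    The symmetric difference (1/n)·Σ[X̃ᵢ(1−Ỹᵢ) + Ỹᵢ(1−X̃ᵢ)]; always in [0, 1].
    """
    a, b = _data(x), _data(y)
    _check_same(a, b)
    xb = binarize(a, threshold_fraction).bits
    yb = binarize(b, threshold_fraction).bits
    return float(np.mean(xb ^ yb))


def l2_matrix(references, trajectory: Trajectory, normalize: bool = True) -> MatchResult:
    """L2 distances of each reference map to each trajectory frame.

    With ``normalize=True`` (default) every map is scaled to unit total
    intensity first: barycenters and deposited maps live on different
    intensity scales, and matching should compare shapes, not scales.
    Ties in the per-row minimum resolve to the smallest frame index.
    """
    frames = [_data(f) for f in trajectory.frames]
    refs = [_data(r) for r in references]
    if not refs:
        raise ValueError("need at least one reference map")
    for r in refs:
        _check_same(r, frames[0])

    def _prep(a: np.ndarray) -> np.ndarray:
        if not normalize:
            return a
        total = a.sum()
        if total == 0:
            raise DegenerateInputError("cannot normalize a zero-mass map")
        return a / total

    frames = [_prep(f) for f in frames]
    refs = [_prep(r) for r in refs]
    l2 = np.empty((len(refs), len(frames)))
    for i, r in enumerate(refs):
        for k, f in enumerate(frames):
            l2[i, k] = np.sqrt(np.sum((r - f) ** 2))
    best_index = np.argmin(l2, axis=1)  # argmin takes the first minimum: smallest index
    best_t = np.asarray(trajectory.ts)[best_index]
    return MatchResult(l2=l2, best_t=best_t, best_index=best_index)
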