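"""Morphing trajectories between two density maps.

Three interpolation methods share one convention — t = 0 is the source map
V0, t = 1 the target V1, and trajectory endpoints return the input maps
verbatim:

``linear``
    voxelwise cross-fade (1−t)·V0 + t·V1.  Cheap, but mass appears and
    disappears in place ("teleportation") instead of moving.
``ot``
    each interior frame is the entropic Wasserstein barycenter of the
    normalized inputs at weights (1−t, t), rescaled to the linearly
    interpolated total intensity — mass is displaced along transport lines.
``semi``
    OT barycenters at a subset of uniformly spaced keyframes, linear fills
    in between: a cheaper approximation when maps are large.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .density import DensityMap, require_same_grid, to_probability, write_map
from .errors import GridMismatchError
from .transport import ConvergenceReport, TransportParams, barycenter

__all__ = [
    "Trajectory",
    "linear_frame",
    "ot_frame",
    "linear_trajectory",
    "ot_trajectory",
    "semi_trajectory",
    "export_trajectory",
]


@dataclass
class Trajectory:
    """An ordered sequence of interpolated maps V_t, t ∈ [0, 1]."""

    frames: list  # list[DensityMap]
    ts: np.ndarray
    method: str  # "ot" | "linear" | "semi"
    params: TransportParams | None = None
    reports: list = field(default_factory=list)  # ConvergenceReport | None per frame

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=np.float64)
        if len(self.frames) != len(self.ts):
            raise ValueError("frames and ts must have equal length")
        if len(self.ts) < 2 or self.ts[0] != 0.0 or self.ts[-1] != 1.0:
            raise ValueError("ts must run from 0 to 1")
        if np.any(np.diff(self.ts) <= 0):
            raise ValueError("ts must be strictly increasing")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise GridMismatchError("all frames must share one grid")
        if not self.reports:
            self.reports = [None] * len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def linear_frame(v0: DensityMap, v1: DensityMap, t: float) -> DensityMap:
    """Voxelwise convex combination (1−t)·V0 + t·V1."""
    require_same_grid(v0, v1)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    return v0.with_data((1.0 - t) * v0.data + t * v1.data)


def ot_frame(
    v0: DensityMap,
    v1: DensityMap,
    t: float,
    params: TransportParams | None = None,
    return_report: bool = False,
):
    """Displacement interpolant at coordinate t.

    Both maps are normalized to unit mass, the barycenter with weights
    (1−t, t) is computed, and the result is rescaled so its total intensity
    is (1−t)·mass(V0) + t·mass(V1).
    """
    require_same_grid(v0, v1)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    params = params or TransportParams()
    p0 = to_probability(v0)
    p1 = to_probability(v1)
    bary, report = barycenter([p0, p1], [1.0 - t, t], params)
    mass = (1.0 - t) * p0.source_mass + t * p1.source_mass
    frame = v0.with_data(bary.data * mass)
    if return_report:
        return frame, report
    return frame


def _frame_ts(n_frames: int) -> np.ndarray:
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    return np.arange(n_frames, dtype=np.float64) / (n_frames - 1)


def _verbatim(v: DensityMap) -> DensityMap:
    return v.with_data(v.data.copy())


def linear_trajectory(v0: DensityMap, v1: DensityMap, n_frames: int) -> Trajectory:
    """Pure cross-fade trajectory; endpoints are the inputs verbatim."""
    ts = _frame_ts(n_frames)
    frames = [_verbatim(v0)]
    frames += [linear_frame(v0, v1, t) for t in ts[1:-1]]
    frames.append(_verbatim(v1))
    return Trajectory(frames=frames, ts=ts, method="linear")


def ot_trajectory(
    v0: DensityMap,
    v1: DensityMap,
    n_frames: int,
    params: TransportParams | None = None,
) -> Trajectory:
    """OT trajectory: one barycenter per interior frame, endpoints verbatim.

    Every interior frame is solved independently from all-ones scalings, so
    the trajectory is deterministic and frames can be recomputed in isolation.
    """
    params = params or TransportParams()
    ts = _frame_ts(n_frames)
    frames = [_verbatim(v0)]
    reports: list[ConvergenceReport | None] = [None]
    for t in ts[1:-1]:
        frame, report = ot_frame(v0, v1, float(t), params, return_report=True)
        frames.append(frame)
        reports.append(report)
    frames.append(_verbatim(v1))
    reports.append(None)
    return Trajectory(frames=frames, ts=ts, method="ot", params=params, reports=reports)


def semi_trajectory(
    v0: DensityMap,
    v1: DensityMap,
    n_frames: int,
    n_keyframes: int,
    params: TransportParams | None = None,
) -> Trajectory:
    """Mixed trajectory: OT barycenters at keyframes, linear fills between.

    ``n_keyframes`` uniformly spaced t values (endpoints included) get true
    barycenters; every other frame is a linear blend of the two bracketing
    keyframes with a locally rescaled coordinate.  n_keyframes = n_frames
    reproduces :func:`ot_trajectory`; n_keyframes = 2 is a pure cross-fade.
    """
    params = params or TransportParams()
    if n_keyframes < 2 or n_keyframes > n_frames:
        raise ValueError("need 2 <= n_keyframes <= n_frames")
    ts = _frame_ts(n_frames)
    key_ts = _frame_ts(n_keyframes)
    key_frames: dict[int, tuple[DensityMap, ConvergenceReport | None]] = {
        0: (_verbatim(v0), None),
        n_keyframes - 1: (_verbatim(v1), None),
    }
    for j in range(1, n_keyframes - 1):
        frame, report = ot_frame(v0, v1, float(key_ts[j]), params, return_report=True)
        key_frames[j] = (frame, report)

    frames: list[DensityMap] = []
    reports: list[ConvergenceReport | None] = []
    for k, t in enumerate(ts):
        if k == 0:
            frames.append(_verbatim(v0))
            reports.append(None)
            continue
        if k == n_frames - 1:
            frames.append(_verbatim(v1))
            reports.append(None)
            continue
        # nearest keyframe coordinate match, else linear fill in the bracket
        j = int(np.round(t * (n_keyframes - 1)))
        if abs(key_ts[j] - t) <= 1e-12:
            frame, report = key_frames[j]
            frames.append(frame.with_data(frame.data.copy()))
            reports.append(report)
            continue
        lo = int(np.floor(t * (n_keyframes - 1)))
        hi = lo + 1
        local = (t - key_ts[lo]) / (key_ts[hi] - key_ts[lo])
        frames.append(linear_frame(key_frames[lo][0], key_frames[hi][0], float(local)))
        reports.append(None)
    return Trajectory(
        frames=frames, ts=ts, method="semi", params=params, reports=reports
    )


def export_trajectory(traj: Trajectory, outdir) -> Path:
    """Write frames as frame_NNN.mrc plus a tab-separated manifest.

    The manifest records per frame: index, t, method, γ, iterations used and
    the convergence flag (empty for frames that required no solve).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    gamma = traj.params.gamma if traj.params is not None else ""
    with manifest.open("w") as fh:
        fh.write("frame\tt\tmethod\tgamma\titerations\tconverged\n")
        for k, (frame, t, report) in enumerate(zip(traj.frames, traj.ts, traj.reports)):
            name = f"frame_{k:03d}.mrc"
            write_map(frame, outdir / name)
            iters = "" if report is None else report.iterations_used
            conv = "" if report is None else report.converged
            fh.write(f"{k}\t{t:.6f}\t{traj.method}\t{gamma}\t{iters}\t{conv}\n")
    return manifest
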