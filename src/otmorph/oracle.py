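"""Dense small-grid transport oracle.

Evaluates the entropic transport objective literally — explicit m×m squared
Euclidean cost matrix over flattened voxels, dense Gibbs kernel, plan
π = diag(u) K diag(v), plan entropy — so that the convolutional solver can be
cross-checked on grids small enough for the m×m matrices to fit in memory.
This is a verification harness, deliberately independent of the
convolutional code path: it never calls :func:`otmorph.transport.apply_kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import xlogy

from .density import ProbabilityField
from .errors import GridMismatchError, NumericalError

__all__ = ["TransportPlanDense", "dense_transport_oracle", "dense_barycenter"]

_MAX_VOXELS = 12**3


@dataclass
class TransportPlanDense:
    """Explicit transport plan between two flattened small-grid measures."""

    plan: np.ndarray  # m×m, nonnegative, marginals = (p, q)
    cost: np.ndarray  # m×m squared Euclidean distances in voxel units
    entropy: float  # H(π) = −Σ π ln π with 0·ln 0 = 0


def _dense_kernel(shape, gamma: float, convention: str) -> tuple[np.ndarray, np.ndarray]:
    coords = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    cost = cdist(coords, coords, metric="sqeuclidean")
    denom = gamma if convention == "standard" else 2.0 * gamma
    return cost, np.exp(-cost / denom)


def dense_transport_oracle(
    p: ProbabilityField,
    q: ProbabilityField,
    gamma: float,
    convention: str = "standard",
    max_iter: int = 20000,
    tol: float = 1e-13,
) -> tuple[float, TransportPlanDense]:
    """Entropic transport cost by explicit dense Sinkhorn on a small grid.

    Returns the converged objective Σ d²π − γH(π) and the plan itself.
    Grids above 12³ voxels are refused (the cost matrix is m×m dense).
    """
    if p.shape != q.shape:
        raise GridMismatchError(f"grids differ: {p.shape} vs {q.shape}")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    m = int(np.prod(p.shape))
    if m > _MAX_VOXELS:
        raise ValueError(f"grid has {m} voxels; dense oracle is capped at {_MAX_VOXELS}")
    cost, kernel = _dense_kernel(p.shape, gamma, convention)
    a = p.data.ravel()
    b = q.data.ravel()
    floor = 1e-300
    u = np.ones(m)
    v = np.ones(m)
    for _ in range(max_iter):
        u_new = a / np.maximum(kernel @ v, floor)
        v_new = b / np.maximum(kernel.T @ u_new, floor)
        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            raise NumericalError("dense Sinkhorn diverged; increase gamma")
        delta = math.sqrt(float(np.sum((u_new - u) ** 2) + np.sum((v_new - v) ** 2)))
        u, v = u_new, v_new
        if delta <= tol:
            break
    plan = u[:, None] * kernel * v[None, :]
    entropy = -float(xlogy(plan, plan).sum())
    w2sq = float((cost * plan).sum()) - gamma * entropy
    return w2sq, TransportPlanDense(plan=plan, cost=cost, entropy=entropy)


def dense_barycenter(
    measures: list[ProbabilityField],
    weights,
    gamma: float,
    convention: str = "standard",
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Iterated-Bregman barycenter with the dense kernel (verification only).

    Mirrors the convolutional barycenter pass but multiplies by the explicit
    kernel matrix; returns the normalized barycenter field on the grid.
    """
    if len(measures) < 2:
        raise ValueError("need at least two measures")
    alphas = np.asarray(weights, dtype=np.float64)
    if np.any(alphas < 0) or abs(alphas.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    shape = measures[0].shape
    m = int(np.prod(shape))
    if m > _MAX_VOXELS:
        raise ValueError(f"grid has {m} voxels; dense oracle is capped at {_MAX_VOXELS}")
    _, kernel = _dense_kernel(shape, gamma, convention)
    floor = 1e-300
    mus = [mm.data.ravel() for mm in measures]
    v = [np.ones(m) for _ in measures]
    prev = None
    mu = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        log_mu = np.zeros(m)
        d_fields = []
        for i, mu_i in enumerate(mus):
            w_i = mu_i / np.maximum(kernel @ v[i], floor)
            d_i = v[i] * (kernel @ w_i)
            d_fields.append(d_i)
            if alphas[i] != 0.0:
                log_mu += alphas[i] * np.log(np.maximum(d_i, floor))
        mu = np.exp(log_mu)
        for i in range(len(mus)):
            v[i] = v[i] * mu / np.maximum(d_fields[i], floor)
        mu_n = mu / mu.sum()
        if prev is not None and math.sqrt(float(np.sum((mu_n - prev) ** 2))) <= tol:
            prev = mu_n
            break
        prev = mu_n
    return prev.reshape(shape)
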