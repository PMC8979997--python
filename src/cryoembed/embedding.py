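"""Weighted spherical embedding (spherical MDS on the unit sphere).

Given a symmetric matrix of target angles in [0, pi] and non-negative
weights, find n points on the unit sphere whose geodesic distances match the
targets in weighted least squares:

    stress = sum_{i != j} w_ij (target_ij - d_ij)^2,   d_ij = arccos(x_i . x_j)

(the ordered sum, each unordered pair counted twice, so the reported value
matches the defining formula literally).  Initialization is spectral: the
cosine matrix of the targets is a Gram matrix of unit vectors when the
targets are realizable, so its top-3 eigenspace recovers the configuration
up to a global orthogonal transform; refinement is projected gradient
descent on the sphere with backtracking line search, which is monotone in
the stress.

Missing targets (weight 0) impose no constraint.  The weighted pair graph
must be connected, otherwise components could spin independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import pairwise_geodesic, xyz_to_sphere_points, sphere_points_to_xyz
from .voting import WeightMatrix

__all__ = [
    "SphereConfig",
    "EmbeddingProblem",
    "stress",
    "initial_embedding",
    "refine_embedding",
    "mirror",
    "embed",
]


@dataclass
class SphereConfig:
    """n points on the unit sphere plus the stress they achieve."""

    xyz: np.ndarray  # (n, 3), unit rows
    stress: float = np.nan

    def __post_init__(self):
        x = np.asarray(self.xyz, dtype=float)
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero vector is not a sphere point")
        self.xyz = x / norms

    @property
    def n(self) -> int:
        return self.xyz.shape[0]

    def sphere_angles(self) -> tuple[np.ndarray, np.ndarray]:
        """(alphas, betas) spherical coordinates of the points."""
        return xyz_to_sphere_points(self.xyz)

    def distances(self) -> np.ndarray:
        return pairwise_geodesic(self.xyz)

    def to_tsv(self, path) -> None:
        alphas, betas = self.sphere_angles()
        with open(path, "w") as fh:
            fh.write("index\talpha_deg\tbeta_deg\n")
            for i, (a, b) in enumerate(zip(np.degrees(alphas), np.degrees(betas))):
                fh.write(f"{i}\t{a:.6f}\t{b:.6f}\n")

    @classmethod
    def from_angles(cls, alphas, betas, stress: float = np.nan) -> "SphereConfig":
        return cls(sphere_points_to_xyz(alphas, betas), stress)


@dataclass
class EmbeddingProblem:
    """Symmetric target angles in [0, pi] with shared non-negative weights."""

    target: np.ndarray
    weights: WeightMatrix

    def __post_init__(self):
        t = np.asarray(self.target, dtype=float)
        w = np.asarray(self.weights.omega, dtype=float)
        if t.shape != w.shape or t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("target and weights must be square matrices of equal size")
        defined = ~np.isnan(t)
        if np.any((t[defined] < -1e-12) | (t[defined] > np.pi + 1e-12)):
            raise ValueError("targets must lie in [0, pi]")
        if np.any(w[np.isnan(t)] != 0):
            raise ValueError("weight must be zero where target is undefined")
        self.target = t
        self._w = w

    @property
    def n(self) -> int:
        return self.target.shape[0]

    @property
    def omega(self) -> np.ndarray:
        return self._w

    def check_connected(self) -> None:
        ncomp, _ = connected_components(csr_matrix(self.omega > 0), directed=False)
        if ncomp != 1:
            raise ValueError("weighted pair graph is disconnected; embedding is not unique")


def stress(config: SphereConfig, prob: EmbeddingProblem) -> float:
    """Ordered-sum weighted squared deviation between targets and geodesics."""
    d = config.distances()
    w = prob.omega
    mask = w > 0
    diff = np.where(mask, np.nan_to_num(prob.target) - d, 0.0)
    return float(np.sum(w * diff * diff))


def initial_embedding(prob: EmbeddingProblem, seed: int = 0) -> SphereConfig:
    """Spectral initialization from the cosine (Gram) matrix of the targets."""
    n = prob.n
    if n < 3:
        raise ValueError("need at least 3 points")
    t = prob.target.copy()
    w = prob.omega
    defined = (w > 0) & ~np.isnan(t)
    off = ~np.eye(n, dtype=bool)
    if np.any(defined & off):
        mean_t = np.average(t[defined & off], weights=w[defined & off])
    else:
        mean_t = np.pi / 2
    g = np.where(defined, np.nan_to_num(np.cos(t)), np.cos(mean_t))
    np.fill_diagonal(g, 1.0)
    g = 0.5 * (g + g.T)
    evals, evecs = np.linalg.eigh(g)
    top = evals[-3:]
    if np.sum(top > 1e-12) < 3:
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        return SphereConfig(pts, np.nan)
    pts = evecs[:, -3:] * np.sqrt(np.maximum(top, 0.0))
    norms = np.linalg.norm(pts, axis=1)
    bad = norms < 1e-12
    if np.any(bad):
        pts[bad] = [0.0, 0.0, 1.0]
    cfg = SphereConfig(pts)
    cfg.stress = stress(cfg, prob)
    return cfg


def _stress_and_grad(x: np.ndarray, t: np.ndarray, w: np.ndarray):
    c = np.clip(x @ x.T, -1.0, 1.0)
    d = np.arccos(c)
    mask = w > 0
    diff = np.where(mask, np.nan_to_num(t) - d, 0.0)
    s = float(np.sum(w * diff * diff))
    sin_d = np.sqrt(np.maximum(1.0 - c * c, 1e-18))
    coef = np.where(mask, 4.0 * w * diff / sin_d, 0.0)
    grad = coef @ x
    return s, grad


def refine_embedding(start: SphereConfig, prob: EmbeddingProblem,
                     tol: float = 1e-9, max_iter: int = 2000) -> SphereConfig:
    """Projected gradient descent with backtracking; monotone non-increasing."""
    x = start.xyz.copy()
    t, w = prob.target, prob.omega
    s, grad = _stress_and_grad(x, t, w)
    if not np.isfinite(s):
        raise ValueError("non-finite stress: check weights and targets")
    total_w = max(np.sum(w), 1e-12)
    step = 0.25 / total_w * prob.n
    for _ in range(max_iter):
        gnorm2 = np.sum(grad * grad)
        if gnorm2 < 1e-24 or s < 1e-30:
            break
        improved = False
        for _ in range(40):
            cand = x - step * grad
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            s_new, g_new = _stress_and_grad(cand, t, w)
            if s_new < s:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        rel = (s - s_new) / max(s, 1e-300)
        x, s, grad = cand, s_new, g_new
        step *= 1.5
        if rel < tol:
            break
    out = SphereConfig(x, s)
    return out


def mirror(config: SphereConfig) -> SphereConfig:
    """Reflect through the XZ plane (negate y); an exact isometry."""
    pts = config.xyz.copy()
    pts[:, 1] *= -1.0
    return SphereConfig(pts, config.stress)


def embed(prob: EmbeddingProblem, restarts: int = 5, tol: float = 1e-9,
          max_iter: int = 2000, seed: int = 0) -> SphereConfig:
    """Spectral start plus seeded random restarts; lowest-stress result wins."""
    prob.check_connected()
    rng = np.random.default_rng(seed)
    starts = [initial_embedding(prob, seed=seed)]
    for _ in range(max(0, restarts - 1)):
        starts.append(SphereConfig(rng.normal(size=(prob.n, 3))))
    best = None
    for s0 in starts:
        refined = refine_embedding(s0, prob, tol=tol, max_iter=max_iter)
        if best is None or refined.stress < best.stress:
            best = refined
    return best
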