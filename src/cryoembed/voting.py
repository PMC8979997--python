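"""Histogram-voting estimation of pairwise dihedral angles from common lines.

For a pair of images (i, j), every third image k implies a candidate dihedral
angle theta_ij^(k) via the spherical law of cosines applied to the three
angles each image measures between its two common lines.  The candidates are
accumulated into a Gaussian-kernel histogram on the grid sigma*t,
t = 0..T-1, sigma = pi/T; the voted dihedral is the grid argmax and the peak
height h_ij serves as a reliability score.  Pairs whose reliability falls at
or below the 10th-percentile threshold H get weight 0; the rest keep
omega_ij = h_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .commonlines import CommonLineSet

__all__ = [
    "DihedralEstimates",
    "WeightMatrix",
    "triplet_dihedral",
    "vote_dihedral",
    "build_dihedral_estimates",
    "compute_weights",
]


@dataclass
class DihedralEstimates:
    """Voted dihedrals theta[i, j] in [0, pi] and peak heights h[i, j]."""

    theta: np.ndarray  # (n, n) symmetric, nan where no evidence
    h: np.ndarray      # (n, n) symmetric, >= 0
    T: int

    @property
    def sigma(self) -> float:
        return np.pi / self.T

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\ttheta_deg\th\n")
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    fh.write(f"{i}\t{j}\t{np.degrees(self.theta[i, j]):.6f}\t"
                             f"{self.h[i, j]:.6f}\n")


@dataclass
class WeightMatrix:
    """Thresholded reliabilities: omega_ij = h_ij if h_ij > H else 0."""

    omega: np.ndarray
    H: float


def _signed_wrap(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(a, dtype=float)))


_DEGENERATE_EPS = 1e-9


def _resolved_gammas(psi_i, psi_j, psi_k):
    """Flip-invariant vertex angles of the normals' spherical triangle.

    ``psi_a`` are the cyclic signed ray separations measured inside each
    image (i: ray-to-k minus ray-to-j; j: ray-to-i minus ray-to-k; k:
    ray-to-j minus ray-to-i).  For a consistent configuration whose common
    lines all follow the n_a x n_b direction convention, the three share one
    sign (the triangle's orientation).  The detector fixes each pair's ray
    direction only up to the antipode, and flipping a pair shifts exactly
    the two corresponding psi by pi -- flipping their signs.  The unique
    even-parity combination restoring a common sign therefore undoes the
    unknown flips, and the vertex angle is |psi| for unflipped entries and
    pi - |psi| for flipped ones.
    """
    sg_i, sg_j, sg_k = np.sign(psi_i), np.sign(psi_j), np.sign(psi_k)
    # target sign: the one the majority holds has an even number of mismatches
    mismatches_pos = (sg_i < 0).astype(int) + (sg_j < 0).astype(int) + (sg_k < 0).astype(int)
    target_pos = mismatches_pos % 2 == 0
    flip_i = np.where(target_pos, sg_i < 0, sg_i > 0)
    flip_j = np.where(target_pos, sg_j < 0, sg_j > 0)
    flip_k = np.where(target_pos, sg_k < 0, sg_k > 0)
    gi = np.where(flip_i, np.pi - np.abs(psi_i), np.abs(psi_i))
    gj = np.where(flip_j, np.pi - np.abs(psi_j), np.abs(psi_j))
    gk = np.where(flip_k, np.pi - np.abs(psi_k), np.abs(psi_k))
    return gi, gj, gk


def triplet_dihedral(cl: CommonLineSet, i: int, j: int, k: int) -> float | None:
    """Dihedral between planes i and j implied by third image k, or None.

    The vertex angles (gamma_i, gamma_j, gamma_k) of the spherical triangle
    formed by the three normals are read off the common-line rays inside
    each image (after resolving the per-pair ray-direction ambiguity); the
    dual spherical law of cosines then gives

        cos(theta_ij) = (cos gamma_k + cos gamma_i cos gamma_j)
                        / (sin gamma_i sin gamma_j).

    The triplet is rejected when any gamma is degenerate (0 or pi) or the
    feasibility condition |numerator| <= denominator fails.
    """
    if len({i, j, k}) != 3:
        raise ValueError("i, j, k must be distinct")
    th = _candidate_thetas(cl, i, j, ks=np.array([k]))
    return float(th[0]) if th.size else None


def _candidate_thetas(cl: CommonLineSet, i: int, j: int,
                      ks: np.ndarray | None = None) -> np.ndarray:
    """Vectorized triplet dihedral candidates over third images k."""
    n = cl.n
    if ks is None:
        ks = np.array([k for k in range(n) if k != i and k != j])
    # The triangle relations below assume the antisymmetric ray convention
    # (the pair's rays along n_a x n_b in image a and n_b x n_a in image b),
    # while the detector matches rays along one shared direction; adding pi
    # to one member of each unordered pair converts between the two, up to
    # whole-pair flips that the parity resolution absorbs.
    def cc(a, b):
        return cl.c[a, b] + np.pi * (np.asarray(a) > np.asarray(b))

    psi_i = _signed_wrap(cc(i, ks) - cc(i, j))
    psi_j = _signed_wrap(cc(j, i) - cc(j, ks))
    psi_k = _signed_wrap(cc(ks, j) - cc(ks, i))
    gi, gj, gk = _resolved_gammas(psi_i, psi_j, psi_k)
    si, sj, sk = np.sin(gi), np.sin(gj), np.sin(gk)
    num = np.cos(gk) + np.cos(gi) * np.cos(gj)
    den = si * sj
    ok = (si >= _DEGENERATE_EPS) & (sj >= _DEGENERATE_EPS) & (sk >= _DEGENERATE_EPS)
    ok &= np.abs(num) <= den
    ok &= np.isfinite(num) & np.isfinite(den)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = np.arccos(np.clip(num / np.where(den == 0, 1.0, den), -1.0, 1.0))
    return thetas[ok]


def vote_dihedral(cl: CommonLineSet, i: int, j: int, T: int = 180) -> tuple[float, float]:
    """Voted dihedral and histogram peak height for pair (i, j).

    Returns (nan, 0.0) when no triplet passes the feasibility check.
    """
    thetas = _candidate_thetas(cl, i, j)
    if thetas.size == 0:
        return (np.nan, 0.0)
    sigma = np.pi / T
    grid = sigma * np.arange(T)
    hist = np.exp(-((grid[None, :] - thetas[:, None]) ** 2) / (2.0 * sigma * sigma))
    hist = hist.sum(axis=0) / np.sqrt(2.0 * np.pi * sigma * sigma)
    t_max = int(np.argmax(hist))
    return (float(sigma * t_max), float(hist[t_max]))


def build_dihedral_estimates(cl: CommonLineSet, T: int = 180) -> DihedralEstimates:
    """Vote every unordered pair once; symmetric by construction."""
    n = cl.n
    if n < 4:
        raise ValueError("voting needs at least 4 images")
    theta = np.full((n, n), np.nan)
    h = np.zeros((n, n))
    sigma = np.pi / T
    grid = sigma * np.arange(T)
    norm = 1.0 / np.sqrt(2.0 * np.pi * sigma * sigma)
    for i in range(n):
        for j in range(i + 1, n):
            thetas = _candidate_thetas(cl, i, j)
            if thetas.size == 0:
                continue
            hist = np.exp(-((grid[None, :] - thetas[:, None]) ** 2)
                          / (2.0 * sigma * sigma)).sum(axis=0) * norm
            t_max = int(np.argmax(hist))
            theta[i, j] = theta[j, i] = sigma * t_max
            h[i, j] = h[j, i] = hist[t_max]
    return DihedralEstimates(theta, h, T)


def compute_weights(d: DihedralEstimates, percentile: float = 10.0) -> WeightMatrix:
    """Zero out the least reliable pairs (nearest-rank percentile threshold)."""
    n = d.n
    iu = np.triu_indices(n, 1)
    hvals = d.h[iu]
    order = np.sort(hvals)
    rank = max(1, int(np.ceil(percentile / 100.0 * order.size)))
    H = float(order[rank - 1])
    omega = np.where(d.h > H, d.h, 0.0)
    np.fill_diagonal(omega, 0.0)
    if not np.any(omega[iu] > 0):
        warnings.warn("all reliabilities tied at the threshold; "
                      "falling back to uniform weights", stacklevel=2)
        omega = np.ones_like(omega)
        np.fill_diagonal(omega, 0.0)
        # undefined dihedrals still carry no weight
        omega[np.isnan(d.theta)] = 0.0
    return WeightMatrix(omega, H)
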