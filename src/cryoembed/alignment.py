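"""Assembly of full orientations from the two spherical embeddings.

The first embedding places the projection normals on the unit sphere; the
second places the local X-axes.  Target angles for the second embedding come
from the common lines and the embedded dihedrals: putting image i in the XY
plane with the common line along X, the X-axes of images i and j sit at
in-plane angles C_ij and C_ji on their respective planes, so the angle
between them is

    phi_ij = arccos(cos C_ij cos C_ji + sin C_ij sin C_ji cos theta_ij^E).

The two embeddings live in arbitrary global frames, so the X-axis cloud is
rotated by the R minimizing the orthogonality defect n_i . (R a'_i) = 0 for
all i (homogeneous least squares on the 9 entries of R: smallest eigenvector
of A^T A, then polar orthogonalization).  The in-plane angle and per-image
consistency defect then follow from

    [cos g_i, sin g_i, delta_i]^T = Ry(-beta_i) Rz(-alpha_i) a''_i,

with Sum delta_i^2 / n the consistency score.  Since each embedding is only
determined up to reflection, all four mirror combinations are scored and the
most consistent one kept; a global mirror (handedness) remains undetermined,
as is intrinsic to common-line data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .commonlines import CommonLineSet
from .embedding import SphereConfig, mirror
from .geometry import OrientationSet, wrap_angle
from .voting import WeightMatrix

__all__ = [
    "XAxisTargets",
    "AlignmentResult",
    "xaxis_angle",
    "build_xaxis_targets",
    "solve_alignment_rotation",
    "extract_gamma",
    "common_line_agreement",
    "assemble_orientations",
]


@dataclass
class XAxisTargets:
    """Target angles between local X-axes, sharing the dihedral weights."""

    phi: np.ndarray  # (n, n) symmetric, nan where unweighted
    weights: WeightMatrix


@dataclass
class AlignmentResult:
    rotation: np.ndarray           # 3x3 aligning the X-axis embedding
    aligned_xaxes: SphereConfig
    gammas: np.ndarray             # (n,) wrapped to [0, 2pi)
    deltas: np.ndarray             # (n,) orthogonality defects
    consistency: float             # Sum delta^2 / n
    mirror_choice: tuple[bool, bool]
    residual: float                # RMS of n_i . a''_i
    degenerate: np.ndarray         # (n,) bool, X-axis parallel to normal
    cl_agreement: float = np.nan   # mean predicted-vs-measured common-line match


def xaxis_angle(c_ij, c_ji, theta_e):
    """Angle in [0, pi] between the local X-axes of an image pair."""
    arg = (np.cos(c_ij) * np.cos(c_ji)
           + np.sin(c_ij) * np.sin(c_ji) * np.cos(theta_e))
    return np.arccos(np.clip(arg, -1.0, 1.0))


def build_xaxis_targets(cl: CommonLineSet, normals: SphereConfig,
                        w: WeightMatrix) -> XAxisTargets:
    """phi_ij from common lines and embedded dihedrals, for weighted pairs."""
    theta_e = normals.distances()
    n = cl.n
    phi = np.full((n, n), np.nan)
    omega = w.omega
    for i in range(n):
        for j in range(i + 1, n):
            if omega[i, j] <= 0 or np.isnan(cl.c[i, j]):
                continue
            p = float(xaxis_angle(cl.c[i, j], cl.c[j, i], theta_e[i, j]))
            phi[i, j] = phi[j, i] = p
    # pairs that lost their target also lose their weight
    adj = omega.copy()
    adj[np.isnan(phi)] = 0.0
    return XAxisTargets(phi, WeightMatrix(adj, w.H))


def solve_alignment_rotation(normals: SphereConfig, xaxes: SphereConfig) -> np.ndarray:
    """Proper rotation making the X-axis cloud orthogonal to the normals.

    Solves the homogeneous system n_i^T R a'_i = 0 over the 9 entries of R
    (smallest eigenvector of A^T A), then projects onto SO(3) via the
    det-corrected polar factor.  Restricting to proper rotations is what
    lets the orthogonality defect discriminate between mirror-consistent
    and mirror-inconsistent embedding pairs: an improper matrix could zero
    the defect for either chirality.  Both signs of the eigenvector are
    projected and the candidate with the smaller defect is returned.
    """
    nvec = normals.xyz
    avec = xaxes.xyz
    n = nvec.shape[0]
    if n < 9:
        raise ValueError("need at least 9 images to determine the 9 entries of R")
    # row i of A: coefficients of vec(R) (row-major R_kl) in n_i^T R a'_i
    A = np.einsum("ik,il->ikl", nvec, avec).reshape(n, 9)
    ata = A.T @ A
    evals, evecs = np.linalg.eigh(ata)
    if evals[1] < 1e-12 * max(evals[-1], 1.0):
        raise ValueError("degenerate geometry: alignment system is rank-deficient")
    m = evecs[:, 0].reshape(3, 3)
    u, s, vt = np.linalg.svd(m)
    if np.any(s < 1e-12):
        raise ValueError("degenerate geometry: singular alignment solution")
    best = None
    for mm in (m, -m):
        uu, _, vvt = np.linalg.svd(mm)
        d = np.sign(np.linalg.det(uu @ vvt))
        uu = uu.copy()
        uu[:, -1] *= d
        r = uu @ vvt
        defect = float(np.sum(np.einsum("ik,kl,il->i", nvec, r, avec) ** 2))
        if best is None or defect < best[0]:
            best = (defect, r)
    return best[1]


def extract_gamma(normals: SphereConfig, aligned_xaxes: SphereConfig
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane angles and consistency defects from the aligned X-axes.

    Returns (gammas, deltas, degenerate); gamma_i = atan2 of the rotated
    X-axis components, delta_i its out-of-plane component (0 for perfectly
    consistent embeddings).
    """
    alphas, betas = normals.sphere_angles()
    a = aligned_xaxes.xyz
    ca, sa = np.cos(alphas), np.sin(alphas)
    cb, sb = np.cos(betas), np.sin(betas)
    # v = Ry(-beta) Rz(-alpha) a, batched
    rz = np.zeros((len(alphas), 3, 3))
    rz[:, 0, 0], rz[:, 0, 1] = ca, sa
    rz[:, 1, 0], rz[:, 1, 1] = -sa, ca
    rz[:, 2, 2] = 1.0
    ry = np.zeros_like(rz)
    ry[:, 0, 0], ry[:, 0, 2] = cb, -sb
    ry[:, 1, 1] = 1.0
    ry[:, 2, 0], ry[:, 2, 2] = sb, cb
    v = np.einsum("nij,njk,nk->ni", ry, rz, a)
    gammas = wrap_angle(np.arctan2(v[:, 1], v[:, 0]))
    deltas = v[:, 2]
    degenerate = np.hypot(v[:, 0], v[:, 1]) < 1e-6
    return gammas, deltas, degenerate


def _alignment_candidate(normals: SphereConfig, xaxes: SphereConfig,
                         flags: tuple[bool, bool]) -> AlignmentResult:
    r = solve_alignment_rotation(normals, xaxes)
    aligned = SphereConfig(xaxes.xyz @ r.T, xaxes.stress)
    gammas, deltas, degen = extract_gamma(normals, aligned)
    consistency = float(np.mean(deltas ** 2))
    residual = float(np.sqrt(np.mean(np.sum(normals.xyz * aligned.xyz, axis=1) ** 2)))
    return AlignmentResult(r, aligned, gammas, deltas, consistency, flags,
                           residual, degen)


def _predicted_common_lines(orientations: OrientationSet) -> tuple[np.ndarray, np.ndarray]:
    """(C_pred, defined) in-plane common-line angles implied by orientations."""
    mats = orientations.matrices()
    normals = mats[:, :, 2]
    u = np.cross(normals[:, None, :], normals[None, :, :])  # (n, n, 3)
    norm = np.linalg.norm(u, axis=-1)
    defined = norm > 1e-9
    u_safe = u / np.where(defined, norm, 1.0)[..., None]
    # in image i's frame: v_ij = R_i^T u_ij
    v = np.einsum("iba,ijb->ija", mats, u_safe)
    c = np.arctan2(v[..., 1], v[..., 0])
    return c, defined


def common_line_agreement(orientations: OrientationSet, cl: CommonLineSet) -> float:
    """Mean agreement in [-1, 1] between predicted and measured common lines.

    Per pair the match is max over the whole-pair ray flip (the detector's
    free antipode) of the mean cosine of the two angle differences, so the
    score is invariant under the physical handedness ambiguity (which shifts
    both members of every pair by pi) while the spurious solution class that
    explains the mirror-reflected images scores low.
    """
    c_pred, defined = _predicted_common_lines(orientations)
    n = cl.n
    iu = np.triu_indices(n, 1)
    measured_ok = ~np.isnan(cl.c[iu])
    ok = defined[iu] & measured_ok
    d_ij = c_pred[iu] - cl.c[iu]
    # c_pred[j, i] is measured along u_ji = -u_ij; the detector's matched
    # pair shares one direction, so shift by pi to compare like with like
    d_ji = c_pred[iu[1], iu[0]] + np.pi - cl.c[iu[1], iu[0]]
    same = 0.5 * (np.cos(d_ij) + np.cos(d_ji))
    flip = 0.5 * (np.cos(d_ij - np.pi) + np.cos(d_ji - np.pi))
    match = np.maximum(same, flip)
    if not np.any(ok):
        return np.nan
    return float(np.mean(match[ok]))


def assemble_orientations(normals: SphereConfig, xaxes: SphereConfig,
                          cl: CommonLineSet | None = None
                          ) -> tuple[OrientationSet, AlignmentResult]:
    """Full Euler angles from the two embeddings.

    All four mirror combinations of the two embeddings are aligned via the
    orthogonality constraint; (alpha, beta) come from the (possibly
    mirrored) normals embedding and gamma from the aligned X-axes.  Because
    a proper gluing rotation exists for either relative chirality (the
    mismatched one yields the configuration explaining the mirror-reflected
    images, with an equally small orthogonality defect), the winning
    combination is chosen by agreement between the common lines the
    candidate implies and the measured ones, with the consistency score
    Sum delta_i^2 / n as tiebreak; the true-handedness ambiguity remains, as
    it must.
    """
    candidates = []
    for m1 in (False, True):
        n_cfg = mirror(normals) if m1 else normals
        for m2 in (False, True):
            x_cfg = mirror(xaxes) if m2 else xaxes
            cand = _alignment_candidate(n_cfg, x_cfg, (m1, m2))
            alphas, betas = n_cfg.sphere_angles()
            orient = OrientationSet(np.column_stack([alphas, betas, cand.gammas]))
            if cl is not None:
                cand.cl_agreement = common_line_agreement(orient, cl)
            candidates.append((cand, orient))
    if cl is not None and not np.isnan(candidates[0][0].cl_agreement):
        key = lambda co: (-co[0].cl_agreement, co[0].consistency)
    else:
        key = lambda co: (co[0].consistency,)
    best, orientations = min(candidates, key=key)
    return orientations, best
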