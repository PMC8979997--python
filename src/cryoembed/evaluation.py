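"""Accuracy metrics: dihedral scatter, globally aligned per-angle RMSE, FSC.

Estimated orientations are defined only up to a global rotation and an
optional global mirror (handedness), so before comparing Euler angles the
estimate is aligned to the reference by the closed-form orthogonal
Procrustes rotation over the per-image rotation matrices, tried with and
without the mirror, keeping whichever gives the smaller mean geodesic
distance on SO(3).  Dihedral angles are invariant to both transforms and
are compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import OrientationSet, pairwise_geodesic

__all__ = [
    "AngleComparison",
    "FSCCurve",
    "dihedral_error_table",
    "mirror_orientations",
    "align_to_reference",
    "euler_rmse",
    "geodesic_errors",
    "compare_orientations",
    "fsc",
]

_J = np.diag([1.0, -1.0, 1.0])


@dataclass
class AngleComparison:
    rmse_alpha: float  # degrees
    rmse_beta: float
    rmse_gamma: float
    mirror_applied: bool
    global_rotation: np.ndarray
    median_geodesic_deg: float
    per_pair_dihedral_errors: np.ndarray  # (m, 2) columns (actual, estimated), radians


@dataclass
class FSCCurve:
    shell_freq: np.ndarray   # 1/A
    correlation: np.ndarray

    def resolution_at(self, threshold: float = 0.143) -> float:
        """First threshold crossing, linearly interpolated, in Angstroms."""
        c = self.correlation
        f = self.shell_freq
        below = np.where(c < threshold)[0]
        below = below[below > 0]
        if below.size == 0:
            return float(1.0 / f[-1])
        k = below[0]
        f0, f1 = f[k - 1], f[k]
        c0, c1 = c[k - 1], c[k]
        if c0 == c1:
            fx = f1
        else:
            fx = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
        return float(1.0 / fx)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("freq_invA\tfsc\n")
            for f, c in zip(self.shell_freq, self.correlation):
                fh.write(f"{f:.6f}\t{c:.6f}\n")


def dihedral_error_table(est: OrientationSet, ref: OrientationSet) -> np.ndarray:
    """(m, 2) array of (actual, estimated) dihedral angles over all pairs."""
    if len(est) != len(ref):
        raise ValueError("orientation sets differ in length")
    iu = np.triu_indices(len(est), 1)
    actual = pairwise_geodesic(ref.normals())[iu]
    estimated = pairwise_geodesic(est.normals())[iu]
    return np.column_stack([actual, estimated])


def mirror_orientations(os_: OrientationSet) -> OrientationSet:
    """Global handedness flip: R_i -> R_i Rz(pi), i.e. gamma_i += pi.

    The point-inverted volume V(-r) reproduces the identical projection
    images when every orientation is right-multiplied by Rz(pi) (the
    inversion flips the integration axis and both in-plane axes; the
    in-plane part is undone by the half-turn).  Combined with the free
    global rotation this generates the full enantiomer solution class that
    common-line data cannot distinguish.
    """
    ang = os_.angles.copy()
    ang[:, 2] += np.pi
    return OrientationSet(ang)


def _procrustes_rotation(mats_est: np.ndarray, mats_ref: np.ndarray) -> np.ndarray:
    """Proper rotation G minimizing sum ||G R_est,i - R_ref,i||_F^2."""
    m = np.einsum("nij,nkj->ik", mats_ref, mats_est)  # sum R_ref R_est^T
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def _mean_geodesic(mats_a: np.ndarray, mats_b: np.ndarray) -> float:
    rel = np.einsum("nij,nkj->nik", mats_a, mats_b)  # A B^T
    tr = np.trace(rel, axis1=1, axis2=2)
    ang = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
    return float(np.mean(ang))


def align_to_reference(est: OrientationSet, ref: OrientationSet
                       ) -> tuple[OrientationSet, np.ndarray, bool]:
    """Best global rotation (and optional mirror) taking est onto ref."""
    if len(est) != len(ref) or len(est) < 2:
        raise ValueError("need two equally sized sets with n >= 2")
    mats_ref = ref.matrices()
    candidates = []
    for mirrored, base in ((False, est), (True, mirror_orientations(est))):
        mats = base.matrices()
        g = _procrustes_rotation(mats, mats_ref)
        aligned = np.einsum("ij,njk->nik", g, mats)
        err = _mean_geodesic(aligned, mats_ref)
        candidates.append((err, aligned, g, mirrored))
    err, aligned, g, mirrored = min(candidates, key=lambda c: c[0])
    return OrientationSet.from_matrices(aligned), g, mirrored


def _wrap_deg(d: np.ndarray) -> np.ndarray:
    return (d + 180.0) % 360.0 - 180.0


def euler_rmse(aligned: OrientationSet, ref: OrientationSet
               ) -> tuple[float, float, float]:
    """Per-Euler-angle circular RMSE in degrees (alpha, beta, gamma)."""
    da = _wrap_deg(np.degrees(aligned.angles[:, 0] - ref.angles[:, 0]))
    db = np.degrees(aligned.angles[:, 1] - ref.angles[:, 1])
    dg = _wrap_deg(np.degrees(aligned.angles[:, 2] - ref.angles[:, 2]))
    return tuple(float(np.sqrt(np.mean(d * d))) for d in (da, db, dg))


def geodesic_errors(aligned: OrientationSet, ref: OrientationSet) -> np.ndarray:
    """Per-image geodesic distance on SO(3), radians."""
    ma, mr = aligned.matrices(), ref.matrices()
    rel = np.einsum("nij,nkj->nik", ma, mr)
    tr = np.trace(rel, axis1=1, axis2=2)
    return np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))


def compare_orientations(est: OrientationSet, ref: OrientationSet) -> AngleComparison:
    """Full comparison report: global alignment, per-angle RMSE, dihedrals."""
    aligned, g, mirrored = align_to_reference(est, ref)
    ra, rb, rg = euler_rmse(aligned, ref)
    med = float(np.degrees(np.median(geodesic_errors(aligned, ref))))
    table = dihedral_error_table(est, ref)
    return AngleComparison(ra, rb, rg, mirrored, g, med, table)


def fsc(v1: np.ndarray, v2: np.ndarray, voxel_size: float = 1.0,
        shell_width: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two equally sized cubic volumes."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("volumes must share a grid")
    L = v1.shape[0]
    f1 = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(v1)))
    f2 = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(v2)))
    ax = np.arange(L) - L // 2
    kx, ky, kz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(kx * kx + ky * ky + kz * kz)
    n_shells = int(np.floor((L // 2) / shell_width))
    shell = np.floor(r / shell_width).astype(int)
    mask = shell < n_shells
    num = np.zeros(n_shells, dtype=complex)
    p1 = np.zeros(n_shells)
    p2 = np.zeros(n_shells)
    np.add.at(num, shell[mask], (f1 * np.conj(f2))[mask])
    np.add.at(p1, shell[mask], (np.abs(f1) ** 2)[mask])
    np.add.at(p2, shell[mask], (np.abs(f2) ** 2)[mask])
    denom = np.sqrt(p1 * p2)
    corr = np.where(denom > 0, num.real / np.where(denom == 0, 1.0, denom), 0.0)
    freqs = (np.arange(n_shells) + 0.5) * shell_width / (L * voxel_size)
    return FSCCurve(freqs, corr)
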