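"""Direct-Fourier reconstruction from oriented projection images.

Each image's centered 2D FFT is a central slice of the volume's 3D FFT
perpendicular to the image normal (central section theorem).  Slices are
splatted into a 3D Fourier accumulator with trilinear (or nearest) weights,
the accumulator is normalized by the accumulated weights (floored to avoid
blow-ups in unfilled regions) and inverse-transformed.  This is a basic
gridding reconstructor intended for validating orientation estimates, not a
production-grade (NUFFT/iterative) inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .commonlines import centered_fft2
from .geometry import OrientationSet
from .simulate import ImageStack, Volume

__all__ = ["ReconstructionSettings", "backproject"]


@dataclass(frozen=True)
class ReconstructionSettings:
    interpolation: str = "linear"  # "linear" | "nearest"
    wiener_floor: float = 1e-3     # fraction of mean weight

    def __post_init__(self):
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")
        if self.wiener_floor <= 0:
            raise ValueError("wiener_floor must be positive")


def backproject(stack: ImageStack, orient: OrientationSet,
                settings: ReconstructionSettings | None = None) -> Volume:
    """Insert every image as a central Fourier slice and invert."""
    settings = settings or ReconstructionSettings()
    if stack.n == 0:
        raise ValueError("empty stack")
    if stack.n != len(orient):
        raise ValueError("stack and orientations differ in length")
    D = stack.image_size
    if stack.n == 1:
        warnings.warn("single image: reconstruction is a single slice "
                      "(rank-deficient)", stacklevel=2)
    normals = orient.normals()
    if stack.n >= 3 and np.linalg.matrix_rank(normals, tol=1e-6) < 3:
        warnings.warn("orientations are coplanar: anisotropic Fourier fill",
                      stacklevel=2)
    mats = orient.matrices()
    center = D // 2
    ax = np.arange(D) - center
    KX, KY = np.meshgrid(ax, ax, indexing="ij")
    kxy = np.stack([KX.ravel(), KY.ravel()])  # (2, D*D)
    acc = np.zeros((D, D, D), dtype=complex)
    wgt = np.zeros((D, D, D))
    for i in range(stack.n):
        F = centered_fft2(stack.data[i]).ravel()
        basis = mats[i][:, :2]  # (3, 2): local X and Y axis columns
        p = basis @ kxy + center  # (3, m) voxel coordinates
        inside = np.all((p >= 0) & (p <= D - 1), axis=0)
        p = p[:, inside]
        vals = F[inside]
        if settings.interpolation == "nearest":
            idx = np.round(p).astype(int)
            np.add.at(acc, (idx[0], idx[1], idx[2]), vals)
            np.add.at(wgt, (idx[0], idx[1], idx[2]), 1.0)
        else:
            base = np.floor(p).astype(int)
            frac = p - base
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = (np.where(dx, frac[0], 1 - frac[0])
                             * np.where(dy, frac[1], 1 - frac[1])
                             * np.where(dz, frac[2], 1 - frac[2]))
                        ix = np.minimum(base[0] + dx, D - 1)
                        iy = np.minimum(base[1] + dy, D - 1)
                        iz = np.minimum(base[2] + dz, D - 1)
                        np.add.at(acc, (ix, iy, iz), w * vals)
                        np.add.at(wgt, (ix, iy, iz), w)
    mean_w = wgt[wgt > 0].mean() if np.any(wgt > 0) else 1.0
    floor = settings.wiener_floor * mean_w
    grid = acc / np.maximum(wgt, floor)
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))).real
    return Volume(vol, stack.pixel_size)
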