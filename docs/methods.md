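# Methods

This note documents the models, conventions, numerical choices and known
limitations of `cryoembed`.  Symbols follow the README.

## Orientation model and conventions

An orientation is the rotation carrying an image's local frame into the
world frame, R(α, β, γ) = Rz(α)·Ry(β)·Rz(γ) (intrinsic ZYZ).  Columns of R
are (local X-axis, local Y-axis, normal); the normal is the spherical point
(α, β).  This convention is fixed by the requirement that
Ry(−β)·Rz(−α) applied to the local X-axis yields (cos γ, sin γ, 0) — the
identity used to read γ off the second embedding — and is verified by
round-trip and consistency tests.  At the gimbal degeneracy (β ∈ {0, π})
the decomposition puts the whole in-plane angle into γ and sets α = 0.
Angles are radians internally, degrees in all files.

Improper (det = −1) matrices are rejected by `rotation_to_euler`:
handedness enters the package only as the explicitly-handled global
ambiguity (below), never as a representable per-image state.

## Simulator

`make_phantom` sums ~100 small anisotropic Gaussian blobs (widths
0.015–0.05 of the box, centers uniform in a ball of radius 0.2·box) into a
granular asymmetric specimen.  The granularity matters: common-line
detection correlates mid-frequency Fourier content, and a specimen made of
a few large blobs has a Gaussian-decaying spectrum with essentially no
usable power beyond a few Fourier pixels — unrealistically hard for any
common-line method, whereas macromolecular densities are granular at the
nanometer scale.  Blob count does *not* scale with box volume: packing
blobs at constant density overlaps them into a smooth mass (central-limit
averaging) and destroys the mid-frequency power again.

Orientations are Haar-uniform via α, γ ~ U[0, 2π), cos β ~ U[−1, 1].
Projection is a real-space line integral: the volume is sampled with
trilinear interpolation at x·u_X + y·u_Y + z·n (pull-back; zero outside the
cube) and summed along z.  The Fourier-slice consistency of this operator
(2D FFT of a projection vs. the central slice of the 3D FFT) is tested at
correlation > 0.98 in the usable band.

SNR is defined as signal variance over noise variance per image, the
dominant convention in the field; noise is drawn i.i.d. Gaussian with
variance var(image)/SNR, added to the *raw* clean projection (no
normalization first), one child seed per image from a single master seed.

## Common-line detection

Each image is resampled onto L = 360 directed polar-Fourier rays over the
radial band [3, 0.4·D] un-padded Fourier pixels.  Three measures keep the
normalized complex cross-correlation informative:

* **3× zero-padding** of the FFT before bilinear polar resampling.  The
  transform oscillates on the scale of one Fourier pixel (the particle
  fills a good fraction of the box), and un-padded bilinear interpolation
  dominated the detection error; 3× padding brings clean-data detection to
  a median error of ~0.5° with ≥95% of pairs within 2 ray bins.
* a **soft circular support mask** (logistic edge, default radius 0.25·D
  matching the phantom support plus margin) applied in real space,
  suppressing the noise outside the particle.
* a **radial Wiener weight** S(r)/(S(r)+N), with the rotationally averaged
  signal power S and flat noise floor N estimated from the whole stack (N
  from the outermost radii).  On clean data the weight tends to 1.

The search runs over directed rays (full [0, 2π)²) so the matched rays
point the same way along the 3D intersection line; which of the two
antipodal parameterizations is returned remains free per pair, and all
downstream formulas are invariant to that whole-pair flip.

Per-pair scores saturate near 1 even for wrong candidates when only the
lowest radii carry signal; this is intrinsic (two projections of a compact
particle always correlate at low frequency), which is why reliability is
assessed downstream by voting rather than by the correlation score.

## Voting geometry

For a triplet (i, j, k), the angles each image measures between its two
common lines are the vertex angles of the spherical triangle formed by the
three normals.  With consistently directed rays the dual spherical law of
cosines gives

cos θ_ij = (cos γ_k + cos γ_i cos γ_j) / (sin γ_i sin γ_j).

The detector's per-pair antipode freedom is resolved exactly: the three
cyclic signed ray separations share one sign for a consistent
configuration, and flipping any pair shifts exactly two of them by π
(flipping their signs), so the unique even-parity correction restoring a
common sign undoes the unknown flips (verified exactly on randomized
configurations).  Triplets violating the feasibility condition
|cos γ_k + cos γ_i cos γ_j| ≤ sin γ_i sin γ_j, or with a degenerate vertex
angle (sin γ < 1e-9), are skipped rather than clamped — clamping would
concentrate spurious votes at 0/π.

Votes accumulate on the grid σt, t = 0…T−1, σ = π/T with T = 180 (1° bins,
matching the 1° ray resolution); the argmax is taken on the grid without
sub-bin refinement.  The weight threshold H is the nearest-rank 10th
percentile of the off-diagonal peak heights, each unordered pair counted
once; ω_ij = h_ij for h_ij > H (strictly) else 0.  If every weight would
vanish (all heights tied) the weights fall back to uniform with a warning.

## Spherical embedding

The stress ε = Σ_{i≠j} ω_ij (target_ij − d_ij)² is the ordered sum (each
unordered pair twice), so reported values match the defining formula
literally.  Initialization is spectral: cos(target) is a Gram matrix of
unit vectors whenever the targets are realizable, so the top-3 eigenspace
(scaled by √eigenvalues, rows renormalized) recovers the configuration up
to a global orthogonal map; missing entries are imputed with the cosine of
the weighted mean target.  Refinement is projected gradient descent on the
sphere with backtracking line search (monotone by construction; tol 1e-9
relative, max 2000 iterations), run from the spectral start plus 4 seeded
random restarts, keeping the lowest stress.  Exact targets are recovered to
stress < 1e-20 for n up to 1000; under 2° Gaussian target noise the
realized distances are ~5× closer to the clean truth than the inputs
(1.41° → 0.28° RMS at n = 100) — the rectification property that motivates
embedding at all.  The weighted pair graph must be connected (checked;
error otherwise).  Triangle-inequality violations in the targets are not
repaired; the weighted least squares absorbs them.

## Assembly and the mirror structure

The gluing rotation solves the homogeneous system n_iᵀ R a′_i = 0 over the
9 entries of R: the smallest eigenvector of AᵀA (rows n_i ⊗ a′_i), then
projection onto SO(3) via the det-corrected polar factor, trying both
eigenvector signs and keeping the smaller orthogonality defect.  Forcing a
*proper* rotation is essential and subtle, for the solution structure is:

* the true gluing R₀ (defect ≈ 0);
* −R₀·(mirror) variants: for either relative chirality of the two
  embedding clouds a proper rotation with an equally small defect exists.
  One chirality yields the physical solution family; the other yields the
  configuration that explains the *mirror-reflected images* — internally
  consistent, orthogonality-perfect, but wrong.

Consequently the consistency score Σδ_i²/n ties across all four mirror
combinations of the two embeddings and cannot select between them.  The
selector instead scores each candidate by agreement between the common
lines it *implies* and the measured ones (mean cosine match, maximized over
the per-pair antipode, so it is invariant under the true handedness
ambiguity), with Σδ²/n as tiebreak.  On clean data the physical candidates
score ≈ 1.0 and the reflected-image candidates ≈ 0.4.

The surviving ambiguity is exactly the physical one: the point-inverted
volume V(−r) reproduces identical projections when every orientation is
right-multiplied by Rz(π), so the enantiomer orientation class is
{G·R_i·Rz(π), G ∈ SO(3)} — same normals, γ shifted by π.  Evaluation's
global alignment therefore tries the estimate and its γ+π mirror, aligning
each by closed-form orthogonal Procrustes over the rotation matrices
(proper G), and keeps the smaller mean geodesic distance.

## Evaluation

Per-angle RMSEs use circular differences wrapped to ±180° (β compared
directly).  Note that the per-angle split of a fixed geodesic error is
frame-dependent — a global rotation of both sets redistributes the error
among α, β, γ (exactly invariant only under rotations about Z) — so the
geodesic per-image error is also reported and is the frame-invariant
metric.  Dihedral angles are invariant to the global rotation and mirror
and are compared without alignment.  FSC is the per-shell normalized
complex correlation of the 3D transforms; resolution is read at a
threshold (default 0.143) by linear interpolation between shells.

## Reconstruction

A deliberately simple direct-Fourier reconstructor validates orientation
estimates: each image's centered 2D FFT is splatted as a central slice with
trilinear weights, the accumulator normalized by weights floored at
1e-3 × their mean, and inverse-transformed.  It recovers the phantom at
correlation > 0.99 from 200 clean projections with true angles, and
near-Nyquist FSC resolution with pipeline-estimated angles.  It makes no
claim to the accuracy of NUFFT/iterative inversion.

## Problem sizes and defaults

Desk-scale experiments use D = 64 boxes with n = 30–100 images (clean
recovery, noise sweeps) and a D = 130, n = 200, SNR = 0.2 replica of the
simulated-benchmark protocol; these sizes keep the full test suite and the
acceptance script to a few minutes while exercising every stage at
realistic geometry.  Defaults: L = 360, band [3, 0.4·D], pad 3, mask
0.25·D, Wiener weighting on, T = 180, weight percentile 10, embedding
restarts 5 / tol 1e-9 / max_iter 2000.  One master seed per run is split
deterministically per stage.

## What the synthetic data does and does not show

The generator reproduces the geometry and noise model of the simulated
benchmark (uniform SO(3), additive white Gaussian noise at a stated SNR,
centered images) but not: CTF, structural heterogeneity, centering errors,
non-uniform angular coverage, or the full spectral richness of a real
macromolecule.  At SNR 0.2 the phantom supports a common-line detection
rate of only ~20–25% at D = 130 — a real ribosome map at the same box size
carries more usable high-frequency power — so noisy-regime accuracies here
(per-angle RMSEs of ~5–10° at n = 200) are magnitudes comparable to the
published benchmark's lowest-SNR regime rather than its SNR-0.2 regime.
Passing tests demonstrate the correctness and internal consistency of the
geometry, voting, embedding and assembly machinery, and the qualitative
noise behavior; they do not certify accuracy on experimental class
averages.

## Known limitations

* No translational search: inputs are assumed centered (class averages
  centered upstream).
* No CTF handling anywhere in the pipeline.
* The correlation score of a detected common line is a poor reliability
  proxy (it saturates); only the voting height is used downstream.
* Handedness is undetermined in principle; reconstructions may be the
  enantiomer of the truth.
* The direct-Fourier reconstructor is for validation, not production maps.
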