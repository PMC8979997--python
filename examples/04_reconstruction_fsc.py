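"""Reconstruct a density map from estimated orientations and measure its
agreement with the original phantom by Fourier shell correlation.

The ab initio orientations are defined only up to a global rotation and
handedness, so they are first aligned to the ground truth; the aligned
angles then drive the direct-Fourier reconstructor.
"""

from cryoembed import (ImageStack, align_to_reference, backproject,
                       estimate_orientations, fsc, make_phantom,
                       project_stack, sample_uniform_orientations)

volume = make_phantom(size=64, seed=1)
truth = sample_uniform_orientations(100, seed=4)
stack_data = project_stack(volume, truth)

outcome = estimate_orientations(stack_data, seed=0)
aligned, _, mirrored = align_to_reference(outcome.orientations, truth)
print(f"global handedness flip applied during alignment: {mirrored}")

reconstruction = backproject(ImageStack(stack_data, volume.voxel_size), aligned)
curve = fsc(reconstruction.data, volume.data, volume.voxel_size)
print(f"FSC resolution at 0.143: {curve.resolution_at(0.143):.2f} A "
      f"(voxel size {volume.voxel_size:.2f} A, Nyquist at "
      f"{2 * volume.voxel_size:.2f} A)")
curve.to_tsv("fsc_curve.tsv")
print("wrote fsc_curve.tsv (freq_invA, fsc)")
# Near-Nyquist resolution on clean data means the estimated angles are
# accurate enough that the reconstruction is limited by the grid, not by
# orientation errors.
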