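"""Ab initio orientation recovery on a clean simulated stack.

Runs the full pipeline -- common-line detection, dihedral voting, the two
spherical embeddings and the orthogonality-constrained assembly -- on 30
noiseless projections, then compares the recovered Euler angles with the
ground truth after removing the global rotation/handedness freedom.
"""

import numpy as np

from cryoembed import (compare_orientations, estimate_orientations,
                       make_phantom, project_stack,
                       sample_uniform_orientations)

volume = make_phantom(size=64, seed=1)
truth = sample_uniform_orientations(30, seed=2)
stack = project_stack(volume, truth)

outcome = estimate_orientations(stack, seed=0)
print(f"first embedding stress : {outcome.stress_normals:.3g}")
print(f"second embedding stress: {outcome.stress_xaxes:.3g}")
print(f"consistency  sum(delta^2)/n: {outcome.alignment.consistency:.3g}")
print(f"common-line agreement of the chosen mirror combination: "
      f"{outcome.alignment.cl_agreement:.4f}")

cmp_ = compare_orientations(outcome.orientations, truth)
errs = np.degrees(np.abs(cmp_.per_pair_dihedral_errors[:, 0]
                         - cmp_.per_pair_dihedral_errors[:, 1]))
print(f"per-angle RMSE (deg): alpha={cmp_.rmse_alpha:.2f} "
      f"beta={cmp_.rmse_beta:.2f} gamma={cmp_.rmse_gamma:.2f}")
print(f"median per-image geodesic error: {cmp_.median_geodesic_deg:.2f} deg")
print(f"max pairwise dihedral error: {errs.max():.2f} deg")
# Sub-degree RMSEs on clean data: residuals reflect the 1-degree ray/bin
# resolution of the common-line search and voting histogram.
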