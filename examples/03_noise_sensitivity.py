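"""Orientation accuracy as a function of image noise.

Projects one specimen at fixed orientations, adds Gaussian white noise at
several SNR levels, and reports how the dihedral-angle errors and per-angle
RMSEs grow as the images get noisier -- the desk-scale analogue of the
simulated-benchmark noise sweep.
"""

import numpy as np

from cryoembed import (NoiseSpec, add_noise, compare_orientations,
                       estimate_orientations, make_phantom, project_stack,
                       sample_uniform_orientations)

volume = make_phantom(size=64, seed=1)
truth = sample_uniform_orientations(60, seed=3)
clean = project_stack(volume, truth)

print(f"{'SNR':>6} {'med dihedral err':>17} {'RMSE alpha/beta/gamma (deg)':>28}")
for snr in (5.0, 1.0, 0.5):
    noisy = np.stack([add_noise(clean[i], NoiseSpec(snr, seed=100 + i))
                      for i in range(len(clean))])
    out = estimate_orientations(noisy, seed=0)
    cmp_ = compare_orientations(out.orientations, truth)
    errs = np.degrees(np.abs(cmp_.per_pair_dihedral_errors[:, 0]
                             - cmp_.per_pair_dihedral_errors[:, 1]))
    print(f"{snr:>6.1f} {np.median(errs):>14.2f}    "
          f"{cmp_.rmse_alpha:>8.2f}/{cmp_.rmse_beta:.2f}/{cmp_.rmse_gamma:.2f}")
# Errors shrink monotonically as SNR rises; the spherical embeddings keep
# the estimates usable even when most individual common lines are wrong.
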