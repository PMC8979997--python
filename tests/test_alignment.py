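import numpy as np
import pytest

from cryoembed.alignment import (assemble_orientations, build_xaxis_targets,
                                 common_line_agreement, extract_gamma,
                                 solve_alignment_rotation, xaxis_angle)
from cryoembed.commonlines import true_common_lines
from cryoembed.embedding import SphereConfig, mirror
from cryoembed.evaluation import align_to_reference, geodesic_errors
from cryoembed.geometry import pairwise_geodesic
from cryoembed.simulate import sample_uniform_orientations
from cryoembed.voting import WeightMatrix


def _rand_rot(rng):
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    r = u @ vt
    if np.linalg.det(r) < 0:
        r[:, 0] *= -1
    return r


def test_xaxis_angle_reductions():
    th = 0.77
    assert np.isclose(xaxis_angle(np.pi / 2, np.pi / 2, th), th)
    c = 1.1
    assert np.isclose(xaxis_angle(0.0, c, 0.3), c)


def test_xaxis_angle_coordinate_oracle():
    """Angle between A_i = (cos C_ij, sin C_ij, 0) and
    A_j = (cos C_ji, sin C_ji cos t, sin C_ji sin t)."""
    rng = np.random.default_rng(0)
    cij = rng.uniform(0, 2 * np.pi, 1000)
    cji = rng.uniform(0, 2 * np.pi, 1000)
    t = rng.uniform(0, np.pi, 1000)
    ai = np.stack([np.cos(cij), np.sin(cij), np.zeros_like(cij)], axis=1)
    aj = np.stack([np.cos(cji), np.sin(cji) * np.cos(t), np.sin(cji) * np.sin(t)], axis=1)
    expected = np.arccos(np.clip(np.sum(ai * aj, axis=1), -1, 1))
    assert np.allclose(xaxis_angle(cij, cji, t), expected, atol=1e-12)


def test_xaxis_angle_specific_value():
    val = np.degrees(xaxis_angle(np.radians(30), np.radians(60), np.radians(45)))
    assert abs(val - 42.3) < 0.1


def test_build_xaxis_targets_matches_truth():
    ors = sample_uniform_orientations(20, seed=1)
    cl = true_common_lines(ors)
    normals = SphereConfig(ors.normals())
    w = np.ones((20, 20))
    np.fill_diagonal(w, 0)
    xt = build_xaxis_targets(cl, normals, WeightMatrix(w, 0.0))
    true_phi = pairwise_geodesic(ors.xaxes())
    iu = np.triu_indices(20, 1)
    defined = ~np.isnan(xt.phi[iu])
    err = np.degrees(np.abs(xt.phi - true_phi))[iu][defined]
    assert np.max(err) < 2.0
    assert np.allclose(xt.phi, xt.phi.T, equal_nan=True)
    # unweighted pairs carry no target
    w2 = w.copy()
    w2[0, 1] = w2[1, 0] = 0.0
    xt2 = build_xaxis_targets(cl, normals, WeightMatrix(w2, 0.0))
    assert np.isnan(xt2.phi[0, 1]) and xt2.weights.omega[0, 1] == 0


def test_solver_identity_when_already_orthogonal():
    ors = sample_uniform_orientations(15, seed=2)
    normals = SphereConfig(ors.normals())
    xaxes = SphereConfig(ors.xaxes())
    r = solve_alignment_rotation(normals, xaxes)
    defect = np.einsum("ik,kl,il->i", normals.xyz, r, xaxes.xyz)
    assert np.sum(defect**2) < 1e-10


def test_solver_recovers_injected_rotation():
    rng = np.random.default_rng(3)
    ors = sample_uniform_orientations(25, seed=4)
    normals = SphereConfig(ors.normals())
    r0 = _rand_rot(rng)
    xaxes = SphereConfig(ors.xaxes() @ r0)   # rotate the cloud away
    r = solve_alignment_rotation(normals, xaxes)
    defect = np.einsum("ik,kl,il->i", normals.xyz, r, xaxes.xyz)
    assert np.sum(defect**2) < 1e-8
    assert np.isclose(np.linalg.det(r), 1.0)


def test_solver_perturbation_stability():
    rng = np.random.default_rng(5)
    ors = sample_uniform_orientations(100, seed=6)
    normals = SphereConfig(ors.normals())
    noise = rng.normal(0, np.radians(1), (100, 3))
    xaxes = SphereConfig(ors.xaxes() + noise)
    r = solve_alignment_rotation(normals, xaxes)
    per_image = np.abs(np.einsum("ik,kl,il->i", normals.xyz, r, xaxes.xyz))
    assert np.sqrt(np.mean(per_image**2)) < 3 * np.radians(1)


def test_solver_needs_nine_images():
    ors = sample_uniform_orientations(5, seed=7)
    with pytest.raises(ValueError, match="9"):
        solve_alignment_rotation(SphereConfig(ors.normals()),
                                 SphereConfig(ors.xaxes()))


def test_extract_gamma_round_trip():
    ors = sample_uniform_orientations(30, seed=8)
    normals = SphereConfig(ors.normals())
    xaxes = SphereConfig(ors.xaxes())
    gammas, deltas, degen = extract_gamma(normals, xaxes)
    assert np.max(np.abs(deltas)) < 1e-10
    assert not degen.any()
    diff = np.angle(np.exp(1j * (gammas - ors.angles[:, 2])))
    assert np.max(np.abs(diff)) < 1e-9


def test_extract_gamma_beta_zero_reads_xaxis_directly():
    normals = SphereConfig(np.array([[0.0, 0.0, 1.0]]))
    g = 0.9
    xaxes = SphereConfig(np.array([[np.cos(g), np.sin(g), 0.0]]))
    gammas, deltas, degen = extract_gamma(normals, xaxes)
    assert np.isclose(gammas[0], g) and abs(deltas[0]) < 1e-12 and not degen[0]


def test_extract_gamma_degenerate_flag():
    normals = SphereConfig(np.array([[0.0, 0.0, 1.0]]))
    xaxes = SphereConfig(np.array([[0.0, 0.0, 1.0]]))  # parallel to normal
    _, deltas, degen = extract_gamma(normals, xaxes)
    assert degen[0] and np.isclose(abs(deltas[0]), 1.0)


def test_assemble_recovers_consistent_inputs():
    ors = sample_uniform_orientations(30, seed=9)
    cl = true_common_lines(ors)
    est, res = assemble_orientations(SphereConfig(ors.normals()),
                                     SphereConfig(ors.xaxes()), cl)
    assert res.consistency < 1e-8
    aligned, _, _ = align_to_reference(est, ors)
    assert np.degrees(np.median(geodesic_errors(aligned, ors))) < 0.1


def test_assemble_heals_injected_mirror():
    ors = sample_uniform_orientations(30, seed=10)
    cl = true_common_lines(ors)
    xm = mirror(SphereConfig(ors.xaxes()))
    est, res = assemble_orientations(SphereConfig(ors.normals()), xm, cl)
    aligned, _, _ = align_to_reference(est, ors)
    assert np.degrees(np.median(geodesic_errors(aligned, ors))) < 0.1


def test_agreement_separates_solution_classes():
    """The flip-invariant common-line match is ~1 for the truth and for its
    enantiomer, and clearly lower for the reflected-image configuration."""
    ors = sample_uniform_orientations(25, seed=11)
    cl = true_common_lines(ors)
    assert common_line_agreement(ors, cl) > 0.999
    from cryoembed.evaluation import mirror_orientations
    assert common_line_agreement(mirror_orientations(ors), cl) > 0.999
    # reflected-image pseudo-solution: conjugate every rotation by J
    from cryoembed.geometry import OrientationSet
    J = np.diag([1.0, -1.0, 1.0])
    flipped = OrientationSet.from_matrices(
        np.einsum("ij,njk,kl->nil", J, ors.matrices(), J))
    assert common_line_agreement(flipped, cl) < 0.5


def test_consistency_grows_with_xaxis_noise():
    ors = sample_uniform_orientations(40, seed=12)
    cl = true_common_lines(ors)
    rng = np.random.default_rng(13)
    scores = []
    for sd in (0.0, np.radians(2), np.radians(5)):
        x = ors.xaxes() + rng.normal(0, sd, (40, 3))
        _, res = assemble_orientations(SphereConfig(ors.normals()),
                                       SphereConfig(x), cl)
        scores.append(res.consistency)
    assert scores[0] <= scores[1] <= scores[2]
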