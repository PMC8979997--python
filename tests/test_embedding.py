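import numpy as np
import pytest

from cryoembed.embedding import (EmbeddingProblem, SphereConfig, embed,
                                 initial_embedding, mirror, refine_embedding,
                                 stress)
from cryoembed.geometry import pairwise_geodesic, rot_z
from cryoembed.voting import WeightMatrix


def _uniform_problem(target):
    n = target.shape[0]
    w = np.ones((n, n))
    np.fill_diagonal(w, 0)
    return EmbeddingProblem(target, WeightMatrix(w, 0.0))


def _random_config(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _procrustes_rms(X, Y):
    """Best-orthogonal-map RMS angular mismatch (radians)."""
    u, _, vt = np.linalg.svd(Y.T @ X)
    q = u @ vt
    d = np.arccos(np.clip(np.sum((X @ q.T) * Y, axis=1), -1, 1))
    return float(np.sqrt(np.mean(d**2)))


def test_stress_zero_at_exact_configuration():
    pts = _random_config(10, 0)
    prob = _uniform_problem(pairwise_geodesic(pts))
    assert stress(SphereConfig(pts), prob) < 1e-20


def test_stress_zero_weights():
    pts = _random_config(5, 1)
    target = pairwise_geodesic(pts) + 0.5
    np.fill_diagonal(target, 0)
    target = np.clip(target, 0, np.pi)
    prob = EmbeddingProblem(target, WeightMatrix(np.zeros((5, 5)), 0.0))
    assert stress(SphereConfig(pts), prob) == 0.0


def test_stress_ordered_sum_arithmetic():
    """Two coincident points with target pi/2 contribute twice."""
    pts = np.array([[0, 0, 1.0], [0, 0, 1.0]])
    target = np.array([[0, np.pi / 2], [np.pi / 2, 0]])
    prob = _uniform_problem(target)
    assert np.isclose(stress(SphereConfig(pts), prob), 2 * (np.pi / 2) ** 2)


def test_initial_embedding_recovers_clean_gram():
    pts = _random_config(40, 2)
    prob = _uniform_problem(pairwise_geodesic(pts))
    cfg = initial_embedding(prob)
    assert cfg.stress < 0.1 * np.mean(prob.target[prob.omega > 0] ** 2) * np.sum(prob.omega)
    assert _procrustes_rms(cfg.xyz, pts) < 1e-6


def test_initial_embedding_three_point_triangle():
    target = np.zeros((3, 3))
    target[0, 1] = target[1, 0] = 0.9
    target[0, 2] = target[2, 0] = 1.3
    target[1, 2] = target[2, 1] = 0.7
    cfg = initial_embedding(_uniform_problem(target))
    d = cfg.distances()
    assert np.allclose(d[np.triu_indices(3, 1)],
                       target[np.triu_indices(3, 1)], atol=1e-6)


def test_initial_embedding_tetrahedron():
    t = np.arccos(-1.0 / 3.0)
    target = np.full((4, 4), t)
    np.fill_diagonal(target, 0)
    cfg = initial_embedding(_uniform_problem(target))
    assert cfg.stress < 1e-8


def test_refine_monotone_and_idempotent_at_truth():
    pts = _random_config(30, 3)
    prob = _uniform_problem(pairwise_geodesic(pts))
    at_truth = refine_embedding(SphereConfig(pts), prob)
    assert at_truth.stress < 1e-20
    start = SphereConfig(_random_config(30, 4))
    refined = refine_embedding(start, prob, max_iter=500)
    assert refined.stress <= stress(start, prob)


def test_embed_exact_recovery_medium():
    for n in (50, 200):
        pts = _random_config(n, n)
        prob = _uniform_problem(pairwise_geodesic(pts))
        cfg = embed(prob, seed=0)
        assert cfg.stress < 1e-6
        res = min(_procrustes_rms(cfg.xyz, pts),
                  _procrustes_rms(mirror(cfg).xyz, pts))
        assert res < 1e-3


def test_embed_large_exact_targets():
    pts = _random_config(1000, 9)
    prob = _uniform_problem(pairwise_geodesic(pts))
    cfg = embed(prob, restarts=1, seed=0)
    dev = np.max(np.abs(cfg.distances() - prob.target)[prob.omega > 0])
    assert np.degrees(dev) < 0.5


def test_stress_invariant_under_global_orthogonal_transform():
    pts = _random_config(25, 5)
    prob = _uniform_problem(pairwise_geodesic(_random_config(25, 6)))
    s0 = stress(SphereConfig(pts), prob)
    rot = rot_z(1.234)
    assert abs(stress(SphereConfig(pts @ rot.T), prob) - s0) < 1e-10
    refl = pts.copy()
    refl[:, 1] *= -1
    assert abs(stress(SphereConfig(refl), prob) - s0) < 1e-10


def test_mirror_is_isometric_involution():
    cfg = SphereConfig(_random_config(12, 7))
    m = mirror(cfg)
    assert np.allclose(pairwise_geodesic(m.xyz), pairwise_geodesic(cfg.xyz))
    assert np.allclose(mirror(m).xyz, cfg.xyz)


def test_chiral_config_not_rotatable_onto_mirror():
    pts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1] / np.sqrt(3)])
    m = mirror(SphereConfig(pts)).xyz
    # proper-rotation-only Procrustes
    u, s, vt = np.linalg.svd(m.T @ pts)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    q = u @ vt
    res = np.max(np.arccos(np.clip(np.sum((pts @ q.T) * m, axis=1), -1, 1)))
    assert res > 0.1


def test_rectification_under_target_noise():
    """Embedding output distances are closer to truth than the noisy targets."""
    rng = np.random.default_rng(8)
    pts = _random_config(100, 10)
    clean = pairwise_geodesic(pts)
    noise = rng.normal(0, np.radians(2), clean.shape)
    noise = 0.5 * (noise + noise.T)
    np.fill_diagonal(noise, 0)
    target = np.clip(clean + noise, 0, np.pi)
    cfg = embed(_uniform_problem(target), seed=0)
    iu = np.triu_indices(100, 1)
    in_rms = np.sqrt(np.mean((target - clean)[iu] ** 2))
    out_rms = np.sqrt(np.mean((cfg.distances() - clean)[iu] ** 2))
    assert out_rms < in_rms


def test_weight_zero_pairs_unconstrained():
    pts = _random_config(6, 11)
    target = pairwise_geodesic(pts)
    w = np.ones((6, 6))
    np.fill_diagonal(w, 0)
    w[0, 5] = w[5, 0] = 0.0
    target_wrong = target.copy()
    target_wrong[0, 5] = target_wrong[5, 0] = np.pi / 7  # ignored
    prob = EmbeddingProblem(target_wrong, WeightMatrix(w, 0.0))
    assert stress(SphereConfig(pts), prob) < 1e-20


def test_disconnected_weight_graph_rejected():
    target = np.full((4, 4), 1.0)
    np.fill_diagonal(target, 0)
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    prob = EmbeddingProblem(target, WeightMatrix(w, 0.0))
    with pytest.raises(ValueError, match="disconnected"):
        embed(prob)


def test_problem_validation():
    target = np.full((3, 3), np.nan)
    w = np.ones((3, 3))
    with pytest.raises(ValueError, match="zero where target"):
        EmbeddingProblem(target, WeightMatrix(w, 0.0))
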