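"""Centroid size, OPA, GPA, tangent projection and Procrustes distances.

Independent oracles: brute-force centroid-size formula, exhaustive rotation
grid search for the optimal pairwise alignment, Monte-Carlo consensus
recovery, and the closed-form relation partial = 2*sin(geodesic/2).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wingmorph as wm
from wingmorph.exceptions import DegenerateConfigurationError, ShapeMismatchError

from conftest import random_configuration, random_similarity


# ---------------------------------------------------------------------------
# centroid size / preshape
# ---------------------------------------------------------------------------


def test_centroid_size_square_and_triangle():
    square = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], float)
    assert wm.centroid_size(wm.LandmarkConfiguration("sq", square)) == pytest.approx(
        2 * np.sqrt(2), abs=1e-12
    )
    ang = 2 * np.pi * np.arange(3) / 3
    tri = np.column_stack([np.cos(ang), np.sin(ang)])
    assert wm.centroid_size(wm.LandmarkConfiguration("tri", tri)) == pytest.approx(
        np.sqrt(3), abs=1e-12
    )


def test_centroid_size_matches_loop_oracle(rng):
    cfg = random_configuration(rng, k=11)
    centroid = cfg.coords.mean(axis=0)
    oracle = np.sqrt(sum((p - centroid) @ (p - centroid) for p in cfg.coords))
    assert wm.centroid_size(cfg) == pytest.approx(oracle, abs=1e-12)


def test_centroid_size_scaling_and_translation(rng):
    cfg = random_configuration(rng)
    cs = wm.centroid_size(cfg)
    assert wm.centroid_size(cfg.with_coords(3.7 * cfg.coords)) == pytest.approx(3.7 * cs)
    assert wm.centroid_size(cfg.with_coords(cfg.coords + [5, -2])) == pytest.approx(cs)


def test_centroid_size_degenerate_warns():
    cfg = wm.LandmarkConfiguration("deg", np.ones((4, 2)))
    with pytest.warns(UserWarning, match="degenerate"):
        assert wm.centroid_size(cfg) == 0.0


def test_preshape_properties(rng):
    cfg = random_configuration(rng)
    ps = wm.preshape(cfg)
    assert wm.centroid_size(ps) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(ps.centroid, 0, atol=1e-12)
    # idempotent
    np.testing.assert_allclose(wm.preshape(ps).coords, ps.coords, atol=1e-12)
    # translation+scale invariant
    moved = cfg.with_coords(0.3 * cfg.coords + [7, 7])
    np.testing.assert_allclose(wm.preshape(moved).coords, ps.coords, atol=1e-12)
    with pytest.raises(DegenerateConfigurationError):
        wm.preshape(wm.LandmarkConfiguration("deg", np.zeros((3, 2))))


# ---------------------------------------------------------------------------
# OPA
# ---------------------------------------------------------------------------


def test_opa_recovers_exact_similarity(rng):
    target = random_configuration(rng)
    theta = np.deg2rad(30)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moving = target.with_coords(target.coords @ R.T + [5, -2])
    fit = wm.opa(target, moving)
    assert fit.distance == pytest.approx(0.0, abs=1e-10)
    # recovered rotation undoes the applied one
    assert abs(abs(fit.rotation_angle) - theta) < 1e-8
    np.testing.assert_allclose(fit.aligned.coords, target.coords, atol=1e-9)
    assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-10)


def test_opa_never_uses_reflection(rng):
    target = random_configuration(rng)
    mirror = target.with_coords(target.coords * [-1, 1])
    fit = wm.opa(target, mirror)
    assert fit.distance > 0.05
    assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-10)


def _grid_search_distance(a, b, step=1e-4):
    """Brute-force minimum over rotation angles of the preshape residual."""
    za = wm.preshape(a).coords
    zb = wm.preshape(b).coords
    best = np.inf
    for theta in np.arange(0, 2 * np.pi, step):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        best = min(best, np.linalg.norm(za - zb @ R.T))
    return best


def test_opa_distance_matches_grid_search(rng):
    for _ in range(5):
        a, b = random_configuration(rng), random_configuration(rng)
        assert wm.opa(a, b).distance == pytest.approx(_grid_search_distance(a, b), abs=1e-6)


def test_opa_shape_mismatch(rng):
    with pytest.raises(ShapeMismatchError):
        wm.opa(random_configuration(rng, k=5), random_configuration(rng, k=6))


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def test_gpa_zero_variance_recovers_single_shape(rng):
    base = random_configuration(rng)
    configs = [
        base.with_coords(random_similarity(base.coords, rng), specimen_id=f"c{i}")
        for i in range(8)
    ]
    res = wm.gpa(wm.LandmarkDataset(configs))
    assert res.converged
    for aligned in res.aligned:
        assert wm.procrustes_distance(aligned, res.consensus) < 1e-8


def test_gpa_result_invariants(small_dataset):
    res = wm.gpa(small_dataset)
    np.testing.assert_allclose(res.consensus.mean(axis=0), 0, atol=1e-10)
    assert np.linalg.norm(res.consensus) == pytest.approx(1.0, abs=1e-10)
    for aligned in res.aligned:
        assert np.linalg.norm(aligned - aligned.mean(axis=0)) == pytest.approx(1.0, abs=1e-10)
    assert np.all(np.diff(res.objective_trace) <= 1e-12)


def test_gpa_order_invariance(small_dataset, rng):
    res = wm.gpa(small_dataset)
    perm = rng.permutation(len(small_dataset))
    shuffled = wm.LandmarkDataset([small_dataset[int(i)] for i in perm])
    res2 = wm.gpa(shuffled)
    np.testing.assert_allclose(res2.consensus, res.consensus, atol=1e-10)
    by_id = {sid: res.aligned[i] for i, sid in enumerate(res.specimen_ids)}
    for i, sid in enumerate(res2.specimen_ids):
        np.testing.assert_allclose(res2.aligned[i], by_id[sid], atol=1e-8)
    assert res2.objective_trace[-1] == pytest.approx(res.objective_trace[-1], abs=1e-8)


def test_gpa_invariant_to_transforming_one_specimen(small_dataset, rng):
    res = wm.gpa(small_dataset)
    configs = list(small_dataset.configurations)
    configs[3] = configs[3].with_coords(random_similarity(configs[3].coords, rng))
    res2 = wm.gpa(wm.LandmarkDataset(configs))
    np.testing.assert_allclose(res2.consensus, res.consensus, atol=1e-8)
    np.testing.assert_allclose(res2.aligned, res.aligned, atol=1e-8)


def test_gpa_consensus_recovery_monte_carlo():
    """Consensus of 200 noisy specimens approaches the true mean shape."""
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 1, 0.0, seed=5)
    ds = wm.simulate_specimens(means, 200, 0.01, seed=6)
    res = wm.gpa(ds)
    assert res.converged
    assert wm.procrustes_distance(res.consensus, template) < 0.005


# ---------------------------------------------------------------------------
# tangent coordinates
# ---------------------------------------------------------------------------


def test_tangent_consensus_maps_to_zero_and_rank(small_dataset):
    res = wm.gpa(small_dataset)
    T = wm.tangent_coordinates(res)
    c = res.consensus.reshape(-1)
    # the consensus itself projects to the zero vector
    assert np.linalg.norm(c - (c @ c) * c) < 1e-12
    k = res.k
    assert np.linalg.matrix_rank(T, tol=1e-9) <= 2 * k - 4


def test_tangent_distances_match_procrustes_for_small_dispersion(small_dataset):
    res = wm.gpa(small_dataset)
    T = wm.tangent_coordinates(res)
    n = len(small_dataset)
    D = wm.distance_matrix(small_dataset, variant="partial").values
    for i in range(n):
        for j in range(i + 1, n):
            d_tan = np.linalg.norm(T[i] - T[j])
            assert d_tan == pytest.approx(D[i, j], rel=0.01)


# ---------------------------------------------------------------------------
# Procrustes distances
# ---------------------------------------------------------------------------


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_distance_similarity_invariance(seed):
    rng = np.random.default_rng(seed)
    cfg = random_configuration(rng)
    moved = cfg.with_coords(random_similarity(cfg.coords, rng))
    assert wm.procrustes_distance(cfg, moved) < 1e-8


def test_distance_symmetry_and_identity(rng):
    for _ in range(10):
        a, b = random_configuration(rng), random_configuration(rng)
        assert wm.procrustes_distance(a, a) == 0.0
        for variant in ("partial", "full", "geodesic"):
            dab = wm.procrustes_distance(a, b, variant)
            dba = wm.procrustes_distance(b, a, variant)
            assert dab == pytest.approx(dba, abs=1e-12)


def test_partial_geodesic_closed_form_relation(rng):
    for _ in range(20):
        a, b = random_configuration(rng), random_configuration(rng)
        partial = wm.procrustes_distance(a, b, "partial")
        rho = wm.procrustes_distance(a, b, "geodesic")
        assert partial == pytest.approx(2 * np.sin(rho / 2), abs=1e-10)
        full = wm.procrustes_distance(a, b, "full")
        assert full == pytest.approx(np.sin(rho), abs=1e-10)


def test_geodesic_triangle_inequality(rng):
    for _ in range(30):
        a, b, c = (random_configuration(rng) for _ in range(3))
        dab = wm.procrustes_distance(a, b, "geodesic")
        dbc = wm.procrustes_distance(b, c, "geodesic")
        dac = wm.procrustes_distance(a, c, "geodesic")
        assert dac <= dab + dbc + 1e-10


def test_distance_matrix_consistency(small_dataset):
    dm = wm.distance_matrix(small_dataset)
    n = len(small_dataset)
    assert dm.values.shape == (n, n)
    np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(dm.values), 0, atol=1e-12)
    for i in range(0, n, 3):
        for j in range(i + 1, n, 4):
            d = wm.procrustes_distance(small_dataset[i], small_dataset[j])
            assert dm.values[i, j] == pytest.approx(d, abs=1e-12)


def test_distance_matrix_identical_shapes(rng):
    base = random_configuration(rng)
    ds = wm.LandmarkDataset(
        [base.with_coords(base.coords, specimen_id=f"c{i}") for i in range(3)]
    )
    np.testing.assert_allclose(wm.distance_matrix(ds).values, 0, atol=1e-12)


def test_distance_matrix_matches_grid_oracle(rng):
    configs = [random_configuration(rng) for _ in range(5)]
    ds = wm.LandmarkDataset(configs)
    dm = wm.distance_matrix(ds)
    for i in range(5):
        for j in range(i + 1, 5):
            assert dm.values[i, j] == pytest.approx(
                _grid_search_distance(configs[i], configs[j]), abs=1e-6
            )
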