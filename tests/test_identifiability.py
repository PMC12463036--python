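import numpy as np
import pytest

import identifim as idf

from conftest import linear_2p_model, rank1_model, random_sensitivity_matrix


# ---------------------------------------------------------------------------
# FIM construction and eigendecomposition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "S, expected",
    [
        (np.eye(2), np.eye(2)),
        (np.array([[1.0, 0.0], [1.0, 1.0]]), np.array([[2.0, 1.0], [1.0, 1.0]])),
    ],
)
def test_fim_is_gram_matrix(S, expected):
    np.testing.assert_allclose(idf.fim(S), expected, atol=1e-14)


def test_fim_positive_semidefinite_on_random_input():
    rng = np.random.default_rng(0)
    for _ in range(20):
        S = rng.standard_normal((rng.integers(2, 10), rng.integers(2, 6)))
        w = np.linalg.eigvalsh(idf.fim(S))
        assert w.min() >= -1e-10 * max(w.max(), 1.0)


def test_eigendecompose_diagonal_case():
    ana = idf.eigendecompose_fim(np.diag([4.0, 1.0, 0.0]), eps_eig=1e-4)
    np.testing.assert_allclose(ana.eigenvalues, [4.0, 1.0, 0.0], atol=1e-14)
    assert ana.r == 2
    np.testing.assert_allclose(np.abs(ana.u_null[:, 0]), [0, 0, 1], atol=1e-12)


def test_eigendecompose_reconstruction_random_psd():
    rng = np.random.default_rng(1)
    A = rng.standard_normal((9, 6))
    F = A.T @ A
    ana = idf.eigendecompose_fim(F, eps_eig=1e-8)
    recon = ana.eigenvectors @ np.diag(ana.eigenvalues) @ ana.eigenvectors.T
    assert np.abs(recon - F).max() < 1e-8 * (1 + ana.eigenvalues.max())
    assert np.abs(ana.eigenvectors.T @ ana.eigenvectors - np.eye(6)).max() < 1e-10
    assert np.all(np.diff(ana.eigenvalues) <= 1e-12)


def test_eigendecompose_sign_convention_is_deterministic():
    rng = np.random.default_rng(2)
    A = rng.standard_normal((8, 4))
    F = A.T @ A
    U1 = idf.eigendecompose_fim(F, 1e-6).eigenvectors
    U2 = idf.eigendecompose_fim(F.copy(), 1e-6).eigenvectors
    np.testing.assert_array_equal(U1, U2)
    for j in range(4):
        assert U1[np.argmax(np.abs(U1[:, j])), j] > 0


def test_eigendecompose_rejects_asymmetric():
    with pytest.raises(ValueError):
        idf.eigendecompose_fim(np.array([[1.0, 5.0], [0.0, 1.0]]), 1e-6)


def test_polynomial_fixture_has_one_null_eigenvalue(poly_analysis):
    _, ana = poly_analysis
    assert np.sum(ana.eigenvalues <= 1e-10) == 1


# ---------------------------------------------------------------------------
# Coordinate metric
# ---------------------------------------------------------------------------

def test_metric_orthogonal_columns():
    rep = idf.coordinate_metric(np.eye(2))
    np.testing.assert_allclose(rep.metric, [1.0, 1.0], atol=1e-12)
    assert rep.flags.all()


def test_metric_identical_columns_vanishes():
    rep = idf.coordinate_metric(np.ones((2, 2)))
    np.testing.assert_allclose(rep.metric, [0.0, 0.0], atol=1e-12)
    assert not rep.flags.any()


def test_metric_requires_two_parameters():
    with pytest.raises(ValueError):
        idf.coordinate_metric(np.ones((3, 1)))


def test_metric_bounded_by_own_column(hill_model, hill_theta, hill_times):
    """Projection residual: 0 ≤ metric ≤ ‖sᵢ‖₂ (and ≤ ‖sᵢ‖∞ on this fixture)."""
    S = idf.sensitivity_matrix(hill_model, hill_theta, hill_times)
    rep = idf.coordinate_metric(S)
    col_max = np.abs(S.values).max(axis=0)
    assert np.all(rep.metric <= col_max + 1e-12)
    assert np.all(rep.metric >= 0)


def test_hill_metric_ordering(hill_model, hill_theta, hill_times):
    """Vmax is pinned down hardest, then Kd; cooperativity n is weakest."""
    S = idf.sensitivity_matrix(hill_model, hill_theta, hill_times)
    m = idf.coordinate_metric(S).metric
    assert m[0] > m[1] > m[2]


def test_theorem3_oracle_equivalence():
    """Zero metric ⇔ column in span of the others (200 random instances)."""
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(200):
        S = random_sensitivity_matrix(rng)
        rep = idf.coordinate_metric(S)
        for i in range(S.shape[1]):
            A = np.delete(S, i, axis=1)
            x, *_ = np.linalg.lstsq(A, S[:, i], rcond=None)
            resid = np.linalg.norm(S[:, i] - A @ x)
            assert (rep.metric[i] <= 1e-10) == (resid <= 1e-10)
            checked += 1
    assert checked >= 400


def test_rank_and_metric_consistency():
    """Full FIM rank ⇔ every coordinate metric positive (random + zoo)."""
    rng = np.random.default_rng(7)
    cases = [random_sensitivity_matrix(rng) for _ in range(60)]
    zoo = [
        idf.sensitivity_matrix(idf.polynomial(), [1, 1, 1], [1.0, 2.0, 3.0]).values,
        idf.sensitivity_matrix(idf.hill(), [2, 1, 4], np.linspace(2, 4, 9)).values,
        idf.sensitivity_matrix(
            idf.lv(), [0.55, 0.028, 0.024, 0.84], np.linspace(0, 20, 25)
        ).values,
    ]
    for S in cases + zoo:
        w = np.clip(np.linalg.eigvalsh(idf.fim(S)), 0, None)
        r = int(np.sum(w > 1e-10 * w.max())) if w.max() > 0 else 0
        metric = idf.coordinate_metric(S).metric
        tol = 1e-8 * max(np.linalg.norm(S, axis=0).max(), 1e-300)
        if r == S.shape[1]:
            assert np.all(metric > tol)
        else:
            assert np.any(metric <= tol)


# ---------------------------------------------------------------------------
# Profile likelihood
# ---------------------------------------------------------------------------

def test_profile_of_linear_model_is_parabola():
    model = linear_2p_model()
    ds = idf.generate_synthetic(model, [1.0, 2.0], [0.0, 1.0, 2.0], 0.0, 0)
    curve = idf.profile_likelihood(model, ds, np.array([1.0, 2.0]), 1)
    assert curve.classification == "identifiable"
    second_diff = np.diff(curve.pl_values, 2)
    assert np.all(second_diff > 0)
    center = curve.pl_values[np.argmin(np.abs(curve.grid - 2.0))]
    assert center == pytest.approx(0.0, abs=1e-9)


def test_profile_of_polynomial_cubic_coefficient_is_flat(
    poly_model, poly_dataset, poly_theta
):
    curve = idf.profile_likelihood(poly_model, poly_dataset, poly_theta, 2)
    assert curve.classification == "flat"
    assert curve.pl_values.max() - curve.pl_values.min() <= 1e-6


def test_profile_values_never_undershoot_global_minimum(
    poly_model, poly_dataset, poly_theta
):
    gmin = idf.loss(poly_model, poly_dataset, poly_theta)
    curve = idf.profile_likelihood(poly_model, poly_dataset, poly_theta, 0)
    assert np.all(curve.pl_values >= gmin - 1e-9 * (1 + abs(gmin)))


def test_hill_profile_classification_matches_metric_flags(
    hill_model, hill_theta, hill_times
):
    ds = idf.generate_synthetic(hill_model, hill_theta, hill_times, 0.0, 0)
    S = idf.sensitivity_matrix(hill_model, hill_theta, hill_times)
    flags = idf.coordinate_metric(S).flags
    for i in range(3):
        curve = idf.profile_likelihood(hill_model, ds, hill_theta, i)
        assert (curve.classification == "identifiable") == bool(flags[i])


# ---------------------------------------------------------------------------
# Contribution index and structural rank
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "F, expected",
    [
        (np.eye(3), 1.0),
        (np.diag([4.0, 1.0]), 0.25),
        (np.ones((2, 2)), 0.0),  # singular
    ],
)
def test_contribution_index_values(F, expected):
    assert idf.contribution_index(F) == pytest.approx(expected, abs=1e-12)


def test_contribution_index_in_unit_interval_on_zoo(hill_model, hill_theta, hill_times):
    S = idf.sensitivity_matrix(hill_model, hill_theta, hill_times)
    xi = idf.contribution_index(idf.fim(S))
    assert 0.0 <= xi <= 1.0


def test_xi_never_decreases_when_null_direction_rows_added():
    rng = np.random.default_rng(3)
    for _ in range(10):
        S = rng.standard_normal((6, 4))
        u = np.linalg.svd(S)[2][-1]  # weakest right-singular direction
        S_def = S - np.outer(S @ u, u)  # exact null direction u
        xi0 = idf.contribution_index(idf.fim(S_def))
        S_aug = np.vstack([S_def, 2.0 * u])
        xi1 = idf.contribution_index(idf.fim(S_aug))
        assert xi1 >= xi0 - 1e-12


def test_fim_eigenvalues_never_decrease_with_added_rows():
    rng = np.random.default_rng(4)
    for _ in range(20):
        S = rng.standard_normal((8, 5))
        extra = rng.standard_normal((3, 5))
        w0 = np.linalg.eigvalsh(idf.fim(S))
        w1 = np.linalg.eigvalsh(idf.fim(np.vstack([S, extra])))
        assert np.all(w1 >= w0 - 1e-10)


def test_structural_rank_polynomial_full(poly_model):
    res = idf.structural_rank_test(poly_model, [1.0, 1.0, 1.0], n_grid=50)
    assert res["rank"] == 3 and res["full_rank"]


def test_structural_rank_detects_redundant_parameterization():
    res = idf.structural_rank_test(rank1_model(), [1.0, 2.0], n_grid=20)
    assert res["rank"] == 1 and not res["full_rank"]


def test_structural_rank_hill_full(hill_model, hill_theta):
    assert idf.structural_rank_test(hill_model, hill_theta, n_grid=50)["full_rank"]


def test_structural_rank_requires_enough_grid(poly_model):
    with pytest.raises(ValueError):
        idf.structural_rank_test(poly_model, [1, 1, 1], n_grid=2)


def test_linearized_problem_dimensions(poly_model, poly_dataset, poly_theta):
    lp = idf.linearized_problem(poly_model, poly_dataset, poly_theta)
    assert lp.b.shape == (poly_dataset.n_times * poly_model.n_observables,)
    # noiseless data at theta*: b reduces to S theta*
    np.testing.assert_allclose(lp.b, lp.S @ poly_theta, atol=1e-10)
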