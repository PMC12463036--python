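import numpy as np
import pytest

import identifim as idf

from conftest import linear_2p_model, rank1_model


def test_loss_zero_for_noiseless_data(poly_model, poly_dataset, poly_theta):
    assert idf.loss(poly_model, poly_dataset, poly_theta) <= 1e-12


def test_loss_single_point_residual():
    model = linear_2p_model()
    ds = idf.Dataset(times=[1.0], observations=[[3.0]], observable_names=("y",))
    # prediction a + b·t = 2 at t=1 for θ=(1,1): residual 1, loss 1
    assert idf.loss(model, ds, [1.0, 1.0]) == pytest.approx(1.0, abs=1e-14)


def test_loss_sums_squared_residuals():
    model = linear_2p_model()
    ds = idf.Dataset(
        times=[0.0, 1.0], observations=[[0.0], [5.0]], observable_names=("y",)
    )
    # predictions (1, 3): residuals (1, -2) -> loss 5
    assert idf.loss(model, ds, [1.0, 2.0]) == pytest.approx(5.0, abs=1e-12)


def test_loss_dimension_mismatch():
    ds = idf.Dataset(
        times=[1.0], observations=[[1.0, 2.0]], observable_names=("a", "b")
    )
    with pytest.raises(ValueError):
        idf.loss(linear_2p_model(), ds, [1.0, 1.0])


def test_linear_model_exact_recovery():
    model = linear_2p_model()
    ds = idf.generate_synthetic(model, [1.0, 2.0], [0.0, 1.0, 2.0], 0.0, 0)
    res = idf.fit_least_squares(model, ds, [0.3, 0.7])
    np.testing.assert_allclose(res.theta_hat, [1.0, 2.0], atol=1e-8)
    assert res.converged


def test_lv_recovery_from_perturbed_start(lv_model, lv_theta):
    times = np.linspace(0, 20, 25)
    ds = idf.generate_synthetic(lv_model, lv_theta, times, 0.0, 0)
    res = idf.fit_least_squares(
        lv_model, ds, 1.3 * lv_theta, bounds=(np.zeros(4), np.full(4, np.inf))
    )
    assert np.abs(res.theta_hat / lv_theta - 1).max() < 1e-3


def test_fit_reports_recomputable_loss(lv_model, lv_theta):
    times = np.linspace(0, 20, 12)
    ds = idf.generate_synthetic(
        lv_model, lv_theta, times, idf.default_sigma(lv_model, lv_theta, times), 3
    )
    res = idf.fit_least_squares(lv_model, ds, lv_theta)
    recomputed = idf.loss(lv_model, ds, res.theta_hat)
    assert res.loss == pytest.approx(recomputed, rel=1e-9)


def test_empty_dataset_rejected(poly_model):
    with pytest.raises(ValueError):
        idf.Dataset(times=[], observations=np.zeros((0, 1)), observable_names=("h",))


def test_regularized_with_empty_null_space_matches_plain(poly_model):
    ds = idf.generate_synthetic(poly_model, [1.0, 1.0, 1.0], [0.5, 1.5, 2.5, 3.5], 0.0, 0)
    theta0 = np.array([1.4, 0.6, 1.2])
    plain = idf.fit_least_squares(poly_model, ds, theta0)
    reg = idf.fit_regularized(
        poly_model, ds, np.array([1.0, 1.0, 1.0]), np.zeros((3, 0)), lam=1.0,
        theta0=theta0,
    )
    np.testing.assert_allclose(reg.theta_hat, plain.theta_hat, atol=1e-10)
    assert reg.regularized


def test_regularized_solution_satisfies_normal_equations():
    """Linearized oracle: (λUUᵀ + SᵀS)θ̃ = Sᵀb + λUUᵀθ* for a linear model."""
    model = rank1_model()
    times = np.array([1.0, 2.0, 3.0])
    theta_star = np.array([1.0, 2.0])
    ds = idf.generate_synthetic(model, theta_star, times, 0.0, 0)
    S = idf.sensitivity_matrix(model, theta_star, times)
    ana = idf.eigendecompose_fim(idf.fim(S), 1e-10)
    u_null = ana.u_null
    assert u_null.shape[1] == 1
    lam = 1.0
    res = idf.fit_regularized(model, ds, theta_star, u_null, lam=lam)
    lp = idf.linearized_problem(model, ds, theta_star, S=S)
    lhs = (lam * u_null @ u_null.T + lp.S.T @ lp.S) @ res.theta_hat
    rhs = lp.S.T @ lp.b + lam * u_null @ u_null.T @ theta_star
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_regularized_objective_is_recomputable(poly_model, poly_dataset, poly_analysis):
    _, ana = poly_analysis
    theta_star = np.array([1.0, 1.0, 1.0])
    res = idf.fit_regularized(
        poly_model, poly_dataset, theta_star, ana.u_null, lam=2.5,
        theta0=np.array([1.3, 0.7, 1.6]),
    )
    penalty = 2.5 * np.sum((ana.u_null.T @ (res.theta_hat - theta_star)) ** 2)
    recomputed = idf.loss(poly_model, poly_dataset, res.theta_hat) + penalty
    assert res.objective == pytest.approx(recomputed, rel=1e-9)


def test_regularized_refit_never_increases_objective(poly_model, poly_dataset, poly_analysis):
    _, ana = poly_analysis
    theta_star = np.array([1.0, 1.0, 1.0])
    theta0 = np.array([1.5, 0.5, 1.8])
    lam = 1.0
    start_obj = idf.loss(poly_model, poly_dataset, theta0) + lam * np.sum(
        (ana.u_null.T @ (theta0 - theta_star)) ** 2
    )
    res = idf.fit_regularized(
        poly_model, poly_dataset, theta_star, ana.u_null, lam=lam, theta0=theta0
    )
    assert res.objective <= start_obj + 1e-12


def test_rejects_non_orthonormal_null_basis(poly_model, poly_dataset):
    bad = np.array([[1.0], [1.0], [0.0]])
    with pytest.raises(ValueError):
        idf.fit_regularized(
            poly_model, poly_dataset, np.ones(3), bad, lam=1.0
        )


def test_regularized_fim_lambda_zero_is_gram(poly_analysis):
    S, ana = poly_analysis
    np.testing.assert_array_equal(
        idf.regularized_fim(S, ana.u_null, 0.0), idf.fim(S)
    )


def test_regularized_fim_block_spectrum():
    # single column of squared norm 5 in a k=2 problem; null direction e2
    S = np.array([[1.0, 0.0], [2.0, 0.0]])
    u_null = np.array([[0.0], [1.0]])
    F = idf.regularized_fim(S, u_null, 1.0)
    np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(F)), [1.0, 5.0], atol=1e-12)


def test_regularized_spectrum_identity_random():
    """Spectrum of λU₀U₀ᵀ + SᵀS = retained eigenvalues ∪ {λ × (k−r)}."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        k, r = 5, 3
        basis = np.linalg.qr(rng.standard_normal((k, k)))[0]
        S = rng.standard_normal((8, r)) @ basis[:, :r].T  # rank r
        ana = idf.eigendecompose_fim(idf.fim(S), eps_eig=1e-9)
        assert ana.r == r
        lam = float(rng.uniform(0.5, 3.0))
        F = idf.regularized_fim(S, ana.u_null, lam)
        got = np.sort(np.linalg.eigvalsh(F))[::-1]
        expected = np.sort(np.concatenate([ana.eigenvalues[:r], [lam] * (k - r)]))[::-1]
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)


def test_regularized_fim_min_eigenvalue_floor(poly_analysis):
    """Smallest eigenvalue ≥ min(λ, smallest retained eigenvalue)."""
    S, ana = poly_analysis
    for lam in (0.1, 1.0, 10.0):
        F = idf.regularized_fim(S, ana.u_null, lam)
        w = np.linalg.eigvalsh(F)
        floor = min(lam, ana.eigenvalues[: ana.r].min())
        assert w.min() >= floor - 1e-9
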