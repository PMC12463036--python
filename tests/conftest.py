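import numpy as np
import pytest

import identifim as idf


@pytest.fixture(scope="session")
def poly_model():
    return idf.polynomial()


@pytest.fixture(scope="session")
def poly_theta():
    return np.array([1.0, 1.0, 1.0])


@pytest.fixture(scope="session")
def poly_dataset(poly_model, poly_theta):
    """Cubic benchmark sampled only at the roots of its cubic term."""
    return idf.generate_synthetic(poly_model, poly_theta, [1.0, 2.0, 3.0], 0.0, 0)


@pytest.fixture(scope="session")
def poly_analysis(poly_model, poly_theta, poly_dataset):
    S = idf.sensitivity_matrix(poly_model, poly_theta, poly_dataset.times)
    ana = idf.eigendecompose_fim(idf.fim(S), 1e-4, poly_model.param_names)
    return S, ana


@pytest.fixture(scope="session")
def hill_model():
    return idf.hill()


@pytest.fixture(scope="session")
def hill_theta():
    return np.array([2.0, 1.0, 4.0])


@pytest.fixture(scope="session")
def hill_times():
    """Packaged saturating-arm assay protocol."""
    return np.linspace(2.0, 4.0, 9)


@pytest.fixture(scope="session")
def lv_model():
    return idf.lv()


@pytest.fixture(scope="session")
def lv_theta():
    return np.array([0.55, 0.028, 0.024, 0.84])


def linear_2p_model():
    """h(t, θ) = θ1 + θ2·t — exactly linear in both parameters."""

    def output(t, th):
        return (th[0] + th[1] * np.asarray(t, float))[:, None]

    return idf.ModelSpec(
        name="linear2",
        kind="closed_form",
        param_names=("a", "b"),
        t_domain=(0.0, 10.0),
        observable_names=("y",),
        output=output,
    )


def rank1_model():
    """h(t, θ) = (θ1 + θ2)·t — structurally rank-deficient."""

    def output(t, th):
        return ((th[0] + th[1]) * np.asarray(t, float))[:, None]

    return idf.ModelSpec(
        name="rank1",
        kind="closed_form",
        param_names=("a", "b"),
        t_domain=(0.0, 10.0),
        observable_names=("y",),
        output=output,
    )


def decay_model():
    """Scalar ODE ẋ = −θ·x, x(0) = 1."""
    return idf.ModelSpec(
        name="decay",
        kind="ode",
        param_names=("rate",),
        t_domain=(0.0, 10.0),
        observable_names=("x",),
        rhs=lambda phi, th, t: np.array([-th[0] * phi[0]]),
        initial_state=lambda th: np.array([1.0]),
        state_names=("x",),
    )


def growth_model():
    """Scalar ODE ẋ = θ·x, x(0) = 1."""
    return idf.ModelSpec(
        name="growth",
        kind="ode",
        param_names=("rate",),
        t_domain=(0.0, 10.0),
        observable_names=("x",),
        rhs=lambda phi, th, t: np.array([th[0] * phi[0]]),
        initial_state=lambda th: np.array([1.0]),
        state_names=("x",),
    )


def random_sensitivity_matrix(rng, max_rows=12, max_k=6):
    """Random S with occasional planted rank deficiencies."""
    k = rng.integers(2, max_k + 1)
    n = rng.integers(k, max_rows + 1)
    S = rng.standard_normal((n, k))
    # plant dependencies: force some columns into the span of the others
    n_dep = rng.integers(0, k)
    for _ in range(n_dep):
        i = rng.integers(0, k)
        others = np.delete(np.arange(k), i)
        coef = rng.standard_normal(others.size)
        S[:, i] = S[:, others] @ coef
    return S
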