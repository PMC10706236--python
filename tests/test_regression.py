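"""SVR solver contract, PLS baseline, and the RMSECV convention."""
import numpy as np
import pytest

from nirsens import (
    FittedModel,
    PlsSpec,
    SvrSpec,
    fit_pls,
    fit_svr,
    kfold_rmsecv,
    make_folds,
)


def linear_data(n=10):
    x = np.arange(n, dtype=float)[:, None]
    return x, 2.0 * x.ravel() + 1.0


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "kwargs,msg",
    [
        (dict(svr_type="epsilon", kernel="linear", C=1.0, epsilon=0.1, gamma=0.5), "gamma"),
        (dict(svr_type="epsilon", kernel="radial_base", C=1.0, epsilon=0.1), "gamma"),
        (dict(svr_type="epsilon", kernel="polynomial", C=1.0, epsilon=0.1, gamma=0.5, degree=3), "coef0"),
        (dict(svr_type="epsilon", kernel="polynomial", C=1.0, epsilon=0.1, gamma=0.5, coef0=0.0, degree=7), "degree"),
        (dict(svr_type="nu", kernel="linear", C=1.0, nu=1.5), "nu"),
        (dict(svr_type="nu", kernel="linear", C=1.0, nu=0.5, epsilon=0.1), "epsilon"),
        (dict(svr_type="epsilon", kernel="linear", C=-1.0, epsilon=0.1), "C"),
        (dict(svr_type="epsilon", kernel="sigmoid", C=1.0, epsilon=0.1, gamma=0.5, coef0=0.0, degree=3), "degree"),
    ],
)
def test_svr_spec_licenses_exactly_table_parameters(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        SvrSpec(**kwargs)


# ---------------------------------------------------------------------------
# solver contract
# ---------------------------------------------------------------------------
def test_epsilon_svr_fits_noiseless_line_within_tube():
    X, y = linear_data()
    spec = SvrSpec(svr_type="epsilon", kernel="linear", C=1e4, epsilon=0.01)
    model = fit_svr(X, y, spec)
    assert np.abs(model.predict(X) - y).max() <= spec.epsilon + 1e-3


def test_epsilon_svr_agrees_with_reference_qp():
    """Small-problem check against an independently solved dual QP:
    maximize -1/2 (a-a*)'K(a-a*) - eps 1'(a+a*) + y'(a-a*) under box and
    equality constraints, solved with SLSQP."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 1))
    y = 1.5 * X.ravel() - 0.5 + rng.normal(0, 0.05, 6)
    C, eps = 10.0, 0.1
    K = X @ X.T
    n = len(y)

    def neg_dual(z):
        a, a_star = z[:n], z[n:]
        d = a - a_star
        return 0.5 * d @ K @ d + eps * z.sum() - y @ d

    cons = {"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:])}
    res = minimize(
        neg_dual,
        np.zeros(2 * n),
        bounds=[(0, C)] * 2 * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    d = res.x[:n] - res.x[n:]
    # intercept from a free (0 < alpha < C) support vector
    free = np.where((res.x[:n] > 1e-6) & (res.x[:n] < C - 1e-6))[0]
    free_star = np.where((res.x[n:] > 1e-6) & (res.x[n:] < C - 1e-6))[0]
    if free.size:
        b = y[free[0]] - eps - K[free[0]] @ d
    else:
        b = y[free_star[0]] + eps - K[free_star[0]] @ d
    ref_pred = K @ d + b

    spec = SvrSpec(svr_type="epsilon", kernel="linear", C=C, epsilon=eps)
    model = fit_svr(X, y, spec)
    np.testing.assert_allclose(model.predict(X), ref_pred, atol=1e-3)


def test_constant_target_predicted_within_tube():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(8, 3))
    y = np.full(8, 4.2)
    spec = SvrSpec(svr_type="epsilon", kernel="radial_base", C=10.0, epsilon=0.05, gamma=0.1)
    model = fit_svr(X, y, spec)
    assert np.abs(model.predict(X) - 4.2).max() <= 0.05 + 1e-6


def test_refit_reproducible_and_rows_local(rng):
    X = rng.normal(size=(12, 4))
    y = rng.normal(size=12)
    spec = SvrSpec(svr_type="epsilon", kernel="radial_base", C=5.0, epsilon=0.05, gamma=0.2)
    m1, m2 = fit_svr(X, y, spec), fit_svr(X, y, spec)
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
    perm = rng.permutation(12)
    np.testing.assert_array_equal(m1.predict(X[perm]), m1.predict(X)[perm])


def test_zero_channel_irrelevant_to_epsilon_svr(rng):
    X = rng.normal(size=(10, 3))
    y = rng.normal(size=10)
    spec = SvrSpec(svr_type="epsilon", kernel="radial_base", C=2.0, epsilon=0.1, gamma=0.3)
    base = fit_svr(X, y, spec)
    padded = fit_svr(np.hstack([X, np.zeros((10, 1))]), y, spec)
    np.testing.assert_allclose(
        padded.predict(np.hstack([X, np.zeros((10, 1))])), base.predict(X), atol=1e-10
    )


def test_large_epsilon_gives_constant_within_tube(rng):
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    eps = (y.max() - y.min()) * 1.1
    spec = SvrSpec(svr_type="epsilon", kernel="linear", C=1.0, epsilon=eps)
    model = fit_svr(X, y, spec)
    pred = model.predict(X)
    assert np.ptp(pred) < 1e-8  # all dual coefficients vanish
    assert np.abs(pred - y).max() <= eps + 1e-6


def test_nu_svr_fits_linear_trend():
    X, y = linear_data()
    spec = SvrSpec(svr_type="nu", kernel="linear", C=100.0, nu=0.8)
    model = fit_svr(X, y, spec)
    assert np.abs(model.predict(X) - y).max() < 0.1


def test_predict_channel_mismatch_errors(rng):
    X = rng.normal(size=(6, 4))
    model = fit_svr(X, rng.normal(size=6),
                    SvrSpec(svr_type="epsilon", kernel="linear", C=1.0, epsilon=0.1))
    with pytest.raises(ValueError, match="4"):
        model.predict(rng.normal(size=(2, 3)))


def test_non_finite_inputs_rejected(rng):
    X = rng.normal(size=(5, 2))
    y = rng.normal(size=5)
    y[2] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_svr(X, y, SvrSpec(svr_type="epsilon", kernel="linear", C=1.0, epsilon=0.1))


def test_model_serialization_roundtrips_predictions_bit_exactly(rng):
    X = rng.normal(size=(15, 6))
    y = rng.normal(size=15)
    for spec in (
        SvrSpec(svr_type="epsilon", kernel="radial_base", C=3.0, epsilon=0.05, gamma=0.4),
        SvrSpec(svr_type="epsilon", kernel="polynomial", C=3.0, epsilon=0.05, gamma=0.4,
                coef0=0.5, degree=3),
    ):
        model = fit_svr(X, y, spec)
        back = FittedModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.predict(X), model.predict(X))
    pls = fit_pls(X, y, n_components=3)
    back = FittedModel.from_json(pls.to_json())
    np.testing.assert_array_equal(back.predict(X), pls.predict(X))


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------
def test_pls_one_component_nails_rank_one_linear_target(rng):
    t = rng.normal(size=20)
    load = rng.normal(size=5)
    X = np.outer(t, load)  # rank-1 design
    y = X @ rng.normal(size=5)  # linear in the single latent direction
    model = fit_pls(X, y, n_components=1)
    assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) < 1e-8


def test_pls_component_bounds():
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(8, 3)), rng.normal(size=8)
    with pytest.raises(ValueError):
        fit_pls(X, y, n_components=0)
    with pytest.raises(ValueError):
        fit_pls(X, y, n_components=10)


def test_pls_full_components_equals_ols(rng):
    X = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    model = fit_pls(X, y, n_components=4)
    Z = np.column_stack([np.ones(30), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    np.testing.assert_allclose(model.predict(X), Z @ beta, atol=1e-8)


# ---------------------------------------------------------------------------
# RMSECV
# ---------------------------------------------------------------------------
def test_kfold_matches_enumerated_fold_loop(rng):
    X = rng.normal(size=(11, 3))
    y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.1, 11)
    spec = PlsSpec(2)
    folds = make_folds(11, 3, seed=5)
    got = kfold_rmsecv(X, y, spec, folds=folds)
    sq = []
    for fold in folds:
        mask = np.ones(11, dtype=bool)
        mask[fold] = False
        model = fit_pls(X[mask], y[mask], n_components=2)
        sq.extend((y[fold] - model.predict(X[fold])) ** 2)
    assert got == pytest.approx(np.sqrt(np.mean(sq)), abs=1e-12)
    # pooled vs fold-averaged differ when folds are unequal
    fold_avg = kfold_rmsecv(X, y, spec, folds=folds, pooled=False)
    assert fold_avg != got


def test_perfect_predictor_has_zero_rmsecv(rng):
    X = rng.normal(size=(12, 3))
    y = X @ np.array([0.5, 1.0, -1.0])
    assert kfold_rmsecv(X, y, PlsSpec(3), k=4, seed=0) < 1e-8


def test_fold_assignment_deterministic_and_bounded():
    f1 = make_folds(10, 3, seed=1)
    f2 = make_folds(10, 3, seed=1)
    assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
    assert sorted(np.concatenate(f1).tolist()) == list(range(10))
    with pytest.raises(ValueError):
        make_folds(4, 5, seed=0)
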