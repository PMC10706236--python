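"""Pre-treatment exactness, limits, and the no-leakage contract."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import spearmanr

from nirsens import (
    GeneratorConfig,
    NormalizationSpec,
    PreprocessChain,
    PreTreatmentSpec,
    SpectraSet,
    apply_normalizer,
    derivative,
    fit_normalizer,
    generate_dataset,
    msc,
    smooth_spline,
    snv,
)


def make_set(rows, wavenumbers=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if wavenumbers is None:
        wavenumbers = np.arange(rows.shape[1], dtype=float)
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=rows,
        sample_ids=np.array([f"S{i}" for i in range(rows.shape[0])]),
        replicate_ids=np.zeros(rows.shape[0], dtype=int),
    )


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------
def test_spline_interpolation_limit(rng):
    ss = make_set(rng.normal(size=(2, 30)))
    out = smooth_spline(ss, p=1.0)
    np.testing.assert_allclose(out.absorbance, ss.absorbance, atol=1e-8)


def test_spline_linear_limit(rng):
    x = np.arange(50, dtype=float)
    y = 0.3 * x + 1.0 + rng.normal(0, 0.1, size=50)
    out = smooth_spline(make_set(y, x), p=1e-9).absorbance[0]
    beta = np.polyfit(x, y, 1)
    np.testing.assert_allclose(out, np.polyval(beta, x), atol=1e-4)


def test_spline_matches_penalized_least_squares_oracle():
    """p=0.01 fit of a noise-free Gaussian band agrees with an independent
    discrete penalized-least-squares solve (second-difference penalty)."""
    x = 4000.0 + 4.0 * np.arange(500)
    truth = 0.8 * np.exp(-0.5 * ((x - 5000.0) / 120.0) ** 2)
    p = 0.01
    lam = (1 - p) / p
    n, h = x.size, 4.0
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n)) / h**2
    oracle = spsolve((sparse.eye(n) + lam * h * (D.T @ D)).tocsc(), truth)
    ours = smooth_spline(make_set(truth, x), p=p).absorbance[0]
    assert np.abs(ours - oracle).max() < 1e-7
    assert np.abs(ours - truth).max() < 1e-4  # distortion at this roughness


def test_spline_rejects_bad_parameter(small_dataset):
    spectra, _, _ = small_dataset
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            smooth_spline(spectra, p=bad)


# ---------------------------------------------------------------------------
# MSC
# ---------------------------------------------------------------------------
def test_msc_inverts_affine_corruption(rng):
    ref = rng.normal(size=40)
    ss = make_set(np.vstack([2.0 * ref + 1.0, ref]))
    corrected, used_ref = msc(ss, reference=ref)
    np.testing.assert_allclose(corrected.absorbance[0], ref, atol=1e-12)
    np.testing.assert_allclose(corrected.absorbance[1], ref, atol=1e-12)
    np.testing.assert_array_equal(used_ref, ref)


def test_msc_idempotent_with_fixed_reference(rng):
    ss = make_set(rng.normal(size=(5, 30)) + np.linspace(0, 1, 30))
    once, ref = msc(ss)
    twice, _ = msc(once, reference=ref)
    np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-10)


def test_msc_zero_variance_reference_rejected(rng):
    ss = make_set(rng.normal(size=(3, 10)))
    with pytest.raises(ValueError, match="variance"):
        msc(ss, reference=np.ones(10))


def test_msc_recovers_common_shape_from_scatter():
    """Gain/offset-corrupted copies of one shape are restored by MSC."""
    x = np.linspace(0, 1, 80)
    shape = np.exp(-0.5 * ((x - 0.5) / 0.1) ** 2)
    rng = np.random.default_rng(0)
    rows = [g * shape + o for g, o in zip(rng.uniform(0.5, 2, 6), rng.uniform(-0.3, 0.3, 6))]
    corrected, _ = msc(make_set(rows))
    # every corrected row collapses onto the (affine-in-shape) reference
    assert np.abs(np.diff(corrected.absorbance, axis=0)).max() < 1e-9
    slope, intercept = np.polyfit(shape, corrected.absorbance[0], 1)
    resid = corrected.absorbance[0] - (slope * shape + intercept)
    assert np.abs(resid).max() < 1e-9


# ---------------------------------------------------------------------------
# SNV
# ---------------------------------------------------------------------------
def test_snv_reference_values_and_moments(rng):
    out = snv(make_set([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)
    rows = snv(make_set(rng.normal(size=(6, 40)))).absorbance
    np.testing.assert_allclose(rows.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(rows.std(axis=1, ddof=1), 1.0, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    a=st.floats(0.1, 50.0),
    b=st.floats(-10.0, 10.0),
)
def test_snv_affine_invariance(seed, a, b):
    x = np.random.default_rng(seed).normal(size=(2, 25))
    base = snv(make_set(x)).absorbance
    scaled = snv(make_set(a * x + b)).absorbance
    np.testing.assert_allclose(scaled, base, atol=1e-9)


def test_snv_constant_row_error_names_row():
    ss = make_set([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    with pytest.raises(ValueError, match="S1"):
        snv(ss)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------
def test_derivatives_exact_on_quadratic():
    ss = make_set([[1.0, 4.0, 9.0, 16.0]])  # f(t) = (t+1)^2 at h = 1
    d1 = derivative(ss, 1).absorbance[0]
    d2 = derivative(ss, 2).absorbance[0]
    np.testing.assert_allclose(d1[1:-1], [4.0, 6.0])
    np.testing.assert_allclose(d2, [2.0, 2.0, 2.0, 2.0])  # one-sided ends exact too


def test_derivative_of_constant_is_zero():
    ss = make_set([np.full(10, 3.3)])
    assert np.all(derivative(ss, 1).absorbance == 0.0)


def test_derivative_rejects_nonuniform_grid():
    ss = make_set([[1.0, 2.0, 3.0]], wavenumbers=np.array([0.0, 1.0, 3.0]))
    with pytest.raises(ValueError, match="uniform"):
        derivative(ss, 1)


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------
def test_minmax_endpoints_and_extension():
    X = np.array([[0.0], [5.0], [10.0]])
    spec = fit_normalizer(X, "minmax")
    np.testing.assert_allclose(apply_normalizer(X, spec).ravel(), [-1.0, 0.0, 1.0])
    outside = apply_normalizer(np.array([[12.0]]), spec)
    assert outside[0, 0] > 1.0  # affine extension, no clipping


def test_pareto_reference_value():
    X = np.array([[0.0], [2.0], [-2.0], [6.0], [4.0], [2.0]])
    spec = fit_normalizer(X, "pareto")
    mu, sd = spec.fitted_params["mean"][0], spec.fitted_params["sd"][0]
    got = apply_normalizer(np.array([[6.0]]), spec)[0, 0]
    np.testing.assert_allclose(got, (6.0 - mu) / np.sqrt(sd))


def test_normalizer_degenerate_columns_rejected():
    const = np.array([[1.0, 2.0], [1.0, 3.0]])
    with pytest.raises(ValueError, match="column 0"):
        fit_normalizer(const, "autoscale")
    with pytest.raises(ValueError, match="column 0"):
        fit_normalizer(const, "minmax")
    with pytest.raises(ValueError, match="column 0"):
        fit_normalizer(np.array([[-1.0], [0.0]]), "poisson")


def test_poisson_and_mean_center_definitions(rng):
    X = np.abs(rng.normal(size=(5, 3))) + 0.5
    np.testing.assert_allclose(
        apply_normalizer(X, fit_normalizer(X, "poisson")), X / np.sqrt(X.mean(axis=0))
    )
    np.testing.assert_allclose(
        apply_normalizer(X, fit_normalizer(X, "mean_center")), X - X.mean(axis=0)
    )


# ---------------------------------------------------------------------------
# chain invariants
# ---------------------------------------------------------------------------
def test_chain_parameters_depend_only_on_calibration_rows(small_dataset):
    spectra, _, _ = small_dataset
    cal = spectra.take_rows(range(10))
    chain1 = PreprocessChain(
        PreTreatmentSpec("msc"), NormalizationSpec("minmax")
    ).fit(cal)
    chain2 = PreprocessChain(
        PreTreatmentSpec("msc"), NormalizationSpec("minmax")
    ).fit(cal)
    np.testing.assert_array_equal(
        chain1.pretreatment.msc_reference, chain2.pretreatment.msc_reference
    )
    # transforming different prediction rows never changes fitted parameters
    chain1.transform(spectra.take_rows(range(10, 20)))
    chain1.transform(spectra.take_rows(range(20, 24)))
    np.testing.assert_array_equal(
        chain1.normalization.fitted_params["min"], chain2.normalization.fitted_params["min"]
    )
    back = PreprocessChain.from_dict(chain1.to_dict())
    np.testing.assert_array_equal(
        back.transform(spectra), chain1.transform(spectra)
    )


def test_scatter_free_rank_order_of_band_area_preserved():
    """Without scatter, SNV and MSC essentially preserve the inter-sample
    ordering of water-band area (rank correlation >= 0.99)."""
    cfg = GeneratorConfig(
        seed=3, scatter_gain_sd=0, scatter_offset_sd=0, noise_sd=0, n_replicates=1
    )
    spectra, _, _ = generate_dataset(cfg)
    grid = spectra.wavenumbers
    win = (grid > 1e7 / 1950) & (grid < 1e7 / 1850)
    raw = spectra.absorbance[:, win].sum(axis=1)
    for transformed in (snv(spectra), msc(spectra)[0]):
        area = transformed.absorbance[:, win].sum(axis=1)
        assert spearmanr(raw, area).statistic >= 0.99
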