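import numpy as np
import pytest

from rangestack import (
    DriverConfig,
    RasterGrid,
    build_driver_table,
    explained_deviance,
    fit_glm,
    fit_quasipoisson,
    read_driver_table,
    vif,
    vifstep,
    write_driver_table,
)
from rangestack.drivers import RankDeficiencyError, _design, p_stars
from rangestack.predictors import PREDICTOR_NAMES, assemble_stack
from rangestack.richness import RichnessMap
from rangestack.synthetic import make_glm_counts


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def newton_poisson_mle(y, X, iters=200, tol=1e-12):
    """Straight Newton-Raphson on the Poisson log-likelihood."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(np.mean(y) + 1e-9)
    for _ in range(iters):
        mu = np.exp(X @ beta)
        step = np.linalg.solve(X.T @ (X * mu[:, None]), X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def poisson_deviance(y, mu):
    """2 sum[y log(y/mu) - (y - mu)], with the y=0 limit."""
    y, mu = np.asarray(y, float), np.asarray(mu, float)
    term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


# ---------------------------------------------------------------------------
# quasi-Poisson fitting
# ---------------------------------------------------------------------------

def test_constant_predictor_is_rank_deficient():
    y = np.array([1, 2, 3, 4])
    X = np.column_stack([np.ones(4), np.full(4, 2.0)])
    with pytest.raises(RankDeficiencyError):
        fit_glm(y, X)


def test_negative_or_fractional_counts_rejected():
    X = np.column_stack([np.ones(4), np.arange(4.0)])
    with pytest.raises(ValueError):
        fit_glm(np.array([1.0, 2.5, 3.0, 4.0]), X)
    with pytest.raises(ValueError):
        fit_glm(np.array([1, -2, 3, 4]), X)


def test_slope_recovery_and_agreement_with_newton_oracle():
    rng = np.random.default_rng(100)
    n = 5000
    x = rng.uniform(0, 1, n)
    y = rng.poisson(np.exp(1.0 + 0.8 * x))
    fit = fit_quasipoisson(y, x, form="linear")
    assert abs(fit.coefficients[1] - 0.8) < 3 * fit.se[1]
    oracle = newton_poisson_mle(y.astype(float), _design(x, "linear"))
    assert np.max(np.abs(fit.coefficients - oracle)) < 1e-6


def test_dispersion_near_one_under_equidispersion():
    rng = np.random.default_rng(101)
    phis = []
    for _ in range(10):
        x = rng.uniform(0, 1, 2000)
        y = rng.poisson(np.exp(0.5 + 0.5 * x))
        phis.append(fit_quasipoisson(y, x).dispersion)
    assert np.mean(phis) == pytest.approx(1.0, abs=0.05)


def test_quasi_standard_errors_scale_with_sqrt_dispersion():
    rng = np.random.default_rng(102)
    x = rng.uniform(0, 1, 3000)
    # overdispersed counts: negative binomial via gamma-mixed Poisson
    mu = np.exp(1.0 + 0.5 * x)
    y = rng.poisson(mu * rng.gamma(2.0, 0.5, size=3000))
    fit = fit_quasipoisson(y, x)
    assert fit.dispersion > 1.2
    poisson_se = fit.se / np.sqrt(fit.dispersion)
    assert np.allclose(fit.se, poisson_se * np.sqrt(fit.dispersion))


def test_quadratic_form_reports_both_terms():
    rng = np.random.default_rng(103)
    x = rng.uniform(-1, 1, 4000)
    y = rng.poisson(np.exp(1.0 + 0.3 * x - 0.5 * x**2))
    fit = fit_quasipoisson(y, x, form="quadratic")
    assert fit.coefficients.shape == (3,)
    assert fit.coefficients[2] == pytest.approx(-0.5, abs=0.1)
    assert fit.coefficients[1] == pytest.approx(0.3, abs=0.1)


# ---------------------------------------------------------------------------
# explained deviance
# ---------------------------------------------------------------------------

def test_intercept_only_model_explains_nothing():
    rng = np.random.default_rng(104)
    y = rng.poisson(5.0, 500)
    fit = fit_glm(y, np.ones((500, 1)))
    d2, _ = explained_deviance(fit)
    assert d2 == pytest.approx(0.0, abs=1e-12)


def test_toy_deviance_ratio_matches_closed_form():
    y = np.array([1, 2, 3, 4], dtype=float)
    x = np.array([1, 2, 3, 4], dtype=float)
    fit = fit_quasipoisson(y, x)
    beta = newton_poisson_mle(y, _design(x, "linear"))
    mu_hat = np.exp(_design(x, "linear") @ beta)
    d2_oracle = 1.0 - poisson_deviance(y, mu_hat) / poisson_deviance(
        y, np.full(4, y.mean())
    )
    assert fit.d2 == pytest.approx(d2_oracle, abs=1e-8)
    assert fit.d2_adjusted == pytest.approx(
        1.0 - (3.0 / 2.0) * (1.0 - d2_oracle), abs=1e-8
    )


def test_unrelated_predictor_explains_almost_nothing():
    rng = np.random.default_rng(105)
    y = rng.poisson(4.0, 5000)
    x = rng.normal(size=5000)
    fit = fit_quasipoisson(y, x)
    assert fit.d2 < 0.01


def test_degenerate_constant_response_rejected():
    fit = fit_glm(np.full(10, 3), np.ones((10, 1)))
    with pytest.raises(ValueError, match="degenerate"):
        fit.d2


def test_full_model_deviance_dominates_single_predictors():
    rng = np.random.default_rng(106)
    X = rng.normal(size=(2000, 3))
    y = rng.poisson(np.exp(1.0 + 0.4 * X[:, 0] - 0.2 * X[:, 1]))
    full = fit_glm(y, np.column_stack([np.ones(2000), X]))
    for j in range(3):
        single = fit_quasipoisson(y, X[:, j])
        assert full.d2 >= single.d2 - 1e-12


def test_significance_stars_cutpoints():
    assert p_stars(0.5) == ""
    assert p_stars(2.0) == "*"      # p ~ 0.0455
    assert p_stars(2.7) == "**"     # p ~ 0.0069
    assert p_stars(4.0) == "***"


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def orthonormal_pair(n=100, seed=0):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=n), rng.normal(size=n)
    ones = np.ones(n) / np.sqrt(n)
    a -= (a @ ones) * ones
    a /= np.linalg.norm(a)
    b -= (b @ ones) * ones
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, b


def test_orthogonal_columns_have_unit_vif():
    a, b = orthonormal_pair()
    assert np.allclose(vif(np.column_stack([a, b])), 1.0, atol=1e-10)


def test_vif_closed_form_at_correlation_0_6():
    a, z = orthonormal_pair(seed=1)
    b = 0.6 * a + np.sqrt(1 - 0.36) * z
    out = vif(np.column_stack([a, b]))
    assert np.max(np.abs(out - 1.5625)) < 1e-9


def test_exact_collinearity_flagged_infinite():
    a, b = orthonormal_pair(seed=2)
    X = np.column_stack([a, b, a + b])
    assert np.isinf(vif(X)[2])


def test_vif_invariant_to_affine_rescaling():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(200, 4))
    X[:, 1] = 0.5 * X[:, 0] + rng.normal(size=200)
    base = vif(X)
    X2 = X.copy()
    X2[:, 1] = 7.0 * X2[:, 1] - 100.0
    assert np.allclose(vif(X2), base)


def test_vifstep_keeps_everything_below_threshold():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(300, 4))
    report = vifstep(X, threshold=10.0, names=list("abcd"))
    assert report.removal_sequence == []
    assert report.retained == list("abcd")
    assert all(v <= 10.0 for v in report.vifs.values())


def test_vifstep_removes_exactly_one_of_a_duplicate_pair():
    rng = np.random.default_rng(22)
    X = rng.normal(size=(300, 3))
    X = np.column_stack([X, X[:, 0]])  # duplicate of column 0
    report = vifstep(X, threshold=10.0, names=list("abcd"))
    assert len(report.removal_sequence) == 1
    assert report.removal_sequence[0] in {"a", "d"}
    assert len(report.retained) == 3


def test_vifstep_matches_independent_greedy_oracle():
    import statsmodels.api as sm

    def oracle_vifstep(X, names, threshold):
        X = X.copy()
        names = list(names)
        while X.shape[1] > 1:
            vals = []
            for j in range(X.shape[1]):
                others = sm.add_constant(np.delete(X, j, axis=1))
                r2 = sm.OLS(X[:, j], others).fit().rsquared
                vals.append(np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2))
            worst = int(np.argmax(vals))
            if vals[worst] <= threshold:
                break
            X = np.delete(X, worst, axis=1)
            names.pop(worst)
        return names

    rng = np.random.default_rng(23)
    for trial in range(5):
        Z = rng.normal(size=(200, 3))
        X = np.column_stack(
            [Z,
             Z[:, 0] + 0.1 * rng.normal(size=200),
             Z[:, 1] - Z[:, 2] + 0.05 * rng.normal(size=200)]
        )
        names = list("abcde")
        ours = vifstep(X, threshold=5.0, names=names)
        assert ours.retained == oracle_vifstep(X, names, 5.0), f"trial {trial}"


# ---------------------------------------------------------------------------
# driver table
# ---------------------------------------------------------------------------

def random_stack(seed=0, shape=(40, 40)):
    rng = np.random.default_rng(seed)
    grid = RasterGrid(np.zeros(shape), 0.0, float(shape[0]), 1.0)
    return assemble_stack(
        {name: grid.copy_with(rng.normal(size=shape)) for name in PREDICTOR_NAMES}
    )


def counts_to_map(counts, group="all"):
    return RichnessMap(group=group, raster=counts, n_species=int(counts.values.max()))


def test_generating_predictor_attains_top_d2():
    stack = random_stack(seed=30)
    beta = [1.5, 0.0, 0.0, 0.8, 0.0, 0.0, 0.0, 0.0]  # topo_heterogeneity dominant
    counts = make_glm_counts(stack, beta, seed=31)
    table = build_driver_table({"all": counts_to_map(counts)}, stack)
    assert table.top_predictor("all", "linear") == "topo_heterogeneity"


def test_row_count_is_groups_by_predictors_by_forms_plus_full():
    stack = random_stack(seed=32)
    counts = make_glm_counts(stack, [1.0, 0.3, 0, 0, 0, 0, 0, 0], seed=33)
    maps = {g: counts_to_map(counts, g) for g in ("all", "diurnal", "nocturnal")}
    table = build_driver_table(maps, stack)
    assert len(table.rows) == 3 * 7 * 2 + 3 * 2
    frame = table.to_frame()
    assert not frame.failed.any()
    combos = frame[frame.predictor != "full"].groupby(
        ["group", "predictor", "form"]
    ).size()
    assert (combos == 1).all()


def test_constant_predictor_row_marked_failed():
    stack = random_stack(seed=34)
    flat = stack.grid.copy_with(np.full(stack.grid.shape, 2.0))
    layers = dict(stack.layers)
    layers["uplift_age"] = flat
    stack2 = assemble_stack(layers)
    counts = make_glm_counts(stack, [1.0, 0.3, 0, 0, 0, 0, 0, 0], seed=35)
    table = build_driver_table(
        {"all": counts_to_map(counts)}, stack2, DriverConfig(standardize=False)
    )
    frame = table.to_frame()
    assert frame[frame.predictor == "uplift_age"].failed.all()
    assert not frame[frame.predictor == "temperature"].failed.any()


def test_driver_table_round_trips_through_csv(tmp_path):
    stack = random_stack(seed=36, shape=(25, 25))
    counts = make_glm_counts(stack, [1.0, 0.4, 0, 0, 0, 0, 0, 0], seed=37)
    table = build_driver_table({"all": counts_to_map(counts)}, stack)
    p = tmp_path / "drivers.csv"
    write_driver_table(table, p)
    back = read_driver_table(p)
    frame = table.to_frame()
    assert len(back) == len(frame) == 7 * 2 + 2
    assert np.allclose(back.D2.to_numpy(), frame.D2.to_numpy(), equal_nan=True)
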