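"""Residualization, partial correlation, mediation, and auxiliary procedures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cbfmed.config import CohortConfig
from cbfmed.mediation import (MediationAnalysis, baron_kenny,
                              bootstrap_mediation, exclude_outliers, mediate,
                              normalize_volume_icv, partial_correlation,
                              residualize, reverse_mediation_check, sobel_test,
                              stratified_residual_sensitivity)
from cbfmed.synthetic import generate_cohort


# ---------------------------------------------------------------------------
# residualization and partial correlation
# ---------------------------------------------------------------------------

def test_residualize_perfect_fit_gives_zero():
    z = np.arange(6.0)
    np.testing.assert_allclose(residualize(2 * z + 1, z), 0.0, atol=1e-12)


def test_residualize_sums_to_zero_and_matches_normal_equations(rng):
    y = rng.normal(size=6)
    Z = rng.normal(size=(6, 2))
    r = residualize(y, Z)
    assert abs(r.sum()) < 1e-10
    X = np.column_stack([np.ones(6), Z])
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent explicit solve
    np.testing.assert_allclose(r, y - X @ beta, atol=1e-10)


def test_residualize_orthogonal_covariate_returns_centered_values():
    y = np.array([1.0, -1.0, 2.0, -2.0])
    z = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to y, zero mean
    np.testing.assert_allclose(residualize(y, z), y - y.mean(), atol=1e-12)


def test_residualize_rank_deficiency_raises():
    z = np.ones(5)
    with pytest.raises(np.linalg.LinAlgError):
        residualize(np.arange(5.0), z)  # constant covariate duplicates intercept


def test_partial_correlation_identity():
    x = np.arange(10.0)
    z = np.array([0.1, -0.2, 0.3, 0.0, -0.1, 0.2, -0.3, 0.1, 0.0, -0.2])
    pc = partial_correlation(x, x + 0 * z, z)
    assert pc.r == pytest.approx(1.0)


def test_partial_correlation_matches_first_order_closed_form(rng):
    x = rng.normal(size=30)
    z = rng.normal(size=30)
    y = 0.5 * x + 0.3 * z + rng.normal(size=30)
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_zy = np.corrcoef(z, y)[0, 1]
    expected = (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz**2) * (1 - r_zy**2))
    pc = partial_correlation(x, y, z)
    assert pc.r == pytest.approx(expected, abs=1e-10)
    assert pc.df == 30 - 2 - 1


def test_partial_correlation_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    df = pd.DataFrame({"x": rng.normal(size=25), "y": rng.normal(size=25),
                       "z": rng.normal(size=25)})
    ours = partial_correlation(df["x"], df["y"], df["z"])
    ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
    assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
    assert ours.p_two_tailed == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


def test_partial_correlation_null_p_values_uniform():
    """Two-tailed p under independence is uniform (KS at alpha = 0.01)."""
    rng = np.random.default_rng(314)
    pvals = []
    for _ in range(400):
        x = rng.normal(size=41)
        y = rng.normal(size=41)
        z = rng.normal(size=41)
        pvals.append(partial_correlation(x, y, z).p_two_tailed)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_partial_correlation_validation(rng):
    with pytest.raises(ValueError):
        partial_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 0.0])
    x = rng.normal(size=10)
    with pytest.raises(ValueError, match="zero-variance"):
        partial_correlation(x, np.full(10, 3.0), rng.normal(size=10))
    with pytest.raises(ValueError):
        partial_correlation(x, x, rng.normal(size=10), alternative="sideways")


# ---------------------------------------------------------------------------
# Baron-Kenny, Sobel, bootstrap
# ---------------------------------------------------------------------------

def test_ols_mediation_identity_on_random_data(rng):
    """path_c == path_c_prime + a*b to numerical precision, any data."""
    for _ in range(20):
        n = int(rng.integers(8, 60))
        x = rng.normal(size=n)
        m = rng.normal(size=n) + 0.5 * x
        y = rng.normal(size=n) + 0.3 * m - 0.2 * x
        res = baron_kenny(x, m, y)
        assert abs(res.path_c - res.path_c_prime - res.indirect) < 1e-10


def test_baron_kenny_classifies_generative_full_mediation():
    cfg = CohortConfig(n_subjects=500, noise_sd_ecrf=1.0, noise_sd_cbf=4.0,
                       path_a=-0.08, path_b=2.24, path_c_prime=0.0)
    cohort = generate_cohort(cfg, seed=17)
    res = baron_kenny(cohort["age"], cohort["ecrf_true"], cohort["cbf_gray"])
    assert res.classification == "full"
    assert res.p_a < 0.05 and res.p_b < 0.05 and res.p_c < 0.05
    assert res.p_c_prime >= 0.05


def test_baron_kenny_classifies_null_a_path_as_none():
    cfg = CohortConfig(n_subjects=500, path_a=0.0)
    cohort = generate_cohort(cfg, seed=18)
    res = baron_kenny(cohort["age"], cohort["ecrf_true"], cohort["cbf_gray"])
    assert res.classification == "none"


def test_baron_kenny_classifies_partial_mediation():
    cfg = CohortConfig(n_subjects=800, noise_sd_ecrf=1.0, noise_sd_cbf=3.0,
                       path_a=-0.08, path_b=2.24, path_c_prime=-0.4)
    cohort = generate_cohort(cfg, seed=19)
    res = baron_kenny(cohort["age"], cohort["ecrf_true"], cohort["cbf_gray"])
    assert res.classification == "partial"


def test_baron_kenny_validation(rng):
    x = np.arange(10.0)
    with pytest.raises(np.linalg.LinAlgError):
        baron_kenny(x, 2 * x + 1, rng.normal(size=10))
    with pytest.raises(ValueError):
        baron_kenny(x[:4], x[:4] ** 2, x[:4])


@pytest.mark.parametrize("a, se_a, b, se_b, expected_z", [
    (0.0, 0.1, 1.0, 0.1, 0.0),                  # null numerator
    (1.0, 0.1, 1.0, 0.1, 1.0 / np.sqrt(0.02)),  # closed-form arithmetic
])
def test_sobel_values(a, se_a, b, se_b, expected_z):
    z, p = sobel_test(a, se_a, b, se_b)
    assert z == pytest.approx(expected_z, abs=1e-12)
    if expected_z == 0.0:
        assert p == 1.0


def test_sobel_symmetry_and_degenerate_convention():
    z1, _ = sobel_test(0.7, 0.2, -1.3, 0.4)
    z2, _ = sobel_test(-1.3, 0.4, 0.7, 0.2)
    assert z1 == pytest.approx(z2, rel=1e-12)
    assert sobel_test(0.0, 0.1, 0.0, 0.1) == (0.0, 1.0)
    with pytest.raises(ValueError):
        sobel_test(1.0, 0.0, 1.0, 0.1)


def test_bootstrap_deterministic_under_seed(cohort41):
    args = (cohort41["age"], cohort41["ecrf_true"], cohort41["cbf_gray"])
    ci1 = bootstrap_mediation(*args, n_resamples=500, seed=42)
    ci2 = bootstrap_mediation(*args, n_resamples=500, seed=42)
    assert (ci1.lo, ci1.hi) == (ci2.lo, ci2.hi)
    ci3 = bootstrap_mediation(*args, n_resamples=500, seed=43)
    assert (ci1.lo, ci1.hi) != (ci3.lo, ci3.hi)
    assert ci1.lo <= ci1.hi


def test_bootstrap_seed_variation_within_monte_carlo_error(cohort41):
    """CI endpoints at 10,000 resamples agree across seeds to quantile-theory MC SE."""
    args = (cohort41["age"], cohort41["ecrf_true"], cohort41["cbf_gray"])
    ci1 = bootstrap_mediation(*args, n_resamples=10_000, seed=1, keep_samples=True)
    ci2 = bootstrap_mediation(*args, n_resamples=10_000, seed=2)
    kde = stats.gaussian_kde(ci1.samples)
    for e1, e2, q in ((ci1.lo, ci2.lo, 0.025), (ci1.hi, ci2.hi, 0.975)):
        se = np.sqrt(q * (1 - q) / 10_000) / float(kde(e1)[0])
        assert abs(e1 - e2) < 4 * se


def test_bootstrap_point_estimate_and_coverage_low_noise():
    """Under low noise the point estimate equals the generative indirect
    effect and the percentile CI covers it."""
    cfg = CohortConfig(n_subjects=60, noise_sd_ecrf=0.1, noise_sd_cbf=0.1,
                       path_a=-0.08, path_b=2.0)
    cohort = generate_cohort(cfg, seed=4)
    ci = bootstrap_mediation(cohort["age"], cohort["ecrf_true"],
                             cohort["cbf_gray"], n_resamples=500, seed=0)
    res = baron_kenny(cohort["age"], cohort["ecrf_true"], cohort["cbf_gray"])
    assert ci.indirect == pytest.approx(res.indirect, rel=1e-10)
    assert ci.indirect == pytest.approx(-0.16, abs=0.02)
    assert ci.lo <= ci.indirect <= ci.hi
    assert ci.excludes_zero


def test_bootstrap_collinear_input_raises():
    x = np.arange(20.0)
    with pytest.raises(np.linalg.LinAlgError):
        bootstrap_mediation(x, 3 * x, x + 1.0, n_resamples=200, seed=0)


def test_bootstrap_validation(cohort41):
    with pytest.raises(ValueError):
        bootstrap_mediation(cohort41["age"], cohort41["ecrf_true"],
                            cohort41["cbf_gray"], n_resamples=10)


def test_closed_form_paths_match_statsmodels(rng):
    """The vectorized bootstrap core agrees with statsmodels OLS."""
    import statsmodels.api as sm
    from cbfmed.mediation import _paths_closed_form
    x = rng.normal(size=30)
    m = 0.5 * x + rng.normal(size=30)
    y = 2.0 * m - 0.3 * x + rng.normal(size=30)
    a, b, cp = _paths_closed_form(x[None], m[None], y[None])
    fit_a = sm.OLS(m, sm.add_constant(x)).fit()
    fit_bc = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()
    assert a[0] == pytest.approx(fit_a.params[1], rel=1e-10)
    assert cp[0] == pytest.approx(fit_bc.params[1], rel=1e-10)
    assert b[0] == pytest.approx(fit_bc.params[2], rel=1e-10)


def test_forward_significant_reverse_not(cohort41):
    """Generative age->eCRF->CBF with c'=0: forward CI excludes 0, reverse doesn't."""
    cfg = CohortConfig(n_subjects=500)
    cohort = generate_cohort(cfg, seed=23)
    fwd = bootstrap_mediation(cohort["age"], cohort["ecrf_true"],
                              cohort["cbf_gray"], n_resamples=1000, seed=0)
    rev = reverse_mediation_check(cohort["age"], cohort["ecrf_true"],
                                  cohort["cbf_gray"], n_resamples=1000, seed=0)
    assert fwd.excludes_zero
    assert not rev.excludes_zero


def test_reverse_check_is_role_swap(cohort41):
    a = reverse_mediation_check(cohort41["age"], cohort41["ecrf_true"],
                                cohort41["cbf_gray"], n_resamples=300, seed=9)
    b = bootstrap_mediation(cohort41["ecrf_true"], cohort41["age"],
                            cohort41["cbf_gray"], n_resamples=300, seed=9)
    assert (a.lo, a.hi) == (b.lo, b.hi)


def test_mediation_estimator_interface(cohort41):
    X = np.column_stack([cohort41["age"], cohort41["ecrf_true"]])
    est = MediationAnalysis(n_resamples=500, random_state=0)
    est.fit(X, cohort41["cbf_gray"])
    res = est.result_
    assert est.classification_ == res.classification
    assert res.bootstrap_ci is not None and res.bootstrap_ci[0] <= res.bootstrap_ci[1]
    assert abs(res.path_c - res.path_c_prime - res.indirect) < 1e-10
    assert est.get_params()["n_resamples"] == 500
    with pytest.raises(ValueError):
        est.fit(X[:, :1], cohort41["cbf_gray"])


# ---------------------------------------------------------------------------
# auxiliary procedures
# ---------------------------------------------------------------------------

def test_normalize_volume_icv_uncorrelated_unchanged():
    icv = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    vol = np.array([7.0, 7.0, 7.0, 7.0, 7.0])
    np.testing.assert_allclose(normalize_volume_icv(vol, icv), vol, atol=1e-12)


def test_normalize_volume_icv_perfect_dependence():
    icv = np.array([1.0e6, 1.2e6, 1.4e6, 1.6e6, 1.8e6])
    vol = 0.001 * icv
    adj = normalize_volume_icv(vol, icv)
    np.testing.assert_allclose(adj, vol.mean(), rtol=1e-10)


def test_normalize_volume_icv_matches_explicit_ols(rng):
    icv = rng.normal(1.45e6, 1e5, 5)
    vol = 0.002 * icv + rng.normal(0, 500.0, 5)
    adj = normalize_volume_icv(vol, icv)
    slope = np.polyfit(icv, vol, 1)[0]  # independent regression
    np.testing.assert_allclose(adj, vol - slope * (icv - icv.mean()), rtol=1e-10)
    assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-8


def test_normalize_volume_icv_zero_variance_warns():
    with pytest.warns(RuntimeWarning):
        out = normalize_volume_icv([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    np.testing.assert_array_equal(out, [1.0, 2.0, 3.0])


def test_exclude_outliers_rule():
    table = pd.DataFrame({
        "id": [f"s{i}" for i in range(41)],
        "cbf": np.r_[np.full(40, 50.0) + np.linspace(-1, 1, 40), 500.0],
    })
    kept, log = exclude_outliers(table, measures=["cbf"], threshold_sd=3.0)
    assert len(kept) == 40
    assert list(log["subject"]) == ["s40"]
    assert list(log["measure"]) == ["cbf"]


def test_exclude_outliers_vacuous_and_degenerate_cases():
    table = pd.DataFrame({"id": list("abc"), "m": [5.0, 5.0, 5.0]})
    with pytest.warns(RuntimeWarning):  # zero-SD column skipped
        kept, log = exclude_outliers(table, measures=["m"])
    assert len(kept) == 3 and log.empty
    table2 = pd.DataFrame({"id": list("abcd"), "m": [1.0, 2.0, 3.0, 100.0]})
    kept2, _ = exclude_outliers(table2, measures=["m"], threshold_sd=np.inf)
    assert len(kept2) == 4
    with pytest.raises(ValueError):
        exclude_outliers(table2, threshold_sd=0.0)


def test_stratified_sensitivity_recovers_within_stratum_slope():
    cfg = CohortConfig(n_subjects=400, noise_sd_cbf=4.0)
    cohort = generate_cohort(cfg, seed=31)
    out = stratified_residual_sensitivity(cohort, ["ecrf_true"],
                                          outcome="cbf_gray")
    row = out.iloc[0]
    assert row["r"] > 0
    assert row["p_two_tailed"] < 0.01


def test_stratified_sensitivity_null_measure_small_r():
    rng = np.random.default_rng(7)
    n = 400
    cohort = generate_cohort(CohortConfig(n_subjects=n), seed=32).copy()
    cohort["noise_measure"] = rng.normal(size=n)
    out = stratified_residual_sensitivity(cohort, ["noise_measure"],
                                          outcome="cbf_gray")
    assert abs(out["r"].iloc[0]) < 3 / np.sqrt(n)


def test_stratified_sensitivity_degenerate_outcome_raises():
    cohort = generate_cohort(CohortConfig(n_subjects=40), seed=33).copy()
    # outcome fully determined by stratum membership -> zero residuals
    strata = cohort["gender_code"] * 2 + (
        cohort.groupby("gender_code")["age"].transform(
            lambda a: (a > a.median()).astype(int)))
    cohort["cbf_gray"] = strata.map({0: 10.0, 1: 20.0, 2: 30.0, 3: 40.0})
    with pytest.raises(ValueError, match="zero variance"):
        stratified_residual_sensitivity(cohort, ["ecrf_true"], outcome="cbf_gray")


def test_stratified_sensitivity_validation():
    cohort = generate_cohort(CohortConfig(n_subjects=40), seed=34).copy()
    with pytest.raises(ValueError, match="n >= 8"):
        stratified_residual_sensitivity(cohort.head(5), ["ecrf_true"])
    single = cohort.copy()
    single["gender_code"] = 1
    with pytest.raises(ValueError, match="both genders"):
        stratified_residual_sensitivity(single, ["ecrf_true"])
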