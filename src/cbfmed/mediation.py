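"""Statistical chain: residualization, partial correlation, Baron-Kenny
mediation with Sobel test and percentile-bootstrap CI, reverse-mediation
check, ICV covariance normalization, outlier exclusion, and the stratified
residual sensitivity analysis.

Conventions
-----------
* Gender (or any covariate) is removed by residualization: each variable is
  regressed on the covariates (with intercept) and the residuals are used
  for all subsequent comparisons.  Partial correlation computed this way is
  algebraically equal to the closed-form partial-correlation formula.
* Mediation follows the three Baron-Kenny regressions
  (m ~ x, y ~ x, y ~ x + m), two-tailed tests throughout; the indirect
  effect a*b is tested by the Sobel z and by a percentile bootstrap over
  case resamples (subjects drawn with replacement).
* Classification: "full" mediation requires the Baron-Kenny pattern (a, b
  and the total effect significant, the direct effect not) AND, when a
  bootstrap CI is available, that the CI exclude 0; "partial" when the
  direct effect stays significant alongside a significant indirect effect;
  "none" otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "residualize",
    "PartialCorrelation",
    "partial_correlation",
    "MediationResult",
    "baron_kenny",
    "sobel_test",
    "BootstrapCI",
    "bootstrap_mediation",
    "reverse_mediation_check",
    "MediationAnalysis",
    "mediate",
    "normalize_volume_icv",
    "exclude_outliers",
    "stratified_residual_sensitivity",
]

logger = logging.getLogger(__name__)


def _as_1d(x, name="array") -> np.ndarray:
    out = np.asarray(x, dtype=float).ravel()
    if out.size == 0:
        raise ValueError(f"{name} is empty")
    return out


def residualize(values, covariates) -> np.ndarray:
    """Residuals of ``values`` after OLS on an intercept plus ``covariates``.

    ``covariates`` may be 1-D (single covariate) or (n, k).  Residuals sum
    to zero by construction.
    """
    y = _as_1d(values, "values")
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != y.size:
        raise ValueError("values and covariates must have equal length")
    X = np.column_stack([np.ones(y.size), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class PartialCorrelation:
    r: float
    df: int
    p_one_tailed: float
    p_two_tailed: float
    n: int


def partial_correlation(x, y, covariates, alternative: str = "two-sided"
                        ) -> PartialCorrelation:
    """Correlation of x and y after residualizing both on the covariates.

    The t test uses df = n - 2 - k (k = number of covariates).
    ``alternative`` selects the one-tailed direction ("greater"/"less") for
    ``p_one_tailed``; with "two-sided" the one-tailed p is reported in the
    direction of the observed correlation.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError("need n > k_covariates + 2")
    rx = residualize(x, Z)
    ry = residualize(y, Z)
    sx, sy = rx.std(), ry.std()
    # tolerance relative to the data scale: exact fits leave only round-off
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero-variance residuals: partial correlation undefined")
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
    p_two = float(2.0 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        p_one = float(stats.t.sf(t, df))
    elif alternative == "less":
        p_one = float(stats.t.cdf(t, df))
    elif alternative == "two-sided":
        p_one = p_two / 2.0
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return PartialCorrelation(r=r, df=df, p_one_tailed=p_one, p_two_tailed=p_two, n=n)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Coefficients of the three mediation regressions plus inference.

    Paths: a (mediator on predictor), c (total effect of predictor on
    outcome), b and c' (outcome on mediator and predictor jointly).
    ``path_c == path_c_prime + indirect`` holds to numerical precision.
    """

    path_a: float
    se_a: float
    p_a: float
    path_c: float
    se_c: float
    p_c: float
    path_b: float
    se_b: float
    p_b: float
    path_c_prime: float
    se_c_prime: float
    p_c_prime: float
    indirect: float
    sobel_z: float
    sobel_p: float
    n: int
    alpha: float = 0.05
    bootstrap_ci: tuple[float, float] | None = None
    n_resamples: int = 0
    confidence: float | None = None
    classification: str = "none"
    labels: dict = field(default_factory=dict)

    def significance_label(self, p: float, marginal_alpha: float = 0.10) -> str:
        if p < self.alpha:
            return "significant"
        if p <= marginal_alpha:
            return "marginal"
        return "ns"


def _classify(res: MediationResult, alpha: float) -> str:
    prereq = res.p_a < alpha and res.p_c < alpha
    if not prereq:
        return "none"
    indirect_ok = res.p_b < alpha
    if res.bootstrap_ci is not None:
        lo, hi = res.bootstrap_ci
        indirect_ok = indirect_ok and (lo > 0 or hi < 0)
    if not indirect_ok:
        return "none"
    return "full" if res.p_c_prime >= alpha else "partial"


def baron_kenny(predictor, mediator, outcome, alpha: float = 0.05
                ) -> MediationResult:
    """The three Baron-Kenny OLS regressions with two-tailed tests.

    Returns a :class:`MediationResult` without bootstrap fields;
    classification uses the regression pattern only.
    """
    x = _as_1d(predictor, "predictor")
    m = _as_1d(mediator, "mediator")
    y = _as_1d(outcome, "outcome")
    if not (x.size == m.size == y.size):
        raise ValueError("predictor, mediator and outcome must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    if abs(np.corrcoef(x, m)[0, 1]) >= 1.0 - 1e-12:
        raise np.linalg.LinAlgError("predictor and mediator are collinear")

    Xx = sm.add_constant(x)
    fit_a = sm.OLS(m, Xx).fit()
    fit_c = sm.OLS(y, Xx).fit()
    Xxm = sm.add_constant(np.column_stack([x, m]))
    fit_bc = sm.OLS(y, Xxm).fit()

    res = MediationResult(
        path_a=float(fit_a.params[1]), se_a=float(fit_a.bse[1]),
        p_a=float(fit_a.pvalues[1]),
        path_c=float(fit_c.params[1]), se_c=float(fit_c.bse[1]),
        p_c=float(fit_c.pvalues[1]),
        path_b=float(fit_bc.params[2]), se_b=float(fit_bc.bse[2]),
        p_b=float(fit_bc.pvalues[2]),
        path_c_prime=float(fit_bc.params[1]), se_c_prime=float(fit_bc.bse[1]),
        p_c_prime=float(fit_bc.pvalues[1]),
        indirect=float(fit_a.params[1] * fit_bc.params[2]),
        sobel_z=0.0, sobel_p=1.0, n=n, alpha=alpha,
    )
    res.sobel_z, res.sobel_p = sobel_test(res.path_a, res.se_a, res.path_b, res.se_b)
    res.classification = _classify(res, alpha)
    res.labels = {
        "a": res.significance_label(res.p_a),
        "b": res.significance_label(res.p_b),
        "c": res.significance_label(res.p_c),
        "c_prime": res.significance_label(res.p_c_prime),
    }
    return res


def sobel_test(path_a: float, se_a: float, path_b: float, se_b: float
               ) -> tuple[float, float]:
    """Sobel z for the indirect effect a*b with delta-method SE.

    z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2); two-tailed normal p.  When both
    paths are exactly zero the statistic is defined as z = 0, p = 1.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be > 0")
    denom = np.sqrt(path_b**2 * se_a**2 + path_a**2 * se_b**2)
    if denom == 0:
        return 0.0, 1.0
    z = float(path_a * path_b / denom)
    return z, float(2.0 * stats.norm.sf(abs(z)))


# -- vectorized closed-form two-predictor OLS for the bootstrap -------------

def _paths_closed_form(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """(a, b, c') for each row of (R, n) resample matrices; NaN if degenerate."""
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = np.sum(xc * xc, axis=-1)
    sxm = np.sum(xc * mc, axis=-1)
    smm = np.sum(mc * mc, axis=-1)
    sxy = np.sum(xc * yc, axis=-1)
    smy = np.sum(mc * yc, axis=-1)
    det = sxx * smm - sxm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(sxx > 0, sxm / np.where(sxx > 0, sxx, 1.0), np.nan)
        ok = det > 0
        safe = np.where(ok, det, 1.0)
        b = np.where(ok, (sxx * smy - sxm * sxy) / safe, np.nan)
        c_prime = np.where(ok, (smm * sxy - sxm * smy) / safe, np.nan)
    return a, b, c_prime


@dataclass
class BootstrapCI:
    lo: float
    hi: float
    indirect: float        # point estimate a*b on the original sample
    n_resamples: int
    confidence: float
    n_redrawn: int = 0
    samples: np.ndarray | None = None

    @property
    def excludes_zero(self) -> bool:
        return self.lo > 0 or self.hi < 0


def bootstrap_mediation(predictor, mediator, outcome, n_resamples: int = 10_000,
                        confidence: float = 0.95, seed=None,
                        keep_samples: bool = False) -> BootstrapCI:
    """Percentile-bootstrap CI of the indirect effect a*b.

    Subjects are resampled with replacement; a and b are re-estimated on
    each resample and the CI is formed from the percentiles of a*b.
    Degenerate resamples (zero predictor or mediator variance) are redrawn
    and counted.  Deterministic under a fixed seed.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    x = _as_1d(predictor, "predictor")
    m = _as_1d(mediator, "mediator")
    y = _as_1d(outcome, "outcome")
    if not (x.size == m.size == y.size):
        raise ValueError("inputs must have equal length")
    n = x.size
    rng = np.random.default_rng(seed)

    a0, b0, _ = _paths_closed_form(x[None, :], m[None, :], y[None, :])
    point = float(a0[0] * b0[0])
    if not np.isfinite(point):
        # every resample would inherit the degeneracy, so fail fast
        raise np.linalg.LinAlgError(
            "predictor and mediator are collinear (or constant): the "
            "two-predictor regression is unidentifiable")

    idx = rng.integers(0, n, size=(n_resamples, n))
    a, b, _ = _paths_closed_form(x[idx], m[idx], y[idx])
    ab = a * b
    n_redrawn = 0
    bad = ~np.isfinite(ab)
    while bad.any():
        n_redrawn += int(bad.sum())
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        a_r, b_r, _ = _paths_closed_form(x[redraw], m[redraw], y[redraw])
        ab[bad] = a_r * b_r
        bad = ~np.isfinite(ab)
    if n_redrawn:
        logger.info("bootstrap_mediation: %d degenerate resamples redrawn", n_redrawn)

    tail = (1.0 - confidence) / 2.0
    lo, hi = np.percentile(ab, [100 * tail, 100 * (1 - tail)])
    return BootstrapCI(lo=float(lo), hi=float(hi), indirect=point,
                       n_resamples=n_resamples, confidence=confidence,
                       n_redrawn=n_redrawn,
                       samples=ab if keep_samples else None)


def reverse_mediation_check(predictor, mediator, outcome, **kwargs) -> BootstrapCI:
    """Bootstrap CI with predictor and mediator roles exchanged.

    Tests the alternative model in which the nominal predictor is mediated
    by the nominal mediator's cause (e.g., age mediating a fitness effect
    instead of fitness mediating the age effect).
    """
    return bootstrap_mediation(mediator, predictor, outcome, **kwargs)


class MediationAnalysis(BaseEstimator):
    """Full mediation analysis as a scikit-learn style estimator.

    ``fit(X, y)`` takes ``X`` of shape (n, 2) with columns
    ``[predictor, mediator]`` (a 2-column DataFrame works) and the outcome
    ``y``; it runs the Baron-Kenny regressions, Sobel test, and (optionally)
    the percentile bootstrap, then classifies the mediation as
    "full"/"partial"/"none".

    Fitted attributes: ``path_a_``, ``path_b_``, ``path_c_``,
    ``path_c_prime_``, ``indirect_``, ``sobel_z_``, ``sobel_p_``,
    ``bootstrap_ci_``, ``classification_``, ``result_``.
    """

    def __init__(self, alpha: float = 0.05, bootstrap: bool = True,
                 n_resamples: int = 10_000, confidence: float = 0.95,
                 random_state=None):
        self.alpha = alpha
        self.bootstrap = bootstrap
        self.n_resamples = n_resamples
        self.confidence = confidence
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): [predictor, mediator]")
        x, m = X[:, 0], X[:, 1]
        y = _as_1d(y, "y")
        res = baron_kenny(x, m, y, alpha=self.alpha)
        if self.bootstrap:
            ci = bootstrap_mediation(x, m, y, n_resamples=self.n_resamples,
                                     confidence=self.confidence,
                                     seed=self.random_state)
            res.bootstrap_ci = (ci.lo, ci.hi)
            res.n_resamples = ci.n_resamples
            res.confidence = ci.confidence
        res.classification = _classify(res, self.alpha)
        self.result_ = res
        self.path_a_ = res.path_a
        self.path_b_ = res.path_b
        self.path_c_ = res.path_c
        self.path_c_prime_ = res.path_c_prime
        self.indirect_ = res.indirect
        self.sobel_z_ = res.sobel_z
        self.sobel_p_ = res.sobel_p
        self.bootstrap_ci_ = res.bootstrap_ci
        self.classification_ = res.classification
        self.n_features_in_ = 2
        return self


def mediate(predictor, mediator, outcome, **kwargs) -> MediationResult:
    """Convenience wrapper: Baron-Kenny + Sobel + bootstrap + classification."""
    X = np.column_stack([_as_1d(predictor), _as_1d(mediator)])
    return MediationAnalysis(**kwargs).fit(X, outcome).result_


# ---------------------------------------------------------------------------
# auxiliary procedures
# ---------------------------------------------------------------------------

def normalize_volume_icv(volumes, icv):
    """Covariance-approach normalization of regional volumes by ICV.

    adjusted_i = volume_i - slope * (icv_i - mean(icv)), with the slope from
    OLS of volume on ICV; the adjusted volumes are uncorrelated with ICV.
    """
    v = _as_1d(volumes, "volumes")
    icv = _as_1d(icv, "icv")
    if v.size != icv.size:
        raise ValueError("volumes and icv must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 subjects")
    icv_c = icv - icv.mean()
    denom = np.sum(icv_c**2)
    if denom == 0:
        warnings.warn("ICV has zero variance; volumes returned unchanged",
                      RuntimeWarning, stacklevel=2)
        return v.copy()
    slope = np.sum(icv_c * v) / denom
    return v - slope * icv_c


def exclude_outliers(table: pd.DataFrame, measures=None,
                     threshold_sd: float = 3.0, id_column: str = "id"
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects with any measure > ``threshold_sd`` SDs from its mean.

    A single pass: column means and SDs are computed on the full sample.
    Returns (retained table, exclusion log with subject, measure, value, z).
    Zero-SD columns are skipped with a warning.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be > 0")
    if measures is None:
        measures = [c for c in table.columns
                    if c != id_column and pd.api.types.is_numeric_dtype(table[c])]
    records = []
    drop = np.zeros(len(table), dtype=bool)
    for col in measures:
        values = table[col].to_numpy(dtype=float)
        sd = values.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"column {col!r} has zero/undefined SD; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        z = (values - values.mean()) / sd
        flag = np.abs(z) > threshold_sd
        for i in np.flatnonzero(flag):
            subject = table[id_column].iloc[i] if id_column in table.columns else i
            records.append({"subject": subject, "measure": col,
                            "value": values[i], "z": z[i]})
        drop |= flag
    log = pd.DataFrame(records, columns=["subject", "measure", "value", "z"])
    return table.loc[~drop].reset_index(drop=True), log


def stratified_residual_sensitivity(cohort: pd.DataFrame, measures,
                                    outcome: str = "cbf_gray",
                                    age_column: str = "age",
                                    gender_column: str = "gender_code"
                                    ) -> pd.DataFrame:
    """Gender x median-split-age stratified residual correlations.

    The sample is split by gender and, within gender, into younger/older
    halves at the median age.  Within each of the four strata the stratum
    mean is subtracted from each measure and from the outcome; the pooled
    residuals of each measure are then correlated with the pooled outcome
    residuals (removing gender and coarse age effects without regression).
    """
    if len(cohort) < 8:
        raise ValueError("need n >= 8")
    genders = sorted(cohort[gender_column].unique())
    if len(genders) < 2:
        raise ValueError("both genders must be present")

    strata = np.empty(len(cohort), dtype=int)
    for gi, g in enumerate(genders):
        sel = (cohort[gender_column] == g).to_numpy()
        ages = cohort.loc[sel, age_column].to_numpy(dtype=float)
        younger = ages <= np.median(ages)
        ids = np.flatnonzero(sel)
        strata[ids[younger]] = 2 * gi
        strata[ids[~younger]] = 2 * gi + 1
    counts = np.bincount(strata, minlength=4)
    if np.any(counts < 2):
        raise ValueError(f"stratum with fewer than 2 subjects (sizes {counts.tolist()})")

    def stratum_residuals(col: str) -> np.ndarray:
        values = cohort[col].to_numpy(dtype=float)
        out = values.copy()
        for s in np.unique(strata):
            out[strata == s] -= values[strata == s].mean()
        return out

    r_out = stratum_residuals(outcome)
    if r_out.std() == 0:
        raise ValueError("outcome residuals have zero variance: correlation undefined")
    rows = []
    for col in measures:
        r_meas = stratum_residuals(col)
        if r_meas.std() == 0:
            raise ValueError(f"measure {col!r} residuals have zero variance")
        r, p_two = stats.pearsonr(r_meas, r_out)
        rows.append({"measure": col, "r": float(r),
                     "p_two_tailed": float(p_two),
                     "p_one_tailed": float(p_two) / 2.0,
                     "n": len(cohort)})
    return pd.DataFrame(rows)
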