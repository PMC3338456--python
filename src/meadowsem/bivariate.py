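"""Exploratory bivariate regression suite.

Fractional logistic regression (quasi-likelihood logit for proportion
responses, with sandwich standard errors), linear/quadratic OLS with
Box-Cox remediation and AIC selection, Spearman rank correlation of
predicted vs. observed values, and a deviance-residual normality
summary. These are meadow-level exploratory fits; no mixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats


@dataclass
class FractionalLogitFit:
    """Quasi-likelihood logit fit for a proportion response in [0, 1]."""

    params: np.ndarray
    bse: np.ndarray  # sandwich (robust) standard errors
    pvalues: np.ndarray
    fitted: np.ndarray  # predicted means, in (0, 1)
    deviance_residuals: np.ndarray
    spearman_pred_obs: float
    converged: bool
    exog_names: list[str] = field(default_factory=list)
    diagnostic: str = ""


@dataclass
class LinearFit:
    """OLS fit of degree 1 or 2 selected by AIC, optionally Box-Cox transformed."""

    degree: int
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    aic: float
    aic_by_degree: dict[int, float]
    box_cox_lambda: float | None


def _fractional_deviance_residuals(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Deviance residuals for the Bernoulli quasi-likelihood with y in [0,1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    d2 = 2.0 * (t1 + t2)
    return np.sign(y - mu) * np.sqrt(np.maximum(d2, 0.0))


def fit_fractional_logit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    add_intercept: bool = True,
    cov_type: str = "HC1",
) -> FractionalLogitFit:
    """Fit a fractional logit by maximizing the Bernoulli quasi-log-likelihood.

    ``mu = expit(X @ beta)``; standard errors are heteroskedasticity-robust
    (sandwich), appropriate because the Bernoulli variance is misspecified
    for fractional responses. Perfect separation is reported through the
    ``converged`` flag and ``diagnostic`` field rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response values must lie in [0, 1]")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(y) > 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["const"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    converged = True
    diagnostic = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(cov_type=cov_type, maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise RuntimeError(f"fractional logit failed: {exc}") from exc
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            converged = False
            diagnostic = str(w.message)
    if not getattr(res, "converged", True):
        converged = False
        diagnostic = diagnostic or "IRLS did not converge"
    if np.any(np.abs(res.params) > 1e3):
        converged = False
        diagnostic = diagnostic or "divergent coefficients (possible perfect separation)"

    mu = np.clip(res.fittedvalues, 1e-12, 1 - 1e-12)
    dev_res = _fractional_deviance_residuals(y, mu)
    rho = spearman_rho(mu, y, warn_on_constant=False)
    return FractionalLogitFit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        fitted=mu,
        deviance_residuals=dev_res,
        spearman_pred_obs=rho,
        converged=converged,
        exog_names=names,
        diagnostic=diagnostic,
    )


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """(y^lam - 1)/lam for lam != 0, log(y) for lam == 0; requires y > 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive y")
    if abs(lam) < 1e-12:
        return np.log(y)
    return (y**lam - 1.0) / lam


def boxcox_profile_loglik(y: np.ndarray, X: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of the Box-Cox regression model at ``lam``.

    For fixed lam, OLS of the transformed response on X profiles out the
    coefficients and error variance; the Jacobian term (lam-1)*sum(log y)
    makes values comparable across lam.
    """
    z = boxcox_transform(y, lam)
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(np.sum((z - X @ beta) ** 2))
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * np.log(rss / n) + (lam - 1.0) * float(np.sum(np.log(y)))


def estimate_boxcox_lambda(
    y: np.ndarray, X: np.ndarray, bounds: tuple[float, float] = (-3.0, 3.0)
) -> float:
    """Maximize the Box-Cox profile log-likelihood over lam by bounded search."""
    res = optimize.minimize_scalar(
        lambda lam: -boxcox_profile_loglik(y, X, lam),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _ols_aic(y: np.ndarray, X: np.ndarray, jacobian: float = 0.0) -> tuple:
    res = sm.OLS(y, X).fit()
    n = len(y)
    rss = float(res.ssr)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * X.shape[1] - 2.0 * jacobian
    return res, aic


def fit_linear_aic(
    y: np.ndarray | pd.Series,
    x: np.ndarray | pd.Series,
    allow_quadratic: bool = True,
    box_cox: bool = False,
) -> LinearFit:
    """Fit degree-1 and (optionally) degree-2 OLS and select by AIC.

    AIC = n*ln(RSS/n) + 2k. With ``box_cox``, the response is first
    transformed at the profile-likelihood lambda estimated on the
    degree-1 design, and the Jacobian correction (lam-1)*sum(log y)
    enters the AIC so transformed fits stay comparable.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if box_cox and np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive y")

    X1 = np.column_stack([np.ones_like(x), x])
    lam = None
    jac = 0.0
    y_work = y
    if box_cox:
        lam = estimate_boxcox_lambda(y, X1)
        jac = (lam - 1.0) * float(np.sum(np.log(y)))
        y_work = boxcox_transform(y, lam)

    fits: dict[int, tuple] = {1: _ols_aic(y_work, X1, jac)}
    if allow_quadratic:
        X2 = np.column_stack([np.ones_like(x), x, x**2])
        fits[2] = _ols_aic(y_work, X2, jac)

    aics = {deg: a for deg, (_, a) in fits.items()}
    best = min(aics, key=aics.get)
    res = fits[best][0]
    return LinearFit(
        degree=best,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        r_squared=float(res.rsquared),
        aic=aics[best],
        aic_by_degree=aics,
        box_cox_lambda=lam,
    )


def spearman_rho(a, b, warn_on_constant: bool = True) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (with a warning) for constant input, where the
    correlation is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("inputs must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        if warn_on_constant:
            warnings.warn("constant input: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


@dataclass
class ResidualNormalitySummary:
    skewness: float
    kurtosis: float  # excess kurtosis
    statistic: float
    pvalue: float
    test: str
    degenerate: bool


def deviance_residual_normality(
    fit: FractionalLogitFit | np.ndarray,
) -> ResidualNormalitySummary:
    """Summarize deviance-residual normality (D'Agostino-Pearson omnibus).

    Reported for goodness-of-fit context only; never gates the pipeline.
    """
    resid = fit.deviance_residuals if isinstance(fit, FractionalLogitFit) else np.asarray(fit, float)
    if np.ptp(resid) == 0:
        return ResidualNormalitySummary(0.0, 0.0, float("nan"), float("nan"),
                                        "dagostino-pearson", True)
    skew = float(stats.skew(resid))
    kurt = float(stats.kurtosis(resid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.normaltest(resid)
    return ResidualNormalitySummary(skew, kurt, float(stat), float(p),
                                    "dagostino-pearson", False)


def bivariate_table(meadow_years: pd.DataFrame) -> pd.DataFrame:
    """Run the exploratory suite on a meadow-year table, meadow-averaged.

    Mirrors the exploratory stage: occupancy rate ~ wetness (fractional
    logit, plus a utilization and interaction check), utilization ~
    wetness, biomass ~ wetness, quality metrics ~ wetness, fecal ~
    utilization (OLS with AIC selection). Returns a tidy frame of
    model, term, estimate, se, p plus fit statistics.
    """
    g = meadow_years.groupby("meadow")
    df = pd.DataFrame(
        {
            "wetness": g["mean_score"].first(),
            "occ_rate": g["occupancy_rate"].mean(),
            "utilization": g["utilization_late"].mean(),
            "biomass": g["biomass_mid"].mean(),
            "cp": g["cp_late"].mean(),
            "tp": g["tp_late"].mean(),
            "adf": g["adf_late"].mean(),
            "fecal": g["fecal_density"].mean(),
        }
    )
    rows = []

    def add_frac(name, fit):
        for term, est, se, p in zip(fit.exog_names, fit.params, fit.bse, fit.pvalues):
            rows.append(
                {
                    "model": name, "kind": "fractional_logit", "term": term,
                    "estimate": est, "se": se, "p": p,
                    "rho_or_r2": fit.spearman_pred_obs,
                    "aic": np.nan, "box_cox_lambda": np.nan,
                    "degree": np.nan, "converged": fit.converged,
                }
            )

    fit = fit_fractional_logit(df["occ_rate"], df[["wetness"]])
    add_frac("occ_rate~wetness", fit)
    fit2 = fit_fractional_logit(df["occ_rate"], df[["wetness", "utilization"]])
    add_frac("occ_rate~wetness+utilization", fit2)
    inter = df[["wetness", "utilization"]].copy()
    inter["wetness_x_utilization"] = inter["wetness"] * inter["utilization"]
    fit3 = fit_fractional_logit(df["occ_rate"], inter)
    add_frac("occ_rate~wetness*utilization", fit3)

    linear_models = [
        ("utilization~wetness", "utilization", "wetness", False),
        ("biomass~wetness", "biomass", "wetness", True),
        ("cp~wetness", "cp", "wetness", False),
        ("tp~wetness", "tp", "wetness", False),
        ("adf~wetness", "adf", "wetness", False),
        ("fecal~utilization", "fecal", "utilization", False),
    ]
    for name, yc, xc, bc in linear_models:
        bc_ok = bc and bool(np.all(df[yc] > 0))
        lf = fit_linear_aic(df[yc], df[xc], allow_quadratic=True, box_cox=bc_ok)
        terms = ["const", xc] + (["I(%s^2)" % xc] if lf.degree == 2 else [])
        for term, est, se, p in zip(terms, lf.params, lf.bse, lf.pvalues):
            rows.append(
                {
                    "model": name, "kind": "ols", "term": term,
                    "estimate": est, "se": se, "p": p,
                    "rho_or_r2": lf.r_squared, "aic": lf.aic,
                    "box_cox_lambda": np.nan if lf.box_cox_lambda is None else lf.box_cox_lambda,
                    "degree": lf.degree, "converged": True,
                }
            )
    return pd.DataFrame(rows)
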