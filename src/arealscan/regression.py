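"""Univariate offset Poisson ecological regression.

Model: o_i ~ Poisson(r_i e_i), ln r_i = β0 + β1 x_i, fitted with the log
link and offset ln e_i so that exp(β) are rate ratios against the
sex/age-standardised expectation.  Covariates enter untransformed or as
quartile categories (lowest quartile = reference); the trend test over
quartiles refits with the integer scores 1–4 as a single covariate and
reports the Wald p of the score coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionFit", "fit_poisson", "quartile_encode", "trend_test", "read_covariates"]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RegressionFit:
    """Coefficients on the log-rate-ratio scale plus fit diagnostics."""

    covariate: str
    form: str  # "null" | "continuous" | "quartile"
    params: pd.Series
    se: pd.Series
    wald_p: pd.Series
    rate_ratio: pd.Series
    conf_int: pd.DataFrame  # exp scale, columns lo/hi
    residual_deviance: float
    aic: float
    loglik: float
    n_regions: int
    fitted: np.ndarray
    trend_p: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        """Table mirroring the usual ecological-regression report columns."""
        out = pd.DataFrame(
            {
                "exp_coef": self.rate_ratio,
                "ci_lo": self.conf_int["lo"],
                "ci_hi": self.conf_int["hi"],
                "wald_p": self.wald_p,
            }
        )
        out.attrs["residual_deviance"] = self.residual_deviance
        out.attrs["aic"] = self.aic
        out.attrs["trend_p"] = self.trend_p
        return out


def _poisson_deviance(o: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(o > 0, o * np.log(np.where(o > 0, o, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(t - (o - mu)))


def quartile_encode(x) -> np.ndarray:
    """Quartile category (1..4) per region; Q1 = lowest quartile.

    Cut points are the empirical 25/50/75 percentiles (linear interpolation
    on order statistics); ties sit in the lower category.  Rejects inputs
    whose ties leave a category empty.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct covariate values for quartiles")
    cuts = np.percentile(x, [25, 50, 75])
    cat = 1 + (x > cuts[0]).astype(int) + (x > cuts[1]).astype(int) + (x > cuts[2]).astype(int)
    present = np.unique(cat)
    if present.size < 4:
        missing = sorted(set(range(1, 5)) - set(present.tolist()))
        raise ValueError(f"ties leave quartile categories empty: Q{missing}")
    return cat


def fit_poisson(o, e, x=None, form: str = "continuous", covariate: str = "x") -> RegressionFit:
    """Maximum-likelihood offset Poisson fit (IRLS via statsmodels GLM).

    ``form``: "null" (intercept only, x ignored), "continuous", or
    "quartile" (indicator coding with Q1 reference plus an integer-score
    trend test).
    """
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if (e <= 0).any():
        raise ValueError("expected counts must be positive for all regions entering the fit")
    n = o.size

    if form == "null" or x is None:
        X = pd.DataFrame({"intercept": np.ones(n)})
        form = "null"
    elif form == "continuous":
        X = pd.DataFrame({"intercept": np.ones(n), covariate: np.asarray(x, dtype=float)})
    elif form == "quartile":
        cat = quartile_encode(x)
        X = pd.DataFrame({"intercept": np.ones(n)})
        for q in (2, 3, 4):
            X[f"{covariate}_Q{q}"] = (cat == q).astype(float)
    else:
        raise ValueError(f"unknown form {form!r}")
    if n < X.shape[1]:
        raise ValueError("fewer regions than parameters")

    model = sm.GLM(o, X, family=sm.families.Poisson(), offset=np.log(e))
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations (covariate={covariate!r}, form={form!r}); "
            f"last deviance {res.deviance:.6g}"
        )

    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    wald_p = pd.Series(res.pvalues, index=X.columns)
    ci = pd.DataFrame(
        {"lo": np.exp(params - _Z975 * se), "hi": np.exp(params + _Z975 * se)}, index=X.columns
    )

    trend_p = None
    if form == "quartile":
        scores = quartile_encode(x).astype(float)
        Xt = pd.DataFrame({"intercept": np.ones(n), "score": scores})
        rt = sm.GLM(o, Xt, family=sm.families.Poisson(), offset=np.log(e)).fit(maxiter=100, tol=1e-8)
        if not rt.converged:
            raise RuntimeError("trend-score fit did not converge")
        trend_p = float(rt.pvalues["score"])

    return RegressionFit(
        covariate=covariate if form != "null" else "(null)",
        form=form,
        params=params,
        se=se,
        wald_p=wald_p,
        rate_ratio=np.exp(params),
        conf_int=ci,
        residual_deviance=_poisson_deviance(o, res.mu),
        aic=float(res.aic),
        loglik=float(res.llf),
        n_regions=n,
        fitted=np.asarray(res.mu),
        trend_p=trend_p,
    )


def trend_test(o, e, x) -> float:
    """P-for-trend across quartiles of x (integer-score Wald test)."""
    fit = fit_poisson(o, e, x, form="quartile")
    return float(fit.trend_p)


def read_covariates(path) -> pd.DataFrame:
    """Read ``covariates.csv`` (region_id + one column per indicator)."""
    df = pd.read_csv(path, dtype={"region_id": str})
    if "region_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'region_id'")
    if df["region_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate region_id")
    return df.set_index("region_id")
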