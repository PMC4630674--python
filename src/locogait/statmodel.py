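"""Mixed-effects modeling of stride parameters.

Stride parameters vary systematically with walking speed and body size, with
substantial between-animal variability on top.  The workflow is: (1)
linearize each parameter's dependence on speed by picking the best of seven
candidate curve families; (2) fit a multilevel linear mixed-effects model of
the (transformed) parameter with fixed effects such as speed and weight and
a per-subject random intercept (optionally a random slope); (3) compare
candidate fixed-effect structures with likelihood-ratio tests on ML fits and
summarize explained variance with marginal / conditional R²; (4) predict a
parameter for a new mouse of given size and speed from the fixed effects,
back-transformed through the linearization.

The mixed-model machinery is statsmodels' ``MixedLM`` (maximum likelihood,
not REML, so that likelihood-ratio comparisons of fixed effects are valid).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "quadratic", "cubic", "inverse", "logarithmic",
            "exponential", "power")


# ---------------------------------------------------------------------------
# linearization families
# ---------------------------------------------------------------------------

def _design(family: str, v: np.ndarray) -> np.ndarray:
    if family == "linear":
        return np.column_stack([np.ones_like(v), v])
    if family == "quadratic":
        return np.column_stack([np.ones_like(v), v, v ** 2])
    if family == "cubic":
        return np.column_stack([np.ones_like(v), v, v ** 2, v ** 3])
    if family == "inverse":
        return np.column_stack([np.ones_like(v), 1.0 / v])
    if family == "logarithmic":
        return np.column_stack([np.ones_like(v), np.log(v)])
    raise ValueError(family)


@dataclass
class LinearizationFit:
    """A fitted speed-linearization: y ≈ family(v; coefficients)."""

    family: str
    coefficients: np.ndarray
    r_squared: float
    residual_normality_p: float
    ranking: list[tuple[str, float]] = field(default_factory=list)
    degenerate: bool = False

    def predict(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        c = self.coefficients
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * v)
        if self.family == "power":
            return c[0] * v ** c[1]
        return _design(self.family, v) @ c

    def transform(self, v: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map the response onto the scale where the family is linear in v
        (log for exponential/power; identity otherwise — polynomial and
        reciprocal families are already linear in their coefficients)."""
        if self.family in ("exponential", "power"):
            return np.log(y)
        return np.asarray(y, dtype=float)

    def back_transform(self, y_lin: np.ndarray) -> np.ndarray:
        if self.family in ("exponential", "power"):
            return np.exp(y_lin)
        return np.asarray(y_lin, dtype=float)

    def linear_predictor(self, v: np.ndarray) -> np.ndarray:
        """The speed regressor on the linearized scale (e.g. log v for the
        power family, 1/v for the inverse family)."""
        v = np.asarray(v, dtype=float)
        if self.family == "power":
            return np.log(v)
        if self.family == "inverse":
            return 1.0 / v
        if self.family == "logarithmic":
            return np.log(v)
        return v


def _fit_family(family: str, v: np.ndarray, y: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray] | None:
    """Least-squares fit of one family; returns (coef, fitted) or None when
    the family's domain excludes the data (non-positive values under
    log/power/inverse)."""
    if family in ("inverse", "logarithmic", "power") and np.any(v <= 0):
        return None
    if family in ("exponential", "power") and np.any(y <= 0):
        return None
    if family in ("exponential", "power"):
        from scipy.optimize import curve_fit

        # initialize from the log-space linear fit, then refine by
        # nonlinear least squares on the original scale
        if family == "exponential":
            reg = v
            func = lambda x, a, b: a * np.exp(b * x)        # noqa: E731
        else:
            reg = np.log(v)
            func = lambda x, a, b: a * x ** b               # noqa: E731
        design = np.column_stack([np.ones_like(reg), reg])
        c0, *_ = np.linalg.lstsq(design, np.log(y), rcond=None)
        p0 = (float(np.exp(c0[0])), float(c0[1]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coef, _ = curve_fit(func, v, y, p0=p0, maxfev=10000)
        except RuntimeError:
            coef = np.asarray(p0)
        fitted = func(v, *coef)
    else:
        design = _design(family, v)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
    return coef, fitted


def fit_linearization(speed: np.ndarray, values: np.ndarray) -> LinearizationFit:
    """Try all seven curve families against parameter-vs-speed data and keep
    the best fit, judged by goodness of fit (R², with a BIC parameter
    penalty so a cubic cannot win on spare parameters alone) and the
    residual-normality (Shapiro-Wilk) diagnostic; near-ties go to the
    simpler family.  The full R² ranking is returned alongside.

    Families whose domain excludes the data (e.g. a log fit with
    non-positive speeds) are skipped with a note.  Degenerate data on which
    all families tie at R² ≈ 0 returns the linear fit, flagged.
    """
    v = np.asarray(speed, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]
    if v.size < 10:
        raise ValueError("linearization needs at least 10 points")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    results: dict[str, tuple[np.ndarray, float, float]] = {}
    for family in FAMILIES:
        fit = _fit_family(family, v, y)
        if fit is None:
            logger.info("family %s skipped: domain excludes data", family)
            continue
        coef, fitted = fit
        resid = y - fitted
        sse = float(np.sum(resid ** 2))
        r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
        k = len(np.atleast_1d(coef))
        n_pts = len(y)
        bic = n_pts * np.log(max(sse / n_pts, 1e-300)) + k * np.log(n_pts)
        if resid.std() > 0 and 3 <= resid.size <= 5000:
            norm_p = float(stats.shapiro(resid).pvalue)
        else:
            norm_p = 1.0
        results[family] = (coef, r2, norm_p, bic)

    if not results:
        raise ValueError("no curve family applicable to the data")

    ranking = sorted(((f, r2) for f, (_, r2, _, _) in results.items()),
                     key=lambda t: -t[1])
    degenerate = ranking[0][1] <= 1e-9
    if degenerate and "linear" in results:
        best = "linear"
        logger.warning("all families tie at R²≈0: returning linear, flagged")
    else:
        # select by BIC so extra polynomial terms must earn their keep;
        # within 2 BIC points prefer the simpler (earlier-listed) family,
        # then better residual normality
        best_bic = min(bic for _, _, _, bic in results.values())
        near = [f for f, (_, _, _, bic) in results.items()
                if bic - best_bic <= 2.0]
        near.sort(key=lambda f: (FAMILIES.index(f), -results[f][2]))
        best = near[0]
    coef, r2, norm_p, _ = results[best]
    return LinearizationFit(family=best, coefficients=np.asarray(coef),
                            r_squared=r2, residual_normality_p=norm_p,
                            ranking=ranking, degenerate=degenerate)


# ---------------------------------------------------------------------------
# linear mixed-effects models
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """A fitted random-intercept (optionally random-slope) mixed model."""

    fixed_terms: list[str]
    coefficients: dict[str, float]
    coefficient_se: dict[str, float]
    random_intercept_var: float
    random_slope_var: float | None
    residual_var: float
    log_likelihood: float
    n_obs: int
    n_subjects: int
    fitted_fixed: np.ndarray           # fixed-effects-only predictions
    converged: bool = True

    @property
    def n_params(self) -> int:
        k = len(self.fixed_terms) + 1          # + intercept
        k += 2 if self.random_slope_var is not None else 1
        return k + 1                           # + residual variance

    def predict_fixed(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects-only) prediction."""
        out = np.full(len(data), self.coefficients["intercept"])
        for term in self.fixed_terms:
            out = out + self.coefficients[term] * data[term].to_numpy(dtype=float)
        return out


def fit_lmm(data: pd.DataFrame, response: str, fixed: list[str],
            group: str = "subject", random_slope: str | None = None) -> LmmFit:
    """Maximum-likelihood fit of a multilevel linear mixed-effects model.

    ``response ~ 1 + fixed... + (1 [+ random_slope] | group)``.  ML rather
    than REML so nested fits can be compared by likelihood ratio.

    Raises
    ------
    ValueError
        With fewer than 2 subjects (the random term is unidentifiable) or a
        singular fixed-effects design; the error names collinear columns.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = data.dropna(subset=[response, group] + list(fixed)).copy()
    groups = df[group].to_numpy()
    n_subjects = len(np.unique(groups))
    if n_subjects < 2:
        raise ValueError("mixed model needs >= 2 subjects for the random term")

    exog = np.column_stack(
        [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in fixed])
    names = ["intercept"] + list(fixed)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        corr = np.corrcoef(exog[:, 1:], rowvar=False) if len(fixed) > 1 else None
        collinear = []
        if corr is not None:
            for i in range(len(fixed)):
                for j in range(i + 1, len(fixed)):
                    if abs(corr[i, j]) > 0.999:
                        collinear.append((fixed[i], fixed[j]))
        raise ValueError(f"singular fixed-effects design; collinear terms: "
                         f"{collinear or names}")

    endog = df[response].to_numpy(dtype=float)
    if random_slope is not None:
        exog_re = np.column_stack([np.ones(len(df)),
                                   df[random_slope].to_numpy(dtype=float)])
    else:
        exog_re = np.ones((len(df), 1))

    model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    # optimizers can stall at the zero-variance boundary (a degenerate
    # solution with infinite reported likelihood); try several and keep the
    # best finite-likelihood fit
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("powell", "lbfgs", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if not np.isfinite(cand.llf):
                continue
            if result is None or cand.llf > result.llf + 1e-9:
                result = cand
    if result is None:
        raise RuntimeError("mixed-model fit failed to converge")

    fe = dict(zip(names, np.asarray(result.fe_params, dtype=float)))
    se = dict(zip(names, np.asarray(result.bse_fe, dtype=float)))
    cov_re = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
    scale = float(result.scale)
    return LmmFit(
        fixed_terms=list(fixed),
        coefficients=fe,
        coefficient_se=se,
        random_intercept_var=float(cov_re[0, 0]),
        random_slope_var=float(cov_re[1, 1]) if random_slope else None,
        residual_var=scale,
        log_likelihood=float(result.llf),
        n_obs=len(df),
        n_subjects=n_subjects,
        fitted_fixed=exog @ np.asarray(result.fe_params, dtype=float),
        converged=bool(result.converged),
    )


def likelihood_ratio_test(nested: LmmFit, full: LmmFit) -> dict[str, float]:
    """Likelihood-ratio comparison of two ML mixed-model fits.

    ``2 * (llf_full - llf_nested)`` referred to a chi-square with degrees of
    freedom equal to the parameter-count difference.  The nested model's
    fixed terms must be a subset of the full model's.
    """
    if not set(nested.fixed_terms) <= set(full.fixed_terms):
        raise ValueError("models are not nested (fixed terms not a subset)")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than nested model")
    statistic = max(2.0 * (full.log_likelihood - nested.log_likelihood), 0.0)
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(statistic, df))
    return {"statistic": float(statistic), "df": df, "p_value": p}


def r2_nakagawa(fit: LmmFit) -> tuple[float, float]:
    """Marginal and conditional R² for a mixed model.

    marginal = var_fixed / (var_fixed + var_random + var_residual);
    conditional adds the random-effect variance to the numerator.
    ``var_fixed`` is the variance of the fixed-effects predictions over the
    data; random-slope variance, if present, is included in var_random.
    """
    var_fixed = float(np.var(fit.fitted_fixed))
    var_random = fit.random_intercept_var + (fit.random_slope_var or 0.0)
    denom = var_fixed + var_random + fit.residual_var
    return var_fixed / denom, (var_fixed + var_random) / denom


def predict_param(lmm: LmmFit, speed: float | np.ndarray,
                  weight: float | np.ndarray | None = None,
                  linearization: LinearizationFit | None = None,
                  speed_range: tuple[float, float] | None = None,
                  weight_range: tuple[float, float] | None = None
                  ) -> np.ndarray:
    """Predict a stride parameter for a mouse of given weight at given speed.

    Uses the fixed effects only (population-level prediction), applying the
    linearization's speed transform on the way in and its back-transform on
    the way out.  Values outside the optional extrapolation guards produce a
    warning but are still returned.
    """
    speed = np.atleast_1d(np.asarray(speed, dtype=float))
    if speed_range is not None and (np.any(speed < speed_range[0])
                                    or np.any(speed > speed_range[1])):
        logger.warning("speed outside the fitted range %s: extrapolating",
                       speed_range)
    data = {"speed": linearization.linear_predictor(speed)
            if linearization is not None else speed}
    if weight is not None:
        w = np.broadcast_to(np.asarray(weight, dtype=float), speed.shape)
        if weight_range is not None and (np.any(w < weight_range[0])
                                         or np.any(w > weight_range[1])):
            logger.warning("weight outside the fitted range %s: extrapolating",
                           weight_range)
        data["weight"] = w
    df = pd.DataFrame(data)
    missing = [t for t in lmm.fixed_terms if t not in df]
    if missing:
        raise ValueError(f"prediction needs values for fixed terms: {missing}")
    pred = lmm.predict_fixed(df)
    if linearization is not None:
        pred = linearization.back_transform(pred)
    return pred
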