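"""Statistical layer: linear and mixed-effects fits, ICC, effect sizes.

Implements the analysis toolkit used around the inhibition estimates:
ordinary least-squares fits of inhibition duration on discharge rate with
R^2 = 1 - SS_res/SS_tot and a slope t-test; random-intercept /
random-intercept+slope linear mixed models (REML) with subject ICC and
likelihood-ratio comparison; one-way random-effects ICC(1,1) from ANOVA mean
squares (both the (k+1)-denominator variant printed in the source analysis
and the standard (k-1) form); Hedges' g on (n-1)-weighted pooled variance
with seeded bootstrap percentile intervals; and the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .model import InvalidSpecError

__all__ = [
    "LinearFit", "MixedModelFit", "EffectSize", "ModelComparison",
    "fit_linear", "classify_r2", "fit_mixed", "compare_mixed",
    "icc_oneway", "effect_contrast", "ks_compare",
    "R2_CLASS_BOUNDS", "EFFECT_BANDS",
]

#: lower bounds for strong / moderate / weak coefficients of determination
R2_CLASS_BOUNDS = {"strong": 0.67, "moderate": 0.33, "weak": 0.19}

#: |g| bounds for small / medium / large effects
EFFECT_BANDS = {"small": 0.20, "medium": 0.50, "large": 0.80}

SIGNIFICANCE_ALPHA = 0.05


class DegeneratePredictorError(ValueError):
    pass


class UndefinedEffectError(ValueError):
    pass


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    mse: float
    n: int
    residuals: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_ALPHA

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "p_value": self.p_value,
                "mse": self.mse, "n": self.n}


def fit_linear(x, y) -> LinearFit:
    """OLS of y on x; p-value from the slope t-test on n-2 df.

    MSE is the mean squared residual, sharing its numerator with R^2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise InvalidSpecError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant predictor")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    resid = np.asarray(res.resid)
    return LinearFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     r_squared=float(res.rsquared),
                     p_value=float(res.pvalues[1]),
                     mse=float(np.mean(resid ** 2)), n=int(x.size),
                     residuals=resid)


def classify_r2(r2: float) -> str:
    """strong (>=0.67), moderate (>=0.33), weak (>=0.19), else negligible."""
    if not 0.0 <= r2 <= 1.0:
        raise InvalidSpecError("R^2 outside [0, 1]")
    for label, bound in R2_CLASS_BOUNDS.items():
        if r2 >= bound:
            return label
    return "negligible"


# ---------------------------------------------------------------------------
# mixed models

@dataclass
class MixedModelFit:
    model_kind: str                 # "random-intercept" | "random-intercept-slope"
    beta0: float
    beta1: float
    beta0_ci: tuple[float, float]
    beta1_ci: tuple[float, float]
    intercept_sd: float
    slope_sd: float | None
    intercept_slope_corr: float | None
    residual_sd: float
    icc_subject: float
    r_squared_marginal: float
    r_squared_conditional: float
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    singular: bool
    method: str = "REML"
    converged: bool = True

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "model_kind", "beta0", "beta1", "intercept_sd", "slope_sd",
            "intercept_slope_corr", "residual_sd", "icc_subject",
            "r_squared_marginal", "r_squared_conditional", "log_likelihood",
            "aic", "bic", "n_obs", "n_groups", "singular", "method",
            "converged")}
        d["beta0_ci"] = list(self.beta0_ci)
        d["beta1_ci"] = list(self.beta1_ci)
        return d


class MixedFitError(RuntimeError):
    pass


# An overfitted random structure is flagged "singular" when the intercept-
# slope correlation sits at (or near) the +/-1 boundary, or when the random
# slope contributes negligibly to the residual scale.  REML optimisers stop
# near, not exactly at, the boundary, unlike fitlme's reported +/-1.
_SINGULAR_CORR = 0.9
_SINGULAR_SLOPE_FRAC = 0.01


def fit_mixed(data: pd.DataFrame, model_kind: str = "random-intercept",
              response: str = "duration", predictor: str = "rate",
              group: str = "subject") -> MixedModelFit:
    """REML linear mixed model of `response` on `predictor`.

    Model 1 (random-intercept): y_ik = b0 + b1*x_ik + u_k + e_ik.
    Model 2 (random-intercept-slope) adds a correlated random slope.
    ICC_subject = intercept variance / (intercept variance + residual
    variance); marginal/conditional R^2 follow the variance-partition
    definition (fixed / fixed+random over total).
    """
    df = pd.DataFrame({"y": data[response], "x": data[predictor],
                       "g": data[group]}).dropna()
    n_groups = df["g"].nunique()
    if n_groups < 3:
        raise InvalidSpecError("need at least 3 subjects")
    if model_kind not in ("random-intercept", "random-intercept-slope"):
        raise InvalidSpecError(f"unknown model kind {model_kind!r}")
    if model_kind == "random-intercept-slope":
        if (df.groupby("g").size() < 3).any():
            raise InvalidSpecError(
                "random-slope model needs >= 3 rows per subject")
        re_formula = "~x"
    else:
        re_formula = "~1"

    model = smf.mixedlm("y ~ x", df, groups=df["g"], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        except Exception as exc:  # pragma: no cover - rare numeric failures
            raise MixedFitError(f"mixed model failed to converge: {exc}")

    beta0, beta1 = float(res.params["Intercept"]), float(res.params["x"])
    ci = res.conf_int()
    cov_re = np.asarray(res.cov_re)
    var_int = float(cov_re[0, 0])
    resid_var = float(res.scale)
    if model_kind == "random-intercept-slope":
        var_slope = float(cov_re[1, 1])
        cov_is = float(cov_re[0, 1])
        denom = math.sqrt(max(var_int * var_slope, 0.0))
        corr = cov_is / denom if denom > 0 else 0.0
        x_var = float(np.var(df["x"]))
        slope_contrib = var_slope * x_var / resid_var if resid_var > 0 else 0.0
        singular = (abs(corr) >= _SINGULAR_CORR
                    or slope_contrib < _SINGULAR_SLOPE_FRAC
                    or var_int <= 1e-10)
    else:
        var_slope, corr, singular = None, None, var_int <= 1e-10

    icc = var_int / (var_int + resid_var) if var_int + resid_var > 0 else 0.0

    # variance-partition R^2: fixed-effect variance over total
    fixed_pred = beta0 + beta1 * df["x"].to_numpy()
    var_fixed = float(np.var(fixed_pred))
    var_random = var_int
    if model_kind == "random-intercept-slope":
        x = df["x"].to_numpy()
        var_random = float(var_int + 2 * cov_is * np.mean(x)
                           + var_slope * np.mean(x ** 2))
    total = var_fixed + var_random + resid_var
    r2_marg = var_fixed / total if total > 0 else 0.0
    r2_cond = (var_fixed + var_random) / total if total > 0 else 0.0

    k_fixed = 2
    k_var = 2 if model_kind == "random-intercept" else 4
    llf = float(res.llf)
    k = k_fixed + k_var
    n = len(df)
    return MixedModelFit(
        model_kind=model_kind, beta0=beta0, beta1=beta1,
        beta0_ci=(float(ci.loc["Intercept", 0]), float(ci.loc["Intercept", 1])),
        beta1_ci=(float(ci.loc["x", 0]), float(ci.loc["x", 1])),
        intercept_sd=math.sqrt(max(var_int, 0.0)),
        slope_sd=None if var_slope is None else math.sqrt(max(var_slope, 0.0)),
        intercept_slope_corr=corr,
        residual_sd=math.sqrt(max(resid_var, 0.0)),
        icc_subject=min(max(icc, 0.0), 1.0),
        r_squared_marginal=r2_marg, r_squared_conditional=r2_cond,
        log_likelihood=llf, aic=2 * k - 2 * llf,
        bic=k * math.log(n) - 2 * llf,
        n_obs=n, n_groups=n_groups, singular=bool(singular),
        converged=bool(res.converged))


@dataclass
class ModelComparison:
    lrt_statistic: float
    p_value: float
    df_diff: int
    aic: tuple[float, float]
    bic: tuple[float, float]
    log_likelihood: tuple[float, float]
    selected: str  # model_kind of the preferred model


def compare_mixed(m1: MixedModelFit, m2: MixedModelFit) -> ModelComparison:
    """Likelihood-ratio test of the random-intercept model against the
    random-intercept+slope model (same data, nested random structures).

    The richer model is selected only when it wins on AIC, BIC, log-
    likelihood and the LRT p-value is below 0.05; otherwise the simpler
    model is kept.
    """
    if (m1.model_kind, m2.model_kind) != ("random-intercept",
                                          "random-intercept-slope"):
        raise InvalidSpecError("compare_mixed expects (model 1, model 2)")
    if m1.n_obs != m2.n_obs or m1.n_groups != m2.n_groups:
        raise InvalidSpecError("models were fitted to different data")
    lrt = max(0.0, 2.0 * (m2.log_likelihood - m1.log_likelihood))
    df_diff = 2  # slope variance + intercept-slope covariance
    p = float(sps.chi2.sf(lrt, df_diff)) if lrt > 0 else 1.0
    better = (m2.aic < m1.aic and m2.bic < m1.bic
              and m2.log_likelihood > m1.log_likelihood
              and p < SIGNIFICANCE_ALPHA)
    return ModelComparison(lrt_statistic=lrt, p_value=p, df_diff=df_diff,
                           aic=(m1.aic, m2.aic), bic=(m1.bic, m2.bic),
                           log_likelihood=(m1.log_likelihood,
                                           m2.log_likelihood),
                           selected=m2.model_kind if better else m1.model_kind)


# ---------------------------------------------------------------------------
# one-way ICC and effect sizes

def icc_oneway(groups: dict[object, np.ndarray] | list[np.ndarray],
               variant: str = "printed") -> float:
    """One-way random-effects ICC(1,1) from ANOVA mean squares.

    variant "printed" uses (MSB - MSW) / (MSB + (k+1) * MSW) as printed in
    the source analysis; "standard" uses the usual (k-1) denominator.  k is
    the mean group size (a decision for unbalanced designs).  The raw value
    may be negative; reports clip to [0, 1] downstream.
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(v, float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, float) for v in groups]
    arrays = [a for a in arrays if a.size]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InvalidSpecError("need >= 2 groups with >= 2 members each")
    k = float(np.mean([a.size for a in arrays]))
    grand = np.concatenate(arrays).mean()
    n_groups = len(arrays)
    n_total = sum(a.size for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    msb = ss_between / (n_groups - 1)
    msw = ss_within / (n_total - n_groups)
    if variant == "printed":
        denom = msb + (k + 1) * msw
    elif variant == "standard":
        denom = msb + (k - 1) * msw
    else:
        raise InvalidSpecError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        return 0.0
    return float((msb - msw) / denom)


@dataclass
class EffectSize:
    hedges_g: float
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    hedges_g_ci: tuple[float, float]
    n_boot: int
    paired: bool

    @property
    def band(self) -> str:
        a = abs(self.hedges_g)
        if a >= EFFECT_BANDS["large"]:
            return "large"
        if a >= EFFECT_BANDS["medium"]:
            return "medium"
        if a >= EFFECT_BANDS["small"]:
            return "small"
        return "negligible"


def _hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / ((na - 1) + (nb - 1)))
    if pooled_var <= 0:
        raise UndefinedEffectError("zero pooled variance")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def effect_contrast(a, b, paired: bool = False, n_boot: int = 10_000,
                    seed: int = 0) -> EffectSize:
    """Hedges' g (a - b) with bootstrap percentile 95% CIs.

    The pooled SD weights each sample variance by (n-1), exactly the printed
    formula; bootstrapping resamples pairs when `paired` else each sample
    independently.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InvalidSpecError("empty sample")
    if paired and a.size != b.size:
        raise InvalidSpecError("paired contrast requires equal lengths")
    g = _hedges_g(a, b) if (a.var(ddof=1) + b.var(ddof=1)) > 0 else \
        _hedges_g(a, b)  # raises UndefinedEffectError on zero variance
    mean_diff = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    gs = np.empty(n_boot)
    for i in range(n_boot):
        if paired:
            idx = rng.integers(0, a.size, a.size)
            ra, rb = a[idx], b[idx]
        else:
            ra = a[rng.integers(0, a.size, a.size)]
            rb = b[rng.integers(0, b.size, b.size)]
        diffs[i] = ra.mean() - rb.mean()
        try:
            gs[i] = _hedges_g(ra, rb)
        except UndefinedEffectError:
            gs[i] = np.nan
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    glo, ghi = np.nanpercentile(gs, [2.5, 97.5])
    return EffectSize(hedges_g=g, mean_diff=mean_diff,
                      mean_diff_ci=(float(lo), float(hi)),
                      hedges_g_ci=(float(glo), float(ghi)),
                      n_boot=n_boot, paired=paired)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 5 or b.size < 5:
        raise InvalidSpecError("need >= 5 values per sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
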