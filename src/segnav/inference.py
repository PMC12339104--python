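"""Statistical machinery for the moderation analyses.

This module covers the full chain used to relate metabolic indices,
genotype and network segregation to navigation performance:

* power transformations of the dependent variable (Box-Cox for strictly
  positive responses, Yeo-Johnson otherwise), with the exponent chosen by
  profile maximum likelihood on a fixed grid;
* Z-scaling of continuous predictors;
* a *ladder* of nested linear mixed-effects models (participant random
  intercept, maximum likelihood) compared pairwise by likelihood-ratio
  tests;
* a variance-inflation-factor screen for multicollinearity;
* Holm-Bonferroni step-down control of the family-wise error rate for
  per-network model families;
* local standardized effect sizes: Cohen's f-squared for main effects and
  the t-statistic approximations delta (categorical x continuous) and rho
  (continuous x continuous) for interactions;
* bias-corrected and accelerated (BCa) bootstrap confidence intervals.

All ladder fits use maximum likelihood (not REML) so that likelihood-ratio
comparisons of fixed-effect structures are valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "box_cox",
    "yeo_johnson",
    "zscore",
    "ModelSpec",
    "ModelFit",
    "LRTResult",
    "fit_ladder",
    "MixedModelLadder",
    "vif_screen",
    "holm_bonferroni",
    "cohens_f2",
    "EffectSize",
    "bodner_effect",
    "bca_ci",
]

logger = logging.getLogger(__name__)

#: profile-likelihood grid for the power-transformation exponent
LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)


# ---------------------------------------------------------------------------
# variable transformations
# ---------------------------------------------------------------------------

def box_cox(y, lam: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox transform of strictly positive data.

    ``(y**lam - 1)/lam`` for ``lam != 0``, ``log(y)`` for ``lam == 0``.
    With ``lam=None`` the exponent maximising the profile log-likelihood
    over :data:`LAMBDA_GRID` is used.  Returns ``(transformed, lam)``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~(y > 0)):
        raise ValueError("Box-Cox requires strictly positive data")
    if lam is None:
        lls = [stats.boxcox_llf(l, y) for l in LAMBDA_GRID]
        lam = float(LAMBDA_GRID[int(np.argmax(lls))])
    lam = float(lam)
    # expm1 form is stable as lam -> 0
    out = np.log(y) if lam == 0.0 else np.expm1(lam * np.log(y)) / lam
    return out, lam


def box_cox_inverse(x, lam: float) -> np.ndarray:
    """Inverse Box-Cox; raises where the inverse leaves the positive domain."""
    x = np.asarray(x, dtype=float)
    if lam == 0.0:
        return np.exp(x)
    base = 1.0 + lam * x
    if np.any(base <= 0):
        raise ValueError("inverse Box-Cox undefined: 1 + lam*x <= 0")
    return np.power(base, 1.0 / lam)


def _yeo_johnson_transform(y: np.ndarray, lam: float) -> np.ndarray:
    pos = y >= 0
    out = np.empty_like(y)
    if lam != 0.0:  # expm1/log1p forms are stable near the branch exponents
        out[pos] = np.expm1(lam * np.log1p(y[pos])) / lam
    else:
        out[pos] = np.log1p(y[pos])
    if lam != 2.0:
        out[~pos] = -np.expm1((2.0 - lam) * np.log1p(-y[~pos])) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-y[~pos])
    return out


def yeo_johnson(y, lam: float | None = None) -> tuple[np.ndarray, float]:
    """Yeo-Johnson transform (handles mixed-sign data); grid profile ML for lam."""
    y = np.asarray(y, dtype=float)
    if lam is None:
        lls = [stats.yeojohnson_llf(l, y) for l in LAMBDA_GRID]
        lam = float(LAMBDA_GRID[int(np.argmax(lls))])
    return _yeo_johnson_transform(y, float(lam)), float(lam)


def zscore(x) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD); constant input is an error."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot Z-transform a constant variable")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# mixed-model ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One rung of a nested mixed-model ladder.

    ``fixed_terms`` and ``covariates`` are patsy term strings (e.g.
    ``"homa_ir*apoe*subtask"``); the model formula is their sum.  The
    random structure is a single random intercept per
    ``random_intercept_group`` and must be identical across a ladder.
    """

    dependent: str
    fixed_terms: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    random_intercept_group: str = "subject_id"
    ladder_position: int = 0

    def formula(self) -> str:
        rhs = list(self.fixed_terms) + list(self.covariates)
        return f"{self.dependent} ~ {' + '.join(rhs) if rhs else '1'}"


@dataclass
class ModelFit:
    """A fitted ladder rung (maximum likelihood, random intercept)."""

    spec: ModelSpec
    log_likelihood: float
    n_params: int          # fixed effects + variance components
    n_fixed: int
    coefficients: pd.Series
    std_errors: pd.Series
    tvalues: pd.Series
    df_resid: float
    converged: bool
    warnings: tuple[str, ...] = ()
    result: object = field(default=None, repr=False)  # statsmodels handle


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of a rung with the one below it."""

    full: int
    reduced: int
    statistic: float
    df: int
    p_value: float


def _design_columns(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    rhs = spec.formula().split("~", 1)[1]
    return list(patsy.dmatrix(rhs, data, return_type="dataframe").columns)


def _check_nested(specs: Sequence[ModelSpec], data: pd.DataFrame) -> None:
    cols = [set(_design_columns(s, data)) for s in specs]
    for k in range(1, len(specs)):
        if not cols[k - 1] <= cols[k]:
            extra = sorted(cols[k - 1] - cols[k])
            raise ValueError(
                f"ladder not nested: rung {k - 1} has columns {extra} "
                f"absent from rung {k}"
            )
        if specs[k].random_intercept_group != specs[0].random_intercept_group:
            raise ValueError("random structure must be identical across a ladder")


def _fit_one(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            spec.formula(), data, groups=data[spec.random_intercept_group]
        )
        try:
            res = model.fit(reml=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning(
                "rung %d: fit failed (%s: %s)", spec.ladder_position,
                type(exc).__name__, exc,
            )
            k = len(model.exog_names)
            nan = pd.Series(np.nan, index=model.exog_names)
            return ModelFit(
                spec=spec, log_likelihood=np.nan, n_params=k + 2, n_fixed=k,
                coefficients=nan, std_errors=nan, tvalues=nan,
                df_resid=float(len(data) - k), converged=False,
                warnings=(f"{type(exc).__name__}: {exc}",),
            )
        if not getattr(res, "converged", True):
            # gradient-based default occasionally stalls on weakly identified
            # subject-level designs; a derivative-free restart usually lands
            res = model.fit(reml=False, method="powell", maxiter=2000)
        captured = [str(w.message) for w in wrec]
    converged = bool(getattr(res, "converged", True)) and not any(
        "singular" in m.lower() for m in captured
    )
    if not converged:
        logger.warning("rung %d: degenerate fit (%s)", spec.ladder_position, captured)
    k_fe = res.k_fe
    return ModelFit(
        spec=spec,
        log_likelihood=float(res.llf),
        n_params=int(k_fe + res.k_re2 + 1),  # + residual variance
        n_fixed=int(k_fe),
        coefficients=res.fe_params,
        std_errors=res.bse_fe,
        tvalues=res.fe_params / res.bse_fe,
        df_resid=float(res.nobs - k_fe),
        converged=converged,
        warnings=tuple(captured),
        result=res,
    )


def fit_ladder(
    specs: Sequence[ModelSpec], data: pd.DataFrame
) -> tuple[list[ModelFit], list[LRTResult]]:
    """Fit a nested model ladder by ML and compare adjacent rungs by LRT.

    Each rung must nest the previous one (its fixed-effect design columns
    are a superset) with an identical random structure.  The LRT statistic
    is ``2*(LL_full - LL_reduced)`` on a chi-square with df equal to the
    fixed-parameter difference; a non-positive statistic (optimizer noise
    on identical designs) is clamped to zero.  Degenerate fits are
    reported with diagnostics and excluded from the LRT chain.
    """
    if not specs:
        raise ValueError("empty ladder")
    complete = data.dropna(
        subset=[c for c in data.columns if data[c].isna().any()]
    ) if data.isna().any().any() else data
    _check_nested(specs, complete)
    fits = [_fit_one(s, complete) for s in specs]
    lrts: list[LRTResult] = []
    for k in range(1, len(fits)):
        red, full = fits[k - 1], fits[k]
        if not (red.converged and full.converged):
            logger.warning("skipping LRT %d vs %d: degenerate fit", k, k - 1)
            continue
        df = full.n_fixed - red.n_fixed
        stat = max(0.0, 2.0 * (full.log_likelihood - red.log_likelihood))
        p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
        lrts.append(LRTResult(full=k, reduced=k - 1, statistic=stat, df=df, p_value=p))
    return fits, lrts


class MixedModelLadder(BaseEstimator):
    """Estimator wrapper around :func:`fit_ladder`.

    Parameters
    ----------
    specs
        Ordered nested :class:`ModelSpec` rungs.

    Attributes
    ----------
    fits_
        One :class:`ModelFit` per rung.
    lrt_
        DataFrame of adjacent-rung likelihood-ratio tests.
    """

    def __init__(self, specs: Sequence[ModelSpec] = ()):
        self.specs = specs

    def fit(self, X: pd.DataFrame, y=None):  # noqa: D102
        fits, lrts = fit_ladder(list(self.specs), X)
        self.fits_ = fits
        self.lrt_ = pd.DataFrame(
            [vars(r) for r in lrts],
            columns=["full", "reduced", "statistic", "df", "p_value"],
        )
        return self

    def summary_table(self) -> pd.DataFrame:
        """One row per rung: formula, log-likelihood, parameter count."""
        return pd.DataFrame(
            {
                "ladder_position": [f.spec.ladder_position for f in self.fits_],
                "formula": [f.spec.formula() for f in self.fits_],
                "log_likelihood": [f.log_likelihood for f in self.fits_],
                "n_params": [f.n_params for f in self.fits_],
                "converged": [f.converged for f in self.fits_],
            }
        )


# ---------------------------------------------------------------------------
# diagnostics and corrections
# ---------------------------------------------------------------------------

def vif_screen(design: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factor per design column.

    ``VIF_j = 1/(1 - R2_j)`` where ``R2_j`` comes from regressing column j
    (with intercept) on the remaining columns.  Exactly collinear columns
    report infinite VIF.  Columns with ``VIF > threshold`` are flagged —
    the signal that a pooled per-network model must be refit per network.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a design matrix with >= 2 columns")
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{j}" for j in range(X.shape[1])
    ]
    vifs = []
    for j in range(X.shape[1]):
        yj = X[:, j]
        others = np.column_stack(
            [np.ones(X.shape[0]), np.delete(X, j, axis=1)]
        )
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        if sst == 0:
            vifs.append(np.inf)  # constant column
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    out = pd.DataFrame({"term": names, "vif": vifs})
    out["flagged"] = out["vif"] > threshold
    return out


def holm_bonferroni(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down FWER correction.

    Returns ``(adjusted, reject)`` in the input order.  Adjusted p-values
    are the running maximum of ``min(1, (m - rank) * p)`` over increasing
    raw p, which makes them monotone in rank; rejection is adjusted <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(scaled)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Local effect size ``(R2_full - R2_reduced) / (1 - R2_full)``."""
    if not (0.0 <= r2_reduced <= r2_full):
        raise ValueError("need 0 <= r2_reduced <= r2_full")
    if r2_full >= 1.0:
        raise ValueError("r2_full must be < 1")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


# ---------------------------------------------------------------------------
# effect sizes for interactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """A standardized local effect with an optional BCa interval."""

    kind: str
    value: float
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 endpoints must be ordered")


def bodner_effect(
    fit: ModelFit, interaction_term: str, kind: str, df: float | None = None
) -> EffectSize:
    """Standardized interaction effect from the term's t statistic.

    ``delta = 2*t/sqrt(df)`` for a categorical x continuous interaction
    (a Cohen's-d-like difference between moderator-conditional slopes) and
    ``rho = t/sqrt(t^2 + df)`` for continuous x continuous (a partial-
    correlation-like magnitude).  Both are zero iff the interaction
    coefficient is zero and carry its sign.  ``df`` defaults to the fit's
    residual degrees of freedom.
    """
    if kind not in ("delta", "rho"):
        raise ValueError("kind must be 'delta' or 'rho'")
    if interaction_term not in fit.tvalues.index:
        raise KeyError(
            f"term {interaction_term!r} not in fit "
            f"(have {list(fit.tvalues.index)})"
        )
    t = float(fit.tvalues[interaction_term])
    df = float(fit.df_resid if df is None else df)
    if df <= 0:
        raise ValueError("df must be positive")
    value = 2.0 * t / np.sqrt(df) if kind == "delta" else t / np.sqrt(t * t + df)
    return EffectSize(kind=f"bodner_{kind}", value=float(value))


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def bca_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    The bias correction ``z0`` comes from the fraction of bootstrap
    replicates below the point estimate; the acceleration ``a`` from the
    jackknife skewness of the statistic.  A degenerate bootstrap
    distribution (all replicates equal) collapses the interval to a point
    and is logged.
    """
    if n_boot < 1000:
        raise ValueError("need at least 1000 bootstrap replicates")
    data = np.asarray(data)
    n = data.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta = float(statistic(data))
    if not np.isfinite(theta):
        raise ValueError("statistic is not finite on the data")
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.asarray([statistic(data[i]) for i in idx], dtype=float)
    if np.ptp(boot) == 0.0:
        logger.warning("degenerate bootstrap distribution; interval collapses")
        return theta, theta
    # bias correction
    prop = np.mean(boot < theta)
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1.0 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)
    # acceleration from the jackknife
    jack = np.asarray(
        [statistic(np.delete(data, i, axis=0)) for i in range(n)], dtype=float
    )
    d = jack.mean() - jack
    denom = 6.0 * np.sum(d**2) ** 1.5
    a = 0.0 if denom == 0 else float(np.sum(d**3) / denom)
    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for q in (alpha, 1.0 - alpha):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        lo_hi.append(float(np.quantile(boot, adj)))
    return lo_hi[0], lo_hi[1]
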