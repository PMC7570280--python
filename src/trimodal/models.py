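"""Regression modelling of the recording outcomes.

Fits and selects models relating the two recording outcomes to the
weekly behavior covariates and the time-constant endpoint histology
covariates at one distance bin:

* units per channel (Y1, channel-level counts, n = 480 by default):
  linear mixed-effects on log(y + 0.5), or Poisson / negative-binomial
  GLM on the counts;
* percent channels active (Y2, animal-week level, n = 48): linear
  mixed-effects on a boundary-safe logit of the proportion, or a
  binomial GLM on the active-channel counts.

Selection is a BIC-type penalized exhaustive best-subset search — the
penalty charges log(n) per nonzero fixed coefficient and per unique
nonzero element of the random-effects covariance — refined by
log-likelihood-ratio tests among nested candidates, with AIC reported
alongside. The candidate covariate pool is small enough (<= 8 terms)
that exhaustive search replaces a coordinate-descent LASSO path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assembly import AnalysisTables, regression_frame

NONZERO_TOL = 1e-8
LRT_ALPHA = 0.05

#: Table-style covariate pools per distance bin (term -> design column)
COVARIATE_POOLS = {
    "0-50": ("time", "ladder_time", "ladder_right_slips",
             "ladder_left_slips", "grid_max_velocity",
             "bbb_permeability", "microglia", "astrocyte"),
    "50-100": ("time", "ladder_time", "ladder_right_slips",
               "ladder_left_slips", "grid_max_velocity",
               "bbb_permeability", "neuron_density"),
}

FAMILIES = ("lme", "glm_poisson", "glm_nb", "glm_binomial")
RANDOM_STRUCTURES = ("none", "intercept", "intercept_slope")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str                  # "units_per_channel" | "pct_channels_active"
    distance_bin: str             # "0-50" | "50-100"
    family: str                   # lme | glm_poisson | glm_nb | glm_binomial
    fixed_terms: tuple[str, ...]  # besides the always-present intercept
    random: str = "none"          # none | intercept | intercept_slope

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.random not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown random structure {self.random!r}")
        if self.random != "none" and self.family != "lme":
            raise ValueError("random effects are only supported for the "
                             "LME family")


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_re: np.ndarray | None
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    conditional_r2: float

    @property
    def k_params(self) -> int:
        k = len(self.coefficients)
        if self.spec.family == "lme":
            k += 1  # residual variance
            if self.spec.random == "intercept":
                k += 1
            elif self.spec.random == "intercept_slope":
                k += 3
        elif self.spec.family == "glm_nb":
            k += 1  # dispersion
        return k


# ---------------------------------------------------------------------------
# Outcome transforms
# ---------------------------------------------------------------------------


def transform_outcome(y, family: str, n_channels: int = 10):
    """Outcome scale used by the LME family.

    Y2 (a percent in [0, 100]) maps through a boundary-safe squeeze to
    ``logit((p (N - 1) + 0.5) / N)`` with ``p = y/100`` and ``N`` the
    number of kept channels; Y1 (a count) maps to ``log(y + 0.5)``. GLM
    families model the raw count/proportion with the canonical link and
    take no pre-transform.
    """
    y = np.asarray(y, dtype=float)
    if family == "pct":
        if np.any((y < 0) | (y > 100)):
            raise ValueError("percent outcome must lie in [0, 100]")
        p = y / 100.0
        q = (p * (n_channels - 1) + 0.5) / n_channels
        return np.log(q / (1 - q))
    if family == "count":
        if np.any(y < 0):
            raise ValueError("count outcome must be nonnegative")
        return np.log(y + 0.5)
    raise ValueError(f"unknown outcome kind {family!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _design(spec: ModelSpec, tables: AnalysisTables,
            standardize: bool = True) -> pd.DataFrame:
    level = "channel" if spec.outcome == "units_per_channel" else "animal"
    df = regression_frame(tables, spec.distance_bin, level=level)
    pool = COVARIATE_POOLS[spec.distance_bin]
    cols = ["animal_id", "y", "time"] + [c for c in pool if c != "time"]
    df = df[cols].dropna().reset_index(drop=True)
    if standardize:
        for c in pool:
            s = df[c].std()
            if s > 0:
                df[c] = (df[c] - df[c].mean()) / s
    return df


def fit(spec: ModelSpec, tables: AnalysisTables,
        standardize: bool = True,
        df: pd.DataFrame | None = None) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Longitudinal rows are not treated as independent when random terms
    are present: the animal is the grouping unit. Histology covariates
    enter as time-constant per-animal baselines; covariates are
    standardized by default (grip force always would be — its scale
    dwarfs the others).
    """
    if df is None:
        df = _design(spec, tables, standardize=standardize)
    if df.animal_id.nunique() < 2:
        raise ValueError("need at least 2 animals")
    terms = list(spec.fixed_terms)
    X = sm.add_constant(df[terms], has_constant="add") if terms else \
        pd.DataFrame({"const": np.ones(len(df))})
    _check_rank(X)
    y_raw = df.y.to_numpy(dtype=float)
    n_keep = tables.config.n_keep

    if spec.family == "lme":
        kind = ("count" if spec.outcome == "units_per_channel" else "pct")
        y = transform_outcome(y_raw, kind, n_channels=n_keep)
        if spec.random == "none":
            res = sm.OLS(y, X).fit()
            ll = float(res.llf)
            k = X.shape[1] + 1
            cov_re = None
            resid_var = float(res.scale)
            re_var = 0.0
        else:
            exog_re = (np.ones((len(df), 1)) if spec.random == "intercept"
                       else np.column_stack([np.ones(len(df)),
                                             df.time.to_numpy(float)]))
            res = _fit_mixedlm(y, X, df.animal_id.to_numpy(), exog_re)
            ll = float(res.llf)
            cov_re = np.atleast_2d(np.asarray(res.cov_re))
            k = X.shape[1] + 1 + (1 if spec.random == "intercept" else 3)
            resid_var = float(res.scale)
            re_var = float(cov_re[0, 0]) if spec.random == "intercept" else \
                float(cov_re[0, 0] + cov_re[1, 1])
        params = pd.Series(np.asarray(res.params)[: X.shape[1]],
                           index=X.columns)
        fitted_fixed = X.to_numpy() @ params.to_numpy()
        var_f = float(np.var(fitted_fixed))
        cond_r2 = (var_f + re_var) / max(var_f + re_var + resid_var, 1e-300)
        return FitResult(
            spec=spec, coefficients=params,
            bse=pd.Series(np.asarray(res.bse)[: X.shape[1]], index=X.columns),
            pvalues=pd.Series(np.asarray(res.pvalues)[: X.shape[1]],
                              index=X.columns),
            cov_re=cov_re, loglik=ll, aic=-2 * ll + 2 * k, n_obs=len(df),
            converged=bool(getattr(res, "converged", True)),
            conditional_r2=float(cond_r2))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.family == "glm_poisson":
            res = sm.GLM(np.round(y_raw), X,
                         family=sm.families.Poisson()).fit()
        elif spec.family == "glm_nb":
            res = sm.NegativeBinomial(np.round(y_raw), X).fit(disp=False)
        elif spec.family == "glm_binomial":
            if spec.outcome != "pct_channels_active":
                raise ValueError("binomial GLM applies to the percent-active "
                                 "outcome")
            succ = np.round(y_raw / 100.0 * n_keep)
            endog = np.column_stack([succ, n_keep - succ])
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        else:  # pragma: no cover
            raise AssertionError
    ll = float(res.llf)
    k = X.shape[1] + (1 if spec.family == "glm_nb" else 0)
    if hasattr(res, "null_deviance"):
        pseudo = 1.0 - res.deviance / max(res.null_deviance, 1e-300)
    else:
        pseudo = float(getattr(res, "prsquared", np.nan))
    params = pd.Series(np.asarray(res.params)[: X.shape[1]], index=X.columns)
    return FitResult(
        spec=spec, coefficients=params,
        bse=pd.Series(np.asarray(res.bse)[: X.shape[1]], index=X.columns),
        pvalues=pd.Series(np.asarray(res.pvalues)[: X.shape[1]],
                          index=X.columns),
        cov_re=None, loglik=ll, aic=-2 * ll + 2 * k, n_obs=len(df),
        converged=bool(getattr(res.mle_retvals, "converged", True)
                       if hasattr(res, "mle_retvals") else True),
        conditional_r2=float(pseudo))


def _fit_mixedlm(y, X, groups, exog_re):
    """ML fit with an optimizer ladder.

    Variance components on the boundary can make a single optimizer
    crash or return a non-finite likelihood; try a sequence and keep the
    first finite fit.
    """
    last_exc = None
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
                res = model.fit(reml=False, method=method)
            if np.isfinite(res.llf):
                return res
        except Exception as exc:   # LinAlgError, convergence failures
            last_exc = exc
    raise RuntimeError(f"mixed model did not converge: {last_exc}")


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # name the aliased columns for the error
        aliased = []
        keep = []
        for c in X.columns:
            trial = keep + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy(float)) < len(trial):
                aliased.append(c)
            else:
                keep.append(c)
        raise ValueError(f"singular design: aliased terms {aliased}")


# ---------------------------------------------------------------------------
# Penalized scoring and selection
# ---------------------------------------------------------------------------


def penalized_score(result: FitResult, tol: float = NONZERO_TOL) -> float:
    """BIC-type score: -2 logLik + log(n) x (nonzero fixed coefficients +
    unique nonzero random-effects covariance elements)."""
    n_fixed = int((result.coefficients.abs() > tol).sum())
    n_re = 0
    if result.cov_re is not None:
        cr = np.atleast_2d(result.cov_re)
        iu = np.triu_indices(cr.shape[0])
        n_re = int((np.abs(cr[iu]) > tol).sum())
    return float(-2.0 * result.loglik
                 + np.log(result.n_obs) * (n_fixed + n_re))


def lrt_pvalue(small: FitResult, big: FitResult) -> float:
    """Log-likelihood-ratio test p-value of a nested pair."""
    from scipy.stats import chi2

    dk = big.k_params - small.k_params
    stat = max(2.0 * (big.loglik - small.loglik), 0.0)
    if dk <= 0:
        return 1.0
    return float(chi2.sf(stat, dk))


@dataclass
class SelectionResult:
    winner: FitResult
    candidates: pd.DataFrame          # one row per candidate, ranked
    coefficient_table: pd.DataFrame   # Table-style report of the winner


def select_model(outcome: str, distance_bin: str, tables: AnalysisTables,
                 families=("lme",), random_structures=("intercept",),
                 pool: tuple[str, ...] | None = None,
                 standardize: bool = True,
                 lrt_alpha: float = LRT_ALPHA,
                 max_pool: int = 8) -> SelectionResult:
    """Exhaustive penalized best-subset search over the covariate pool.

    Every subset of the pool (intercept always included) is fitted for
    every requested family x random structure; candidates are ranked by
    the penalized score with AIC reported alongside. The ranked winner is
    then compared by likelihood-ratio test against its nested candidates
    within the same family/random structure: when a smaller nested model
    is not rejected at ``lrt_alpha``, the smallest such model (best score
    among equals) is preferred — two equivalent fits resolve to the more
    parsimonious one.
    """
    if pool is None:
        pool = COVARIATE_POOLS[distance_bin]
    pool = tuple(pool)
    if len(pool) > max_pool:
        raise ValueError(f"covariate pool larger than {max_pool}; "
                         "exhaustive search not appropriate")
    base_design = {}
    records = []
    fits: dict[ModelSpec, FitResult] = {}
    for family in families:
        rss = random_structures if family == "lme" else ("none",)
        for rs in rss:
            for r in range(len(pool) + 1):
                for terms in combinations(pool, r):
                    spec = ModelSpec(outcome=outcome,
                                     distance_bin=distance_bin,
                                     family=family, fixed_terms=terms,
                                     random=rs)
                    key = (spec.outcome, spec.distance_bin)
                    if key not in base_design:
                        base_design[key] = _design(spec, tables,
                                                   standardize=standardize)
                    try:
                        res = fit(spec, tables, standardize=standardize,
                                  df=base_design[key])
                    except Exception as exc:  # singular / non-convergent
                        records.append(dict(
                            family=family, random=rs, terms=",".join(terms),
                            loglik=np.nan, aic=np.nan, score=np.nan,
                            conditional_r2=np.nan, error=str(exc)))
                        continue
                    fits[spec] = res
                    records.append(dict(
                        family=family, random=rs, terms=",".join(terms),
                        loglik=res.loglik, aic=res.aic,
                        score=penalized_score(res),
                        conditional_r2=res.conditional_r2, error=""))
    cand = pd.DataFrame(records).sort_values(
        "score", na_position="last", ignore_index=True)
    if not fits:
        raise RuntimeError(
            "no candidate model converged; per-candidate diagnostics:\n"
            + cand.to_string())

    winner_spec = min(fits, key=lambda s: penalized_score(fits[s]))
    winner = fits[winner_spec]

    # parsimony tie-break: a nested submodel that scores no worse and that
    # the LRT cannot distinguish from the winner (two equivalent fits
    # resolve to the smaller model); the penalized ranking itself is never
    # overridden
    best_score = penalized_score(winner)
    nested = [s for s in fits
              if s.family == winner_spec.family
              and s.random == winner_spec.random
              and set(s.fixed_terms) < set(winner_spec.fixed_terms)
              and penalized_score(fits[s]) <= best_score + 1e-9]
    keepers = [s for s in nested
               if lrt_pvalue(fits[s], winner) > lrt_alpha]
    if keepers:
        keepers.sort(key=lambda s: (len(s.fixed_terms),
                                    penalized_score(fits[s])))
        winner_spec = keepers[0]
        winner = fits[winner_spec]

    coef = pd.DataFrame({
        "exploratory_variable": winner.coefficients.index,
        "estimate": winner.coefficients.to_numpy(),
        "p_value": winner.pvalues.reindex(winner.coefficients.index)
                         .to_numpy(),
    })
    return SelectionResult(winner=winner, candidates=cand,
                           coefficient_table=coef)
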