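"""Multilevel trend statistics for the training and shooting outcomes.

Observations (block- or condition-level outcomes) are nested within
subjects. The model ladder runs intercepts-only, level-1 predictors
(Block, Modulation or Condition), level-2 Session terms, then the full
model with Group and its cross-level interactions; estimation is REML
with a random intercept and, where specified, a random Session slope.
Reported alongside the fixed effects: variance components, the
intraclass correlation ICC = tau0 / (tau0 + sigma2), the design effect
1 + (n - 1) * ICC, AIC/BIC, a fixed-effects pseudo-R^2 (variance of the
fixed-effect predictions over outcome variance), and simple slopes with
delta-method standard errors.

Coding: Group INC = 0 / ALT = 1; Modulation Down = 0 / Up = 1;
Condition Low = 0 / High = 1; Session and Block enter uncentered at
their printed 1-based values. Fixed-effect p-values are Wald z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "ModelResult",
    "SlopeResult",
    "encode_table",
    "fit_intercepts_only",
    "fit_mlm",
    "design_effect",
    "pseudo_r2_fixed",
    "simple_slopes",
    "assumption_checks",
    "AssumptionReport",
    "classify_responders",
    "model_ladder",
]

GROUP_CODES = {"INC": 0, "ALT": 1}
CONDITION_CODES = {"Low": 0, "High": 1}


@dataclass
class ModelSpec:
    """Formula-level description of one mixed model."""

    outcome: str
    fixed: tuple[str, ...] = ()
    random_session_slope: bool = False

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class ModelResult:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    tau_intercept: float
    tau_session_slope: Optional[float]
    sigma2_residual: float
    icc: float
    aic: float
    bic: float
    pseudo_r2: float
    converged: bool
    n_obs: int
    n_subjects: int
    cov_params: pd.DataFrame = field(repr=False, default=None)
    fitted_fixed: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula,
            "random_session_slope": self.spec.random_session_slope,
            "fixed_effects": {
                name: {
                    "beta": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "tau_intercept": self.tau_intercept,
            "tau_session_slope": self.tau_session_slope,
            "sigma2_residual": self.sigma2_residual,
            "icc": self.icc,
            "aic": self.aic,
            "bic": self.bic,
            "pseudo_r2_fixed": self.pseudo_r2,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


@dataclass
class SlopeResult:
    moderator_level: float
    slope: float
    se: float
    p: float


def encode_table(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of the long table (group/condition labels to 0/1);
    leaves already-numeric columns untouched."""
    out = table.copy()
    if "group" in out.columns and out["group"].dtype == object:
        out["group"] = out["group"].map(GROUP_CODES)
        if out["group"].isna().any():
            raise ValueError("unknown group labels (expected INC/ALT)")
    if "condition" in out.columns and out["condition"].dtype == object:
        out["condition"] = out["condition"].map(CONDITION_CODES)
        if out["condition"].isna().any():
            raise ValueError("unknown condition labels (expected Low/High)")
    return out


def _check_table(table: pd.DataFrame, outcome: str) -> None:
    if "subject" not in table.columns:
        raise ValueError("table needs a 'subject' column")
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} missing")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")


def _try_optimizers(model):
    """Robust REML optimization: a single optimizer can stop at a poor
    local optimum (or raise a singular inner solve at a zero-variance
    boundary), so fit with two gradient methods and keep the higher
    restricted log-likelihood; derivative-free methods are the fallback."""
    best = None
    last: Exception | None = None
    for method in ("lbfgs", "bfgs"):
        try:
            fit = model.fit(reml=True, method=method)
            if best is None or fit.llf > best.llf:
                best = fit
        except np.linalg.LinAlgError as exc:
            last = exc
    if best is not None:
        return best
    for method in ("powell", "nm"):
        try:
            return model.fit(reml=True, method=method)
        except np.linalg.LinAlgError as exc:
            last = exc
    raise last


def _fit(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    table = encode_table(table).dropna(subset=[spec.outcome]).reset_index(drop=True)
    _check_table(table, spec.outcome)
    degraded = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            re_formula = "~session" if spec.random_session_slope else "~1"
            model = smf.mixedlm(spec.formula, table, groups=table["subject"],
                                re_formula=re_formula)
            fit = _try_optimizers(model)
        except np.linalg.LinAlgError:
            if not spec.random_session_slope:
                raise
            # singular random-slope fit: fall back to random intercept,
            # slope variance floored at 0, flagged via `converged`
            degraded = True
            model = smf.mixedlm(spec.formula, table, groups=table["subject"],
                                re_formula="~1")
            fit = _try_optimizers(model)

    fe_names = list(model.exog_names)
    params = fit.params[fe_names]
    bse = fit.bse[fe_names]
    pvalues = fit.pvalues[fe_names]

    cov_re = np.asarray(fit.cov_re)
    tau0 = max(float(cov_re[0, 0]), 0.0)
    if spec.random_session_slope:
        tau1 = 0.0 if degraded else max(float(cov_re[1, 1]), 0.0)
    else:
        tau1 = None
    sigma2 = max(float(fit.scale), 0.0)
    icc = tau0 / (tau0 + sigma2) if tau0 + sigma2 > 0 else 0.0

    # MixedLMResults exposes no AIC/BIC; compute from the (REML)
    # log-likelihood with k = fixed effects + variance parameters.
    k = len(fe_names) + (3 if spec.random_session_slope else 1) + 1
    n = len(table)
    ll = float(fit.llf)
    aic = -2 * ll + 2 * k
    bic = -2 * ll + k * np.log(n)

    X = np.asarray(model.exog)
    fitted_fixed = X @ params.to_numpy()
    var_y = float(np.var(table[spec.outcome].to_numpy()))
    pseudo = float(np.var(fitted_fixed) / var_y) if var_y > 0 else float("nan")

    return ModelResult(
        spec=spec,
        params=params,
        bse=bse,
        pvalues=pvalues,
        tau_intercept=tau0,
        tau_session_slope=tau1,
        sigma2_residual=sigma2,
        icc=icc,
        aic=aic,
        bic=bic,
        pseudo_r2=pseudo,
        converged=bool(fit.converged) and not degraded,
        n_obs=n,
        n_subjects=table["subject"].nunique(),
        cov_params=fit.cov_params().loc[fe_names, fe_names],
        fitted_fixed=fitted_fixed,
    )


def fit_intercepts_only(table: pd.DataFrame, outcome: str = "y") -> ModelResult:
    """Random-intercept (null) model by REML; its ICC partitions outcome
    variance into between- and within-subject shares."""
    return _fit(table, ModelSpec(outcome=outcome))


def fit_mlm(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """REML mixed model per spec, random intercept plus optional random
    Session slope. Singular fits are floored at zero variance and
    flagged via `converged`."""
    return _fit(table, spec)


def design_effect(icc: float, n_per_cluster: float) -> float:
    """Variance inflation of clustered sampling: 1 + (n - 1) * ICC.
    Values above 2 are conventional evidence for multilevel structure."""
    if not 0 <= icc <= 1:
        raise ValueError("icc must be in [0, 1]")
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    return 1.0 + (n_per_cluster - 1.0) * icc


def pseudo_r2_fixed(result: ModelResult, table: pd.DataFrame) -> float:
    """Fixed-effects pseudo-R^2: variance of the fixed-effect predictions
    over the variance of the observed outcome."""
    table = encode_table(table)
    y = table[result.spec.outcome].to_numpy(dtype=float)
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("zero outcome variance: pseudo-R^2 undefined")
    return float(np.var(result.fitted_fixed) / var_y)


def simple_slopes(
    result: ModelResult,
    focal: str = "session",
    moderator: str = "group",
    levels: Sequence[float] = (0.0, 1.0),
) -> list[SlopeResult]:
    """Conditional slope of the focal predictor at each moderator level:
    b(g) = beta_focal + beta_interaction * g, with the delta-method SE
    from the fixed-effect covariance."""
    inter = None
    for cand in (f"{focal}:{moderator}", f"{moderator}:{focal}"):
        if cand in result.params.index:
            inter = cand
            break
    if inter is None:
        raise ValueError(f"no {focal} x {moderator} interaction in the model")
    if focal not in result.params.index:
        raise ValueError(f"focal predictor {focal!r} not in the model")
    b_f = float(result.params[focal])
    b_i = float(result.params[inter])
    V = result.cov_params
    var_f = float(V.loc[focal, focal])
    var_i = float(V.loc[inter, inter])
    cov_fi = float(V.loc[focal, inter])
    out = []
    for g in levels:
        slope = b_f + b_i * g
        se = float(np.sqrt(var_f + g**2 * var_i + 2 * g * cov_fi))
        z = slope / se if se > 0 else np.inf
        p = 2 * sps.norm.sf(abs(z))
        out.append(SlopeResult(moderator_level=float(g), slope=slope, se=se, p=float(p)))
    return out


@dataclass
class AssumptionReport:
    outlier_subjects: list[str]
    skewness: float
    kurtosis: float
    skewness_flag: bool
    kurtosis_flag: bool
    vif: dict[str, float]
    residual_mean: float
    residual_sd: float
    residuals: np.ndarray = field(repr=False, default=None)


def assumption_checks(table: pd.DataFrame, result: ModelResult) -> AssumptionReport:
    """Pre/post-model screens: subject-mean outliers beyond 2 SD,
    outcome skewness/kurtosis with +/-3 flags, VIF per fixed-effect
    predictor, and marginal-residual summaries for QQ/heteroscedasticity
    plots."""
    table = encode_table(table)
    y = table[result.spec.outcome].to_numpy(dtype=float)

    subj_means = table.groupby("subject")[result.spec.outcome].mean()
    z = (subj_means - subj_means.mean()) / subj_means.std(ddof=0)
    outliers = list(subj_means.index[np.abs(z) > 2])

    skew = float(sps.skew(y))
    kurt = float(sps.kurtosis(y))

    vif: dict[str, float] = {}
    names = [n for n in result.params.index if n != "Intercept"]
    if len(names) >= 1:
        X = np.column_stack(
            [np.ones(len(table))]
            + [_design_column(table, n) for n in names]
        )
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        for j, name in enumerate(names, start=1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vif[name] = float(variance_inflation_factor(X, j))

    resid = y - result.fitted_fixed
    return AssumptionReport(
        outlier_subjects=outliers,
        skewness=skew,
        kurtosis=kurt,
        skewness_flag=abs(skew) > 3,
        kurtosis_flag=abs(kurt) > 3,
        vif=vif,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std()),
        residuals=resid,
    )


def _design_column(table: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    out = np.ones(len(table))
    for c in cols:
        out = out * table[c].to_numpy(dtype=float)
    return out


def classify_responders(
    table: pd.DataFrame, outcome: str = "y", alpha: float = 0.05
) -> pd.Series:
    """Per-subject responder screen: a subject responds iff the
    univariate regression of the outcome on session OR on modulation has
    a two-sided p below alpha. Constant outcomes are non-responders."""
    if "subject" not in table.columns or outcome not in table.columns:
        raise ValueError(f"table needs 'subject' and {outcome!r} columns")
    flags = {}
    for sid, sub in table.groupby("subject"):
        if len(sub) < 10:
            raise ValueError(f"subject {sid}: need >= 10 observations")
        y = sub[outcome].to_numpy(dtype=float)
        if np.var(y) == 0:
            flags[sid] = False
            continue
        responder = False
        for pred in ("session", "modulation"):
            if pred not in sub.columns:
                continue
            x = sub[pred].to_numpy(dtype=float)
            if np.var(x) == 0:
                continue
            X = sm.add_constant(x)
            fit = sm.OLS(y, X).fit()
            if fit.pvalues[1] < alpha:
                responder = True
                break
        flags[sid] = responder
    return pd.Series(flags, name="responder")


def model_ladder(
    table: pd.DataFrame,
    outcome: str,
    level1: Sequence[str],
    random_session_slope_full: bool = True,
) -> dict[str, ModelResult]:
    """Four-step ladder: intercepts-only; + level-1 predictors; + Session
    and Session interactions; + Group and its cross-level interactions
    (the full model, with a random Session slope by default).

    Modulation enters as a main effect only: the up-only arm modulates
    Up in every block, so Group x Modulation terms are exactly collinear
    with Group and Modulation (the printed model has the same shape —
    Session/Group interact with Block or Condition, never Modulation).
    """
    l1 = list(level1)
    inter = [p for p in l1 if p != "modulation"]
    steps: dict[str, ModelResult] = {}
    steps["intercepts_only"] = _fit(table, ModelSpec(outcome=outcome))
    steps["level1"] = _fit(table, ModelSpec(outcome=outcome, fixed=tuple(l1)))
    l2 = l1 + ["session"] + [f"{p}:session" for p in inter]
    steps["level2"] = _fit(table, ModelSpec(outcome=outcome, fixed=tuple(l2)))
    full = l2 + ["group", "group:session"] + [f"group:{p}" for p in inter] + [
        f"group:session:{p}" for p in inter
    ]
    steps["full"] = _fit(
        table,
        ModelSpec(outcome=outcome, fixed=tuple(full),
                  random_session_slope=random_session_slope_full),
    )
    return steps
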