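"""Effect estimation for the two-arm trial.

Estimands
---------
* **ITT** — effect of allocation on the full analysis set (all randomised
  participants with a measured outcome), by robust linear regression
  (Huber M-estimation, tuning constant 1.345) of the outcome on
  allocation plus the five minimisation covariates.
* **CACE** — the complier average causal effect, identified by two-stage
  least squares with randomised allocation as the instrument for
  received exposure (compliant pre-lance stroking). Non-compliance is
  one-sided: control participants cannot receive the exposure, so the
  CACE equals the per-protocol effect in compliers.
* **Binary outcome** — covariate-adjusted logistic regression, reported
  as an odds ratio, with the risk ratio derived from model-standardised
  predicted risks; a Firth-penalised fit is substituted (and flagged) on
  separation.

P-values for reported results come from permutation of allocation labels
with full re-estimation; the Holm step-down method shares one alpha
across the secondary-outcome family. Confidence intervals are
model-based (robust / IV covariance).

All functions consume a tidy analysis frame with one row per participant
(columns ``allocated``, ``exposed``, the covariates ``ga``,
``postnatal``, ``sex``, ``site``, ``reason``, optionally ``stai_base``,
and the outcome columns), as produced by
:func:`painrct.synthetic.generate_outcome_frame` or
:func:`painrct.pipeline.score_dataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.sandbox.regression.gmm import IV2SLS
from statsmodels.stats.multitest import multipletests

from painrct.errors import (
    EmptyAnalysisError,
    InvalidArgumentError,
    PainRCTError,
    WeakInstrumentError,
)

__all__ = [
    "AnalysisSpec",
    "EffectEstimate",
    "covariate_matrix",
    "itt_estimate",
    "cace_estimate",
    "binary_effect",
    "permutation_pvalue",
    "fast_linear_permutation_pvalues",
    "holm_adjust",
]

HUBER_T = 1.345
MINIMISATION_COVARIATES = ("ga", "postnatal", "sex", "site", "reason")


@dataclass(frozen=True)
class AnalysisSpec:
    """What to estimate and how to test it."""

    outcome: str = "nnrf"             # nnrf | pipp | tachycardia | stai_post
    estimand: str = "ITT"             # ITT | CACE
    n_permutations: int = 10000
    seed: int = 0
    alpha_primary: float = 0.05
    alpha_family_secondary: float = 0.05
    adjust_covariates: bool = True

    @property
    def covariates(self) -> tuple[str, ...]:
        if not self.adjust_covariates:
            return ()
        if self.outcome == "stai_post":
            return MINIMISATION_COVARIATES + ("stai_base",)
        return MINIMISATION_COVARIATES


@dataclass
class EffectEstimate:
    """Point estimate with model CI and raw / family-adjusted p-values."""

    outcome: str
    estimand: str
    estimate: float
    sd_of_outcome_difference: float
    ci_low: float
    ci_high: float
    p_raw: float
    n_analysed: int
    p_adjusted: float = float("nan")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise InvalidArgumentError("CI must bracket the estimate")


def covariate_matrix(frame: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate design (categoricals dummy-coded, first level dropped)."""
    cols = []
    for c in covariates:
        if c not in frame.columns:
            raise InvalidArgumentError(f"covariate column {c!r} missing from frame")
        if frame[c].dtype == object:
            dummies = pd.get_dummies(frame[c], prefix=c, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(frame[c].astype(float).to_frame(c))
    if not cols:
        return pd.DataFrame(index=frame.index)
    return pd.concat(cols, axis=1)


def _complete_cases(frame: pd.DataFrame, spec: AnalysisSpec) -> pd.DataFrame:
    needed = list(dict.fromkeys([spec.outcome, "allocated", "exposed", *spec.covariates]))
    missing_cols = [c for c in needed if c not in frame.columns]
    if missing_cols:
        raise InvalidArgumentError(f"frame lacks columns {missing_cols}")
    sub = frame.dropna(subset=needed).reset_index(drop=True)
    if len(sub) == 0:
        raise EmptyAnalysisError(f"no complete cases for outcome {spec.outcome!r}")
    return sub


def _pooled_sd(frame: pd.DataFrame, outcome: str) -> float:
    groups = [g[outcome].to_numpy(float) for _, g in frame.groupby("allocated")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return float("nan")
    num = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups)
    den = sum(len(g) - 1 for g in groups)
    return float(np.sqrt(num / den))


def _design(frame: pd.DataFrame, spec: AnalysisSpec, treatment_col: str):
    X = covariate_matrix(frame, spec.covariates)
    X.insert(0, treatment_col, frame[treatment_col].astype(float))
    X = sm.add_constant(X, has_constant="add")
    return frame[spec.outcome].to_numpy(float), X


def itt_estimate(frame: pd.DataFrame, spec: AnalysisSpec | None = None) -> EffectEstimate:
    """Intention-to-treat effect by Huber robust regression.

    The estimate is the allocation coefficient; the CI comes from the
    robust covariance; ``p_raw`` is the asymptotic z-test p-value and is
    replaced by a permutation p-value in pipeline reports.
    """
    spec = spec or AnalysisSpec()
    sub = _complete_cases(frame, spec)
    y, X = _design(sub, spec, "allocated")
    ols = sm.OLS(y, X).fit()
    scale_y = float(np.std(y)) or 1.0
    if np.max(np.abs(ols.resid)) < 1e-10 * scale_y:
        # perfect fit: the M-estimator scale is degenerate, OLS is exact
        res = ols
    else:
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T)).fit()
        if not np.all(np.isfinite(np.asarray(res.params))):
            res = ols
    est = float(res.params["allocated"])
    se = float(res.bse["allocated"])
    z = norm.ppf(0.975)
    p = 2 * norm.sf(abs(est / se)) if se > 0 else (1.0 if est == 0 else 0.0)
    return EffectEstimate(
        outcome=spec.outcome,
        estimand="ITT",
        estimate=est,
        sd_of_outcome_difference=_pooled_sd(sub, spec.outcome),
        ci_low=est - z * se,
        ci_high=est + z * se,
        p_raw=float(p),
        n_analysed=len(sub),
        extra={"se": se},
    )


def cace_estimate(frame: pd.DataFrame, spec: AnalysisSpec | None = None) -> EffectEstimate:
    """Complier average causal effect by two-stage least squares.

    Allocation instruments received exposure; covariates enter both
    stages. With full compliance the exposure equals allocation and the
    fit reduces to ordinary least squares on allocation.
    """
    spec = spec or AnalysisSpec(estimand="CACE")
    sub = _complete_cases(frame, spec)
    z_col = sub["allocated"].to_numpy(float)
    d_col = sub["exposed"].to_numpy(float)
    # first-stage strength: partial covariance of instrument and exposure
    if np.var(z_col) == 0 or abs(np.cov(z_col, d_col)[0, 1]) < 1e-12:
        raise WeakInstrumentError(
            "allocation carries no information about exposure (no compliers?)"
        )
    y, X_endog = _design(sub, spec, "exposed")
    _, X_instr = _design(sub, spec, "allocated")
    res = IV2SLS(y, X_endog, instrument=X_instr).fit()
    idx = list(X_endog.columns).index("exposed")
    est = float(np.asarray(res.params)[idx])
    se = float(np.asarray(res.bse)[idx])
    zq = norm.ppf(0.975)
    p = 2 * norm.sf(abs(est / se)) if se > 0 else (1.0 if est == 0 else 0.0)
    return EffectEstimate(
        outcome=spec.outcome,
        estimand="CACE",
        estimate=est,
        sd_of_outcome_difference=_pooled_sd(sub, spec.outcome),
        ci_low=est - zq * se,
        ci_high=est + zq * se,
        p_raw=float(p),
        n_analysed=len(sub),
        extra={"se": se, "first_stage_rate_difference": float(np.mean(d_col[z_col == 1]) - np.mean(d_col[z_col == 0]))},
    )


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalised logistic regression (Jeffreys-prior score correction)."""
    n, p = X.shape
    beta = np.zeros(p)
    cov = np.eye(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        sw = np.sqrt(w)
        XW = X * sw[:, None]
        info = XW.T @ XW
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, cov, XW)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        # dampen huge steps for stability on near-separated data
        norm_step = np.max(np.abs(step))
        if norm_step > 5.0:
            step *= 5.0 / norm_step
        beta = beta + step
        if norm_step < tol:
            break
    return beta, cov


def binary_effect(frame: pd.DataFrame, spec: AnalysisSpec | None = None) -> EffectEstimate:
    """Covariate-adjusted logistic regression for a binary outcome.

    Returns the allocation log-odds coefficient; ``extra`` carries the
    odds ratio with CI, the model-standardised risk ratio, and a
    ``firth`` flag when separation forced the penalised fallback.
    """
    spec = spec or AnalysisSpec(outcome="tachycardia")
    sub = _complete_cases(frame, spec)
    y, X = _design(sub, spec, "allocated")
    if len(np.unique(y)) < 2:
        raise EmptyAnalysisError("binary outcome is constant; no effect estimable")
    Xv = X.to_numpy(float)
    firth = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xv, family=sm.families.Binomial()).fit(maxiter=200)
        params, cov = np.asarray(res.params), np.asarray(res.cov_params())
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15:
            raise PainRCTError("separation suspected")
    except Exception:
        params, cov = _firth_logit(Xv, y)
        firth = True
    idx = list(X.columns).index("allocated")
    est = float(params[idx])
    se = float(np.sqrt(max(cov[idx, idx], 0.0)))
    zq = norm.ppf(0.975)
    p = 2 * norm.sf(abs(est / se)) if se > 0 else 1.0

    # model-standardised risks: everyone allocated vs no one
    def _mean_risk(val: float) -> float:
        Xc = Xv.copy()
        Xc[:, idx] = val
        return float(np.mean(expit(Xc @ params)))

    r1, r0 = _mean_risk(1.0), _mean_risk(0.0)
    return EffectEstimate(
        outcome=spec.outcome,
        estimand=spec.estimand,
        estimate=est,
        sd_of_outcome_difference=float("nan"),
        ci_low=est - zq * se,
        ci_high=est + zq * se,
        p_raw=float(p),
        n_analysed=len(sub),
        extra={
            "odds_ratio": math.exp(est),
            "or_ci": (math.exp(est - zq * se), math.exp(est + zq * se)),
            "risk_ratio": r1 / r0 if r0 > 0 else float("inf"),
            "firth": firth,
        },
    )


def _permute_allocation(sub: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute the (allocation, exposure) pair jointly across participants.

    The pair travels together so the instrument–exposure link survives
    the permutation; under the null of no effect the outcome is
    exchangeable with respect to it.
    """
    perm = rng.permutation(len(sub))
    out = sub.copy()
    out["allocated"] = sub["allocated"].to_numpy()[perm]
    out["exposed"] = sub["exposed"].to_numpy()[perm]
    if "arm" in out.columns:
        out["arm"] = sub["arm"].to_numpy()[perm]
    return out


def permutation_pvalue(
    frame: pd.DataFrame,
    spec: AnalysisSpec,
    estimator,
    rng=None,
    max_failure_rate: float = 0.01,
) -> float:
    """Two-sided permutation p-value with full re-estimation.

    ``estimator`` maps an analysis frame to an :class:`EffectEstimate`
    (or directly to a float statistic); allocation labels are permuted
    and the estimator recomputed for each draw:

        p = (1 + #{|T_perm| >= |T_obs|}) / (1 + B)

    Aborts if the estimator fails on more than ``max_failure_rate`` of
    the permutations.
    """
    if spec.n_permutations < 1:
        raise InvalidArgumentError("n_permutations must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng
    )
    sub = _complete_cases(frame, spec)

    def _stat(f: pd.DataFrame) -> float:
        r = estimator(f, spec) if _takes_spec(estimator) else estimator(f)
        return float(r.estimate) if isinstance(r, EffectEstimate) else float(r)

    t_obs = abs(_stat(sub))
    exceed, failures, valid = 0, 0, 0
    for _ in range(spec.n_permutations):
        permuted = _permute_allocation(sub, rng)
        try:
            t = abs(_stat(permuted))
        except Exception:
            failures += 1
            continue
        valid += 1
        if t >= t_obs - 1e-12:
            exceed += 1
    if failures > max_failure_rate * spec.n_permutations:
        raise PainRCTError(
            f"estimator failed on {failures}/{spec.n_permutations} permutations"
        )
    return (1 + exceed) / (1 + valid)


def _takes_spec(estimator) -> bool:
    import inspect

    try:
        return len(inspect.signature(estimator).parameters) >= 2
    except (TypeError, ValueError):
        return False


def fast_linear_permutation_pvalues(
    y: np.ndarray,
    allocated: np.ndarray,
    covariates: np.ndarray | None,
    n_permutations: int,
    rng: np.random.Generator,
    reference_allocations: np.ndarray | None = None,
) -> float:
    """Randomisation p-value for the OLS allocation coefficient, vectorised.

    Residualising outcome and (re-drawn) allocation against the fixed
    covariate block (Frisch–Waugh–Lovell) reproduces exactly the
    coefficient a full refit would give, so thousands of draws cost two
    matrix products. The reference set is either free label permutations
    (default) or, for exactness under covariate-adaptive allocation, a
    precomputed ``(n, n_permutations)`` matrix of re-randomised
    allocations from :func:`painrct.randomisation.batch_minimisation_allocations`.
    On Gaussian data the OLS coefficient is the statistic the Huber fit
    converges to.
    """
    y = np.asarray(y, float)
    a = np.asarray(allocated, float)
    n = y.size
    if covariates is None or covariates.size == 0:
        Xc = np.ones((n, 1))
    else:
        Xc = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    Q, _ = np.linalg.qr(Xc)

    def _resid(v):
        return v - Q @ (Q.T @ v)

    my = _resid(y)
    ma = _resid(a)
    denom = float(ma @ ma)
    if denom == 0:
        return 1.0
    t_obs = abs(float(ma @ my) / denom)

    if reference_allocations is not None:
        perms = np.asarray(reference_allocations, float)
        if perms.shape != (n, n_permutations):
            raise InvalidArgumentError(
                f"reference_allocations must be (n={n}, B={n_permutations}), got {perms.shape}"
            )
    else:
        perms = np.empty((n, n_permutations))
        for b in range(n_permutations):
            perms[:, b] = a[rng.permutation(n)]
    mp = perms - Q @ (Q.T @ perms)
    num = mp.T @ my
    den = np.einsum("ij,ij->j", mp, mp)
    den[den == 0] = np.inf
    t_perm = np.abs(num / den)
    exceed = int(np.sum(t_perm >= t_obs - 1e-12))
    return (1 + exceed) / (1 + n_permutations)


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1, adjusted >= raw)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("holm_adjust needs at least one p-value")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="holm")[1]]
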