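"""Logistic readmission models.

Unplanned 30-day readmission (coded 1) is regressed on the LACE total
plus one covariate: sex for the trauma cohort (female = 0, male = 1) and
age in years for general surgery.  Fitting is maximum likelihood by
Newton iteration (tolerance 1e-8 on the score norm, at most 50 steps),
with Wald standard errors from the inverse observed information; odds
ratios are exp(beta) with 95% Wald intervals exponentiated from the
log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["LogisticFit", "fit_logistic", "fit_cohort_models", "ReadmissionLogit",
           "SeparationError"]

_Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximum (quasi-separation)."""


@dataclass(frozen=True)
class LogisticFit:
    """Coefficient table of a fitted logistic model.

    ``or_`` is exp(beta) per term and ``or_ci`` the 95% Wald interval
    exp(beta +/- 1.96 SE); the intercept row is included.
    """

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    or_: np.ndarray
    or_ci: np.ndarray  # shape (k, 2)
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int

    def term(self, name: str) -> dict[str, float]:
        """Per-term row as a dict: beta, se, z, p, or, or_low, or_high."""
        i = self.names.index(name)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "z": float(self.z[i]),
            "p": float(self.p[i]),
            "or": float(self.or_[i]),
            "or_low": float(self.or_ci[i, 0]),
            "or_high": float(self.or_ci[i, 1]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "or": self.or_,
                "or_low": self.or_ci[:, 0],
                "or_high": self.or_ci[:, 1],
            },
            index=list(self.names),
        )


def fit_logistic(predictors: pd.DataFrame, outcome) -> LogisticFit:
    """Fit outcome ~ intercept + predictors by Newton maximum likelihood.

    ``predictors`` is a DataFrame of named numeric columns (the intercept
    is added automatically); ``outcome`` a binary 0/1 sequence containing
    both classes.  Quasi-separation surfaces as :class:`SeparationError`
    naming the diverging term.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("design matrix contains non-finite values")
    zero_var = [c for c in X.columns if X[c].nunique() <= 1]
    if zero_var:
        raise ValueError(f"zero-variance predictor column(s): {zero_var}")

    design = sm.add_constant(X, prepend=True, has_constant="raise")
    model = sm.Logit(y, design)
    try:
        res = model.fit(method="newton", tol=1e-8, maxiter=50, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed to converge: {exc}") from exc

    beta = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False) or np.abs(beta).max() > 30:
        worst = design.columns[int(np.abs(beta).argmax())]
        raise SeparationError(
            f"non-convergence (possible quasi-separation); largest coefficient "
            f"on term {worst!r}"
        )
    se = np.asarray(res.bse, dtype=float)
    names = tuple(
        "intercept" if c == "const" else str(c) for c in design.columns
    )
    ci = np.column_stack([np.exp(beta - _Z_95 * se), np.exp(beta + _Z_95 * se)])
    return LogisticFit(
        names=names,
        beta=beta,
        se=se,
        z=np.asarray(res.tvalues, dtype=float),
        p=np.asarray(res.pvalues, dtype=float),
        or_=np.exp(beta),
        or_ci=ci,
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        log_likelihood=float(res.llf),
        n_obs=int(res.nobs),
    )


_SEX_CODE = {"female": 0.0, "male": 1.0}


def fit_cohort_models(frame: pd.DataFrame) -> dict[str, dict]:
    """Fit the per-cohort readmission models present in ``frame``.

    Trauma: outcome ~ LACE + sex (unknown sex dropped, count reported).
    General: outcome ~ LACE + age.  Returns, per cohort, the
    :class:`LogisticFit` and the number of records excluded for a missing
    covariate.
    """
    out: dict[str, dict] = {}
    y_all = (frame["outcome"] == "unplanned_readmission").astype(float)
    for cohort, sub in frame.groupby("cohort", sort=True):
        if cohort == "trauma":
            usable = sub[sub["sex"].isin(_SEX_CODE)]
            X = pd.DataFrame(
                {
                    "lace_total": usable["lace_total"].astype(float),
                    "sex_male": usable["sex"].map(_SEX_CODE),
                }
            )
        else:
            usable = sub[sub["age"].notna()]
            X = pd.DataFrame(
                {
                    "lace_total": usable["lace_total"].astype(float),
                    "age": usable["age"].astype(float),
                }
            )
        fit = fit_logistic(X, y_all.loc[usable.index].to_numpy())
        out[str(cohort)] = {"fit": fit, "n_excluded": len(sub) - len(usable)}
    return out


class ReadmissionLogit(BaseEstimator):
    """sklearn-style wrapper around the logistic readmission model.

    Parameters
    ----------
    predictors : sequence of str
        Design columns taken from X (default LACE total alone).

    Fitted attributes: ``fit_`` (the :class:`LogisticFit` table),
    ``coef_`` and ``intercept_``.
    """

    def __init__(self, predictors: tuple[str, ...] = ("lace_total",)):
        self.predictors = predictors

    def fit(self, X: pd.DataFrame, y) -> "ReadmissionLogit":
        design = X[list(self.predictors)]
        self.fit_ = fit_logistic(design, y)
        self.intercept_ = float(self.fit_.beta[0])
        self.coef_ = self.fit_.beta[1:].copy()
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.intercept_ + X[list(self.predictors)].to_numpy(float) @ self.coef_
        p = expit(eta)
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
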