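"""Logistic disease-risk models as scikit-learn style estimators.

Six candidate models are used to analyse a trial, two per "approach":

typical (no titer):        logit p = b0 + b1*VS + b2*C        [+ b12*C*VS]
CoP-based, linear titer:   logit p = b0 + b1*T + b2*C         [+ b12*C*T]
CoP-based, quadratic:      logit p = b0 + b1*T + b2*T^2 + b3*C [+ b23*C*T^2]

where VS is vaccination status, T the log2 titer and C the binary
baseline covariate (age group, 1 = older).  ``PoDLogisticModel`` wraps a
statsmodels binomial-logistic maximum-likelihood fit behind the sklearn
estimator contract (``fit``/``predict_proba``/``get_params``) and exposes
the fitted coefficients, Wald standard errors and p-values, the
log-likelihood, AIC and the coefficient covariance as trailing-underscore
attributes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from copve.simulate import TrialData

__all__ = [
    "PoDLogisticModel",
    "fit_model",
    "wald_pvalue",
    "typical_candidates",
    "cop_candidates",
]

#: Coefficients larger than this in absolute value flag (quasi-)complete
#: separation: the MLE is drifting to infinity.
SEPARATION_BOUND = 50.0


def _as_frame(X, y=None):
    """Accept a TrialData, a trial DataFrame, or (X, y)."""
    if isinstance(X, TrialData):
        X = X.data
    X = pd.DataFrame(X)
    if y is None:
        if "disease_status" not in X.columns:
            raise ValueError("y not given and no 'disease_status' column")
        y = X["disease_status"]
    return X, np.asarray(y, dtype=float)


class PoDLogisticModel(BaseEstimator):
    """One of the candidate logistic models for disease status.

    Parameters
    ----------
    approach : {"typical", "cop"}
        "typical" uses vaccination status as the exposure predictor;
        "cop" replaces it with the log2 titer (the correlate of
        protection).
    titer_term : {"none", "linear", "quadratic"}
        Functional form of the titer effect.  Must be "none" for the
        typical approach and "linear" or "quadratic" for the CoP-based
        approach.
    interaction : bool
        Include the covariate interaction (C*VS for typical, C*T for
        linear CoP, C*T^2 for quadratic CoP).
    covariate : bool
        Include the baseline covariate.  ``False`` gives the minimal
        exposure-only model (e.g. intercept + VS), which is not one of
        the six candidates but is the natural logistic analogue of
        case counting.

    Attributes (after ``fit``)
    --------------------------
    params_, bse_, pvalues_ : pandas.Series indexed by term name
    cov_params_ : pandas.DataFrame, coefficient covariance
    llf_, aic_ : float
    n_params_, n_obs_ : int
    converged_ : bool, False on non-convergence or separation
    """

    def __init__(self, approach="cop", titer_term="linear",
                 interaction=False, covariate=True):
        self.approach = approach
        self.titer_term = titer_term
        self.interaction = interaction
        self.covariate = covariate

    # ------------------------------------------------------------------
    def _validate_spec(self):
        if self.approach not in ("typical", "cop"):
            raise ValueError("approach must be 'typical' or 'cop'")
        if self.approach == "typical" and self.titer_term != "none":
            raise ValueError("typical approach takes titer_term='none'")
        if self.approach == "cop" and self.titer_term not in ("linear", "quadratic"):
            raise ValueError("cop approach takes titer_term 'linear' or "
                             "'quadratic'")
        if self.interaction and not self.covariate:
            raise ValueError("interaction requires the covariate")

    @property
    def interaction_term(self) -> str | None:
        """Name of the interaction column, or None."""
        if not self.interaction:
            return None
        if self.approach == "typical":
            return "vaccination_status:age_group"
        if self.titer_term == "linear":
            return "log_titer:age_group"
        return "log_titer_sq:age_group"

    @property
    def label(self) -> str:
        """Short model tag, e.g. 'cop_quad_int'."""
        base = {"typical": "typical", "cop": None}[self.approach]
        if base is None:
            base = "cop_linear" if self.titer_term == "linear" else "cop_quad"
        if not self.covariate:
            base += "_nocov"
        return base + ("_int" if self.interaction else "")

    def design_matrix(self, X) -> pd.DataFrame:
        """Design matrix (with intercept) for rows of a trial table."""
        self._validate_spec()
        if isinstance(X, TrialData):
            X = X.data
        X = pd.DataFrame(X)
        cols = {"intercept": np.ones(len(X))}
        if self.approach == "typical":
            cols["vaccination_status"] = X["vaccination_status"].to_numpy(float)
        else:
            T = X["log_titer"].to_numpy(float)
            cols["log_titer"] = T
            if self.titer_term == "quadratic":
                cols["log_titer_sq"] = T ** 2
        if self.covariate:
            C = X["age_group"].to_numpy(float)
            cols["age_group"] = C
            term = self.interaction_term
            if term is not None:
                left = term.split(":")[0]
                cols[term] = cols[left] * C
        return pd.DataFrame(cols, index=X.index)

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Maximum-likelihood fit by Newton iteration (tol 1e-8).

        Non-convergence and separation are flagged via ``converged_``
        rather than raised, so a simulation study can count and skip
        pathological replicates.
        """
        frame, y = _as_frame(X, y)
        design = self.design_matrix(frame)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("disease status must be binary 0/1")

        terms = list(design.columns)
        ok = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design.to_numpy()).fit(
                    method="newton", maxiter=100, tol=1e-8, disp=0)
            params = res.params
            ok = bool(res.mle_retvals.get("converged", True))
            ok = ok and np.all(np.isfinite(params))
            ok = ok and float(np.max(np.abs(params))) < SEPARATION_BOUND
        except Exception:  # separation / singular information
            res = None
            ok = False

        if res is not None:
            self.params_ = pd.Series(res.params, index=terms)
            self.bse_ = pd.Series(res.bse, index=terms)
            self.pvalues_ = pd.Series(res.pvalues, index=terms)
            self.cov_params_ = pd.DataFrame(np.asarray(res.cov_params()),
                                            index=terms, columns=terms)
            self.llf_ = float(res.llf)
            self.aic_ = float(res.aic)
        else:
            nan = pd.Series(np.nan, index=terms)
            self.params_, self.bse_, self.pvalues_ = nan, nan.copy(), nan.copy()
            self.cov_params_ = pd.DataFrame(np.nan, index=terms, columns=terms)
            self.llf_ = np.nan
            self.aic_ = np.nan
        self.terms_ = terms
        self.n_params_ = len(terms)
        self.n_obs_ = len(design)
        self.converged_ = ok
        self.classes_ = np.array([0, 1])
        return self

    def predict_pod(self, X) -> np.ndarray:
        """Fitted disease probability for each row of X."""
        from scipy.special import expit

        design = self.design_matrix(X)
        return expit(design.to_numpy() @ self.params_.to_numpy())

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.predict_pod(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_pod(X) >= 0.5).astype(int)

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-term summary (term, estimate, se, p) plus fit stats."""
        df = pd.DataFrame({
            "term": self.terms_,
            "estimate": self.params_.to_numpy(),
            "se": self.bse_.to_numpy(),
            "p_value": self.pvalues_.to_numpy(),
        })
        df["model"] = self.label
        df["aic"] = self.aic_
        df["loglik"] = self.llf_
        df["converged"] = self.converged_
        return df


def fit_model(trial, approach="cop", titer_term="linear", interaction=False,
              covariate=True) -> PoDLogisticModel:
    """Fit one candidate model to a trial; returns the fitted estimator."""
    return PoDLogisticModel(approach=approach, titer_term=titer_term,
                            interaction=interaction,
                            covariate=covariate).fit(trial)


def wald_pvalue(model: PoDLogisticModel, term: str) -> float:
    """Two-sided Wald p-value of a fitted term."""
    if term not in model.params_.index:
        raise KeyError(f"term {term!r} not in model "
                       f"{model.label}: {list(model.params_.index)}")
    return float(model.pvalues_[term])


def typical_candidates() -> list[PoDLogisticModel]:
    """The two typical-approach candidate models (no-interaction first)."""
    return [
        PoDLogisticModel(approach="typical", titer_term="none", interaction=False),
        PoDLogisticModel(approach="typical", titer_term="none", interaction=True),
    ]


def cop_candidates() -> list[PoDLogisticModel]:
    """The four CoP-based candidates, ordered by parameter count."""
    return [
        PoDLogisticModel(approach="cop", titer_term="linear", interaction=False),
        PoDLogisticModel(approach="cop", titer_term="linear", interaction=True),
        PoDLogisticModel(approach="cop", titer_term="quadratic", interaction=False),
        PoDLogisticModel(approach="cop", titer_term="quadratic", interaction=True),
    ]
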