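"""Vaccine efficacy estimation: point estimates and resampling intervals.

VE is one minus the relative risk of disease, vaccinated versus control.
Three estimators are provided:

* **case counting** — attack rates per arm, with a Katz normal
  approximation on the log relative risk for the 95% CI;
* **model-based (typical or CoP)** — the relative risk of the two arms'
  *average model-predicted* disease probabilities, each subject evaluated
  at their own predictors (g-computation / standardization).  The CI
  couples a multivariate-normal draw of the coefficients around the MLE
  with a within-arm subject bootstrap, one pair per replicate, and takes
  percentile bounds.

Subgroup estimates simply restrict both arm averages to the subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from copve.estimators import PoDLogisticModel
from copve.simulate import TrialData, _normalize_subgroup

__all__ = [
    "VEEstimate",
    "ve_point",
    "resample_ve",
    "ve_interval",
    "case_count_ve",
    "case_count_ve_from_counts",
]

_CHUNK = 50  # bootstrap replicates vectorized per block


@dataclass
class VEEstimate:
    """A VE point estimate with its 95% confidence interval (fractions)."""

    point: float
    ci_low: float
    ci_high: float
    method: str                      # "case_count" | "typical" | "cop"
    subgroup: str = "overall"
    n_resamples: int | None = None
    seed: int | None = None
    n_redraws: int = 0
    ci_defined: bool = True

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


def _subgroup_mask(df, subgroup):
    g = _normalize_subgroup(subgroup)
    if g is None:
        return np.ones(len(df), dtype=bool)
    return df["age_group"].to_numpy() == g


def ve_point(model: PoDLogisticModel, trial: TrialData,
             subgroup: str = "overall") -> float:
    """Standardized-prediction VE from a fitted model, as a fraction.

    Averages the fitted disease probability over each arm's subjects
    (restricted to ``subgroup``), each evaluated at their own observed
    predictors, and returns 1 - mean_vacc / mean_ctrl.
    """
    if not model.converged_:
        raise ValueError("model did not converge; VE undefined")
    df = trial.data
    mask = _subgroup_mask(df, subgroup)
    vacc = df["vaccination_status"].to_numpy() == 1
    for arm, name in ((vacc, "vaccinated"), (~vacc, "control")):
        if not np.any(arm & mask):
            raise ValueError(f"subgroup {subgroup!r} empty in {name} arm")
    p = model.predict_pod(df)
    p_vacc = p[vacc & mask].mean()
    p_ctrl = p[~vacc & mask].mean()
    if p_ctrl == 0.0:
        raise ZeroDivisionError("mean control probability is zero")
    return float(1.0 - p_vacc / p_ctrl)


def _draw_betas(model, n, rng):
    cov = model.cov_params_.to_numpy()
    mean = model.params_.to_numpy()
    return rng.multivariate_normal(mean, cov, size=n, method="svd")


def resample_ve(model: PoDLogisticModel, trial: TrialData,
                subgroups=("younger", "older", "overall"),
                n_resamples: int = 2000, seed=None,
                refit: bool = False):
    """Joint parameter-resampling + subject-bootstrap VE replicates.

    Each replicate draws one coefficient vector from
    MVN(MLE, covariance), resamples subjects with replacement within each
    arm (each resampled subject keeps all their characteristics), and
    recomputes the standardized VE for every requested subgroup from the
    same resample.  With ``refit=True`` the model is instead refitted to
    each bootstrap sample and the coefficient draw uses the refitted MLE
    and covariance (slower; off by default).

    Returns
    -------
    (ves, n_redraws) : dict mapping subgroup -> ndarray of n_resamples VE
        values, and the count of degenerate replicates that were redrawn
        (a resample leaving a requested subgroup empty in either arm).
    """
    if not model.converged_:
        raise ValueError("model did not converge; cannot resample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = trial.data
    vacc = df["vaccination_status"].to_numpy() == 1
    Xv = model.design_matrix(df[vacc]).to_numpy()
    Xc = model.design_matrix(df[~vacc]).to_numpy()
    gv = df.loc[vacc, "age_group"].to_numpy()
    gc = df.loc[~vacc, "age_group"].to_numpy()
    nv, nc = len(Xv), len(Xc)
    groups = [_normalize_subgroup(s) for s in subgroups]

    out = {s: np.empty(n_resamples) for s in subgroups}
    n_redraws = 0
    filled = 0
    while filled < n_resamples:
        s = min(_CHUNK, n_resamples - filled)
        iv = rng.integers(0, nv, size=(s, nv))
        ic = rng.integers(0, nc, size=(s, nc))
        if refit:
            betas = np.empty((s, len(model.params_)))
            for b in range(s):
                rows = np.concatenate([np.flatnonzero(vacc)[iv[b]],
                                       np.flatnonzero(~vacc)[ic[b]]])
                boot = df.iloc[rows]
                m = PoDLogisticModel(**model.get_params()).fit(boot)
                if not m.converged_:
                    betas[b] = model.params_.to_numpy()  # fall back to MLE
                else:
                    betas[b] = _draw_betas(m, 1, rng)[0]
        else:
            betas = _draw_betas(model, s, rng)
        # per-subject linear predictors for all draws, then gather the
        # bootstrap resample: cheaper than gathering design rows
        pv = expit(np.take_along_axis((Xv @ betas.T).T, iv, axis=1))
        pc = expit(np.take_along_axis((Xc @ betas.T).T, ic, axis=1))
        Gv, Gc = gv[iv], gc[ic]

        chunk_ok = np.ones(s, dtype=bool)
        chunk_ve = {s_: np.empty(s) for s_ in subgroups}
        for tag, g in zip(subgroups, groups):
            if g is None:
                mv = np.ones_like(pv, dtype=bool)
                mc = np.ones_like(pc, dtype=bool)
            else:
                mv, mc = Gv == g, Gc == g
            nv_g = mv.sum(axis=1)
            nc_g = mc.sum(axis=1)
            ok = (nv_g > 0) & (nc_g > 0)
            chunk_ok &= ok
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_v = (pv * mv).sum(axis=1) / nv_g
                mean_c = (pc * mc).sum(axis=1) / nc_g
                chunk_ve[tag] = 1.0 - mean_v / mean_c

        keep = np.flatnonzero(chunk_ok)
        n_redraws += s - len(keep)
        take = keep[: n_resamples - filled]
        for tag in subgroups:
            out[tag][filled:filled + len(take)] = chunk_ve[tag][take]
        filled += len(take)
        if n_redraws > 100 * n_resamples:
            raise RuntimeError("too many degenerate resamples; subgroup "
                               "too sparse for bootstrap")
    return out, n_redraws


def ve_interval(model: PoDLogisticModel, trial: TrialData,
                subgroup: str = "overall", n_resamples: int = 2000,
                seed=None, refit: bool = False) -> VEEstimate:
    """95% percentile CI for the model-based VE of one subgroup."""
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    ves, n_redraws = resample_ve(model, trial, subgroups=(subgroup,),
                                 n_resamples=n_resamples, seed=seed,
                                 refit=refit)
    draws = ves[subgroup]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return VEEstimate(
        point=ve_point(model, trial, subgroup),
        ci_low=float(lo), ci_high=float(hi),
        method=model.approach, subgroup=subgroup,
        n_resamples=n_resamples,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_redraws=n_redraws,
    )


def case_count_ve_from_counts(cases_vacc: int, n_vacc: int,
                              cases_ctrl: int, n_ctrl: int,
                              subgroup: str = "overall") -> VEEstimate:
    """Attack-rate VE with the Katz log-relative-risk 95% CI.

    VE = 1 - (cases_vacc/n_vacc) / (cases_ctrl/n_ctrl); the CI
    exponentiates log RR +/- 1.96 * sqrt(1/cases_vacc - 1/n_vacc
    + 1/cases_ctrl - 1/n_ctrl).  With zero vaccinated cases the point
    estimate is 1 and the CI is flagged non-computable; zero control
    cases leave VE undefined and raise.
    """
    if cases_ctrl <= 0:
        raise ZeroDivisionError("no control cases: case-count VE undefined")
    rr = (cases_vacc / n_vacc) / (cases_ctrl / n_ctrl)
    if cases_vacc == 0:
        return VEEstimate(point=1.0, ci_low=np.nan, ci_high=np.nan,
                          method="case_count", subgroup=subgroup,
                          ci_defined=False)
    z = norm.ppf(0.975)
    se = np.sqrt(1.0 / cases_vacc - 1.0 / n_vacc
                 + 1.0 / cases_ctrl - 1.0 / n_ctrl)
    log_rr = np.log(rr)
    return VEEstimate(
        point=float(1.0 - rr),
        ci_low=float(1.0 - np.exp(log_rr + z * se)),
        ci_high=float(1.0 - np.exp(log_rr - z * se)),
        method="case_count", subgroup=subgroup,
    )


def case_count_ve(trial: TrialData, subgroup: str = "overall") -> VEEstimate:
    """Case-count VE of a trial subgroup (see ``case_count_ve_from_counts``)."""
    df = trial.data
    mask = _subgroup_mask(df, subgroup)
    vacc = df["vaccination_status"].to_numpy() == 1
    ds = df["disease_status"].to_numpy()
    n_v = int((vacc & mask).sum())
    n_c = int((~vacc & mask).sum())
    if n_v == 0 or n_c == 0:
        raise ValueError(f"subgroup {subgroup!r} empty in one arm")
    return case_count_ve_from_counts(int(ds[vacc & mask].sum()), n_v,
                                     int(ds[~vacc & mask].sum()), n_c,
                                     subgroup=subgroup)
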