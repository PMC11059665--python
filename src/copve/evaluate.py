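"""Simulation-study harness: covariate-effect decisions, AIC model
selection, and operating characteristics over replicated trials.

Each simulated trial is analysed the same way a real one would be:

1. *Statistical significance* of the baseline covariate is assessed per
   approach from the pair of candidate models without / with the
   interaction (the CoP-based approach uses its linear-titer models for
   this step).  The test is positive if either the covariate main effect
   (no-interaction model) or the interaction coefficient (interaction
   model) has a Wald p-value below alpha.
2. *Clinical significance* uses the minimum-AIC candidate model of each
   approach to produce standardized VE estimates (with resampling CIs)
   per covariate subgroup, alongside plain case-count VE.

Repeating over R seeded replicates of paired effect / no-effect
scenarios yields true/false positive rates, predictive values and the
accuracy/precision summaries of the VE estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copve.efficacy import case_count_ve, resample_ve, ve_point
from copve.estimators import (PoDLogisticModel, cop_candidates,
                              typical_candidates, wald_pvalue)
from copve.simulate import ScenarioConfig, make_scenario, simulate_trial, true_ve

__all__ = [
    "SignificanceResult",
    "covariate_decision",
    "OperatingCharacteristics",
    "StudyResult",
    "assess_significance",
    "select_best_model",
    "run_simulation_study",
    "operating_characteristics",
    "ve_accuracy_summary",
    "ci_narrower_fraction",
]


@dataclass
class SignificanceResult:
    """Outcome of the covariate-effect test for one approach."""

    approach: str
    positive: bool | None            # None: indeterminate (fit failure)
    p_covariate: float
    p_interaction: float
    alpha: float = 0.05

    @property
    def min_p(self) -> float:
        return min(self.p_covariate, self.p_interaction)


@dataclass
class OperatingCharacteristics:
    """Classification metrics of the covariate test, in percent."""

    tpr: float
    tnr: float
    ppv: float
    npv: float
    auc: float | None = None
    n_effect: int = 0
    n_no_effect: int = 0

    @property
    def fpr(self) -> float:
        return 100.0 - self.tnr

    @property
    def fnr(self) -> float:
        return 100.0 - self.tpr


@dataclass
class StudyResult:
    """Tidy per-trial outputs of ``run_simulation_study``.

    decisions : one row per (scenario, replicate, approach) with the
        covariate / interaction p-values and the positive/negative call.
    selections : AIC-selected model label per (scenario, replicate,
        approach).
    ve : one row per (scenario, replicate, method, subgroup) with the VE
        point estimate and, when computed, the 95% CI (all fractions).
    """

    decisions: pd.DataFrame
    selections: pd.DataFrame
    ve: pd.DataFrame
    config: dict = field(default_factory=dict)


def covariate_decision(p_covariate: float, p_interaction: float,
                       alpha: float = 0.05) -> bool:
    """Positive iff the covariate main effect or the interaction is
    significant at ``alpha``."""
    return bool(p_covariate < alpha or p_interaction < alpha)


def _fit_candidates(trial, approach):
    cands = typical_candidates() if approach == "typical" else cop_candidates()
    return [m.fit(trial) for m in cands]


def assess_significance(trial, approach: str, alpha: float = 0.05,
                        fits=None, use_best_fit: bool = False) -> SignificanceResult:
    """Covariate-effect decision for one trial and approach.

    By default (Step-3 rule) the candidate pair is the no-interaction and
    interaction models — typical models for ``approach="typical"``,
    *linear*-titer CoP models for ``approach="cop"`` — and the test is
    positive if the covariate main effect (no-interaction model) or the
    interaction term (interaction model) is significant at ``alpha``.
    With ``use_best_fit=True`` the decision instead reads the covariate
    and interaction p-values off the minimum-AIC candidate model.
    """
    if fits is None:
        fits = _fit_candidates(trial, approach)
    if use_best_fit:
        best = select_best_model(trial, approach, fits=fits)
        p_cov = wald_pvalue(best, "age_group")
        term = best.interaction_term
        p_int = wald_pvalue(best, term) if term else np.inf
        positive = covariate_decision(p_cov, p_int, alpha)
        return SignificanceResult(approach, positive, p_cov, p_int, alpha)

    if approach == "typical":
        plain, inter = fits[0], fits[1]
    else:
        plain = next(m for m in fits
                     if m.titer_term == "linear" and not m.interaction)
        inter = next(m for m in fits
                     if m.titer_term == "linear" and m.interaction)
    if not (plain.converged_ and inter.converged_):
        return SignificanceResult(approach, None, np.nan, np.nan, alpha)
    p_cov = wald_pvalue(plain, "age_group")
    p_int = wald_pvalue(inter, inter.interaction_term)
    positive = covariate_decision(p_cov, p_int, alpha)
    return SignificanceResult(approach, positive, p_cov, p_int, alpha)


def select_best_model(trial, approach: str, fits=None) -> PoDLogisticModel:
    """Minimum-AIC candidate of an approach; ties go to fewer parameters."""
    if fits is None:
        fits = _fit_candidates(trial, approach)
    ok = [m for m in fits if m.converged_]
    if not ok:
        raise RuntimeError(f"all {approach} candidate fits failed")
    return min(ok, key=lambda m: (m.aic_, m.n_params_))


def _trial_seed_sequence(master_seed: int, scenario_index: int, replicate: int):
    return np.random.SeedSequence((int(master_seed), scenario_index, replicate))


def run_simulation_study(scenarios=("i", "ii", "iii", "iv"),
                         n_replicates: int = 100,
                         n_resamples: int = 2000,
                         seed: int = 0,
                         alpha: float = 0.05,
                         compute_ci: bool = True,
                         ci_methods=("cop", "typical"),
                         subgroups=("younger", "older"),
                         refit: bool = False,
                         use_best_fit: bool = False) -> StudyResult:
    """Simulate and fully analyse R trials per scenario.

    Every trial draws its own random stream from a seed sequence keyed by
    (master seed, scenario index, replicate), so results are reproducible
    and growing ``n_replicates`` leaves earlier trials untouched.
    Per-trial fit failures are recorded as indeterminate rather than
    aborting the study.
    """
    dec_rows, sel_rows, ve_rows = [], [], []
    for si, scen in enumerate(scenarios):
        config = scen if isinstance(scen, ScenarioConfig) else make_scenario(scen)
        for r in range(n_replicates):
            ss = _trial_seed_sequence(seed, si, r)
            rng_sim, rng_cop, rng_typ = (np.random.default_rng(c)
                                         for c in ss.spawn(3))
            trial = simulate_trial(config, rng_sim)
            fits = {a: _fit_candidates(trial, a) for a in ("typical", "cop")}

            for approach in ("typical", "cop"):
                sig = assess_significance(trial, approach, alpha=alpha,
                                          fits=fits[approach],
                                          use_best_fit=use_best_fit)
                dec_rows.append({
                    "scenario": config.label, "replicate": r,
                    "approach": approach, "positive": sig.positive,
                    "p_covariate": sig.p_covariate,
                    "p_interaction": sig.p_interaction,
                })

            selected = {}
            for approach in ("typical", "cop"):
                try:
                    best = select_best_model(trial, approach,
                                             fits=fits[approach])
                except RuntimeError:
                    best = None
                selected[approach] = best
                sel_rows.append({
                    "scenario": config.label, "replicate": r,
                    "approach": approach,
                    "model": best.label if best else "failed",
                })

            ci_rngs = {"cop": rng_cop, "typical": rng_typ}
            for sub in subgroups:
                cc = case_count_ve(trial, sub)
                ve_rows.append({
                    "scenario": config.label, "replicate": r,
                    "method": "case_count", "subgroup": sub,
                    "ve": cc.point, "ci_low": cc.ci_low,
                    "ci_high": cc.ci_high,
                })
            for approach in ("typical", "cop"):
                best = selected[approach]
                if best is None:
                    continue
                points = {s: ve_point(best, trial, s) for s in subgroups}
                cis = {}
                if compute_ci and approach in ci_methods:
                    draws, _ = resample_ve(best, trial, subgroups=subgroups,
                                           n_resamples=n_resamples,
                                           seed=ci_rngs[approach],
                                           refit=refit)
                    cis = {s: np.percentile(draws[s], [2.5, 97.5])
                           for s in subgroups}
                for sub in subgroups:
                    lo, hi = cis.get(sub, (np.nan, np.nan))
                    ve_rows.append({
                        "scenario": config.label, "replicate": r,
                        "method": approach, "subgroup": sub,
                        "ve": points[sub], "ci_low": lo, "ci_high": hi,
                    })

    decisions = pd.DataFrame(dec_rows)
    selections = pd.DataFrame(sel_rows)
    ve = pd.DataFrame(ve_rows)
    if len(ve):
        ve["ci_width"] = ve["ci_high"] - ve["ci_low"]
    return StudyResult(decisions=decisions, selections=selections, ve=ve,
                       config={
                           "scenarios": [s if isinstance(s, str) else s.label
                                         for s in scenarios],
                           "n_replicates": n_replicates,
                           "n_resamples": n_resamples, "seed": seed,
                           "alpha": alpha, "compute_ci": compute_ci,
                           "subgroups": list(subgroups),
                       })


def positive_rate(decisions: pd.DataFrame, scenario: str, approach: str) -> float:
    """Fraction of determinate trials called positive, in percent."""
    d = decisions[(decisions["scenario"] == scenario)
                  & (decisions["approach"] == approach)
                  & decisions["positive"].notna()]
    if len(d) == 0:
        raise ValueError(f"no determinate decisions for {scenario}/{approach}")
    return 100.0 * d["positive"].astype(bool).mean()


def operating_characteristics(decisions: pd.DataFrame, approach: str,
                              scenario_no_effect: str, scenario_effect: str,
                              with_auc: bool = True) -> OperatingCharacteristics:
    """TPR/TNR/PPV/NPV (and AUC) for a matched scenario pair.

    Predictive values assume equal priors on the effect and no-effect
    scenarios: PPV = TPR / (TPR + FPR), NPV = TNR / (TNR + FNR).  The
    AUC scores each trial by the smaller of its covariate and
    interaction p-values (smaller = more evidence of an effect) and pools
    the two scenarios' trials.
    """
    tpr = positive_rate(decisions, scenario_effect, approach)
    tnr = 100.0 - positive_rate(decisions, scenario_no_effect, approach)
    fpr, fnr = 100.0 - tnr, 100.0 - tpr
    ppv = 100.0 * tpr / (tpr + fpr) if tpr + fpr > 0 else np.nan
    npv = 100.0 * tnr / (tnr + fnr) if tnr + fnr > 0 else np.nan

    auc = None
    if with_auc:
        from sklearn.metrics import roc_auc_score

        d = decisions[decisions["approach"] == approach]
        rows = d[d["scenario"].isin([scenario_no_effect, scenario_effect])]
        rows = rows[rows["positive"].notna()]
        y = (rows["scenario"] == scenario_effect).astype(int)
        score = -np.minimum(rows["p_covariate"], rows["p_interaction"])
        auc = 100.0 * float(roc_auc_score(y, score))
    d_eff = decisions[(decisions["scenario"] == scenario_effect)
                      & (decisions["approach"] == approach)]
    d_no = decisions[(decisions["scenario"] == scenario_no_effect)
                     & (decisions["approach"] == approach)]
    return OperatingCharacteristics(tpr=tpr, tnr=tnr, ppv=ppv, npv=npv,
                                    auc=auc, n_effect=len(d_eff),
                                    n_no_effect=len(d_no))


def selection_rate(selections: pd.DataFrame, scenario: str, approach: str,
                   model_label: str) -> float:
    """Percent of trials where AIC picked ``model_label``."""
    s = selections[(selections["scenario"] == scenario)
                   & (selections["approach"] == approach)]
    if len(s) == 0:
        raise ValueError(f"no selections for {scenario}/{approach}")
    return 100.0 * (s["model"] == model_label).mean()


def _truth_table(scenarios, subgroups):
    truths = {}
    for scen in scenarios:
        config = scen if isinstance(scen, ScenarioConfig) else make_scenario(scen)
        for sub in subgroups:
            truths[(config.label, sub)] = true_ve(config, sub)
    return truths


def ve_accuracy_summary(study: StudyResult, truths=None) -> pd.DataFrame:
    """Accuracy/precision of each VE method per scenario and subgroup.

    Returns one row per (scenario, subgroup, method) with, in percentage
    points: the median and IQR of the VE point estimates, bias of the
    median against the scenario's true VE, mean squared error, the
    median CI width, and the CI coverage of the truth (NaN when CIs were
    not computed).
    """
    ve = study.ve
    scenarios = sorted(ve["scenario"].unique())
    subgroups = list(dict.fromkeys(ve["subgroup"]))
    if truths is None:
        truths = _truth_table(scenarios, subgroups)

    rows = []
    for (scen, sub, method), grp in ve.groupby(
            ["scenario", "subgroup", "method"], sort=True):
        truth = truths[(scen, sub)]
        est = grp["ve"].to_numpy()
        q1, med, q3 = np.percentile(est, [25, 50, 75])
        has_ci = grp["ci_low"].notna() & grp["ci_high"].notna()
        coverage = np.nan
        width = np.nan
        if has_ci.any():
            g = grp[has_ci]
            coverage = 100.0 * ((g["ci_low"] <= truth)
                                & (truth <= g["ci_high"])).mean()
            width = 100.0 * float(g["ci_width"].median())
        rows.append({
            "scenario": scen, "subgroup": sub, "method": method,
            "n": len(grp),
            "true_ve": 100.0 * truth,
            "median_ve": 100.0 * med,
            "iqr": 100.0 * (q3 - q1),
            "median_bias": 100.0 * (med - truth),
            "mse": float(np.mean((100.0 * (est - truth)) ** 2)),
            "median_ci_width": width,
            "ci_coverage": coverage,
        })
    return pd.DataFrame(rows)


def ci_narrower_fraction(study: StudyResult) -> pd.DataFrame:
    """Per scenario/subgroup: percent of trials with a narrower CoP CI.

    Pairs the CoP-based and typical intervals within each replicate;
    trials where either interval is undefined are dropped.
    """
    ve = study.ve
    wide = ve.pivot_table(index=["scenario", "subgroup", "replicate"],
                          columns="method", values="ci_width")
    wide = wide.dropna(subset=["cop", "typical"])
    rows = []
    for (scen, sub), grp in wide.groupby(level=["scenario", "subgroup"]):
        rows.append({
            "scenario": scen, "subgroup": sub, "n": len(grp),
            "cop_narrower_pct": 100.0 * (grp["cop"] < grp["typical"]).mean(),
        })
    return pd.DataFrame(rows)
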