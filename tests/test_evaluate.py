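"""Tests of the study harness: decisions, selection, metrics, summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copve.estimators import PoDLogisticModel
from copve.evaluate import (StudyResult, assess_significance,
                            ci_narrower_fraction, covariate_decision,
                            operating_characteristics, run_simulation_study,
                            select_best_model, selection_rate,
                            ve_accuracy_summary)
from copve.simulate import make_scenario, simulate_trial


def small_scenario(scenario_id, n_total=3000):
    return dataclasses.replace(make_scenario(scenario_id), n_total=n_total)


class TestDecisionRule:
    @pytest.mark.parametrize("p_cov, p_int, expected",
                             [(0.03, 0.40, True),
                              (0.20, 0.051, False),
                              (0.20, 0.049, True),
                              (0.05, 0.05, False)])
    def test_examples(self, p_cov, p_int, expected):
        assert covariate_decision(p_cov, p_int, alpha=0.05) is expected

    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.001, 0.5), st.floats(0, 0.5))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_alpha(self, p1, p2, alpha, bump):
        if covariate_decision(p1, p2, alpha):
            assert covariate_decision(p1, p2, alpha + bump)

    def test_on_effect_trial(self, trial_ii):
        for approach in ("typical", "cop"):
            sig = assess_significance(trial_ii, approach)
            assert sig.positive is True
            assert sig.min_p == min(sig.p_covariate, sig.p_interaction)

    def test_best_fit_variant_runs(self, trial_ii):
        sig = assess_significance(trial_ii, "cop", use_best_fit=True)
        assert sig.positive in (True, False)


class TestModelSelection:
    def test_min_aic_wins(self, trial_iv):
        best = select_best_model(trial_iv, "cop")
        fits = [m.fit(trial_iv) for m in
                (PoDLogisticModel("cop", "linear"),
                 PoDLogisticModel("cop", "linear", True),
                 PoDLogisticModel("cop", "quadratic"),
                 PoDLogisticModel("cop", "quadratic", True))]
        assert best.aic_ == min(f.aic_ for f in fits)

    def test_tie_breaks_to_fewer_parameters(self):
        a = PoDLogisticModel("cop", "linear")
        a.aic_, a.n_params_, a.converged_ = 100.0, 3, True
        b = PoDLogisticModel("cop", "quadratic")
        b.aic_, b.n_params_, b.converged_ = 100.0, 4, True
        assert select_best_model(None, "cop", fits=[b, a]) is a

    def test_all_failed_raises(self):
        a = PoDLogisticModel("cop", "linear")
        a.converged_ = False
        with pytest.raises(RuntimeError):
            select_best_model(None, "cop", fits=[a])


def _decisions_frame(approach, scenario, n_pos, n_neg):
    rows = []
    for i in range(n_pos + n_neg):
        rows.append({"scenario": scenario, "replicate": i,
                     "approach": approach, "positive": i < n_pos,
                     "p_covariate": 0.01 if i < n_pos else 0.5,
                     "p_interaction": 0.5})
    return pd.DataFrame(rows)


class TestOperatingCharacteristics:
    @pytest.mark.parametrize(
        "tpr, tnr, ppv, npv",
        [  # the four printed cells of the reference metric table
            (100.00, 90.62, 91.42, 100.00),   # typical, logistic truth
            (100.00, 90.66, 91.46, 100.00),   # cop, logistic truth
            (99.30, 91.12, 91.79, 99.24),     # typical, Hill truth
            (99.62, 94.08, 94.39, 99.60),     # cop, Hill truth
        ])
    def test_predictive_value_identities(self, tpr, tnr, ppv, npv):
        """PPV = TPR/(TPR+FPR) and NPV = TNR/(TNR+FNR) under equal
        scenario priors reproduce the reference table to 2 decimals."""
        n = 10000
        dec = pd.concat([
            _decisions_frame("cop", "eff", round(n * tpr / 100),
                             n - round(n * tpr / 100)),
            _decisions_frame("cop", "null", n - round(n * tnr / 100),
                             round(n * tnr / 100)),
        ], ignore_index=True)
        oc = operating_characteristics(dec, "cop", "null", "eff",
                                       with_auc=False)
        assert oc.tpr == pytest.approx(tpr, abs=1e-9)
        assert oc.ppv == pytest.approx(ppv, abs=0.005)
        assert oc.npv == pytest.approx(npv, abs=0.005)
        assert oc.tpr + oc.fnr == pytest.approx(100.0)
        assert oc.tnr + oc.fpr == pytest.approx(100.0)

    def test_perfect_classifier(self):
        dec = pd.concat([_decisions_frame("cop", "eff", 100, 0),
                         _decisions_frame("cop", "null", 0, 100)],
                        ignore_index=True)
        oc = operating_characteristics(dec, "cop", "null", "eff")
        assert (oc.tpr, oc.fpr, oc.ppv) == (100.0, 0.0, 100.0)
        assert oc.auc == pytest.approx(100.0)


class TestRunSimulationStudy:
    def test_reproducible_and_extendable(self):
        scen = [small_scenario("ii")]
        kw = dict(scenarios=scen, n_resamples=100, seed=7,
                  compute_ci=True, subgroups=("younger", "older"))
        a = run_simulation_study(n_replicates=2, **kw)
        b = run_simulation_study(n_replicates=2, **kw)
        pd.testing.assert_frame_equal(a.ve, b.ve)
        pd.testing.assert_frame_equal(a.decisions, b.decisions)
        c = run_simulation_study(n_replicates=3, **kw)
        pd.testing.assert_frame_equal(
            a.ve, c.ve[c.ve.replicate < 2].reset_index(drop=True))

    def test_outputs_well_formed(self):
        study = run_simulation_study(scenarios=[small_scenario("iv")],
                                     n_replicates=2, n_resamples=100,
                                     seed=1)
        assert set(study.decisions.approach) == {"typical", "cop"}
        assert set(study.ve.method) == {"case_count", "typical", "cop"}
        model_rows = study.ve[study.ve.method != "case_count"]
        assert (model_rows.ci_low <= model_rows.ci_high).all()
        sel = study.selections
        assert sel[sel.approach == "typical"].model.isin(
            ["typical", "typical_int", "failed"]).all()
        assert sel[sel.approach == "cop"].model.str.startswith("cop").all()

    def test_no_ci_mode_skips_intervals(self):
        study = run_simulation_study(scenarios=[small_scenario("i")],
                                     n_replicates=2, compute_ci=False,
                                     seed=1)
        model_rows = study.ve[study.ve.method != "case_count"]
        assert model_rows.ci_low.isna().all()
        assert model_rows.ve.notna().all()


class TestSummaries:
    def _toy_study(self):
        rows = []
        for rep in range(4):
            for method, ve, w in (("cop", 0.78, 0.10),
                                  ("typical", 0.70 + 0.02 * rep, 0.20)):
                rows.append({"scenario": "i", "replicate": rep,
                             "method": method, "subgroup": "younger",
                             "ve": ve, "ci_low": ve - w / 2,
                             "ci_high": ve + w / 2, "ci_width": w})
        return StudyResult(decisions=pd.DataFrame(),
                           selections=pd.DataFrame(),
                           ve=pd.DataFrame(rows))

    def test_degenerate_method_has_zero_iqr_and_mse_bias_sq(self):
        study = self._toy_study()
        truths = {("i", "younger"): 0.80}
        summ = ve_accuracy_summary(study, truths=truths)
        cop = summ[summ.method == "cop"].iloc[0]
        assert cop["iqr"] == 0.0
        assert cop["mse"] == pytest.approx(cop["median_bias"] ** 2)
        assert cop["median_bias"] == pytest.approx(-2.0)
        assert cop["ci_coverage"] == 100.0

    def test_ci_narrower_fraction_pairs_by_replicate(self):
        frac = ci_narrower_fraction(self._toy_study())
        assert frac.iloc[0]["cop_narrower_pct"] == 100.0
        assert frac.iloc[0]["n"] == 4

    def test_selection_rate(self):
        sel = pd.DataFrame({
            "scenario": ["i"] * 4, "replicate": range(4),
            "approach": ["typical"] * 4,
            "model": ["typical", "typical", "typical_int", "typical"]})
        assert selection_rate(sel, "i", "typical", "typical") == 75.0
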