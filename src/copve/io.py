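"""Trial-data CSV interchange, scenario serialization and report tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from copve.models import Coefficients, HillParams
from copve.simulate import TRIAL_COLUMNS, ScenarioConfig, TrialData

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "report_tables",
]

REQUIRED_COLUMNS = ["disease_status", "vaccination_status", "log_titer",
                    "age_group"]


def read_trial_csv(path) -> TrialData:
    """Read subject-level trial data, validating every record.

    Requires columns disease_status, vaccination_status, log_titer and
    age_group (subject_id is added if missing).  Binary columns must be
    0/1 and titers finite numbers; validation errors name the offending
    column and rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", np.arange(1, len(df) + 1))

    problems = []
    for col in ("disease_status", "vaccination_status", "age_group"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~vals.isin([0, 1])].tolist()
        if bad:
            problems.append(f"column {col!r} not binary 0/1 at rows {bad[:10]}")
        df[col] = vals
    titer = pd.to_numeric(df["log_titer"], errors="coerce")
    bad = df.index[~np.isfinite(titer)].tolist()
    if bad:
        problems.append(f"column 'log_titer' non-numeric/non-finite at rows "
                        f"{bad[:10]}")
    df["log_titer"] = titer
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))

    df = df[TRIAL_COLUMNS].astype(
        {"subject_id": np.int64, "disease_status": np.int64,
         "vaccination_status": np.int64, "age_group": np.int64})
    return TrialData(data=df.reset_index(drop=True))


def write_trial_csv(trial: TrialData, path) -> None:
    """Write a trial as UTF-8 comma-delimited text (full float precision)."""
    trial.data[TRIAL_COLUMNS].to_csv(path, index=False,
                                     float_format="%.17g")


def scenario_to_yaml(config: ScenarioConfig, path=None) -> str:
    """Serialize a scenario (including its PoD parameters) to YAML."""
    d = dataclasses.asdict(config)
    d["pod_params"] = dataclasses.asdict(config.pod_params)
    text = yaml.safe_dump(d, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def scenario_from_yaml(source) -> ScenarioConfig:
    """Load a scenario from a YAML string or file path."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    d = yaml.safe_load(text)
    params = d.pop("pod_params")
    cls = Coefficients if d["pod_family"] == "logistic" else HillParams
    return ScenarioConfig(pod_params=cls(**params), **d)


def _round_pct(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    return out


def report_tables(study, out_dir) -> dict[str, Path]:
    """Write tidy CSV reports for a completed simulation study.

    Produces per-trial tables (decisions, model selections, VE
    estimates) and aggregated tables: operating characteristics per
    approach and scenario pair, model-selection rates, and the VE
    accuracy/precision summary.  Percentages are rounded to 2 decimals;
    re-running on the same study writes byte-identical files.
    """
    from copve.evaluate import (ci_narrower_fraction,
                                operating_characteristics,
                                ve_accuracy_summary)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit(name, df):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    emit("decisions", study.decisions)
    emit("selections", study.selections)
    emit("ve_estimates", study.ve)

    scen = set(study.decisions["scenario"]) if len(study.decisions) else set()
    oc_rows = []
    for no_eff, eff in (("i", "ii"), ("iii", "iv")):
        if not {no_eff, eff} <= scen:
            continue
        for approach in ("typical", "cop"):
            oc = operating_characteristics(study.decisions, approach,
                                           no_eff, eff)
            oc_rows.append({
                "scenario_pair": f"{no_eff}/{eff}", "approach": approach,
                "tpr": oc.tpr, "tnr": oc.tnr, "ppv": oc.ppv, "npv": oc.npv,
                "auc": oc.auc,
            })
    if oc_rows:
        emit("operating_characteristics", _round_pct(pd.DataFrame(oc_rows)))

    if len(study.selections):
        counts = (study.selections
                  .groupby(["scenario", "approach", "model"])
                  .size().rename("n_trials").reset_index()
                  .sort_values(["scenario", "approach", "model"],
                               kind="stable", ignore_index=True))
        totals = counts.groupby(["scenario", "approach"])["n_trials"].transform("sum")
        counts["pct"] = (100.0 * counts["n_trials"] / totals).round(2)
        emit("model_selection", counts)

    if len(study.ve):
        emit("ve_accuracy", _round_pct(ve_accuracy_summary(study)))
        narrower = ci_narrower_fraction(study)
        if len(narrower):
            emit("ci_narrower", _round_pct(narrower))

    summary = dict(study.config)
    (out_dir / "study_config.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["study_config"] = out_dir / "study_config.json"
    return paths
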