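"""In-silico phase-3 vaccine trial generation and true-VE calibration.

A scenario fixes a "truth": a PoD curve family with its parameters, the
normal log2-titer distributions of the vaccinated and control arms, the
covariate-group mix and the arm ratio.  Trials are generated by sampling
titers and covariate labels, then drawing disease status Bernoulli from
the true PoD curve.  ``true_ve`` integrates the same truth analytically
(1-D quadrature against the titer densities) so simulation output can be
compared to the efficacy the scenario actually implies.

The single binary covariate is interpreted as an age group; the group
coded ``C=1`` ("older") is the one whose protection is attenuated (the
interaction slope in the logistic truth, the ``k`` multiplier in the Hill
truth), the coding under which the built-in scenario parameters reproduce
their stated subgroup efficacies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import norm

from copve.models import Coefficients, HillParams, hill_pod, linear_predictor, pod_from_lp

__all__ = [
    "ScenarioConfig",
    "TrialData",
    "SCENARIOS",
    "make_scenario",
    "true_pod",
    "simulate_trial",
    "true_ve",
]

#: Floor applied to log2 titers before evaluating the Hill truth curve,
#: which is undefined at T <= 0.  With control titers ~ Normal(5, 2) the
#: probability mass below zero is ~3e-7, so the floor is numerically
#: irrelevant; it only keeps stray draws in-domain.
HILL_TITER_FLOOR = 1e-6

TRIAL_COLUMNS = ["subject_id", "disease_status", "vaccination_status",
                 "log_titer", "age_group"]


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulation truth: PoD curve, titer distributions, design mix."""

    label: str
    pod_family: str                       # "logistic" | "hill"
    pod_params: Coefficients | HillParams
    titer_mean_vacc: float = 10.0
    titer_sd_vacc: float = 2.0
    titer_mean_ctrl: float = 5.0
    titer_sd_ctrl: float = 2.0
    frac_group1: float = 0.25             # proportion with C=1 ("older")
    frac_vacc: float = 2.0 / 3.0          # 2:1 vaccinated : control
    n_total: int = 15000
    group_mode: str = "bernoulli"         # "bernoulli" | "fixed"

    def __post_init__(self) -> None:
        if self.pod_family not in ("logistic", "hill"):
            raise ValueError("pod_family must be 'logistic' or 'hill'")
        if self.pod_family == "logistic" and not isinstance(self.pod_params, Coefficients):
            raise TypeError("logistic truth needs Coefficients")
        if self.pod_family == "hill" and not isinstance(self.pod_params, HillParams):
            raise TypeError("hill truth needs HillParams")
        for f in ("frac_group1", "frac_vacc"):
            if not 0.0 < getattr(self, f) < 1.0:
                raise ValueError(f"{f} must lie in (0, 1)")
        if self.titer_sd_vacc <= 0 or self.titer_sd_ctrl <= 0:
            raise ValueError("titer sds must be positive")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.group_mode not in ("bernoulli", "fixed"):
            raise ValueError("group_mode must be 'bernoulli' or 'fixed'")


@dataclass
class TrialData:
    """One simulated (or imported) trial: one row per subject.

    ``data`` has columns subject_id, disease_status (0/1),
    vaccination_status (0/1, 1 = vaccinated), log_titer (log2 scale) and
    age_group (0/1, 1 = older).
    """

    data: pd.DataFrame
    scenario_label: str = ""
    seed: int | None = None

    @property
    def n_vaccinated(self) -> int:
        return int((self.data["vaccination_status"] == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.data["vaccination_status"] == 0).sum())

    def __len__(self) -> int:
        return len(self.data)


def _scenario_registry() -> dict[str, ScenarioConfig]:
    logistic_null = Coefficients(beta0=-2.0, beta_titer=-0.33,
                                 beta_int=0.0, interaction="cov_titer")
    logistic_eff = replace(logistic_null, beta_int=0.184)
    hill_null = HillParams(p_max=0.033, et50=7.12, gamma=7.0, k=1.0)
    hill_eff = HillParams(p_max=0.033, et50=7.12, gamma=7.0, k=1.361)
    return {
        "i": ScenarioConfig(label="i", pod_family="logistic", pod_params=logistic_null),
        "ii": ScenarioConfig(label="ii", pod_family="logistic", pod_params=logistic_eff),
        "iii": ScenarioConfig(label="iii", pod_family="hill", pod_params=hill_null),
        "iv": ScenarioConfig(label="iv", pod_family="hill", pod_params=hill_eff),
    }


SCENARIOS = _scenario_registry()


def make_scenario(scenario_id: str) -> ScenarioConfig:
    """Return the built-in scenario configuration ``i``/``ii``/``iii``/``iv``.

    Scenarios i and ii use the logistic truth (intercept -2, titer slope
    -0.33) without / with a covariate-by-titer interaction (+0.184 in the
    older group); iii and iv use the Hill truth (p_max 0.033, et50 7.12,
    gamma 7) without / with the older-group et50 multiplier k = 1.361.
    All share 15,000 subjects, 2:1 vaccinated:control, 25% older, and
    log2-titer distributions Normal(10, 2) vaccinated / Normal(5, 2)
    control identical across age groups.
    """
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: "
            f"{sorted(SCENARIOS)}"
        ) from None


def true_pod(config: ScenarioConfig, T, C):
    """Evaluate the scenario's true PoD curve at log2 titer T, group C."""
    if config.pod_family == "logistic":
        return pod_from_lp(linear_predictor(config.pod_params, T=T, VS=0.0, C=C))
    T = np.maximum(np.asarray(T, dtype=float), HILL_TITER_FLOOR)
    return hill_pod(T, C, config.pod_params)


def simulate_trial(config: ScenarioConfig, seed=None) -> TrialData:
    """Generate one trial under ``config``.

    Arm sizes are deterministic (``round(n_total * frac_vacc)``
    vaccinated, remainder control).  Covariate-group membership is
    Bernoulli(frac_group1) per subject by default, or deterministically
    rounded per arm with ``group_mode="fixed"``.  Titers are normal on
    the log2 scale per arm, identical across covariate groups; disease
    status is Bernoulli from the true PoD curve.

    ``seed`` may be an int, ``None`` or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_total
    n_vacc = int(round(n * config.frac_vacc))
    vs = np.zeros(n, dtype=np.int64)
    vs[:n_vacc] = 1

    if config.group_mode == "bernoulli":
        grp = (rng.random(n) < config.frac_group1).astype(np.int64)
    else:
        grp = np.zeros(n, dtype=np.int64)
        for arm in (0, 1):
            idx = np.flatnonzero(vs == arm)
            n1 = int(round(len(idx) * config.frac_group1))
            grp[idx[:n1]] = 1

    titer = np.empty(n, dtype=float)
    titer[vs == 1] = rng.normal(config.titer_mean_vacc, config.titer_sd_vacc,
                                n_vacc)
    titer[vs == 0] = rng.normal(config.titer_mean_ctrl, config.titer_sd_ctrl,
                                n - n_vacc)

    p = np.asarray(true_pod(config, titer, grp), dtype=float)
    ds = (rng.random(n) < p).astype(np.int64)

    df = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "disease_status": ds,
        "vaccination_status": vs,
        "log_titer": titer,
        "age_group": grp,
    })
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return TrialData(data=df, scenario_label=config.label,
                     seed=None if seed_val is None else int(seed_val))


def _expected_pod(config: ScenarioConfig, mean: float, sd: float, C: int) -> float:
    """E[PoD(T, C)] for T ~ Normal(mean, sd), by adaptive quadrature."""
    def integrand(t):
        return true_pod(config, t, C) * norm.pdf(t, mean, sd)

    val, _ = quad(integrand, mean - 8.0 * sd, mean + 8.0 * sd,
                  epsabs=1e-12, epsrel=1e-10, limit=200)
    return val


def true_ve(config: ScenarioConfig, subgroup: str = "overall") -> float:
    """True vaccine efficacy implied by a scenario, as a fraction.

    VE = 1 - E[PoD(T_vacc, C)] / E[PoD(T_ctrl, C)], with the expectations
    taken over the arm-specific normal log2-titer distributions.  The
    "overall" value mixes the covariate groups by ``frac_group1`` in both
    the numerator and the denominator.
    """
    group = _normalize_subgroup(subgroup)
    if group is None:
        w1 = config.frac_group1
        num = ((1 - w1) * _expected_pod(config, config.titer_mean_vacc,
                                        config.titer_sd_vacc, 0)
               + w1 * _expected_pod(config, config.titer_mean_vacc,
                                    config.titer_sd_vacc, 1))
        den = ((1 - w1) * _expected_pod(config, config.titer_mean_ctrl,
                                        config.titer_sd_ctrl, 0)
               + w1 * _expected_pod(config, config.titer_mean_ctrl,
                                    config.titer_sd_ctrl, 1))
    else:
        num = _expected_pod(config, config.titer_mean_vacc,
                            config.titer_sd_vacc, group)
        den = _expected_pod(config, config.titer_mean_ctrl,
                            config.titer_sd_ctrl, group)
    if den == 0.0:
        raise ZeroDivisionError("expected control PoD is zero; VE undefined")
    return 1.0 - num / den


def _normalize_subgroup(subgroup: str):
    """Map a subgroup tag to 0 (younger), 1 (older) or None (overall)."""
    tags = {
        "group0": 0, "younger": 0,
        "group1": 1, "older": 1,
        "overall": None, "all": None,
    }
    try:
        return tags[subgroup]
    except KeyError:
        raise ValueError(
            f"unknown subgroup {subgroup!r}; expected one of {sorted(tags)}"
        ) from None
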