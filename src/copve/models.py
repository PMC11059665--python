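"""Pure mathematical forms of the probability-of-disease (PoD) models.

A PoD curve maps a subject's log2 antibody titer ``T`` (and optionally a
binary baseline covariate ``C`` and vaccination status ``VS``) to the
probability of contracting disease during the trial observation period.
Two families are used as simulation truth: a logistic curve whose log-odds
is linear (or quadratic) in ``T``, and a Hill curve, the classical
sigmoidal dose-response form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "Coefficients",
    "HillParams",
    "linear_predictor",
    "pod_from_lp",
    "hill_pod",
    "quadratic_vertex",
]

#: Valid interaction tags: which pair of predictors the interaction
#: coefficient multiplies.
INTERACTIONS = ("cov_vs", "cov_titer", "cov_titer2")


@dataclass(frozen=True)
class Coefficients:
    """Coefficients of a logistic log-odds (linear predictor) model.

    Any subset may be zero; a zero coefficient is treated as an absent
    term.  ``beta_int`` multiplies the product named by ``interaction``:
    ``"cov_vs"`` for C*VS, ``"cov_titer"`` for C*T, ``"cov_titer2"``
    for C*T^2.

    Parameters
    ----------
    beta0 : intercept, on the log-odds scale.
    beta_titer : slope on the log2 titer T.
    beta_titer2 : coefficient on T^2.
    beta_vs : coefficient on vaccination status VS (1 = vaccinated).
    beta_cov : main effect of the binary covariate C.
    beta_int : interaction coefficient (see ``interaction``).
    """

    beta0: float = 0.0
    beta_titer: float = 0.0
    beta_titer2: float = 0.0
    beta_vs: float = 0.0
    beta_cov: float = 0.0
    beta_int: float = 0.0
    interaction: str = "cov_titer"

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_titer", "beta_titer2", "beta_vs",
                     "beta_cov", "beta_int"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.interaction not in INTERACTIONS:
            raise ValueError(
                f"interaction must be one of {INTERACTIONS}, "
                f"got {self.interaction!r}"
            )


@dataclass(frozen=True)
class HillParams:
    """Parameters of the Hill-form PoD truth curve.

    ``p_max`` is the maximal disease probability (the plateau at low
    titer), ``et50`` the log2 titer at half-maximal protection, ``gamma``
    the steepness, and ``k`` a multiplier applied to ``et50`` in the
    covariate group C=1 (k>1 shifts the curve right, i.e. attenuates
    protection at a given titer).
    """

    p_max: float
    et50: float
    gamma: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must lie in (0, 1)")
        if self.et50 <= 0 or self.gamma <= 0 or self.k <= 0:
            raise ValueError("et50, gamma and k must be positive")


def linear_predictor(coeffs, T=None, VS=None, C=0.0):
    """Evaluate the logistic-model linear predictor (log-odds).

    lp = beta0 + beta_titer*T + beta_titer2*T^2 + beta_vs*VS + beta_cov*C
    plus the interaction term selected by ``coeffs.interaction``.

    ``T`` and ``VS`` may be omitted (``None``) only when every
    coefficient that needs them is zero.  Array inputs broadcast.
    """
    needs_T = (coeffs.beta_titer != 0.0 or coeffs.beta_titer2 != 0.0
               or (coeffs.beta_int != 0.0
                   and coeffs.interaction in ("cov_titer", "cov_titer2")))
    needs_VS = (coeffs.beta_vs != 0.0
                or (coeffs.beta_int != 0.0 and coeffs.interaction == "cov_vs"))
    if T is None and needs_T:
        raise ValueError("titer coefficient present but T not supplied")
    if VS is None and needs_VS:
        raise ValueError("vaccination-status coefficient present but VS "
                         "not supplied")

    T = 0.0 if T is None else np.asarray(T, dtype=float)
    VS = 0.0 if VS is None else np.asarray(VS, dtype=float)
    C = np.asarray(C, dtype=float)

    y = (coeffs.beta0 + coeffs.beta_titer * T + coeffs.beta_titer2 * T ** 2
         + coeffs.beta_vs * VS + coeffs.beta_cov * C)
    if coeffs.interaction == "cov_vs":
        y = y + coeffs.beta_int * C * VS
    elif coeffs.interaction == "cov_titer":
        y = y + coeffs.beta_int * C * T
    else:
        y = y + coeffs.beta_int * C * T ** 2
    return y if np.ndim(y) else float(y)


def pod_from_lp(y):
    """Logistic link: probability of disease from log-odds."""
    y = np.asarray(y, dtype=float)
    p = expit(y)
    return p if p.ndim else float(p)


def hill_pod(T, C, params: HillParams):
    """Hill-form probability of disease.

    p = p_max / (1 + (et50 * k**C / T) ** (-gamma))

    which equals ``p_max / (1 + (T / (et50 * k**C)) ** gamma)``: the curve
    decreases from ``p_max`` toward 0 as the titer grows, crossing
    ``p_max / 2`` at ``T = et50 * k**C``.  Requires ``T > 0`` (the model
    lives on the positive log-titer axis).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("hill_pod requires T > 0")
    C = np.asarray(C, dtype=float)
    ratio = params.et50 * params.k ** C / T
    p = params.p_max / (1.0 + ratio ** (-params.gamma))
    return p if p.ndim else float(p)


def quadratic_vertex(beta0: float, beta1: float, beta2: float):
    """Vertex of a quadratic-in-titer logistic PoD curve.

    For log-odds ``beta0 + beta1*T + beta2*T^2`` with ``beta2 < 0`` the
    disease probability is maximal at ``b = -beta1 / (2*beta2)`` with
    value ``sigmoid(beta0 - beta1**2 / (4*beta2))``.

    Returns
    -------
    (b, p_at_b) : titer at the maximum and the maximal PoD.
    """
    if beta2 >= 0:
        raise ValueError("quadratic_vertex requires beta2 < 0 (concave "
                         "log-odds)")
    b = -beta1 / (2.0 * beta2)
    p_at_b = float(expit(beta0 - beta1 ** 2 / (4.0 * beta2)))
    return float(b), p_at_b
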