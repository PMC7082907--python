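"""Two-part improper survival model with a mechanistic latent-clone core.

The model describes the time to first detection of anti-drug antibodies
(ADA) in a population that mixes three kinds of subjects:

* *pre-immune* subjects carry ADA before the first drug administration and
  contribute a point mass at time zero, with genotype-dependent probability
  ``pi(G1) = expit(theta + beta * G1)``;
* *immune-tolerant* subjects never produce ADA and contribute a defect
  (point mass at infinity) in the survival distribution of the non-zero
  times;
* *immune-reactive* subjects produce ADA at a finite time.

For non-pre-immune subjects the event time is the earliest detection time
over a latent number ``K`` of activated B-cell clones.  ``K`` follows a
Katz-family count distribution (mean parameter ``omega``, dispersion
``gamma``: Poisson at ``gamma = 0``, negative binomial for
``0 < gamma < 1``, under-dispersed for ``gamma < 0``) and each clone's
detection hazard is scaled by a Gamma(1, tau) affinity.  Marginalising the
latent variables yields closed-form improper survival functions; the
probability of never experiencing the event (the *tail defect*) is the
Katz probability of zero clones, ``(1 - gamma)**(omega / gamma)``
(``exp(-omega)`` in the Poisson case).

Genotype enters through dummies ``(G1, G2)`` (see :mod:`twistest.datamodel`)
with log-linear effects ``alpha1, alpha2`` on the affinity scale and linear
effects ``gamma1, gamma2`` on the clone-count dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParams",
    "INFINITE",
    "preimmune_prob",
    "survival_reference",
    "survival_variant",
    "tail_defect",
    "invert_survival",
    "latent_oracle_sample",
]

#: Sentinel for an immune-tolerant subject's event time (never occurs).
INFINITE = np.inf

#: Below this |gamma*G| the Poisson (gamma -> 0) closed form is used to
#: avoid the 0/0 in the Katz exponent.
GAMMA_EPS = 1e-8


def _identity(t):
    return np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-part improper survival model.

    Parameters
    ----------
    theta
        Intercept of the logistic pre-immune part; ``expit(theta)`` is the
        pre-immune probability in the reference genotype group.
    beta
        Genotype (allele-count) effect in the logistic part.
    omega
        Mean number of latent B-cell clones in the reference group
        (``> 0``); the reference tail defect is ``exp(-omega)``.
    tau
        Affinity scale of the Gamma(1, tau) clone-affinity distribution
        (``> 0``).
    alpha1, alpha2
        Genotype effects on the log affinity scale.
    gamma1, gamma2
        Genotype effects on the clone-count dispersion; every observable
        combination ``gamma1*G1 + gamma2*G2`` must stay below 1.
    baseline_cumhaz
        Baseline integrated hazard ``H0(t)``, positive and non-decreasing
        with ``H0(0) = 0``.  Defaults to the identity, which is the scale
        used throughout the simulation study.
    """

    theta: float = 0.0
    beta: float = 0.0
    omega: float = math.log(2.0)
    tau: float = 1.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    baseline_cumhaz: Callable[[np.ndarray], np.ndarray] = field(
        default=_identity, repr=False
    )

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        for g1, g2 in ((1, 1), (2, 0)):
            if self.gamma_g(g1, g2) >= 1.0:
                raise ValueError(
                    "Katz constraint violated: gamma1*G1 + gamma2*G2 = "
                    f"{self.gamma_g(g1, g2)} >= 1 for genotype (G1={g1}, G2={g2})"
                )

    def alpha_g(self, g1, g2):
        """Log affinity-scale effect ``alpha1*G1 + alpha2*G2``."""
        return self.alpha1 * np.asarray(g1) + self.alpha2 * np.asarray(g2)

    def gamma_g(self, g1, g2):
        """Dispersion effect ``gamma1*G1 + gamma2*G2``."""
        return self.gamma1 * np.asarray(g1) + self.gamma2 * np.asarray(g2)


def preimmune_prob(g1, params: ModelParams):
    """Probability of being pre-immune given the allele count ``G1``.

    Logistic in the allele count: ``expit(theta + beta * G1)``.
    """
    return expit(params.theta + params.beta * np.asarray(g1, dtype=float))


def survival_reference(t, params: ModelParams):
    """Improper survival function of the reference genotype group.

    ``S(t) = exp(-omega * (1 - (1 + H0(t) * tau)^-1))``; decreases from 1
    at ``t = 0`` to the tail defect ``exp(-omega)`` as ``t -> inf``.
    """
    h = params.baseline_cumhaz(np.asarray(t, dtype=float)) * params.tau
    return np.exp(-params.omega * (1.0 - 1.0 / (1.0 + h)))


def survival_variant(t, g1, g2, params: ModelParams):
    """Improper survival function for an arbitrary genotype ``(G1, G2)``.

    The Katz exponent form
    ``[(1 - gG/(1 + H0(t) tau e^{aG})) / (1 - gG)]^(-omega/gG)`` with
    ``aG = alpha1*G1 + alpha2*G2`` and ``gG = gamma1*G1 + gamma2*G2``.
    As ``gG -> 0`` this converges to the reference (Poisson) form with
    ``tau`` scaled by ``e^{aG}``; values of ``|gG|`` below ``1e-8`` are
    evaluated through that limit for numerical continuity.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    gG = np.asarray(params.gamma_g(g1, g2), dtype=float)
    if np.any(gG >= 1.0):
        raise ValueError("gamma1*G1 + gamma2*G2 must be < 1")
    aG = np.asarray(params.alpha_g(g1, g2), dtype=float)
    h = params.baseline_cumhaz(np.asarray(t, dtype=float)) * params.tau * np.exp(aG)
    with np.errstate(divide="ignore", invalid="ignore"):
        katz = ((1.0 - gG / (1.0 + h)) / (1.0 - gG)) ** (-params.omega / gG)
    poisson = np.exp(-params.omega * (1.0 - 1.0 / (1.0 + h)))
    return np.where(np.abs(gG) < GAMMA_EPS, poisson, katz)


def tail_defect(g1, g2, params: ModelParams):
    """Probability of never experiencing the event for genotype ``(G1, G2)``.

    This is the Katz probability-generating function at zero,
    ``(1 - gG)^(omega/gG)``, i.e. the probability of carrying zero
    activated clones; ``exp(-omega)`` in the Poisson limit ``gG = 0``.
    Under-dispersion (``gG < 0``) raises the tail above ``exp(-omega)``,
    over-dispersion lowers it.
    """
    gG = np.asarray(params.gamma_g(g1, g2), dtype=float)
    if np.any(gG >= 1.0):
        raise ValueError("gamma1*G1 + gamma2*G2 must be < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        katz = (1.0 - gG) ** (params.omega / gG)
    return np.where(np.abs(gG) < GAMMA_EPS, np.exp(-params.omega), katz)


def invert_survival(u, g1, g2, params: ModelParams):
    """Invert the improper survival function: the ``t`` with ``S(t) = u``.

    Draws with ``u`` at or below the genotype's tail defect map to
    :data:`INFINITE` (immune-tolerant subject).  Requires the default
    identity baseline ``H0(t) = t``; for another baseline invert ``H0``
    on the returned value.

    Parameters
    ----------
    u
        Uniform draw(s) in ``(0, 1]``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u > 1.0):
        raise ValueError("u must lie in (0, 1]")
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    gG = np.asarray(params.gamma_g(g1, g2), dtype=float)
    aG = np.asarray(params.alpha_g(g1, g2), dtype=float)
    tail = tail_defect(g1, g2, params)

    with np.errstate(divide="ignore", invalid="ignore"):
        # Poisson branch: 1 + t*tau*e^aG = (1 + ln u / omega)^-1
        t_pois = (1.0 / (1.0 + np.log(u) / params.omega) - 1.0) / (
            params.tau * np.exp(aG)
        )
        # Katz branch via s = u^(-gG/omega)
        s = u ** (-gG / params.omega)
        t_katz = (gG / (1.0 - s * (1.0 - gG)) - 1.0) / (params.tau * np.exp(aG))
    t = np.where(np.abs(gG) < GAMMA_EPS, t_pois, t_katz)
    # u == 1 can undershoot 0 by rounding; tolerant draws go to infinity
    t = np.clip(t, 0.0, None)
    return np.where(u <= tail, INFINITE, t)


def latent_oracle_sample(
    g1: int,
    g2: int,
    params: ModelParams,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample event times from the latent-clone mechanism directly.

    A Monte-Carlo oracle for the closed forms: draw the clone count ``K``
    (Poisson(omega) at ``gG = 0``, negative binomial with size
    ``omega/gG`` and success probability ``gG`` for ``0 < gG < 1``), then
    the summed affinity ``W ~ Gamma(K, tau * e^{aG})``, then the event
    time with conditional survival ``exp(-W * H0(t))`` — for the identity
    baseline, ``T = E / W`` with ``E`` standard exponential.  ``K = 0``
    yields :data:`INFINITE`.

    Only ``gG >= 0`` is supported: the under-dispersed Katz branch is a
    binomial-type law that is ill-defined unless ``omega/|gG|`` is an
    integer, so sampling there goes through :func:`invert_survival`
    instead.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gG = float(params.gamma_g(g1, g2))
    aG = float(params.alpha_g(g1, g2))
    if gG < 0:
        raise ValueError(
            "latent oracle supports gamma1*G1 + gamma2*G2 >= 0 only "
            "(the under-dispersed Katz branch has no general sampler); "
            "use invert_survival"
        )
    if n == 0:
        return np.empty(0)
    if gG < GAMMA_EPS:
        k = rng.poisson(params.omega, size=n)
    else:
        # negative binomial with pgf [(1 - gG s)/(1 - gG)]^(-omega/gG)
        k = rng.negative_binomial(params.omega / gG, 1.0 - gG, size=n)
    scale = params.tau * math.exp(aG)
    w = rng.gamma(shape=k, scale=scale)  # shape 0 -> w = 0
    e = rng.standard_exponential(size=n)
    with np.errstate(divide="ignore"):
        t = np.where(k == 0, INFINITE, e / np.where(w > 0, w, np.nan))
    return t
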