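"""Scenario-based Monte-Carlo data generator.

Replicates the simulation design of the power study: genotypes are sums
of two Bernoulli(MAF) draws, pre-immune status follows the logistic
part, event times for non-pre-immune subjects are drawn by inverting the
closed-form improper survival functions (with the identity baseline,
``S_AA(t) = exp[-omega (1 - (1+t)^-1)]``), and censoring is uniform with
an upper bound calibrated by Monte Carlo so that a target fraction of
the *finite-time* (immune-reactive) subjects is censored — the tail
defect fraction is excluded from the censoring percentage by
construction.

Immune-tolerant subjects (infinite latent event time) are always
censored.  Without censoring they are assigned an administrative horizon
one time unit past the largest finite event time of the replicate, so
they remain at risk through the last failure — the condition under
which the terminal Nelson-Aalen value estimates ``omega``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import model
from .datamodel import Dataset, dataset_from_arrays
from .model import ModelParams

__all__ = [
    "Scenario",
    "GENETIC_MODELS",
    "alpha_effects",
    "gamma_effects",
    "draw_genotypes",
    "draw_preimmune",
    "draw_event_times",
    "calibrate_censoring",
    "generate_dataset",
]

GENETIC_MODELS = ("additive", "dominant", "recessive", "overdominant")

#: Sample size used when calibrating the uniform censoring bound.
CALIBRATION_DRAWS = 100_000
#: Fixed seed of the calibration stream, independent of replicate seeds.
CALIBRATION_SEED = 987_654_321
#: Calibration tolerance on the censored fraction.
CALIBRATION_TOL = 5e-3


def alpha_effects(genetic_model: str, risk: float) -> tuple[float, float]:
    """Affinity effects ``(alpha1, alpha2)`` realising a target risk.

    The target is ``exp(alpha1 G1 + alpha2 G2) = risk`` for the genotype
    group(s) carrying the effect under the given genetic model:
    additive ``(log(risk)/2, 0)``, dominant ``(log(risk)/2,
    log(risk)/2)``, recessive ``(log(risk)/2, -log(risk)/2)``,
    overdominant ``(0, log(risk))``.
    """
    la = math.log(risk)
    table = {
        "additive": (0.5 * la, 0.0),
        "dominant": (0.5 * la, 0.5 * la),
        "recessive": (0.5 * la, -0.5 * la),
        "overdominant": (0.0, la),
    }
    try:
        return table[genetic_model]
    except KeyError:
        raise ValueError(
            f"unknown genetic model {genetic_model!r}; choose from {GENETIC_MODELS}"
        ) from None


def gamma_effects(genetic_model: str, gamma1: float) -> tuple[float, float]:
    """Dispersion effects ``(gamma1, gamma2)`` under a genetic model.

    Follows the dummy-variable taxonomy: additive ``gamma2 = 0``,
    dominant ``gamma2 = gamma1``, recessive ``gamma2 = -gamma1``,
    overdominant ``(0, gamma1)`` (the magnitude then acts on the
    heterozygote only).
    """
    table = {
        "additive": (gamma1, 0.0),
        "dominant": (gamma1, gamma1),
        "recessive": (gamma1, -gamma1),
        "overdominant": (0.0, gamma1),
    }
    try:
        return table[genetic_model]
    except KeyError:
        raise ValueError(
            f"unknown genetic model {genetic_model!r}; choose from {GENETIC_MODELS}"
        ) from None


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration.

    Defaults are the base conditions of the power study: 1000 subjects,
    1000 replications, MAF 0.2, 10% pre-immune in the reference group,
    reference tail defect 0.5, no censoring, 5% nominal level, and all
    genotype effects null.
    """

    n: int = 1000
    replications: int = 1000
    maf: float = 0.2
    preimmune_rate: float = 0.1
    beta: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    tail: float = 0.5
    censoring: float = 0.0
    level: float = 0.05
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF must be in (0, 0.5], got {self.maf}")
        if not (0.0 < self.preimmune_rate < 1.0):
            raise ValueError("pre-immune rate must be in (0, 1)")
        if not (0.0 < self.tail < 1.0):
            raise ValueError("tail defect must be in (0, 1)")
        if not (0.0 <= self.censoring < 1.0):
            raise ValueError("censoring fraction must be in [0, 1)")
        self.params  # trigger the Katz constraint check

    @property
    def omega(self) -> float:
        return -math.log(self.tail)

    @property
    def params(self) -> ModelParams:
        return ModelParams(
            theta=float(logit(self.preimmune_rate)),
            beta=self.beta,
            omega=self.omega,
            tau=1.0,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            gamma1=self.gamma1,
            gamma2=self.gamma2,
        )

    @classmethod
    def from_genetic_models(
        cls,
        *,
        alpha_model: str = "additive",
        alpha_risk: float = 1.0,
        gamma_model: str = "additive",
        gamma1: float = 0.0,
        beta_risk: float = 1.0,
        **kwargs,
    ) -> "Scenario":
        """Build a scenario from genetic-model names and risk ratios.

        ``alpha_risk`` and ``beta_risk`` are the multiplicative effects
        ``e^alpha`` and ``e^beta`` of the study tables; ``gamma1`` is the
        per-allele dispersion shift.
        """
        a1, a2 = alpha_effects(alpha_model, alpha_risk)
        g1, g2 = gamma_effects(gamma_model, gamma1)
        return cls(
            beta=math.log(beta_risk),
            alpha1=a1,
            alpha2=a2,
            gamma1=g1,
            gamma2=g2,
            **kwargs,
        )

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)


def draw_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Allele counts as the sum of two independent Bernoulli(MAF) draws."""
    if not (0.0 < maf < 1.0):
        raise ValueError(f"MAF must be in (0, 1), got {maf}")
    return rng.binomial(2, maf, size=n)


def draw_preimmune(
    g1: np.ndarray, theta: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Pre-immune indicators from the logistic model."""
    p = expit(theta + beta * np.asarray(g1, dtype=float))
    return (rng.random(p.shape[0]) < p).astype(np.int64)


def draw_event_times(
    g1: np.ndarray, g2: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Latent event times (``inf`` for immune-tolerant) per subject."""
    u = 1.0 - rng.random(np.asarray(g1).shape[0])  # uniform on (0, 1]
    return model.invert_survival(u, g1, g2, params)


def _calibration_times(scenario: Scenario) -> np.ndarray:
    """Finite latent event times of a large fixed-seed draw."""
    rng = np.random.default_rng(CALIBRATION_SEED)
    counts = draw_genotypes(CALIBRATION_DRAWS, scenario.maf, rng)
    params = scenario.params
    z = draw_preimmune(counts, params.theta, params.beta, rng)
    g2 = (counts == 1).astype(np.int64)
    t = draw_event_times(counts[z == 0], g2[z == 0], params, rng)
    return t[np.isfinite(t)]


def calibrate_censoring(scenario: Scenario) -> float | None:
    """Uniform upper bound ``c`` hitting the target censored fraction.

    Censoring times are U(0, c); among immune-reactive (finite ``T``)
    subjects the censored fraction is ``E[min(T, c)] / c``, estimated on
    a fixed-seed Monte-Carlo sample and solved for ``c`` by root
    finding.  Returns ``None`` (disabled) for a zero target.
    """
    target = scenario.censoring
    if target == 0.0:
        return None
    t = _calibration_times(scenario)

    def frac(c: float) -> float:
        return float(np.minimum(t, c).mean() / c) - target

    lo, hi = 1e-6, 1.0
    while frac(hi) > 0 and hi < 1e12:
        hi *= 2.0
    if frac(hi) > 0:
        raise RuntimeError(
            f"censoring target {target} unattainable: even c={hi:g} censors "
            "too many immune-reactive subjects"
        )
    c = brentq(frac, lo, hi, xtol=1e-10, rtol=1e-12)
    realized = frac(c) + target
    if abs(realized - target) > CALIBRATION_TOL:
        raise RuntimeError(
            f"censoring calibration failed: realized {realized:.4f} vs target {target}"
        )
    return float(c)


def generate_dataset(
    scenario: Scenario,
    rng: int | np.random.Generator | None = None,
    *,
    censor_bound: float | None = None,
) -> Dataset:
    """Draw one replicate dataset under a scenario.

    Pre-immune subjects get ``(X=0, delta=1, Z=1)``.  Immune-reactive
    subjects get ``X = min(T, C)`` with ``delta = 1{T <= C}``.
    Immune-tolerant subjects are censored at ``C`` when censoring is
    enabled, else at the administrative horizon (one unit past the last
    finite event time).  Pass ``censor_bound`` to reuse a calibrated
    bound across replicates; otherwise it is calibrated on the fly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(scenario.seed if rng is None else rng)
    params = scenario.params
    counts = draw_genotypes(scenario.n, scenario.maf, rng)
    z = draw_preimmune(counts, params.theta, params.beta, rng)
    g2 = (counts == 1).astype(np.int64)
    t = np.zeros(scenario.n)
    t[z == 0] = draw_event_times(counts[z == 0], g2[z == 0], params, rng)

    x = np.zeros(scenario.n)
    delta = np.ones(scenario.n, dtype=np.int64)
    free = z == 0
    if scenario.censoring > 0.0:
        if censor_bound is None:
            censor_bound = calibrate_censoring(scenario)
        c = rng.uniform(0.0, censor_bound, size=scenario.n)
        x[free] = np.minimum(t[free], c[free])
        delta[free] = (t[free] <= c[free]).astype(np.int64)
    else:
        finite = free & np.isfinite(t)
        horizon = 1.0 + (t[finite].max() if finite.any() else 1.0)
        x[free] = np.where(np.isfinite(t[free]), t[free], horizon)
        delta[free] = np.isfinite(t[free]).astype(np.int64)
    # guard the X > 0 contract: a zero uniform draw has measure zero but
    # clip anyway for robustness
    x[free] = np.maximum(x[free], 1e-300)
    return dataset_from_arrays(x, delta, z, counts)
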