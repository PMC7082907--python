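"""The TWIST statistic: a two-part score test for improper survival data.

The null hypothesis is that genotype affects neither the pre-immune
fraction nor the improper survival distribution of the non-pre-immune
subjects (``beta = alpha1 = alpha2 = gamma1 = gamma2 = 0``).  The
statistic is the sum of two score chi-squares:

* ``S1`` — the score test of the genotype effect in the logistic
  pre-immune part: ``V = sum G1_i (Z_i - pi0_hat)`` with the profiled
  information ``J = pi0_hat (1 - pi0_hat) sum (G1_i - mean G1)^2``;
* ``S2`` — a weighted-logrank-type score on the non-pre-immune subjects,
  with components ``U_a = sum_i delta_i W_a(t_i) (g_i - gbar(t_i))``
  for the four null parameters (affinity effects alpha1, alpha2 weighted
  by ``W1``, dispersion effects gamma1, gamma2 weighted by ``W2``;
  covariates G1, G2 respectively), ``gbar(t)`` the at-risk genotype mean
  and the martingale information
  ``I_ab = sum_i delta_i W_a(t_i) W_b(t_i) Cov_risk(g_a, g_b)(t_i)``.

Under the null ``S1 + S2`` is asymptotically chi-square with five degrees
of freedom (1 + 4); degenerate parts (no pre-immune variation, monomorphic
genotype, no heterozygotes) reduce the degrees of freedom and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import Dataset
from .estimators import EstimationError, HazardEstimate, nelson_aalen

__all__ = ["ScoreComponents", "TestResult", "score_logistic", "score_survival", "twist_test"]

#: Relative eigenvalue threshold below which an information direction is
#: treated as null (rank-deficient genotype configuration).
RANK_TOL = 1e-10


@dataclass(frozen=True)
class ScoreComponents:
    """Raw score pieces of the two parts, before combination."""

    v_beta: float
    j_beta: float
    u: np.ndarray  # (U_alpha1, U_alpha2, U_gamma1, U_gamma2)
    info: np.ndarray  # 4x4
    rank: int


@dataclass(frozen=True)
class TestResult:
    """A two-part chi-square test result."""

    statistic: float
    df: int
    p_value: float
    s1: float
    s2: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def row(self, variant_id: str = "variant", dataset: Dataset | None = None) -> dict:
        """One-row serialisation for result tables."""
        out = {"variant_id": variant_id}
        if dataset is not None:
            out.update(
                n=dataset.n,
                n_preimmune=dataset.n_preimmune,
                n_events=dataset.n_events,
            )
        out.update(
            S1=self.s1,
            S2=self.s2,
            statistic=self.statistic,
            df=self.df,
            p_value=self.p_value,
            flags=";".join(self.flags),
        )
        return out


def score_logistic(dataset: Dataset) -> tuple[float, float, tuple[str, ...]]:
    """Score and information of the logistic (pre-immune) part.

    Returns ``(V, J, flags)``.  With the intercept profiled out the score
    is ``V = sum (G1_i - mean G1)(Z_i - pi0_hat)`` — identical to the raw
    ``sum G1_i (Z_i - pi0_hat)`` because the residuals sum to zero — and
    the efficient information is
    ``J = pi0_hat (1 - pi0_hat) sum (G1_i - mean G1)^2``.
    A degenerate part (``pi0_hat`` in {0, 1} or constant ``G1``) yields
    ``J = 0`` with a flag; downstream, ``S1`` is then 0 with one fewer df.
    """
    z = dataset.pre_immune
    g1 = dataset.g1
    pi0 = float(z.mean())
    flags: tuple[str, ...] = ()
    centred = g1 - g1.mean()
    j = pi0 * (1.0 - pi0) * float(centred @ centred)
    v = float(g1 @ (z - pi0))
    if pi0 in (0.0, 1.0) or j == 0.0:
        flags = ("degenerate-logistic-part",)
        return 0.0, 0.0, flags
    return v, j, flags


def score_survival(
    dataset: Dataset, estimate: HazardEstimate | None = None, *, unit_weights: bool = False
) -> ScoreComponents:
    """Score vector and information of the survival part.

    Component order is ``(alpha1, alpha2, gamma1, gamma2)`` with weight
    map ``alpha -> W1``, ``gamma -> W2`` and covariate map
    ``(alpha1, gamma1) -> G1``, ``(alpha2, gamma2) -> G2``.
    ``unit_weights=True`` replaces both weights by 1, which collapses the
    alpha- and gamma-components onto the ordinary logrank score for G1
    and G2 (used by the comparator test and for cross-validation).
    """
    if estimate is None:
        estimate = nelson_aalen(dataset)
    keep = dataset.pre_immune == 0
    x = dataset.time[keep]
    d = dataset.event[keep]
    covs = np.column_stack([dataset.g1[keep], dataset.g2[keep]]).astype(float)

    order = np.argsort(x, kind="stable")
    x, d = x[order], d[order]
    covs = covs[order]

    times = estimate.event_times  # distinct failure times, ascending
    n_ev = estimate.n_events
    y = estimate.n_at_risk.astype(float)
    if unit_weights:
        w1 = w2 = np.ones_like(times)
    else:
        w1, w2 = estimate.weight_pair(times, left=True)

    # suffix sums over the time-sorted sample give at-risk moments
    def suffix(a: np.ndarray) -> np.ndarray:
        return np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])

    risk_start = np.searchsorted(x, times, side="left")
    s_g = np.column_stack([suffix(covs[:, 0])[risk_start], suffix(covs[:, 1])[risk_start]])
    s_gg = np.empty((times.size, 2, 2))
    for a in range(2):
        for b in range(a, 2):
            s_gg[:, a, b] = s_gg[:, b, a] = suffix(covs[:, a] * covs[:, b])[risk_start]
    mean_g = s_g / y[:, None]
    cov_g = s_gg / y[:, None, None] - mean_g[:, :, None] * mean_g[:, None, :]

    # sum of covariates over the tied failures at each distinct time
    ev_time_idx = np.searchsorted(times, x[d == 1])
    s_fail = np.zeros((times.size, 2))
    np.add.at(s_fail, ev_time_idx, covs[d == 1])

    resid = s_fail - n_ev[:, None] * mean_g  # observed minus expected
    w = np.column_stack([w1, w1, w2, w2])  # weight per component
    cov_idx = np.array([0, 1, 0, 1])  # covariate per component
    u = np.array([float(w[:, a] @ resid[:, cov_idx[a]]) for a in range(4)])

    info = np.empty((4, 4))
    for a in range(4):
        for b in range(a, 4):
            info[a, b] = info[b, a] = float(
                np.sum(n_ev * w[:, a] * w[:, b] * cov_g[:, cov_idx[a], cov_idx[b]])
            )

    eigval = np.linalg.eigvalsh(info)
    rank = int(np.sum(eigval > RANK_TOL * max(eigval[-1], 1.0)))
    return ScoreComponents(v_beta=np.nan, j_beta=np.nan, u=u, info=info, rank=rank)


def _quadratic_form(u: np.ndarray, info: np.ndarray) -> tuple[float, int]:
    """``u' pinv(info) u`` with df = numerical rank of ``info``."""
    eigval, eigvec = np.linalg.eigh(info)
    keep = eigval > RANK_TOL * max(eigval[-1], 1.0)
    if not keep.any():
        return 0.0, 0
    proj = eigvec[:, keep].T @ u
    return float(np.sum(proj**2 / eigval[keep])), int(keep.sum())


def twist_test(dataset: Dataset) -> TestResult:
    """Run the TWIST on a dataset: ``S1 + S2`` against chi-square.

    Degrees of freedom are 5 when both parts are fully informative
    (1 for the logistic part + 4 for the survival part); a degenerate
    logistic part drops its df, and a rank-deficient survival
    information (monomorphic genotype, absent heterozygotes, ...) drops
    to its rank, with flags recording the reduction.
    """
    v, j, flags = score_logistic(dataset)
    if j > 0:
        s1 = v * v / j
        df1 = 1
    else:
        s1, df1 = 0.0, 0

    try:
        estimate = nelson_aalen(dataset)
    except EstimationError:
        if df1 == 0:
            raise
        # no failures at all: only the logistic part is testable
        p = float(stats.chi2.sf(s1, df1))
        return TestResult(s1, df1, p, s1, 0.0, flags + ("no-failures",))

    comp = score_survival(dataset, estimate)
    s2, df2 = _quadratic_form(comp.u, comp.info)
    if df2 < 4:
        flags = flags + ("rank-deficient-information",)

    statistic = s1 + s2
    df = df1 + df2
    p_value = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return TestResult(statistic, df, p_value, s1, s2, flags)
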