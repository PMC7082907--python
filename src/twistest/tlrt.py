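"""Two-part logrank comparator test (TLRT).

A two-part test in the style of Lachenbruch's tests for semi-continuous
data, adapted to genotype groups: the first part is the 2-df score test
of equal pre-immune proportions across the three genotype groups
(genotype entered categorically in the logistic model, which makes the
score test the Pearson chi-square of the 2x3 table); the second part is
the k-sample logrank statistic (k = 3 genotype groups, 2 df) on the
non-pre-immune subjects.  The parts are independent score statistics and
their sum is referred to a chi-square with the summed degrees of freedom
(4 when all three genotype groups are present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import Dataset, DatasetError, dataset_from_arrays
from .estimators import nelson_aalen
from .twist import _quadratic_form, score_survival

__all__ = ["TlrtResult", "tlrt_test"]


@dataclass(frozen=True)
class TlrtResult:
    """Result of the two-part logrank test."""

    statistic: float
    df: int
    p_value: float
    binary_part: float
    binary_df: int
    logrank_part: float
    logrank_df: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def row(self, variant_id: str = "variant", dataset: Dataset | None = None) -> dict:
        out = {"variant_id": variant_id}
        if dataset is not None:
            out.update(
                n=dataset.n,
                n_preimmune=dataset.n_preimmune,
                n_events=dataset.n_events,
            )
        out.update(
            S1=self.binary_part,
            S2=self.logrank_part,
            statistic=self.statistic,
            df=self.df,
            p_value=self.p_value,
            flags=";".join(self.flags),
        )
        return out


def _binary_score(dataset: Dataset) -> tuple[float, int, tuple[str, ...]]:
    """Score test of equal pre-immune proportions across genotype groups.

    Uses the pooled ``pi0_hat`` under the null (the same plug-in as the
    TWIST's logistic part).  Equivalent to the Pearson chi-square of the
    pre-immune x genotype contingency table.
    """
    z = dataset.pre_immune
    groups = dataset.allele_count
    pi0 = float(z.mean())
    present = np.unique(groups)
    if pi0 in (0.0, 1.0) or present.size < 2:
        return 0.0, 0, ("degenerate-binary-part",)
    # score components for the non-reference group indicators
    non_ref = present[1:]
    u = np.array([float(z[groups == g].sum() - pi0 * (groups == g).sum()) for g in non_ref])
    n_g = np.array([(groups == g).sum() for g in non_ref], dtype=float)
    info = pi0 * (1.0 - pi0) * (np.diag(n_g) - np.outer(n_g, n_g) / dataset.n)
    s, df = _quadratic_form(u, info)
    return s, df, ()


def _logrank_part(dataset: Dataset) -> tuple[float, int]:
    """k-sample logrank on the non-pre-immune subjects (score form).

    Implemented as the unit-weight survival score restricted to
    group-indicator covariates: with groups recoded as indicator dummies,
    the score vector is the classical observed-minus-expected of each
    non-reference group and the information is the per-event at-risk
    covariance (Breslow convention under ties).
    """
    keep = dataset.pre_immune == 0
    groups = dataset.allele_count[keep]
    present = np.unique(groups)
    if present.size < 2:
        raise DatasetError("all non-pre-immune subjects share one genotype group")
    # recode the two non-reference groups as (G1, G2) = indicator dummies
    # via allele-count relabelling: reference -> 0, others -> 1 resp. 2
    relabel = {g: i for i, g in enumerate(present)}
    recoded = np.array([relabel[g] for g in groups])
    surv = dataset_from_arrays(
        dataset.time[keep],
        dataset.event[keep],
        np.zeros(int(keep.sum()), dtype=int),
        recoded if present.size == 3 else np.where(recoded == 1, 2, 0),
    )
    comp = score_survival(surv, nelson_aalen(surv), unit_weights=True)
    # unit weights make the alpha and gamma components identical; keep the
    # (alpha1, alpha2) pair, whose covariates are (G1, G2).  The group
    # indicators 1{group1} = G2 and 1{group2} = (G1 - G2)/2 span the same
    # space as (G1, G2), and the score quadratic form is invariant under
    # that reparameterisation.
    if present.size == 3:
        u, info = comp.u[:2], comp.info[:2, :2]
    else:
        u, info = comp.u[:1], comp.info[:1, :1]
    return _quadratic_form(u, info)


def tlrt_test(dataset: Dataset) -> TlrtResult:
    """Run the two-part logrank test.

    Requires at least two genotype groups; the logrank part requires at
    least one failure among non-pre-immune subjects.
    """
    if np.unique(dataset.allele_count).size < 2:
        raise DatasetError("TLRT requires at least two genotype groups")
    s_bin, df_bin, flags = _binary_score(dataset)
    s_lr, df_lr = _logrank_part(dataset)
    statistic = s_bin + s_lr
    df = df_bin + df_lr
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return TlrtResult(statistic, df, p, s_bin, df_bin, s_lr, df_lr, flags)
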