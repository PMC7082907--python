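"""Null-hypothesis plug-in estimators for the two-part score test.

All quantities are computed on the pooled sample (genotypes mixed), with
pre-immune subjects excluded from the survival part entirely: the
Nelson-Aalen cumulative hazard with Breslow tie handling, its terminal
value ``omega_hat = Lambda(t_max)`` (the plug-in for the bounded-hazard
ceiling, valid when follow-up is long enough for every immune-reactive
subject to fail), the pre-immune proportion ``pi0_hat``, and the
event-time weights

    W1(t) = 1 - 2 * Lambda(t-) / omega_hat
    W2(t) = 1 -     Lambda(t-) / omega_hat

evaluated on the left-continuous path (the value just before the jump).
W1 drives the affinity (alpha) score components, W2 the dispersion
(gamma) components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Dataset

__all__ = ["HazardEstimate", "EstimationError", "nelson_aalen", "weights", "preimmune_rate"]


class EstimationError(ValueError):
    """Raised when a plug-in estimator is undefined (e.g. no failures)."""


@dataclass(frozen=True)
class HazardEstimate:
    """Left/right-continuous Nelson-Aalen path on the non-pre-immune sample.

    Attributes
    ----------
    event_times
        Ordered distinct failure times among ``Z = 0`` subjects.
    n_events, n_at_risk
        Tied-event count ``d_j`` and risk-set size ``Y_j`` at each time.
    cumhaz
        Right-continuous path ``Lambda(t_j)`` (cumulative ``d_j / Y_j``).
    cumhaz_left
        Left-continuous path ``Lambda(t_j-)`` (pre-jump value).
    omega_hat
        ``Lambda(t_max)``, the terminal (maximum) value.
    pi0_hat
        Observed pre-immune proportion in the full sample.
    """

    event_times: np.ndarray
    n_events: np.ndarray
    n_at_risk: np.ndarray
    cumhaz: np.ndarray
    cumhaz_left: np.ndarray
    omega_hat: float
    pi0_hat: float

    def cumhaz_at(self, t, *, left: bool = False) -> np.ndarray:
        """Evaluate the step path at arbitrary times.

        ``left=True`` returns ``Lambda(t-)``.
        """
        t = np.asarray(t, dtype=float)
        side = "left" if left else "right"
        idx = np.searchsorted(self.event_times, t, side=side)
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]

    def weight_pair(self, t, *, left: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """``(W1, W2)`` at times ``t`` (left-continuous by default)."""
        ratio = self.cumhaz_at(t, left=left) / self.omega_hat
        ratio = np.clip(ratio, 0.0, 1.0)
        return 1.0 - 2.0 * ratio, 1.0 - ratio

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-event-time dump (time, d, Y, Lambda, W1, W2)."""
        ratio = np.clip(self.cumhaz_left / self.omega_hat, 0.0, 1.0)
        return pd.DataFrame(
            {
                "time": self.event_times,
                "d": self.n_events,
                "Y": self.n_at_risk,
                "cumhaz": self.cumhaz,
                "W1": 1.0 - 2.0 * ratio,
                "W2": 1.0 - ratio,
            }
        )


def nelson_aalen(dataset: Dataset) -> HazardEstimate:
    """Nelson-Aalen cumulative hazard on the non-pre-immune subjects.

    Ties are handled Breslow-style: ``d_j`` failures at ``t_j`` with
    ``Y_j`` at risk contribute one increment ``d_j / Y_j``.
    """
    keep = dataset.pre_immune == 0
    x = dataset.time[keep]
    d = dataset.event[keep]
    if x.size == 0 or d.sum() == 0:
        raise EstimationError("no failures; TWIST survival part undefined")
    order = np.argsort(x, kind="stable")
    x, d = x[order], d[order]
    # distinct failure times with tied-event counts and risk-set sizes
    t_event = x[d == 1]
    uniq, first_idx, counts = np.unique(t_event, return_index=True, return_counts=True)
    # risk set: subjects with X >= t (left searchsorted on the sorted pooled times)
    at_risk = x.size - np.searchsorted(x, uniq, side="left")
    increments = counts / at_risk
    cumhaz = np.cumsum(increments)
    cumhaz_left = cumhaz - increments
    return HazardEstimate(
        event_times=uniq,
        n_events=counts,
        n_at_risk=at_risk,
        cumhaz=cumhaz,
        cumhaz_left=cumhaz_left,
        omega_hat=float(cumhaz[-1]),
        pi0_hat=float(dataset.pre_immune.mean()),
    )


def weights(estimate: HazardEstimate, t) -> tuple[np.ndarray, np.ndarray]:
    """Event-time weights ``(W1, W2)`` at ``t``, left-continuous.

    ``W1 = 1 - 2 Lambda(t-)/omega_hat`` ranges over [-1, 1];
    ``W2 = 1 - Lambda(t-)/omega_hat`` over [0, 1]; ``W1 = 2 W2 - 1``.
    """
    return estimate.weight_pair(t, left=True)


def preimmune_rate(dataset: Dataset) -> float:
    """Observed pre-immune proportion ``pi0_hat = #{Z=1} / n``."""
    return float(dataset.pre_immune.mean())
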