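"""Weighted Nelson-Aalen cumulative risk with delta-method confidence limits.

At each distinct event time ``t_i`` let ``d_i`` be the weighted number of
events and ``Y_i`` the weighted number at risk just before ``t_i`` (events
are counted before tied censorings leave the risk set).  The estimator is

    H(t_i) = sum_{j<=i} d_j / Y_j            (cumulative hazard)
    V(t_i) = sum_{j<=i} d_j / Y_j**2         (Poisson-type hazard variance)
    F(t_i) = 1 - exp(-H(t_i))                (cumulative risk)
    SE(F)  = exp(-H) * sqrt(V)               (delta method)

with identity-scale Wald limits ``F ± z * SE``.  Multiplying every case
weight by a common constant ``c`` leaves H and F unchanged and divides
every SE (hence every CL width) by ``sqrt(c)`` — the exact scaling law the
ghost-augmentation procedure exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import special

from .cohort import Cohort

__all__ = ["Z975", "RiskCurve", "nelson_aalen_curve", "risk_at"]

#: exact upper 97.5% standard-normal quantile (not the rounded 1.96)
Z975 = float(special.ndtri(0.975))


@dataclass
class RiskCurve:
    """A cumulative-risk function with pointwise SEs and 95% limits.

    For the nonparametric kind the curve is a right-continuous step
    function over the distinct event times and carries the weighted
    at-risk and event counts; parametric curves are smooth functions
    sampled on a time grid, with ``at_risk``/``events`` unset.
    """

    times: np.ndarray
    risk: np.ndarray
    se: np.ndarray
    cl_lower: np.ndarray
    cl_upper: np.ndarray
    kind: str
    at_risk: Optional[np.ndarray] = None
    events: Optional[np.ndarray] = None
    cum_hazard: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)


def nelson_aalen_curve(cohort: Cohort, z: float = Z975) -> RiskCurve:
    """Weighted Nelson-Aalen cumulative-risk curve for a cohort.

    Parameters
    ----------
    cohort:
        Right-censored weighted survival data with at least one event.
    z:
        Normal quantile for the Wald limits; default the exact 97.5%
        quantile, set ``z=1.96`` for rounded-quantile mimicry.
    """
    t = cohort.time
    e = cohort.event
    w = cohort.weight

    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    w_sorted = w[order]
    is_event = e[order] == 1

    event_times = np.unique(t_sorted[is_event])
    if event_times.size == 0:
        raise ValueError("no event times: cohort contains no events")

    # weighted events d_i at each distinct event time
    ev_t = t_sorted[is_event]
    ev_w = w_sorted[is_event]
    idx = np.searchsorted(event_times, ev_t)
    d = np.zeros(event_times.size)
    np.add.at(d, idx, ev_w)

    # weighted at-risk Y_i = sum of weights with time >= t_i
    total = w_sorted.sum()
    cum_before = np.concatenate(([0.0], np.cumsum(w_sorted)))
    k = np.searchsorted(t_sorted, event_times, side="left")
    at_risk = total - cum_before[k]

    haz = np.cumsum(d / at_risk)
    var = np.cumsum(d / at_risk ** 2)
    surv = np.exp(-haz)
    risk = -np.expm1(-haz)
    se = surv * np.sqrt(var)

    return RiskCurve(
        times=event_times,
        risk=risk,
        se=se,
        cl_lower=risk - z * se,
        cl_upper=risk + z * se,
        kind="nonparametric",
        at_risk=at_risk,
        events=d,
        cum_hazard=haz,
        meta={
            "z": z,
            "variance": "poisson (sum d/Y^2)",
            "n_nominal": cohort.n_nominal,
            "total_weight": total,
        },
    )


def risk_at(curve: RiskCurve, t: float) -> Tuple[float, float, float, float]:
    """Evaluate a risk curve at time ``t``.

    Step curves are right-continuous: the value at the largest tabulated
    time ``<= t`` applies; before the first tabulated time everything is 0.
    Returns ``(risk, se, cl_lower, cl_upper)``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    i = int(np.searchsorted(curve.times, t, side="right")) - 1
    if i < 0:
        return (0.0, 0.0, 0.0, 0.0)
    return (
        float(curve.risk[i]),
        float(curve.se[i]),
        float(curve.cl_lower[i]),
        float(curve.cl_upper[i]),
    )
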