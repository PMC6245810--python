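"""Pseudo-observation ("ghost") augmentation of the nonparametric estimator.

A ghost is a fictitious added subject realized as a uniform weight
increment: adding M ghosts to a cohort of nominal size N multiplies every
case weight by (N + M)/N.  Because the Nelson-Aalen risk is invariant to a
common weight rescaling while every standard error shrinks by
sqrt(1 + M/N), ghosts tighten the confidence limits without perturbing the
estimated curve.  The number M at which the weighted nonparametric CL
width at a chosen time first drops strictly below a parametric model's
width is that model's efficiency advantage expressed as hidden
observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .cohort import Cohort
from .nonparametric import nelson_aalen_curve, risk_at

__all__ = [
    "GhostSearchError",
    "GhostResult",
    "weighted_width",
    "apply_ghost_weights",
    "closed_form_ghosts",
    "iterative_ghost_search",
    "find_ghosts",
]

#: sanity ceiling on the ghost search; the width shrinks as 1/sqrt(M) so the
#: search always terminates, but a target this far below the starting width
#: almost certainly signals a unit error in the inputs
MAX_GHOSTS_DEFAULT = 50_000_000


class GhostSearchError(ValueError):
    """Raised when a ghost search is infeasible or exceeds the sanity ceiling."""


@dataclass
class GhostResult:
    """Outcome of a ghost search at one evaluation time.

    ``weight`` is the final uniform per-subject weight (N + M)/N;
    ``trajectory`` holds the visited ``(m, width)`` pairs when recording
    was requested.
    """

    m: int
    n_nominal: int
    weight: float
    target_width: float
    achieved_width: float
    eval_time: float
    trajectory: Optional[List[Tuple[int, float]]] = field(default=None, repr=False)

    @property
    def effective_sample_size(self) -> float:
        """Nominal size plus ghosts, N + M."""
        return self.n_nominal + self.m


def weighted_width(width0: float, m: int, n_nominal: int) -> float:
    """CL width after adding m ghosts: width0 / sqrt(1 + m/N).

    This is the exact consequence of the weight-scaling law; both the
    iterative search and the closed-form oracle evaluate their stopping
    predicate through this one function so they agree bit for bit.
    """
    return width0 / math.sqrt(1.0 + m / n_nominal)


def apply_ghost_weights(cohort: Cohort, m: int) -> Cohort:
    """Distribute m ghosts uniformly: multiply every weight by (N + m)/N.

    The returned cohort keeps ``n_nominal = N``, so its total weighted size
    is N + m (for a unit-weight input).  The risk curve is unchanged; every
    SE is divided by sqrt(1 + m/N).
    """
    m = int(m)
    if m < 0:
        raise ValueError("ghost count m must be non-negative")
    if m == 0:
        return cohort
    n = cohort.n_nominal
    factor = (n + m) / n
    return Cohort.from_arrays(
        cohort.time,
        cohort.event,
        cohort.weight * factor,
        n_nominal=n,
        label=cohort.label,
    )


def closed_form_ghosts(width0: float, target_width: float, n_nominal: int) -> int:
    """Smallest integer M >= 0 with width0 / sqrt(1 + M/N) < target_width.

    The analytic candidate ``floor(N ((width0/target)^2 - 1)) + 1`` is
    refined by direct predicate evaluation at the neighbouring integers, so
    floating-point boundary cases (exact equality included) are decided by
    the strict inequality itself, never by the formula alone.
    """
    if width0 <= 0 or target_width <= 0:
        raise ValueError("width0 and target_width must be strictly positive")
    if n_nominal < 1:
        raise ValueError("n_nominal must be at least 1")
    if weighted_width(width0, 0, n_nominal) < target_width:
        return 0
    ratio2 = (width0 / target_width) ** 2
    m = int(math.floor(n_nominal * (ratio2 - 1.0))) + 1
    m = max(m, 1)
    while m > 0 and weighted_width(width0, m - 1, n_nominal) < target_width:
        m -= 1
    while not weighted_width(width0, m, n_nominal) < target_width:
        m += 1
    return m


def iterative_ghost_search(
    width0: float,
    target_width: float,
    n_nominal: int,
    max_m: int = MAX_GHOSTS_DEFAULT,
    record_trajectory: bool = False,
) -> Tuple[int, float, Optional[List[Tuple[int, float]]]]:
    """One-by-one ghost search on the scaled width.

    Increments M starting from 0, each step evaluating the weighted width
    through the exact scaling law, and stops at the first M whose width is
    strictly below ``target_width``.  Returns ``(m, achieved_width,
    trajectory)``.  This is the search :func:`closed_form_ghosts` solves
    analytically; the two must agree on every input.
    """
    if width0 <= 0 or target_width <= 0:
        raise GhostSearchError("width0 and target_width must be strictly positive")
    if n_nominal < 1:
        raise GhostSearchError("n_nominal must be at least 1")
    trajectory: Optional[List[Tuple[int, float]]] = [] if record_trajectory else None
    m = 0
    while True:
        width = weighted_width(width0, m, n_nominal)
        if trajectory is not None:
            trajectory.append((m, width))
        if width < target_width:
            return m, width, trajectory
        m += 1
        if m > max_m:
            raise GhostSearchError(
                f"ghost search exceeded the sanity ceiling of {max_m} "
                f"pseudo-observations (width0={width0:g}, target={target_width:g})"
            )


def find_ghosts(
    cohort: Cohort,
    target_width: float,
    eval_time: float,
    record_trajectory: bool = False,
    refit: bool = False,
    max_m: int = MAX_GHOSTS_DEFAULT,
) -> GhostResult:
    """Add ghosts one by one until the nonparametric CL width at
    ``eval_time`` is strictly smaller than ``target_width``.

    By default each step applies the exact scaling law to the unweighted
    width (identical results to refitting, at arithmetic cost); with
    ``refit=True`` the Nelson-Aalen estimator is literally re-run on the
    reweighted cohort at every step, as a slow validation path.
    """
    if target_width <= 0:
        raise GhostSearchError("target_width must be strictly positive")
    base = nelson_aalen_curve(cohort)
    _, _, lo, hi = risk_at(base, eval_time)
    width0 = hi - lo
    if width0 <= 0:
        raise GhostSearchError(
            f"nonparametric CL width undefined at t={eval_time}: "
            "no events at or before the evaluation time"
        )
    n = cohort.n_nominal

    if refit:
        trajectory = [] if record_trajectory else None
        m = 0
        while True:
            curve = nelson_aalen_curve(apply_ghost_weights(cohort, m))
            _, _, lo, hi = risk_at(curve, eval_time)
            width = hi - lo
            if trajectory is not None:
                trajectory.append((m, width))
            if width < target_width:
                break
            m += 1
            if m > max_m:
                raise GhostSearchError(
                    f"ghost search exceeded the sanity ceiling of {max_m} "
                    f"pseudo-observations (width0={width0:g}, target={target_width:g})"
                )
    else:
        m, width, trajectory = iterative_ghost_search(
            width0, target_width, n, max_m=max_m, record_trajectory=record_trajectory
        )

    return GhostResult(
        m=m,
        n_nominal=n,
        weight=1.0 + m / n,
        target_width=float(target_width),
        achieved_width=width,
        eval_time=float(eval_time),
        trajectory=trajectory,
    )
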