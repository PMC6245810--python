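"""Core data types for right-censored, case-weighted survival data.

A cohort is a flat table of subjects, each with a follow-up time (years
from the study origin), an event indicator (1 = the composite endpoint
occurred at that time, 0 = censored), and a positive case weight.  Weights
default to 1 and are real-valued: the ghost-augmentation machinery relies
on uniform fractional weights such as 1 + M/N.

On-disk format is delimited text (CSV by default) with a header row;
round-tripping through :func:`write_cohort` / :func:`read_cohort` preserves
times, events and weights exactly (17 significant digits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortError", "Observation", "Cohort", "read_cohort", "write_cohort"]


class CohortError(ValueError):
    """Raised when survival data violate the cohort invariants."""


@dataclass(frozen=True)
class Observation:
    """One subject's follow-up record.

    Parameters
    ----------
    time:
        Follow-up duration in years; strictly positive and finite.
    event:
        1 if the endpoint (e.g. AIDS or death) occurred at `time`,
        0 if follow-up was censored there.
    weight:
        Case weight, strictly positive and finite.  Default 1.
    """

    time: float
    event: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.time, (int, float)) and math.isfinite(self.time)):
            raise CohortError(f"time must be a finite number, got {self.time!r}")
        if self.time <= 0:
            raise CohortError(f"time must be strictly positive, got {self.time!r}")
        if self.event not in (0, 1):
            raise CohortError(f"event indicator must be 0 or 1, got {self.event!r}")
        if not (isinstance(self.weight, (int, float)) and math.isfinite(self.weight)):
            raise CohortError(f"weight must be a finite number, got {self.weight!r}")
        if self.weight <= 0:
            raise CohortError(f"weight must be strictly positive, got {self.weight!r}")


class Cohort:
    """A weighted collection of right-censored observations.

    `n_nominal` is the unweighted head count N of the original sample; it
    stays fixed when ghost weights inflate the total weighted size beyond N.
    """

    def __init__(
        self,
        observations: Iterable[Observation],
        n_nominal: Optional[int] = None,
        label: str = "",
    ) -> None:
        obs = tuple(observations)
        if not obs:
            raise CohortError("cohort must contain at least one observation")
        time = np.array([o.time for o in obs], dtype=float)
        event = np.array([o.event for o in obs], dtype=np.int64)
        weight = np.array([o.weight for o in obs], dtype=float)
        self._init_from_arrays(time, event, weight, n_nominal, label)

    # -- construction -----------------------------------------------------

    def _init_from_arrays(self, time, event, weight, n_nominal, label) -> None:
        self._time = time
        self._event = event
        self._weight = weight
        self.n_nominal = int(n_nominal) if n_nominal is not None else len(time)
        if self.n_nominal < 1:
            raise CohortError("n_nominal must be at least 1")
        self.label = label

    @classmethod
    def from_arrays(
        cls,
        time: Sequence[float],
        event: Sequence[int],
        weight: Optional[Sequence[float]] = None,
        n_nominal: Optional[int] = None,
        label: str = "",
    ) -> "Cohort":
        """Vectorised constructor; validates the same invariants as
        :class:`Observation` and reports the first offending row (1-based)."""
        time = np.asarray(time, dtype=float)
        event_arr = np.asarray(event)
        if weight is None:
            weight_arr = np.ones_like(time)
        else:
            weight_arr = np.asarray(weight, dtype=float)
        if time.ndim != 1 or time.size == 0:
            raise CohortError("cohort must contain at least one observation")
        if not (event_arr.shape == time.shape and weight_arr.shape == time.shape):
            raise CohortError("time, event and weight must have equal length")

        bad = ~(np.isfinite(time) & (time > 0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortError(
                f"row {row}: time must be a strictly positive finite number, "
                f"got {time[bad][0]!r}"
            )
        if not np.isin(event_arr, (0, 1)).all():
            bad = ~np.isin(event_arr, (0, 1))
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortError(
                f"row {row}: event indicator must be 0 or 1, got {event_arr[bad][0]!r}"
            )
        bad = ~(np.isfinite(weight_arr) & (weight_arr > 0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortError(
                f"row {row}: weight must be a strictly positive finite number, "
                f"got {weight_arr[bad][0]!r}"
            )

        self = cls.__new__(cls)
        self._init_from_arrays(
            time.copy(),
            event_arr.astype(np.int64),
            weight_arr.copy(),
            n_nominal,
            label,
        )
        return self

    # -- accessors --------------------------------------------------------

    @property
    def time(self) -> np.ndarray:
        """Follow-up times (years); treat as read-only."""
        return self._time

    @property
    def event(self) -> np.ndarray:
        """Event indicators (0/1); treat as read-only."""
        return self._event

    @property
    def weight(self) -> np.ndarray:
        """Case weights; treat as read-only."""
        return self._weight

    @property
    def observations(self) -> tuple:
        return tuple(
            Observation(float(t), int(e), float(w))
            for t, e, w in zip(self._time, self._event, self._weight)
        )

    @property
    def total_weight(self) -> float:
        """Total weighted size, Σ weight."""
        return float(self._weight.sum())

    @property
    def n_events(self) -> float:
        """Weighted number of events, Σ weight · event."""
        return float(self._weight[self._event == 1].sum())

    def __len__(self) -> int:
        return len(self._time)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.n_nominal == other.n_nominal
            and np.array_equal(self._time, other._time)
            and np.array_equal(self._event, other._event)
            and np.array_equal(self._weight, other._weight)
        )

    def __repr__(self) -> str:
        return (
            f"Cohort(n={len(self)}, n_nominal={self.n_nominal}, "
            f"events={self.n_events:g}, total_weight={self.total_weight:g}, "
            f"label={self.label!r})"
        )

    def with_weights(self, weight: Sequence[float]) -> "Cohort":
        """Copy of the cohort with replaced case weights (same n_nominal)."""
        return Cohort.from_arrays(
            self._time, self._event, weight, n_nominal=self.n_nominal, label=self.label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self._time, "event": self._event, "weight": self._weight}
        )


def read_cohort(
    path,
    time_column: str = "time",
    event_column: str = "event",
    weight_column: Optional[str] = "weight",
    delimiter: str = ",",
) -> Cohort:
    """Read a cohort from delimited text.

    The file must have a header row naming `time_column` and `event_column`.
    If `weight_column` is absent from the file (or passed as None) every
    weight is 1.  Rows violating the observation invariants are rejected
    with their 1-based data-row index.
    """
    try:
        # round_trip parsing so 17-significant-digit output re-reads bit for bit
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise CohortError(f"{path}: no data rows")
    for col in (time_column, event_column):
        if col not in df.columns:
            raise CohortError(f"{path}: missing required column {col!r}")

    time = pd.to_numeric(df[time_column], errors="coerce").to_numpy(dtype=float)
    if np.isnan(time).any():
        row = int(np.flatnonzero(np.isnan(time))[0]) + 1
        raise CohortError(f"{path}: row {row}: non-numeric time {df[time_column].iloc[row - 1]!r}")
    event = pd.to_numeric(df[event_column], errors="coerce").to_numpy(dtype=float)
    if np.isnan(event).any():
        row = int(np.flatnonzero(np.isnan(event))[0]) + 1
        raise CohortError(f"{path}: row {row}: non-numeric event {df[event_column].iloc[row - 1]!r}")

    weight = None
    if weight_column is not None and weight_column in df.columns:
        weight = pd.to_numeric(df[weight_column], errors="coerce").to_numpy(dtype=float)
        if np.isnan(weight).any():
            row = int(np.flatnonzero(np.isnan(weight))[0]) + 1
            raise CohortError(
                f"{path}: row {row}: non-numeric weight {df[weight_column].iloc[row - 1]!r}"
            )

    try:
        return Cohort.from_arrays(time, event, weight, label=str(path))
    except CohortError as err:
        raise CohortError(f"{path}: {err}") from None


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text with columns time, event, weight.

    Floats are written with 17 significant digits so a re-read reproduces
    them bit for bit.
    """
    cohort.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")
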