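"""Event-record data containers: the unit of estimation.

A :class:`SubjectRecord` carries one patient's dosing history, observed
concentrations and covariates (body weight plus named continuous
laboratory values and binary co-medication flags).  An
:class:`EventDataset` is the collection used for estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseEvent", "Observation", "SubjectRecord", "EventDataset"]

_WEIGHT_SANITY = (20.0, 200.0)  # kg


@dataclass(frozen=True)
class DoseEvent:
    """One dose record: ``amount`` mg given at ``time`` h.

    ``n_doses > 1`` encodes a train of equally spaced doses starting at
    ``time``; ``ss=True`` marks the regimen as already at steady state at
    ``time`` (interval required in both cases).
    """

    time: float
    amount: float
    interval: float | None = None
    n_doses: int = 1
    ss: bool = False

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if (self.ss or self.n_doses > 1) and (self.interval is None or self.interval <= 0):
            raise ValueError("steady-state or multi-dose events need a positive interval")


@dataclass(frozen=True)
class Observation:
    """One observed concentration: ``value`` ng/mL at ``time`` h."""

    time: float
    value: float


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    weight: float
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.weight <= 0:
            raise ValueError(f"subject {self.id}: weight must be positive")
        if not (_WEIGHT_SANITY[0] <= self.weight <= _WEIGHT_SANITY[1]):
            warnings.warn(
                f"subject {self.id}: weight {self.weight} kg outside sanity "
                f"range {_WEIGHT_SANITY}",
                stacklevel=2,
            )
        times = [e.time for e in self.doses] + [o.time for o in self.observations]
        if any(t < 0 for t in times):
            raise ValueError(f"subject {self.id}: negative event time")
        obs_t = [o.time for o in self.observations]
        if any(b < a for a, b in zip(obs_t, obs_t[1:])):
            raise ValueError(f"subject {self.id}: observation times must be non-decreasing")

    @property
    def n_obs(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class EventDataset:
    """A collection of subjects; the unit of population estimation."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def estimation_subjects(self) -> tuple[SubjectRecord, ...]:
        """Subjects usable for estimation (at least one observation)."""
        return tuple(s for s in self.subjects if s.n_obs >= 1)

    def subset(self, indices) -> "EventDataset":
        """A new dataset from subject positions (with repeats, for bootstrap)."""
        subs = []
        for k, i in enumerate(indices):
            s = self.subjects[i]
            # re-label so bootstrap repeats remain distinct subjects
            subs.append(
                SubjectRecord(
                    id=f"{s.id}#{k}" if list(indices).count(i) > 1 else s.id,
                    weight=s.weight,
                    doses=s.doses,
                    observations=s.observations,
                    covariates=dict(s.covariates),
                )
            )
        return EventDataset(tuple(subs))

    def covariate_values(self, name: str) -> np.ndarray:
        out = []
        for s in self.subjects:
            if name == "weight":
                out.append(s.weight)
            elif name in s.covariates:
                out.append(s.covariates[name])
            else:
                from .popmodel import MissingCovariateError

                raise MissingCovariateError(
                    f"subject {s.id} lacks covariate {name!r}"
                )
        return np.asarray(out, dtype=float)
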