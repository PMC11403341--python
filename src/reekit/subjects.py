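"""Subject records and anthropometric derivations.

A :class:`Subject` is one adult with the four predictors every equation in
the registry may require — sex, age (years), weight (kg), height (cm) —
plus, optionally, resting energy expenditure measured by indirect
calorimetry (kcal/day). The supported domain is healthy adults aged
18–60 y; ages outside that range trigger a :class:`DomainWarning`, not an
error, because the equations extrapolate smoothly even if their validity
does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

MALE = "male"
FEMALE = "female"

SUPPORTED_AGE_RANGE = (18.0, 60.0)


class DomainWarning(UserWarning):
    """Subject lies outside the 18-60 y adult domain the equations cover."""


class InvalidSubjectError(ValueError):
    """Subject field violates a hard invariant (non-positive weight etc.)."""


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight in kg and height in cm.

    Raises
    ------
    InvalidSubjectError
        If weight or height is not strictly positive (or not finite).
    """
    weight = float(weight)
    height = float(height)
    if not (weight > 0) or not (height > 0):
        raise InvalidSubjectError(
            f"weight and height must be > 0, got weight={weight}, height={height}"
        )
    bmi = weight / (height / 100.0) ** 2
    if not (bmi > 0) or bmi != bmi or bmi == float("inf"):
        raise InvalidSubjectError(f"BMI is not finite/positive: {bmi}")
    return bmi


def _normalise_sex(sex: str) -> str:
    token = str(sex).strip().lower()
    if token in ("m", "male", "1"):
        return MALE
    if token in ("f", "female", "0"):
        return FEMALE
    raise InvalidSubjectError(f"unknown sex token: {sex!r}")


@dataclass(frozen=True)
class Subject:
    """One study participant.

    Parameters
    ----------
    id : str
        Opaque identifier (row number, study code, ...).
    sex : {"male", "female"}
        Accepts "M"/"F" case-insensitively at construction.
    age : float
        Age in years. Values outside [18, 60] emit :class:`DomainWarning`.
    weight : float
        Body weight in kg, > 0.
    height : float
        Standing height in cm, > 0.
    ree_measured : float, optional
        Resting energy expenditure from indirect calorimetry, kcal/day, > 0.
    """

    id: str
    sex: str
    age: float
    weight: float
    height: float
    ree_measured: Optional[float] = None
    bmi: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", _normalise_sex(self.sex))
        object.__setattr__(self, "age", float(self.age))
        object.__setattr__(self, "weight", float(self.weight))
        object.__setattr__(self, "height", float(self.height))
        object.__setattr__(self, "bmi", compute_bmi(self.weight, self.height))
        lo, hi = SUPPORTED_AGE_RANGE
        if not (lo <= self.age <= hi):
            warnings.warn(
                f"subject {self.id!r}: age {self.age} y outside supported "
                f"domain [{lo}, {hi}]",
                DomainWarning,
                stacklevel=3,
            )
        if self.ree_measured is not None:
            ree = float(self.ree_measured)
            if not ree > 0:
                raise InvalidSubjectError(
                    f"subject {self.id!r}: measured REE must be > 0, got {ree}"
                )
            object.__setattr__(self, "ree_measured", ree)

    @property
    def is_male(self) -> bool:
        return self.sex == MALE


def require_measured(cohort: Iterable[Subject]) -> list[Subject]:
    """Return the cohort as a list, insisting every subject has measured REE."""
    subjects = list(cohort)
    missing = [s.id for s in subjects if s.ree_measured is None]
    if missing:
        raise InvalidSubjectError(
            f"{len(missing)} subject(s) lack measured REE (e.g. {missing[:5]})"
        )
    return subjects
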