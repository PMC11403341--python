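"""Registry of resting-energy-expenditure predictive equations.

Every equation is stored declaratively: a list of strata (a predicate on
sex, age and BMI plus one coefficient row) together with its sex coding and
output unit. Evaluation is the same generic routine for all of them —
select the single matching stratum, evaluate the (possibly power-law)
linear form, convert to kcal/day. Coefficients are stored exactly as
published; nothing is re-derived.

The registry holds 20 equations: 19 literature variants (FAO/WHO/UNU and
Frankenfield each contribute two — with and without height) plus the
weight/sex/age equation developed by this package's split-sample workflow
(`new_equation`, see :mod:`reekit.development`).

Sex codings differ across the literature and are stored per equation:
most indicator equations use male = 1 / female = 0, but de la Cruz Marcos
codes female = 1, and Ganpule subtracts its sex term for women only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .subjects import FEMALE, MALE, Subject

__all__ = [
    "CoefficientRow",
    "Stratum",
    "EquationSpec",
    "Prediction",
    "ConsistencyError",
    "list_equations",
    "get_equation",
    "predict",
    "predict_cohort",
    "group_mean_prediction",
    "registry_to_json",
    "KCAL_PER_MJ",
]

#: thermochemical calorie: 1 MJ = 1000/4.184 kcal
KCAL_PER_MJ = 1000.0 / 4.184


class ConsistencyError(RuntimeError):
    """Registry internal invariant violated (no or multiple strata match)."""


@dataclass(frozen=True)
class CoefficientRow:
    """One linear (or power-law) coefficient row, in the equation's raw unit.

    ``raw = weight*WT**weight_exponent + height*HT + age*AGE + sex*S + intercept``
    where ``S`` is the 0/1 sex indicator under the spec's coding.
    """

    weight: float = 0.0
    height: float = 0.0
    age: float = 0.0
    sex: float = 0.0
    intercept: float = 0.0
    weight_exponent: float = 1.0

    def evaluate(self, wt: float, ht: float, age: float, sex_indicator: float) -> float:
        return (
            self.weight * wt**self.weight_exponent
            + self.height * ht
            + self.age * age
            + self.sex * sex_indicator
            + self.intercept
        )


@dataclass(frozen=True)
class Stratum:
    """Predicate on (sex, age, BMI) paired with a coefficient row.

    Interval bounds are None for unbounded; inclusivity flags resolve the
    boundary conventions (age 30 belongs to the older stratum, BMI 18.5 to
    the normal-weight stratum, BMI 30 to the obese stratum where the
    equation splits there).
    """

    row: CoefficientRow
    sex: Optional[str] = None  # "male"/"female"/None (any)
    age_lo: Optional[float] = None
    age_hi: Optional[float] = None
    age_lo_incl: bool = True
    age_hi_incl: bool = False
    bmi_lo: Optional[float] = None
    bmi_hi: Optional[float] = None
    bmi_lo_incl: bool = True
    bmi_hi_incl: bool = False

    def matches(self, subject: Subject) -> bool:
        if self.sex is not None and subject.sex != self.sex:
            return False
        for value, lo, hi, lo_incl, hi_incl in (
            (subject.age, self.age_lo, self.age_hi, self.age_lo_incl, self.age_hi_incl),
            (subject.bmi, self.bmi_lo, self.bmi_hi, self.bmi_lo_incl, self.bmi_hi_incl),
        ):
            if lo is not None and (value < lo or (value == lo and not lo_incl)):
                return False
            if hi is not None and (value > hi or (value == hi and not hi_incl)):
                return False
        return True


@dataclass(frozen=True)
class EquationSpec:
    """One predictive equation: metadata, sex coding, unit, strata."""

    id: str
    display_name: str
    required_inputs: frozenset[str]
    strata: tuple[Stratum, ...]
    #: "male=1", "female=1", or "stratified" (separate rows per sex)
    sex_coding: str
    #: raw output unit before conversion
    output_unit: str = "kcal/day"
    #: multiply raw output by this to obtain kcal/day
    conversion_to_kcal: float = 1.0

    def sex_indicator(self, sex: str) -> float:
        if self.sex_coding == "male=1":
            return 1.0 if sex == MALE else 0.0
        if self.sex_coding == "female=1":
            return 1.0 if sex == FEMALE else 0.0
        return 0.0  # stratified: rows are sex-specific already

    def matching_stratum(self, subject: Subject) -> Stratum:
        hits = [s for s in self.strata if s.matches(subject)]
        if len(hits) != 1:
            raise ConsistencyError(
                f"equation {self.id!r}: {len(hits)} strata match subject "
                f"{subject.id!r} (sex={subject.sex}, age={subject.age}, "
                f"bmi={subject.bmi:.2f})"
            )
        return hits[0]


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    equation_id: str
    ree_predicted: float  # kcal/day


def predict(spec: EquationSpec, subject: Subject) -> Prediction:
    """Evaluate one equation for one subject, in kcal/day."""
    stratum = spec.matching_stratum(subject)
    raw = stratum.row.evaluate(
        subject.weight, subject.height, subject.age, spec.sex_indicator(subject.sex)
    )
    kcal = raw * spec.conversion_to_kcal
    if not math.isfinite(kcal):
        raise ConsistencyError(
            f"equation {spec.id!r} produced non-finite prediction for "
            f"subject {subject.id!r}"
        )
    return Prediction(subject.id, spec.id, kcal)


def predict_cohort(spec: EquationSpec, subjects: Iterable[Subject]) -> list[Prediction]:
    """Element-wise :func:`predict`; order and length preserved."""
    out = []
    for s in subjects:
        try:
            out.append(predict(spec, s))
        except Exception as exc:
            raise type(exc)(f"subject {s.id!r}: {exc}") from exc
    return out


def group_mean_prediction(
    spec: EquationSpec,
    weight: float,
    height: float,
    age: float,
    male_fraction: float,
) -> float:
    """Group-mean prediction from group-mean inputs and sex composition.

    For equations linear in weight/height/age with either an additive sex
    indicator or per-sex coefficient rows (and no age/BMI strata crossed by
    the group), the mean of per-subject predictions equals the prediction
    at the mean inputs averaged over the sex mix — so Table-style group
    means are reproducible from printed summary statistics alone.
    """
    male = Subject("group-male", MALE, age, weight, height)
    female = Subject("group-female", FEMALE, age, weight, height)
    return (
        male_fraction * predict(spec, male).ree_predicted
        + (1.0 - male_fraction) * predict(spec, female).ree_predicted
    )


def _sex_rows(male: CoefficientRow, female: CoefficientRow) -> tuple[Stratum, ...]:
    return (Stratum(row=male, sex=MALE), Stratum(row=female, sex=FEMALE))


def _sex_age_rows(
    rows: dict[tuple[str, str], CoefficientRow]
) -> tuple[Stratum, ...]:
    """Rows keyed by (sex, "young"/"old"); age split [18,30) / [30,60]."""
    out = []
    for (sex, band), row in rows.items():
        if band == "young":
            out.append(Stratum(row=row, sex=sex, age_hi=30.0, age_hi_incl=False))
        else:
            out.append(Stratum(row=row, sex=sex, age_lo=30.0, age_lo_incl=True))
    return tuple(out)


def _build_registry() -> tuple[EquationSpec, ...]:
    R = CoefficientRow
    specs: list[EquationSpec] = []

    specs.append(
        EquationSpec(
            id="harris_benedict",
            display_name="Harris and Benedict",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="stratified",
            strata=_sex_rows(
                R(weight=13.7516, height=5.0033, age=-6.755, intercept=66.473),
                R(weight=9.5634, height=1.8496, age=-4.6756, intercept=655.0955),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="roza_shizgal",
            display_name="Roza and Shizgal",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="stratified",
            strata=_sex_rows(
                R(weight=13.397, height=4.799, age=-5.677, intercept=88.362),
                R(weight=9.247, height=3.098, age=-4.33, intercept=477.593),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="fao_who_unu_weight",
            display_name="FAO/WHO/UNU, weight",
            required_inputs=frozenset({"sex", "age", "weight"}),
            sex_coding="stratified",
            strata=_sex_age_rows(
                {
                    (MALE, "young"): R(weight=15.3, intercept=679),
                    (MALE, "old"): R(weight=11.6, intercept=879),
                    (FEMALE, "young"): R(weight=14.7, intercept=496),
                    (FEMALE, "old"): R(weight=8.7, intercept=829),
                }
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="fao_who_unu_weight_height",
            display_name="FAO/WHO/UNU, weight and height",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="stratified",
            strata=_sex_age_rows(
                {
                    (MALE, "young"): R(weight=15.4, height=0.27, intercept=717),
                    (MALE, "old"): R(weight=11.3, height=0.16, intercept=901),
                    (FEMALE, "young"): R(weight=13.3, height=3.34, intercept=35),
                    (FEMALE, "old"): R(weight=8.7, height=-0.25, intercept=865),
                }
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="schofield",
            display_name="Schofield",
            required_inputs=frozenset({"sex", "age", "weight"}),
            sex_coding="stratified",
            strata=_sex_age_rows(
                {
                    (MALE, "young"): R(weight=15.057, intercept=692.2),
                    (MALE, "old"): R(weight=11.472, intercept=873.1),
                    (FEMALE, "young"): R(weight=14.818, intercept=486.6),
                    (FEMALE, "old"): R(weight=8.126, intercept=845.6),
                }
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="owen",
            display_name="Owen et al.",
            required_inputs=frozenset({"sex", "weight"}),
            sex_coding="stratified",
            strata=_sex_rows(
                R(weight=10.2, intercept=879),
                R(weight=7.18, intercept=795),
            ),
        )
    )
    # Original Mifflin-St Jeor constants (+5 male, -161 female); see docs.
    specs.append(
        EquationSpec(
            id="mifflin",
            display_name="Mifflin-St Jeor",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="stratified",
            strata=_sex_rows(
                R(weight=10, height=6.25, age=-5, intercept=5),
                R(weight=10, height=6.25, age=-5, intercept=-161),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="de_lorenzo",
            display_name="De Lorenzo et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="stratified",
            output_unit="kJ/day",
            conversion_to_kcal=1.0 / 4.184,
            strata=_sex_rows(
                R(weight=53.284, height=20.957, age=-23.859, intercept=487),
                R(weight=46.322, height=15.744, age=-16.66, intercept=944),
            ),
        )
    )
    # Mueller: MJ/day, BMI-stratified, additive male=1 indicator.
    specs.append(
        EquationSpec(
            id="muller",
            display_name="Mueller et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height", "bmi"}),
            sex_coding="male=1",
            output_unit="MJ/day",
            conversion_to_kcal=KCAL_PER_MJ,
            strata=(
                Stratum(
                    row=R(weight=0.07122, age=-0.02149, sex=0.82, intercept=0.731),
                    bmi_hi=18.5,
                    bmi_hi_incl=False,
                ),
                Stratum(
                    row=R(
                        weight=0.02219,
                        height=0.02118,
                        sex=0.884,
                        age=-0.01191,
                        intercept=1.233,
                    ),
                    bmi_lo=18.5,
                    bmi_lo_incl=True,
                    bmi_hi=25.0,
                    bmi_hi_incl=True,
                ),
                Stratum(
                    row=R(weight=0.04507, sex=1.006, age=-0.01553, intercept=3.407),
                    bmi_lo=25.0,
                    bmi_lo_incl=False,
                    bmi_hi=30.0,
                    bmi_hi_incl=True,
                ),
                Stratum(
                    row=R(weight=0.05, age=-0.01586, sex=1.103, intercept=2.924),
                    bmi_lo=30.0,
                    bmi_lo_incl=False,
                ),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="livingston",
            display_name="Livingston and Kohlstadt",
            required_inputs=frozenset({"sex", "age", "weight"}),
            sex_coding="stratified",
            strata=_sex_rows(
                R(weight=293, weight_exponent=0.433, age=-5.92),
                R(weight=248, weight_exponent=0.4356, age=-5.09),
            ),
        )
    )
    # Ganpule: single kJ row; the 547.3 sex term is subtracted for women.
    specs.append(
        EquationSpec(
            id="ganpule",
            display_name="Ganpule et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="female=1",
            output_unit="kJ/day",
            conversion_to_kcal=1.0 / 4.186,
            strata=(
                Stratum(
                    row=R(
                        weight=48.1, height=23.4, age=-13.8, sex=-547.3, intercept=-423.5
                    )
                ),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="korth",
            display_name="Korth et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="male=1",
            output_unit="kJ/day",
            conversion_to_kcal=1.0 / 4.184,
            strata=(
                Stratum(
                    row=R(
                        weight=41.5, height=35.0, sex=1107.4, age=-19.1, intercept=-1731.2
                    )
                ),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="frankenfield_no_height",
            display_name="Frankenfield et al., without height",
            required_inputs=frozenset({"sex", "age", "weight", "bmi"}),
            sex_coding="male=1",
            strata=(
                Stratum(
                    row=R(weight=10, age=-5, sex=274, intercept=865),
                    bmi_lo=30.0,
                    bmi_lo_incl=True,
                ),
                Stratum(
                    row=R(weight=11, age=-6, sex=230, intercept=838),
                    bmi_hi=30.0,
                    bmi_hi_incl=False,
                ),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="frankenfield_height",
            display_name="Frankenfield et al., with height",
            required_inputs=frozenset({"sex", "age", "weight", "height", "bmi"}),
            sex_coding="male=1",
            strata=(
                Stratum(
                    row=R(weight=10, height=3, age=-5, sex=244, intercept=440),
                    bmi_lo=30.0,
                    bmi_lo_incl=True,
                ),
                Stratum(
                    row=R(weight=10, height=3, age=-5, sex=207, intercept=454),
                    bmi_hi=30.0,
                    bmi_hi_incl=False,
                ),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="de_la_cruz_marcos",
            display_name="de la Cruz Marcos et al.",
            required_inputs=frozenset({"sex", "age", "weight"}),
            sex_coding="female=1",
            strata=(
                Stratum(row=R(intercept=1376.4, sex=-308, weight=11.1, age=-8)),
            ),
        )
    )
    # Nikooyeh: age-stratified; the published 18-30 y rows carry a positive
    # age coefficient (+27.5/y) and are implemented exactly as published.
    specs.append(
        EquationSpec(
            id="nikooyeh",
            display_name="Nikooyeh et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="stratified",
            strata=_sex_age_rows(
                {
                    (MALE, "young"): R(height=8.4, weight=5, age=27.5, intercept=-869.7),
                    (MALE, "old"): R(
                        height=7.8, weight=12.5, age=-5.64, intercept=-349.9
                    ),
                    (FEMALE, "young"): R(
                        height=8.4, weight=5, age=27.5, intercept=-979.7
                    ),
                    (FEMALE, "old"): R(
                        height=7.8, weight=12.5, age=-5.64, intercept=-455.4
                    ),
                }
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="fairoosa",
            display_name="Fairoosa et al.",
            required_inputs=frozenset({"sex", "weight"}),
            sex_coding="male=1",
            strata=(Stratum(row=R(intercept=284.5, weight=13.2, sex=133.0)),),
        )
    )
    specs.append(
        EquationSpec(
            id="marra",
            display_name="Marra et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="male=1",
            strata=(
                Stratum(
                    row=R(intercept=70.4, weight=12.1, height=3.83, sex=139, age=-1.82)
                ),
            ),
        )
    )
    specs.append(
        EquationSpec(
            id="nichols",
            display_name="Nichols et al.",
            required_inputs=frozenset({"sex", "age", "weight", "height"}),
            sex_coding="male=1",
            strata=(
                Stratum(
                    row=R(
                        intercept=295.92, sex=171.29, age=-5.89, weight=10.52, height=3.30
                    )
                ),
            ),
        )
    )
    # Equation developed by this package's split-sample workflow (Tehran
    # adult cohort, weight/sex/age retained by stepwise selection).
    specs.append(
        EquationSpec(
            id="new_equation",
            display_name="New equation",
            required_inputs=frozenset({"sex", "age", "weight"}),
            sex_coding="male=1",
            strata=(
                Stratum(
                    row=R(weight=8.957, sex=280.613, age=-7.795, intercept=1039.837)
                ),
            ),
        )
    )

    ids = [s.id for s in specs]
    assert len(ids) == len(set(ids)) == 20
    return tuple(specs)


_REGISTRY: tuple[EquationSpec, ...] = _build_registry()
_BY_ID = {s.id: s for s in _REGISTRY}


def list_equations() -> tuple[EquationSpec, ...]:
    """All registry entries, one per published equation variant, in table order."""
    return _REGISTRY


def get_equation(equation_id: str) -> EquationSpec:
    try:
        return _BY_ID[equation_id]
    except KeyError:
        raise KeyError(
            f"unknown equation id {equation_id!r}; known: {sorted(_BY_ID)}"
        ) from None


def registry_to_json(specs: Optional[Sequence[EquationSpec]] = None) -> list[dict]:
    """Serialise the registry for audit (ids, strata, coefficients, units)."""
    out = []
    for spec in specs if specs is not None else _REGISTRY:
        out.append(
            {
                "id": spec.id,
                "display_name": spec.display_name,
                "required_inputs": sorted(spec.required_inputs),
                "sex_coding": spec.sex_coding,
                "output_unit": spec.output_unit,
                "conversion_to_kcal": spec.conversion_to_kcal,
                "strata": [
                    {
                        "sex": s.sex,
                        "age": [s.age_lo, s.age_hi, s.age_lo_incl, s.age_hi_incl],
                        "bmi": [s.bmi_lo, s.bmi_hi, s.bmi_lo_incl, s.bmi_hi_incl],
                        "coefficients": {
                            "weight": s.row.weight,
                            "weight_exponent": s.row.weight_exponent,
                            "height": s.row.height,
                            "age": s.row.age,
                            "sex": s.row.sex,
                            "intercept": s.row.intercept,
                        },
                    }
                    for s in spec.strata
                ],
            }
        )
    return out
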