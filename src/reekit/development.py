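"""Split-sample development of a new REE prediction equation.

The workflow mirrors standard practice for deriving anthropometric
prediction equations: randomly halve the cohort into development and
validation groups, check the halves are comparable (independent-samples t
for continuous variables, Pearson chi-square for sex), then run classic
stepwise multivariable linear regression of measured REE on age, sex,
weight and height in the development half. The selected model is wrapped
as a registry-compatible equation so the validation battery treats it
exactly like the published equations.

Stepwise selection uses the SPSS-style criteria: at each step the
not-yet-included candidate with the smallest partial-F p-value enters if
p <= p_enter (default 0.05), then any included predictor with p >= p_remove
(default 0.10) is removed. With p_enter = 1 and p_remove > 1 the procedure
degenerates to ordinary least squares on all candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .equations import CoefficientRow, EquationSpec, Stratum
from .subjects import MALE, Subject, require_measured

__all__ = [
    "SplitResult",
    "GroupComparison",
    "RegressionFit",
    "CollinearityError",
    "random_split",
    "compare_groups",
    "stepwise_regression",
    "fit_to_equation",
    "cohort_frame",
]

CANDIDATES = ("weight", "sex", "age", "height")


@dataclass(frozen=True)
class SplitResult:
    development: tuple[Subject, ...]
    validation: tuple[Subject, ...]
    seed: int


@dataclass(frozen=True)
class GroupComparison:
    """Table-1-style comparability check between the two halves."""

    continuous: pd.DataFrame  # index: variable; columns: dev/val mean, sd, p
    sex_counts: pd.DataFrame  # females/males per group
    sex_p: float


@dataclass(frozen=True)
class RegressionFit:
    """Final stepwise model with coefficients and fit statistics."""

    included_predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    std_errors: dict[str, float]
    p_values: dict[str, float]
    r: float
    r_squared: float
    adj_r_squared: float
    n: int
    excluded_predictors: dict[str, float]  # candidate -> final-step entry p
    fitted_values: tuple[float, ...] = field(repr=False, default=())

    def predict_row(self, weight: float, sex01: float, age: float, height: float) -> float:
        x = {"weight": weight, "sex": sex01, "age": age, "height": height}
        return self.intercept + sum(
            self.coefficients[p] * x[p] for p in self.included_predictors
        )


class CollinearityError(ValueError):
    """Design matrix is singular; names the offending predictors."""


def cohort_frame(cohort: Iterable[Subject]) -> pd.DataFrame:
    """Cohort as a DataFrame with sex coded male = 1, female = 0."""
    rows = [
        {
            "id": s.id,
            "sex": 1.0 if s.sex == MALE else 0.0,
            "age": s.age,
            "weight": s.weight,
            "height": s.height,
            "bmi": s.bmi,
            "ree_measured": s.ree_measured,
        }
        for s in cohort
    ]
    return pd.DataFrame(rows)


def random_split(cohort: Sequence[Subject], seed: int) -> SplitResult:
    """Simple (unstratified) random half-split, reproducible by seed.

    Sizes differ by at most one; 284 subjects split 142/142.
    """
    subjects = list(cohort)
    if len(subjects) < 4:
        raise ValueError(f"cohort too small to split: n={len(subjects)} < 4")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    half = (len(subjects) + 1) // 2
    dev = tuple(subjects[i] for i in sorted(order[:half]))
    val = tuple(subjects[i] for i in sorted(order[half:]))
    return SplitResult(development=dev, validation=val, seed=seed)


_CONTINUOUS = ["age", "weight", "height", "bmi", "ree_measured"]


def compare_groups(split: SplitResult) -> GroupComparison:
    """Independent-samples t per continuous variable; Pearson chi-square for sex.

    Zero variance in both groups with equal means yields p = NaN
    (non-computable marker) rather than an error.
    """
    dev = cohort_frame(split.development)
    val = cohort_frame(split.validation)
    if dev.empty or val.empty:
        raise ValueError("both split halves must be non-empty")
    rows = []
    for var in _CONTINUOUS:
        a = dev[var].dropna().to_numpy(float)
        b = val[var].dropna().to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if a.mean() == b.mean() else float("nan")
        else:
            p = float(stats.ttest_ind(a, b).pvalue)
        rows.append(
            {
                "variable": var,
                "dev_mean": a.mean(),
                "dev_sd": a.std(ddof=1) if len(a) > 1 else 0.0,
                "val_mean": b.mean(),
                "val_sd": b.std(ddof=1) if len(b) > 1 else 0.0,
                "p": p,
            }
        )
    continuous = pd.DataFrame(rows).set_index("variable")

    counts = pd.DataFrame(
        {
            "development": [
                int((dev["sex"] == 0).sum()),
                int((dev["sex"] == 1).sum()),
            ],
            "validation": [
                int((val["sex"] == 0).sum()),
                int((val["sex"] == 1).sum()),
            ],
        },
        index=["females", "males"],
    )
    table = counts.to_numpy().T  # rows = groups, cols = sexes
    if (table.sum(axis=0) == 0).any():
        sex_p = float("nan")
    else:
        # Pearson chi-square without continuity correction (SPSS primary row)
        sex_p = float(stats.chi2_contingency(table, correction=False)[1])
    return GroupComparison(continuous=continuous, sex_counts=counts, sex_p=sex_p)


def _entry_pvalue(y: np.ndarray, X: pd.DataFrame, included: list[str], cand: str) -> float:
    design = sm.add_constant(X[included + [cand]], has_constant="add")
    fit = sm.OLS(y, design).fit()
    p = float(fit.pvalues[cand])
    # zero-residual fits give 0/0 t statistics for null predictors
    return 1.0 if math.isnan(p) else p


def _check_collinearity(X: pd.DataFrame, predictors: Sequence[str]) -> None:
    if not predictors:
        return
    design = sm.add_constant(X[list(predictors)], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise CollinearityError(
            f"singular design matrix among predictors {list(predictors)}"
        )


def stepwise_regression(
    cohort: Iterable[Subject],
    candidates: Sequence[str] = CANDIDATES,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionFit:
    """Forward-entry / backward-removal stepwise OLS of measured REE.

    Parameters
    ----------
    cohort : iterable of Subject
        Every subject must carry measured REE.
    candidates : sequence of {"weight", "sex", "age", "height"}
        Predictors offered to the selection. Sex is coded male = 1.
    p_enter, p_remove : float
        Partial-F (equivalently t) p-value thresholds; requires
        p_remove > p_enter so a predictor is never entered and removed in
        the same step.
    """
    if not p_remove > p_enter:
        raise ValueError(f"p_remove ({p_remove}) must exceed p_enter ({p_enter})")
    subjects = require_measured(cohort)
    candidates = list(candidates)
    if len(subjects) <= len(candidates) + 2:
        raise ValueError(
            f"n={len(subjects)} too small for {len(candidates)} candidates"
        )
    frame = cohort_frame(subjects)
    y = frame["ree_measured"].to_numpy(float)
    X = frame[candidates].astype(float)
    _check_collinearity(X, candidates)

    included: list[str] = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in included]
        if remaining:
            entry_p = {c: _entry_pvalue(y, X, included, c) for c in remaining}
            best = min(entry_p, key=entry_p.get)
            if entry_p[best] <= p_enter:
                included.append(best)
                changed = True
        if included:
            fit = sm.OLS(y, sm.add_constant(X[included], has_constant="add")).fit()
            removal_p = fit.pvalues.drop("const").fillna(0.0)
            worst = removal_p.idxmax()
            if removal_p[worst] >= p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            break

    design = sm.add_constant(X[included], has_constant="add")
    final = sm.OLS(y, design).fit()
    if included:
        r2 = float(final.rsquared)
        adj_r2 = float(final.rsquared_adj)
        coefs = {p: float(final.params[p]) for p in included}
        ses = {p: float(final.bse[p]) for p in included}
        pvals = {p: float(final.pvalues[p]) for p in included}
        intercept = float(final.params["const"])
    else:  # empty model: intercept = sample mean
        r2, adj_r2 = 0.0, 0.0
        coefs, ses, pvals = {}, {}, {}
        intercept = float(np.mean(y))
    excluded = {
        c: _entry_pvalue(y, X, included, c) for c in candidates if c not in included
    }
    return RegressionFit(
        included_predictors=tuple(included),
        coefficients=coefs,
        intercept=intercept,
        std_errors=ses,
        p_values=pvals,
        r=math.sqrt(max(r2, 0.0)),
        r_squared=r2,
        adj_r_squared=adj_r2,
        n=len(subjects),
        excluded_predictors=excluded,
        fitted_values=tuple(float(v) for v in final.fittedvalues)
        if included
        else tuple([intercept] * len(subjects)),
    )


def fit_to_equation(
    fit: RegressionFit, equation_id: str = "developed_equation"
) -> EquationSpec:
    """Wrap a fitted model as a registry-compatible spec (male = 1 coding)."""
    row = CoefficientRow(
        weight=fit.coefficients.get("weight", 0.0),
        height=fit.coefficients.get("height", 0.0),
        age=fit.coefficients.get("age", 0.0),
        sex=fit.coefficients.get("sex", 0.0),
        intercept=fit.intercept,
    )
    required = {"sex"} | set(fit.included_predictors)
    return EquationSpec(
        id=equation_id,
        display_name="Stepwise-developed equation",
        required_inputs=frozenset(required),
        sex_coding="male=1",
        strata=(Stratum(row=row),),
    )
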