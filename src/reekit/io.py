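"""Cohort CSV I/O and report rendering.

Cohort files carry one subject per row with the header
``id,sex,age_y,weight_kg,height_cm,ree_ic_kcal``; sex accepts M/F in any
case and the measured-REE column may be empty. Reports mirror the layout
of standard validation tables (precision: mean ± SD, paired-t p, r, R²,
adjusted R², RMSE, accuracy breakdown; agreement: mean difference, mean
percentage error, limits of agreement, % outside, proportional-bias rho)
and can be written as CSV, markdown or JSON. CSV/markdown round numbers
for presentation; JSON keeps full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .subjects import InvalidSubjectError, Subject
from .validation import AgreementReport, PrecisionReport

__all__ = ["read_cohort", "write_cohort", "precision_frame", "agreement_frame", "write_reports"]

COHORT_COLUMNS = ["id", "sex", "age_y", "weight_kg", "height_cm", "ree_ic_kcal"]


class CohortFormatError(ValueError):
    """Malformed cohort CSV; message names the row and column."""


def read_cohort(path: str | Path) -> list[Subject]:
    """Read a cohort CSV into Subject records.

    Numeric fields are validated per cell so errors cite the offending row
    (1-based, excluding the header) and column. Rows without an id get
    ``row<k>``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS[1:5] if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    subjects = []
    for k, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        sid = record.get("id", "") or f"row{k}"
        values = {}
        for col in ("age_y", "weight_kg", "height_cm"):
            try:
                values[col] = float(record[col])
            except ValueError:
                raise CohortFormatError(
                    f"{path}: row {k}, column {col!r}: not a number: {record[col]!r}"
                ) from None
        ree_raw = record.get("ree_ic_kcal", "").strip()
        if ree_raw:
            try:
                ree: Optional[float] = float(ree_raw)
            except ValueError:
                raise CohortFormatError(
                    f"{path}: row {k}, column 'ree_ic_kcal': not a number: {ree_raw!r}"
                ) from None
        else:
            ree = None
        try:
            subjects.append(
                Subject(
                    id=sid,
                    sex=record["sex"],
                    age=values["age_y"],
                    weight=values["weight_kg"],
                    height=values["height_cm"],
                    ree_measured=ree,
                )
            )
        except InvalidSubjectError as exc:
            raise CohortFormatError(f"{path}: row {k}: {exc}") from exc
    return subjects


def write_cohort(subjects: Sequence[Subject], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "sex": ["M" if s.is_male else "F" for s in subjects],
            "age_y": [s.age for s in subjects],
            "weight_kg": [s.weight for s in subjects],
            "height_cm": [s.height for s in subjects],
            "ree_ic_kcal": [
                "" if s.ree_measured is None else s.ree_measured for s in subjects
            ],
        }
    )
    frame.to_csv(path, index=False)


def precision_frame(reports: Sequence[PrecisionReport]) -> pd.DataFrame:
    """Precision reports as a DataFrame in validation-table column order."""
    return pd.DataFrame(
        {
            "equation_id": [r.equation_id for r in reports],
            "n": [r.n for r in reports],
            "mean_pred_kcal": [r.mean_predicted for r in reports],
            "sd_pred_kcal": [r.sd_predicted for r in reports],
            "paired_t_p": [r.paired_t_p for r in reports],
            "pearson_r": [r.pearson_r for r in reports],
            "r_squared": [r.r_squared for r in reports],
            "adj_r_squared": [r.adj_r_squared for r in reports],
            "rmse_kcal": [r.rmse for r in reports],
            "accurate_pct": [r.accurate_pct for r in reports],
            "under_pct": [r.under_pct for r in reports],
            "over_pct": [r.over_pct for r in reports],
        }
    )


def agreement_frame(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    """Agreement reports as a DataFrame in validation-table column order."""
    return pd.DataFrame(
        {
            "equation_id": [r.equation_id for r in reports],
            "n": [r.n for r in reports],
            "mean_difference_kcal": [r.mean_difference for r in reports],
            "mean_percentage_error": [r.mean_percentage_error for r in reports],
            "loa_lower_kcal": [r.loa_lower for r in reports],
            "loa_upper_kcal": [r.loa_upper for r in reports],
            "pct_outside_loa": [r.pct_outside_loa for r in reports],
            "proportional_bias_rho": [r.proportional_bias_rho for r in reports],
            "proportional_bias_p": [r.proportional_bias_p for r in reports],
        }
    )


_ROUNDING = {
    "mean_pred_kcal": 2,
    "sd_pred_kcal": 2,
    "paired_t_p": 3,
    "pearson_r": 2,
    "r_squared": 3,
    "adj_r_squared": 3,
    "rmse_kcal": 2,
    "accurate_pct": 1,
    "under_pct": 1,
    "over_pct": 1,
    "mean_difference_kcal": 2,
    "mean_percentage_error": 1,
    "loa_lower_kcal": 2,
    "loa_upper_kcal": 2,
    "pct_outside_loa": 2,
    "proportional_bias_rho": 2,
    "proportional_bias_p": 3,
}


def _rounded(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col, nd in _ROUNDING.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out


def write_reports(
    precision: Sequence[PrecisionReport],
    agreement: Sequence[AgreementReport],
    outdir: str | Path,
    fmt: str = "csv",
) -> list[Path]:
    """Write precision/agreement tables; returns the paths written.

    ``fmt`` is one of csv, markdown, json. Presentation formats (csv,
    markdown) round to table precision; json keeps full precision.
    """
    if not precision and not agreement:
        raise ValueError("no reports to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {"precision": precision_frame(precision), "agreement": agreement_frame(agreement)}
    written = []
    for name, frame in frames.items():
        if fmt == "csv":
            p = outdir / f"{name}.csv"
            _rounded(frame).to_csv(p, index=False)
        elif fmt == "markdown":
            p = outdir / f"{name}.md"
            p.write_text(_rounded(frame).to_markdown(index=False) + "\n")
        elif fmt == "json":
            p = outdir / f"{name}.json"
            p.write_text(json.dumps(frame.to_dict(orient="records"), indent=2) + "\n")
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(p)
    return written
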