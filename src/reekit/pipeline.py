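"""End-to-end split → develop → validate pipeline.

Chains the module stages the way a validation study is run: random
half-split of the input cohort, Table-1-style comparability checks,
stepwise development of a new equation on one half, then the full
precision/agreement battery for every selected registry equation plus the
newly developed one on the held-out half. Emits machine-readable
artifacts: the group comparison, the fit (coefficients and fit
statistics), the report tables and per-equation Bland–Altman plot data
(subject id, average, difference, limits of agreement), plus a plain-text
run log recording seed and thresholds. The log stays at summary level —
no subject-level data at default verbosity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .development import (
    RegressionFit,
    compare_groups,
    fit_to_equation,
    random_split,
    stepwise_regression,
)
from .equations import EquationSpec, get_equation, list_equations, predict_cohort
from .io import read_cohort, write_reports
from .subjects import Subject, require_measured
from .validation import LOA_MULTIPLIER, validation_table

__all__ = ["RunConfig", "PipelineResult", "run_full_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run; flags override file values."""

    cohort_path: Optional[str] = None  # None: caller passes subjects directly
    equations: tuple[str, ...] = ("all",)
    split_seed: int = 0
    p_enter: float = 0.05
    p_remove: float = 0.10
    accuracy_band: float = 0.10
    output_dir: str = "ree_run"
    report_format: str = "csv"

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy_band < 1.0:
            raise ValueError("accuracy_band must be in (0, 1)")
        if self.report_format not in ("csv", "markdown", "json"):
            raise ValueError(f"unknown report format {self.report_format!r}")
        known = {s.id for s in list_equations()}
        for eq in self.equations:
            if eq != "all" and eq not in known:
                raise ValueError(f"unknown equation id {eq!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load JSON or YAML config; keyword overrides win."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "equations" in data:
            data["equations"] = tuple(data["equations"])
        data.update(overrides)
        return cls(**data)

    def selected_specs(self) -> list[EquationSpec]:
        if "all" in self.equations:
            return list(list_equations())
        return [get_equation(e) for e in self.equations]


@dataclass(frozen=True)
class PipelineResult:
    fit: RegressionFit
    developed_spec: EquationSpec
    artifacts: tuple[Path, ...]
    output_dir: Path


def _fit_payload(fit: RegressionFit) -> dict:
    return {
        "included_predictors": list(fit.included_predictors),
        "coefficients": fit.coefficients,
        "intercept": fit.intercept,
        "std_errors": fit.std_errors,
        "p_values": fit.p_values,
        "r": fit.r,
        "r_squared": fit.r_squared,
        "adj_r_squared": fit.adj_r_squared,
        "n": fit.n,
        "excluded_predictors": fit.excluded_predictors,
    }


def run_full_pipeline(
    config: RunConfig, subjects: Optional[Sequence[Subject]] = None
) -> PipelineResult:
    """Run split → compare → stepwise fit → validation battery → reports."""
    stage = "load"
    try:
        if subjects is None:
            if config.cohort_path is None:
                raise ValueError("no cohort: set cohort_path or pass subjects")
            subjects = read_cohort(config.cohort_path)
        cohort = require_measured(subjects)

        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts: list[Path] = []

        stage = "split"
        split = random_split(cohort, seed=config.split_seed)

        stage = "compare_groups"
        comparison = compare_groups(split)
        p = outdir / "group_comparison.csv"
        comparison.continuous.round(6).to_csv(p)
        artifacts.append(p)
        p = outdir / "sex_comparison.json"
        p.write_text(
            json.dumps(
                {
                    "counts": comparison.sex_counts.to_dict(),
                    "chi_square_p": comparison.sex_p,
                },
                indent=2,
            )
            + "\n"
        )
        artifacts.append(p)

        stage = "stepwise_fit"
        fit = stepwise_regression(
            split.development,
            p_enter=config.p_enter,
            p_remove=config.p_remove,
        )
        developed = fit_to_equation(fit)
        p = outdir / "fit.json"
        p.write_text(json.dumps(_fit_payload(fit), indent=2) + "\n")
        artifacts.append(p)

        stage = "validation"
        specs = config.selected_specs() + [developed]
        reports = validation_table(split.validation, specs, band=config.accuracy_band)
        precision = [pr for pr, _ in reports]
        agreement = [ag for _, ag in reports]
        artifacts += write_reports(
            precision, agreement, outdir, fmt=config.report_format
        )

        stage = "plot_data"
        measured = np.array([s.ree_measured for s in split.validation])
        ids = [s.id for s in split.validation]
        for spec, (_, ag) in zip(specs, reports):
            predicted = np.array(
                [pr.ree_predicted for pr in predict_cohort(spec, split.validation)]
            )
            frame = pd.DataFrame(
                {
                    "subject_id": ids,
                    "average_kcal": (predicted + measured) / 2.0,
                    "difference_kcal": predicted - measured,
                }
            )
            frame["loa_lower_kcal"] = ag.loa_lower
            frame["loa_upper_kcal"] = ag.loa_upper
            p = outdir / f"bland_altman_{spec.id}.csv"
            frame.to_csv(p, index=False)
            artifacts.append(p)

        stage = "log"
        p = outdir / "run.log"
        p.write_text(
            "\n".join(
                [
                    f"reekit {__version__}",
                    f"n_subjects={len(cohort)} development={len(split.development)} "
                    f"validation={len(split.validation)}",
                    f"split_seed={config.split_seed}",
                    f"p_enter={config.p_enter} p_remove={config.p_remove}",
                    f"accuracy_band={config.accuracy_band}",
                    f"loa_multiplier={LOA_MULTIPLIER}",
                    f"equations={[s.id for s in specs]}",
                    f"included_predictors={list(fit.included_predictors)}",
                ]
            )
            + "\n"
        )
        artifacts.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        fit=fit,
        developed_spec=developed,
        artifacts=tuple(artifacts),
        output_dir=outdir,
    )
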