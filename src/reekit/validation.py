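"""Group- and individual-level validation of REE predictions.

For each equation, predicted REE is compared against indirect-calorimetry
measurements with the standard method-comparison battery:

* precision — paired t-test, Pearson r, linear-regression R² / adjusted R²
  and RMSE, and the individual-level accuracy rate (share of subjects
  predicted within ±10% of measured);
* agreement — Bland–Altman mean difference, 95% limits of agreement
  (mean ± 1.96 SD of the differences), share of subjects outside the
  limits, mean percentage error, and proportional bias as the Pearson
  correlation between differences and averages.

Sign convention throughout: difference = predicted − measured, so
overprediction is positive.

The regression behind R² and RMSE puts measured REE on the left-hand side
(measured ~ predicted); RMSE is the residual standard error
sqrt(SSres/(n−2)), which ties it to R² and the SD of measured values via
RMSE = SD(measured)·sqrt((1−R²)(n−1)/(n−2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .equations import EquationSpec, predict_cohort
from .subjects import Subject, require_measured

__all__ = [
    "PrecisionReport",
    "AgreementReport",
    "accuracy_rate",
    "mean_percentage_error",
    "bland_altman",
    "precision_stats",
    "validation_table",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class PrecisionReport:
    equation_id: str
    n: int
    mean_predicted: float
    sd_predicted: float
    paired_t_p: float
    pearson_r: float
    r_squared: float
    adj_r_squared: float
    rmse: float
    accurate_pct: float
    under_pct: float
    over_pct: float


@dataclass(frozen=True)
class AgreementReport:
    equation_id: str
    n: int
    mean_difference: float
    mean_percentage_error: float
    loa_lower: float
    loa_upper: float
    pct_outside_loa: float
    proportional_bias_rho: float
    proportional_bias_p: float


def _paired_arrays(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValueError(f"length mismatch: measured {m.shape}, predicted {p.shape}")
    if m.size == 0:
        raise ValueError("empty input")
    if np.any(m <= 0):
        raise ValueError("measured REE must be strictly positive")
    return m, p


def accuracy_rate(
    measured: Sequence[float], predicted: Sequence[float], band: float = 0.10
) -> tuple[float, float, float]:
    """Percent of subjects predicted accurately / under / over.

    Accurate means |predicted − measured| / measured <= band (boundary
    inclusive); under/over are predictions below/above the band. Returns
    ``(accurate_pct, under_pct, over_pct)`` summing to 100.
    """
    m, p = _paired_arrays(measured, predicted)
    rel = (p - m) / m
    under = rel < -band
    over = rel > band
    accurate = ~(under | over)
    n = m.size
    return (
        100.0 * accurate.sum() / n,
        100.0 * under.sum() / n,
        100.0 * over.sum() / n,
    )


def mean_percentage_error(measured: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean of (predicted − measured)/measured × 100; overprediction positive."""
    m, p = _paired_arrays(measured, predicted)
    return float(np.mean((p - m) / m) * 100.0)


def bland_altman(
    measured: Sequence[float],
    predicted: Sequence[float],
    equation_id: str = "",
) -> AgreementReport:
    """Bland–Altman agreement between predicted and measured REE.

    Differences d = predicted − measured are plotted against averages
    a = (predicted + measured)/2; limits of agreement are
    mean(d) ± 1.96·SD(d) with the n−1 sample SD. ``pct_outside_loa`` counts
    differences strictly outside the limits. Proportional bias is the
    Pearson correlation of d with a (negative when low-REE subjects are
    overpredicted and high-REE subjects underpredicted); with zero
    variance in d or a it is reported as NaN.
    """
    m, p = _paired_arrays(measured, predicted)
    if m.size < 3:
        raise ValueError(f"need n >= 3 for limits of agreement, got {m.size}")
    d = p - m
    a = (p + m) / 2.0
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    lower = mean_d - LOA_MULTIPLIER * sd_d
    upper = mean_d + LOA_MULTIPLIER * sd_d
    outside = float(100.0 * np.mean((d < lower) | (d > upper)))
    if sd_d == 0 or np.ptp(a) == 0:
        rho, rho_p = float("nan"), float("nan")
    else:
        res = stats.pearsonr(d, a)
        rho, rho_p = float(res.statistic), float(res.pvalue)
    return AgreementReport(
        equation_id=equation_id,
        n=int(m.size),
        mean_difference=mean_d,
        mean_percentage_error=mean_percentage_error(m, p),
        loa_lower=lower,
        loa_upper=upper,
        pct_outside_loa=outside,
        proportional_bias_rho=rho,
        proportional_bias_p=rho_p,
    )


def precision_stats(
    measured: Sequence[float],
    predicted: Sequence[float],
    equation_id: str = "",
    band: float = 0.10,
) -> PrecisionReport:
    """Paired t, Pearson r, regression R²/adjusted R²/RMSE, accuracy bands.

    R², adjusted R² = 1 − (1−R²)(n−1)/(n−2) and RMSE = sqrt(SSres/(n−2))
    come from the simple regression of measured on predicted. A constant
    predicted vector makes r, R², adjusted R² and RMSE non-computable
    (NaN).
    """
    m, p = _paired_arrays(measured, predicted)
    n = int(m.size)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    d = p - m
    if np.ptp(d) == 0:
        # all differences identical: paired t is degenerate
        t_p = 1.0 if d[0] == 0 else 0.0
    else:
        t_p = float(stats.ttest_rel(p, m).pvalue)
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        r = r2 = adj_r2 = rmse = float("nan")
    else:
        r = float(stats.pearsonr(p, m).statistic)
        r2 = r * r
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        # residual SE of measured ~ predicted
        ss_tot = float(np.sum((m - m.mean()) ** 2))
        rmse = float(np.sqrt(ss_tot * (1.0 - r2) / (n - 2)))
    acc, under, over = accuracy_rate(m, p, band=band)
    return PrecisionReport(
        equation_id=equation_id,
        n=n,
        mean_predicted=float(np.mean(p)),
        sd_predicted=float(np.std(p, ddof=1)),
        paired_t_p=t_p,
        pearson_r=r,
        r_squared=r2,
        adj_r_squared=adj_r2,
        rmse=rmse,
        accurate_pct=acc,
        under_pct=under,
        over_pct=over,
    )


def validation_table(
    cohort: Iterable[Subject],
    specs: Sequence[EquationSpec],
    band: float = 0.10,
) -> list[tuple[PrecisionReport, AgreementReport]]:
    """One (precision, agreement) report pair per equation, deterministic.

    A failure in one equation is recorded as a pair of NaN-filled reports
    and does not abort the remaining equations.
    """
    subjects = require_measured(cohort)
    measured = np.array([s.ree_measured for s in subjects], dtype=float)
    out = []
    for spec in specs:
        try:
            predicted = np.array(
                [pr.ree_predicted for pr in predict_cohort(spec, subjects)]
            )
            out.append(
                (
                    precision_stats(measured, predicted, spec.id, band=band),
                    bland_altman(measured, predicted, spec.id),
                )
            )
        except Exception:
            nan = float("nan")
            out.append(
                (
                    PrecisionReport(spec.id, len(subjects), *([nan] * 10)),
                    AgreementReport(spec.id, len(subjects), *([nan] * 7)),
                )
            )
    return out
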