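"""Internal-standard-normalized linear calibration and back-calculation.

The calibration line regresses the analyte/IS response ratio on nominal
concentration by (optionally weighted) least squares; unknowns are
quantified by inverting the fitted line within the validated range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "fit_calibration",
    "back_calculate",
    "back_calc_table",
    "quantify",
]

WEIGHTINGS = ("none", "1/x", "1/x2")

#: back-calculation deviation limits: |dev| <= 15% (20% at the LLOQ level)
BACKCALC_LIMIT_PCT = 15.0
BACKCALC_LIMIT_LLOQ_PCT = 20.0


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration well: nominal concentration plus raw responses."""

    nominal: float  # ng/mL
    analyte_response: float
    is_response: float

    def __post_init__(self) -> None:
        if self.is_response <= 0:
            raise ValueError("is_response must be positive")
        if self.nominal < 0:
            raise ValueError("nominal must be non-negative")

    @property
    def ratio(self) -> float:
        """Analyte/IS response ratio (the regression ordinate)."""
        return self.analyte_response / self.is_response


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line ratio = slope * conc + intercept with its range."""

    slope: float
    intercept: float
    r_squared: float
    lloq: float
    uloq: float
    n_points: int
    weighting: str = "none"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if not self.lloq < self.uloq:
            raise ValueError("lloq must be below uloq")


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}; use one of {WEIGHTINGS}")


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    weighting: str = "none",
) -> CalibrationCurve:
    """Weighted least-squares line of response ratio on nominal concentration.

    Requires >= 3 distinct nominal levels. R-squared is computed under the
    same weights; the quantification range is [min nominal, max nominal].
    """
    x = np.array([s.nominal for s in standards], dtype=float)
    y = np.array([s.ratio for s in standards], dtype=float)
    if len(set(x.tolist())) < 3:
        raise InsufficientDataError(
            f"{len(set(x.tolist()))} distinct levels; >= 3 required"
        )
    if weighting != "none" and np.any(x <= 0):
        raise ValueError("1/x weighting requires positive nominals")
    w = _weights(x, weighting)

    # closed-form weighted normal equations
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise InsufficientDataError("all nominal levels identical (rank deficient)")
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        lloq=float(x.min()),
        uloq=float(x.max()),
        n_points=len(standards),
        weighting=weighting,
    )


def back_calculate(curve: CalibrationCurve, ratio: float) -> float:
    """Invert the calibration line: (ratio - intercept) / slope.

    May return a negative value; BLQ policy is the caller's decision.
    """
    return (ratio - curve.intercept) / curve.slope


def back_calc_table(
    curve: CalibrationCurve,
    standards: Sequence[CalibrationStandard],
) -> pd.DataFrame:
    """Back-calculate each standard and flag deviations.

    deviation % = (calculated - nominal)/nominal * 100. A standard passes if
    |deviation| <= 15%, or <= 20% when its nominal is the curve's LLOQ.
    """
    rows = []
    for s in standards:
        if s.nominal == 0:
            raise UndefinedStatisticError("deviation undefined for nominal 0")
        calc = back_calculate(curve, s.ratio)
        dev = (calc - s.nominal) / s.nominal * 100.0
        is_lloq = s.nominal == curve.lloq
        limit = BACKCALC_LIMIT_LLOQ_PCT if is_lloq else BACKCALC_LIMIT_PCT
        rows.append(
            {
                "nominal": s.nominal,
                "calculated": calc,
                "deviation_pct": dev,
                "is_lloq": is_lloq,
                "pass": abs(dev) <= limit,
            }
        )
    return pd.DataFrame(rows)


def quantify(
    curve: CalibrationCurve,
    unknowns: pd.DataFrame,
    dilution_factor: float = 1.0,
) -> pd.DataFrame:
    """Quantify plate rows against the fitted curve.

    ``unknowns`` must carry ``analyte_response`` and ``is_response`` columns.
    Returns a copy with ``calculated_ng_per_ml`` (dilution-corrected) and
    ``blq`` / ``above_uloq`` flag columns. Values below the LLOQ are flagged
    BLQ, values above the ULOQ without dilution are flagged above-ULOQ;
    nothing is clamped.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    out = unknowns.copy()
    ratio = out["analyte_response"].to_numpy(float) / out["is_response"].to_numpy(float)
    conc = np.array([back_calculate(curve, r) for r in ratio]) * dilution_factor
    out["calculated_ng_per_ml"] = conc
    out["blq"] = conc < curve.lloq
    out["above_uloq"] = (conc > curve.uloq) & (dilution_factor == 1.0)
    return out
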