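"""Bioanalytical method validation statistics and acceptance judgments.

Implements accuracy, within-/between-run precision, IS-normalized matrix
factor, carryover, stability ratios, dilution integrity and the
with/without-hydrolysis comparison, each judged against configurable
thresholds. Two presets ship: ``paper`` (CV <= 5%, accuracy 85-115%, LLOQ
80-120%) and ``ema`` (CV <= 15%/20% at LLOQ, same accuracy bounds).

Accuracy is calculated/nominal x 100. The SD convention defaults to the
population divisor (n); pass/fail flags are judged on the rounded reported
statistics so every flag is derivable from the printed report alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError
from .stats import round_half_up

__all__ = [
    "QCMeasurement",
    "AcceptanceThresholds",
    "SummaryStats",
    "ValidationReport",
    "PRESETS",
    "mean_sd_cv",
    "accuracy_pct",
    "within_run",
    "between_run",
    "matrix_factor",
    "stability_ratio",
    "carryover_check",
    "dilution_integrity",
    "hydrolysis_comparison",
]


@dataclass(frozen=True)
class QCMeasurement:
    """One quantified quality-control replicate."""

    nominal: float  # ng/mL
    calculated: float  # ng/mL
    run_id: str = "run1"
    condition: str = "fresh"  # fresh | freeze_thaw | short_term | long_term | diluted

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError("nominal must be positive")


@dataclass(frozen=True)
class AcceptanceThresholds:
    """Acceptance limits plus statistical conventions for reporting."""

    cv_max_pct: float = 5.0
    cv_max_pct_lloq: float = 5.0
    accuracy_low_pct: float = 85.0
    accuracy_high_pct: float = 115.0
    accuracy_lloq_low_pct: float = 80.0
    accuracy_lloq_high_pct: float = 120.0
    carryover_max_frac_of_lloq: float = 0.20
    is_carryover_max_frac: float = 0.05
    sd_convention: str = "population"  # population (n) | sample (n-1)
    rounding_decimals: int = 1

    def __post_init__(self) -> None:
        if not self.accuracy_low_pct < self.accuracy_high_pct:
            raise ValueError("accuracy bounds inverted")
        if not self.accuracy_lloq_low_pct < self.accuracy_lloq_high_pct:
            raise ValueError("LLOQ accuracy bounds inverted")
        if self.cv_max_pct <= 0 or self.cv_max_pct_lloq <= 0:
            raise ValueError("cv limits must be positive")
        if self.sd_convention not in ("population", "sample"):
            raise ValueError("sd_convention must be 'population' or 'sample'")


PRESETS = {
    "paper": AcceptanceThresholds(),
    "ema": AcceptanceThresholds(cv_max_pct=15.0, cv_max_pct_lloq=20.0),
}


class SummaryStats(NamedTuple):
    mean: float
    sd: float
    cv_pct: float
    n: int


def mean_sd_cv(values: Sequence[float], sd_convention: str = "population") -> SummaryStats:
    """Mean, SD (divisor n or n-1) and CV% of a replicate set."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"{arr.size} replicate(s); >= 2 required")
    mean = float(arr.mean())
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    ddof = {"population": 0, "sample": 1}[sd_convention]
    sd = float(arr.std(ddof=ddof))
    return SummaryStats(mean=mean, sd=sd, cv_pct=sd / mean * 100.0, n=int(arr.size))


def accuracy_pct(mean_calculated: float, nominal: float, decimals: int | None = 1) -> float:
    """Mean calculated over nominal, as a percentage."""
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    acc = mean_calculated / nominal * 100.0
    return acc if decimals is None else round_half_up(acc, decimals)


def stability_ratio(stressed_mean: float, nominal: float, decimals: int | None = 1) -> float:
    """Stressed-sample mean over nominal, as a percentage."""
    return accuracy_pct(stressed_mean, nominal, decimals)


def _as_frame(qcs) -> pd.DataFrame:
    if isinstance(qcs, pd.DataFrame):
        return qcs
    return pd.DataFrame(
        [
            {
                "nominal": q.nominal,
                "calculated": q.calculated,
                "run_id": q.run_id,
                "condition": q.condition,
            }
            for q in qcs
        ]
    )


def _judge_levels(
    df: pd.DataFrame,
    thresholds: AcceptanceThresholds,
    lloq_level: float | None,
) -> pd.DataFrame:
    """Per-level accuracy/CV table with pass flags (judged on rounded values)."""
    dec = thresholds.rounding_decimals
    if lloq_level is None:
        lloq_level = float(df["nominal"].min())
    rows = []
    for nominal, grp in df.groupby("nominal", sort=True):
        stats = mean_sd_cv(grp["calculated"], thresholds.sd_convention)
        acc = round_half_up(stats.mean / nominal * 100.0, dec)
        cv = round_half_up(stats.cv_pct, dec)
        is_lloq = nominal == lloq_level
        lo = thresholds.accuracy_lloq_low_pct if is_lloq else thresholds.accuracy_low_pct
        hi = thresholds.accuracy_lloq_high_pct if is_lloq else thresholds.accuracy_high_pct
        cv_max = thresholds.cv_max_pct_lloq if is_lloq else thresholds.cv_max_pct
        acc_pass = lo <= acc <= hi
        cv_pass = cv <= cv_max
        rows.append(
            {
                "nominal": float(nominal),
                "n": stats.n,
                "mean": stats.mean,
                "sd": stats.sd,
                "accuracy_pct": acc,
                "cv_pct": cv,
                "is_lloq": is_lloq,
                "accuracy_pass": acc_pass,
                "cv_pass": cv_pass,
                "pass": acc_pass and cv_pass,
            }
        )
    return pd.DataFrame(rows)


def within_run(
    qcs,
    thresholds: AcceptanceThresholds,
    lloq_level: float | None = None,
) -> pd.DataFrame:
    """Per-level accuracy and precision of replicates from a single run.

    ``qcs`` is a DataFrame with ``nominal``/``calculated``/``run_id`` columns
    or a sequence of :class:`QCMeasurement`. The level equal to
    ``lloq_level`` (default: the lowest nominal) is judged on LLOQ bounds.
    """
    df = _as_frame(qcs)
    runs = df["run_id"].unique()
    if len(runs) != 1:
        raise ValueError(f"within-run statistics require one run; got {len(runs)}")
    return _judge_levels(df, thresholds, lloq_level)


def between_run(
    qcs,
    thresholds: AcceptanceThresholds,
    lloq_level: float | None = None,
) -> pd.DataFrame:
    """Per-level statistics pooling all replicates across >= 2 runs."""
    df = _as_frame(qcs)
    if df["run_id"].nunique() < 2:
        raise InsufficientDataError("between-run statistics require >= 2 runs")
    return _judge_levels(df, thresholds, lloq_level)


def matrix_factor(
    analyte_in_matrix: float,
    analyte_in_solvent: float,
    is_in_matrix: float,
    is_in_solvent: float,
) -> tuple[float, float, float]:
    """Matrix factors (matrix/solvent peak area ratios) and the IS-normalized MF."""
    if analyte_in_solvent <= 0 or is_in_solvent <= 0:
        raise ValueError("solvent areas must be positive")
    if analyte_in_matrix <= 0 or is_in_matrix <= 0:
        raise ValueError("matrix areas must be positive")
    mf_analyte = analyte_in_matrix / analyte_in_solvent
    mf_is = is_in_matrix / is_in_solvent
    return mf_analyte, mf_is, mf_analyte / mf_is


def carryover_check(
    blank_response_after_uloq: float,
    lloq_response: float,
    is_blank_response: float,
    is_response: float,
    thresholds: AcceptanceThresholds,
) -> bool:
    """Blank injected after the ULOQ sample: pass iff the residual analyte
    response is strictly below 20% of the LLOQ response (default) and the
    residual IS response strictly below 5% of the working IS response."""
    if lloq_response <= 0:
        raise ValueError("lloq_response must be positive")
    if is_response <= 0:
        raise ValueError("is_response must be positive")
    analyte_ok = blank_response_after_uloq < thresholds.carryover_max_frac_of_lloq * lloq_response
    is_ok = is_blank_response < thresholds.is_carryover_max_frac * is_response
    return bool(analyte_ok and is_ok)


def dilution_integrity(
    diluted_measurements,
    dilution_factor: float,
    nominal_levels: Sequence[float],
    thresholds: AcceptanceThresholds,
    min_replicates: int = 5,
) -> pd.DataFrame:
    """Accuracy/CV of dilution-factor-corrected measurements per level.

    ``diluted_measurements`` carries the concentrations measured *after*
    dilution; each is multiplied by ``dilution_factor`` before judging
    against the undiluted nominal on the standard accuracy/CV bounds.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    df = _as_frame(diluted_measurements).copy()
    df["calculated"] = df["calculated"] * dilution_factor
    missing = set(float(v) for v in nominal_levels) - set(df["nominal"].astype(float))
    if missing:
        raise InsufficientDataError(f"missing dilution levels: {sorted(missing)}")
    df = df[df["nominal"].astype(float).isin([float(v) for v in nominal_levels])]
    counts = df.groupby("nominal").size()
    if (counts < min_replicates).any():
        raise InsufficientDataError(
            f"each dilution level needs >= {min_replicates} replicates"
        )
    # dilution QCs sit above the ULOQ; none is the LLOQ level
    return _judge_levels(df, thresholds, lloq_level=-1.0)


def hydrolysis_comparison(
    with_hydrolysis: Sequence[float],
    without_hydrolysis: Sequence[float],
    sd_convention: str = "population",
    decimals: int = 0,
) -> pd.DataFrame:
    """Side-by-side mean/SD/CV summary of the two sample-preparation arms,
    rounded to ``decimals`` for table-style reporting."""
    rows = []
    for label, values in (
        ("with_hydrolysis", with_hydrolysis),
        ("without_hydrolysis", without_hydrolysis),
    ):
        s = mean_sd_cv(values, sd_convention)
        rows.append(
            {
                "preparation": label,
                "n": s.n,
                "mean": round_half_up(s.mean, decimals),
                "sd": round_half_up(s.sd, decimals),
                "cv_pct": round_half_up(s.cv_pct, decimals),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Container for every evaluated section plus overall pass flags.

    Sections left as ``None`` were not evaluated (missing input roles);
    they are rendered as "not evaluated" rather than failing the run.
    """

    thresholds: AcceptanceThresholds
    within_run_by_run: dict[str, pd.DataFrame] = field(default_factory=dict)
    between_run_table: pd.DataFrame | None = None
    stability_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    dilution_table: pd.DataFrame | None = None
    carryover_pass: bool | None = None
    matrix_factor_table: pd.DataFrame | None = None
    hydrolysis_table: pd.DataFrame | None = None

    def _section_frames(self):
        for run_id, tbl in sorted(self.within_run_by_run.items()):
            yield f"within_run[{run_id}]", tbl
        if self.between_run_table is not None:
            yield "between_run", self.between_run_table
        for cond, tbl in sorted(self.stability_tables.items()):
            yield f"stability[{cond}]", tbl
        if self.dilution_table is not None:
            yield "dilution_integrity", self.dilution_table

    @property
    def overall_pass(self) -> bool:
        ok = True
        for _, tbl in self._section_frames():
            ok &= bool(tbl["pass"].all())
        if self.carryover_pass is not None:
            ok &= self.carryover_pass
        return ok

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-statistic table for CSV export."""
        rows = []
        for section, tbl in self._section_frames():
            for _, r in tbl.iterrows():
                rows.append(
                    {
                        "section": section,
                        "nominal_ng_per_ml": r["nominal"],
                        "n": r["n"],
                        "mean_ng_per_ml": r["mean"],
                        "sd_ng_per_ml": r["sd"],
                        "accuracy_pct": r["accuracy_pct"],
                        "cv_pct": r["cv_pct"],
                        "pass": r["pass"],
                    }
                )
        if self.carryover_pass is not None:
            rows.append(
                {
                    "section": "carryover",
                    "nominal_ng_per_ml": np.nan,
                    "n": 1,
                    "mean_ng_per_ml": np.nan,
                    "sd_ng_per_ml": np.nan,
                    "accuracy_pct": np.nan,
                    "cv_pct": np.nan,
                    "pass": self.carryover_pass,
                }
            )
        if self.matrix_factor_table is not None:
            for _, r in self.matrix_factor_table.iterrows():
                rows.append(
                    {
                        "section": "matrix_factor",
                        "nominal_ng_per_ml": r.get("nominal", np.nan),
                        "n": r.get("n", 1),
                        "mean_ng_per_ml": r["is_normalized_mf"],
                        "sd_ng_per_ml": np.nan,
                        "accuracy_pct": np.nan,
                        "cv_pct": r.get("cv_pct", np.nan),
                        "pass": True,
                    }
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        dec = self.thresholds.rounding_decimals
        lines = ["Validation report", "=" * 17, ""]
        any_section = False
        for section, tbl in self._section_frames():
            any_section = True
            lines.append(section)
            for _, r in tbl.iterrows():
                lines.append(
                    f"  level {r['nominal']:g} ng/mL (n={int(r['n'])}): "
                    f"accuracy {r['accuracy_pct']:.{dec}f}%, "
                    f"CV {r['cv_pct']:.{dec}f}% -> "
                    f"{'PASS' if r['pass'] else 'FAIL'}"
                )
            lines.append("")
        if self.carryover_pass is not None:
            any_section = True
            lines.append(
                f"carryover: {'PASS' if self.carryover_pass else 'FAIL'}"
            )
            lines.append("")
        if self.hydrolysis_table is not None:
            lines.append("hydrolysis comparison")
            for _, r in self.hydrolysis_table.iterrows():
                lines.append(
                    f"  {r['preparation']} (n={int(r['n'])}): "
                    f"mean {r['mean']:g}, SD {r['sd']:g}, CV {r['cv_pct']:g}%"
                )
            lines.append("")
        for section in ("within_run", "between_run", "stability", "dilution_integrity", "carryover"):
            evaluated = any(section in s for s, _ in self._section_frames()) or (
                section == "carryover" and self.carryover_pass is not None
            )
            if not evaluated:
                lines.append(f"{section}: not evaluated")
        if any_section:
            lines.append("")
            lines.append(f"overall: {'PASS' if self.overall_pass else 'FAIL'}")
        return "\n".join(lines) + "\n"


def with_preset(name: str, **overrides) -> AcceptanceThresholds:
    """Look up a threshold preset by name, optionally overriding fields."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; use one of {sorted(PRESETS)}")
    return replace(preset, **overrides) if overrides else preset
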