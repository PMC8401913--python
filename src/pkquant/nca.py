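"""Noncompartmental pharmacokinetic analysis.

Per-subject estimation of the terminal rate constant (semi-log regression
over a selected terminal subset), half-life, Cmax/Tmax, linear-trapezoidal
AUC and AUMC, MRT, volume of distribution and clearance (IV), and absolute
oral bioavailability against an IV reference, plus mean +/- SD summaries
across subjects.

Conventions (all configurable):

* terminal-subset selection: contiguous terminal suffixes of >= 3 points
  (excluding Tmax for oral profiles, excluding the first sample for IV),
  best adjusted R-squared wins, ties broken toward more points. A fixed
  ``last_3`` policy is also available.
* linear trapezoid only; oral profiles are prepended with (0, 0), IV bolus
  profiles back-extrapolate C(0) from the first two observed points
  (log-linear) or start at the first observed point per ``c0_policy``.
* BLQ points before Tmax contribute 0; BLQ points after Tmax are excluded.
* Vd = dose_amount / (lambda_z * AUC); Cl = lambda_z * Vd. The ``auc_inf``
  convention extrapolates AUC by C_last / lambda_z first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    NoEliminationPhaseError,
    NotApplicableError,
    WindowError,
)

__all__ = [
    "ConcentrationTimeProfile",
    "LambdaZFit",
    "NCAResult",
    "cmax_tmax",
    "fit_lambda_z",
    "half_life",
    "auc_trapezoid",
    "aumc_trapezoid",
    "mrt",
    "vd_cl",
    "bioavailability",
    "run_nca",
    "summarize",
]

ROUTES = ("iv_bolus", "oral")
LAMBDA_Z_POLICIES = ("best_adj_r2", "last_3")
C0_POLICIES = ("extrapolate", "first_point")

NG_PER_MG = 1e6


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's concentration-time points with dosing metadata.

    times are minutes (strictly increasing), concentrations ng/mL
    (non-negative), ``blq`` marks points below the quantification limit
    (raw values retained).
    """

    subject_id: str
    route: str
    dose_per_kg: float  # mg/kg
    body_weight: float | None  # kg
    times: np.ndarray
    concs: np.ndarray
    blq: np.ndarray

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ConfigurationError(f"route must be one of {ROUTES}")
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concs, dtype=float)
        b = np.asarray(self.blq, dtype=bool)
        if not (t.size == c.size == b.size):
            raise ValueError("times, concs, blq must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concs", c)
        object.__setattr__(self, "blq", b)

    @property
    def dose_amount_ng(self) -> float:
        if self.body_weight is None:
            raise ConfigurationError("body_weight required for absolute dose amount")
        return self.dose_per_kg * self.body_weight * NG_PER_MG

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of the non-BLQ points."""
        m = ~self.blq
        return self.times[m], self.concs[m]


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float  # 1/min
    n_points: int
    adj_r2: float
    t_first: float
    t_last: float
    log_intercept: float  # ln(conc) at t = 0 of the terminal regression


@dataclass
class NCAResult:
    subject_id: str
    route: str
    c_max: float
    t_max: float
    lambda_z: float | None = None
    lambda_z_points: int | None = None
    lambda_z_adj_r2: float | None = None
    t_half: float | None = None
    auc_0_t: float | None = None
    aumc_0_t: float | None = None
    mrt_0_t: float | None = None
    vd: float | None = None  # mL
    cl: float | None = None  # mL/min
    f_pct: float | None = None


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum observed (non-BLQ) concentration and its time; earliest on ties."""
    t, c = profile.observed()
    if t.size == 0:
        raise InsufficientDataError("profile has no quantifiable points")
    i = int(np.argmax(c))  # argmax -> first maximum
    return float(c[i]), float(t[i])


def _ols_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted R^2 of logc ~ t (simple OLS)."""
    n = t.size
    tbar, ybar = t.mean(), logc.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (logc - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = logc - (slope * t + intercept)
    ss_res = (resid**2).sum()
    ss_tot = ((logc - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, adj


def _terminal_candidates(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    t, c = profile.observed()
    if t.size == 0:
        raise InsufficientDataError("profile has no quantifiable points")
    _, tmax = cmax_tmax(profile)
    if profile.route == "oral":
        mask = t > tmax  # absorption phase excluded, Tmax itself too
    else:
        mask = np.ones(t.size, dtype=bool)  # IV bolus: elimination from t=0
    mask &= c > 0
    return t[mask], c[mask]


def fit_lambda_z(
    profile: ConcentrationTimeProfile,
    selection_policy: str = "best_adj_r2",
) -> LambdaZFit:
    """Terminal rate constant from OLS of ln(conc) on time.

    ``best_adj_r2`` searches all contiguous terminal suffixes of >= 3
    candidate points and keeps the one maximizing adjusted R^2 (ties go to
    the subset with more points); ``last_3`` always uses the last three.
    """
    if selection_policy not in LAMBDA_Z_POLICIES:
        raise ConfigurationError(f"policy must be one of {LAMBDA_Z_POLICIES}")
    t, c = _terminal_candidates(profile)
    if t.size < 3:
        raise InsufficientDataError(
            f"{t.size} terminal candidate point(s); >= 3 required"
        )
    logc = np.log(c)

    if selection_policy == "last_3":
        starts = [t.size - 3]
    else:
        starts = list(range(0, t.size - 2))  # longest suffix first

    best: LambdaZFit | None = None
    for s in starts:
        slope, intercept, adj = _ols_loglinear(t[s:], logc[s:])
        if slope >= 0:
            continue
        if best is None or adj > best.adj_r2 + 1e-12:
            best = LambdaZFit(
                lambda_z=-slope,
                n_points=t.size - s,
                adj_r2=adj,
                t_first=float(t[s]),
                t_last=float(t[-1]),
                log_intercept=intercept,
            )
    if best is None:
        raise NoEliminationPhaseError("no terminal subset with a negative slope")
    return best


def half_life(lambda_z: float) -> float:
    """ln(2) / lambda_z, minutes."""
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive")
    return math.log(2.0) / lambda_z


def _integration_grid(
    profile: ConcentrationTimeProfile,
    c0_policy: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Time/concentration grid with BLQ policy and time-zero handling applied."""
    if c0_policy not in C0_POLICIES:
        raise ConfigurationError(f"c0_policy must be one of {C0_POLICIES}")
    _, tmax = cmax_tmax(profile)
    ts, cs = [], []
    for ti, ci, bi in zip(profile.times, profile.concs, profile.blq):
        if bi:
            if ti < tmax:
                ts.append(float(ti))
                cs.append(0.0)
            # post-Tmax BLQ excluded
        else:
            ts.append(float(ti))
            cs.append(float(ci))
    t = np.array(ts)
    c = np.array(cs)
    if t.size and t[0] > 0:
        if profile.route == "oral":
            t = np.insert(t, 0, 0.0)
            c = np.insert(c, 0, 0.0)
        elif c0_policy == "extrapolate":
            c1, c2 = c[0], c[1] if c.size > 1 else c[0]
            if c.size > 1 and c1 > 0 and c2 > 0 and c2 < c1:
                slope = (math.log(c2) - math.log(c1)) / (t[1] - t[0])
                c0 = math.exp(math.log(c1) - slope * t[0])
            else:
                c0 = c1  # no declining start; carry the first value back
            t = np.insert(t, 0, 0.0)
            c = np.insert(c, 0, c0)
    return t, c


def _trapz_to(t: np.ndarray, y: np.ndarray, t_end: float) -> float:
    """Linear trapezoid of y(t) from t[0] to t_end (interpolating the last
    partial segment)."""
    total = 0.0
    for i in range(t.size - 1):
        if t[i + 1] <= t_end:
            total += 0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i])
        elif t[i] < t_end:
            frac = (t_end - t[i]) / (t[i + 1] - t[i])
            y_end = y[i] + frac * (y[i + 1] - y[i])
            total += 0.5 * (y[i] + y_end) * (t_end - t[i])
            break
        else:
            break
    return total


def auc_trapezoid(
    profile: ConcentrationTimeProfile,
    t_end: float | None = None,
    c0_policy: str = "extrapolate",
) -> float:
    """Linear-trapezoidal AUC from time zero to ``t_end`` (default: last
    observed time), ng*min/mL."""
    t, c = _integration_grid(profile, c0_policy)
    if t.size < 2:
        raise InsufficientDataError("AUC requires >= 2 points")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-9:
        raise WindowError(f"t_end {t_end} beyond last observed time {t[-1]}")
    return _trapz_to(t, c, t_end)


def aumc_trapezoid(
    profile: ConcentrationTimeProfile,
    t_end: float | None = None,
    c0_policy: str = "extrapolate",
) -> float:
    """Linear-trapezoidal area under the first-moment curve t*C(t),
    ng*min^2/mL."""
    t, c = _integration_grid(profile, c0_policy)
    if t.size < 2:
        raise InsufficientDataError("AUMC requires >= 2 points")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-9:
        raise WindowError(f"t_end {t_end} beyond last observed time {t[-1]}")
    return _trapz_to(t, t * c, t_end)


def mrt(auc_0_t: float, aumc_0_t: float) -> float:
    """Mean residence time AUMC/AUC, minutes."""
    if auc_0_t <= 0:
        raise ValueError("AUC must be positive")
    return aumc_0_t / auc_0_t


def vd_cl(
    profile: ConcentrationTimeProfile,
    lambda_z: float,
    auc_0_t: float,
    convention: str = "standard",
) -> tuple[float, float]:
    """Volume of distribution (mL) and clearance (mL/min) for an IV bolus.

    ``standard``: Vd = dose/(lambda_z * AUC0-t). ``auc_inf``: the AUC is
    first extrapolated by C_last/lambda_z. Either way Cl = lambda_z * Vd.
    """
    if profile.route != "iv_bolus":
        raise NotApplicableError("Vd/Cl defined here for IV bolus only")
    if lambda_z <= 0 or auc_0_t <= 0:
        raise ValueError("lambda_z and AUC must be positive")
    if convention not in ("standard", "auc_inf"):
        raise ConfigurationError("convention must be 'standard' or 'auc_inf'")
    dose = profile.dose_amount_ng
    auc = auc_0_t
    if convention == "auc_inf":
        _, c = profile.observed()
        auc = auc_0_t + float(c[-1]) / lambda_z
    vd = dose / (lambda_z * auc)
    return vd, lambda_z * vd


def bioavailability(
    auc_oral: float,
    dose_oral_per_kg: float,
    auc_iv: float,
    dose_iv_per_kg: float,
) -> float:
    """Absolute bioavailability: dose-corrected oral AUC over IV AUC, %."""
    if min(auc_oral, dose_oral_per_kg, auc_iv, dose_iv_per_kg) <= 0:
        raise ValueError("all AUCs and doses must be positive")
    return (auc_oral / dose_oral_per_kg) / (auc_iv / dose_iv_per_kg) * 100.0


def run_nca(
    profile: ConcentrationTimeProfile,
    *,
    lambda_z_policy: str = "best_adj_r2",
    auc_convention: str = "standard",
    c0_policy: str = "extrapolate",
    iv_reference: tuple[float, float] | None = None,
) -> NCAResult:
    """Full NCA for one subject.

    ``iv_reference`` is an (AUC0-t, dose_per_kg) pair from the IV arm used to
    compute F for oral profiles.
    """
    c_max, t_max = cmax_tmax(profile)
    res = NCAResult(
        subject_id=profile.subject_id,
        route=profile.route,
        c_max=c_max,
        t_max=t_max,
    )
    fit = fit_lambda_z(profile, lambda_z_policy)
    res.lambda_z = fit.lambda_z
    res.lambda_z_points = fit.n_points
    res.lambda_z_adj_r2 = fit.adj_r2
    res.t_half = half_life(fit.lambda_z)
    res.auc_0_t = auc_trapezoid(profile, c0_policy=c0_policy)
    res.aumc_0_t = aumc_trapezoid(profile, c0_policy=c0_policy)
    res.mrt_0_t = mrt(res.auc_0_t, res.aumc_0_t)
    if profile.route == "iv_bolus" and profile.body_weight is not None:
        res.vd, res.cl = vd_cl(profile, res.lambda_z, res.auc_0_t, auc_convention)
    if profile.route == "oral" and iv_reference is not None:
        auc_iv, dose_iv = iv_reference
        res.f_pct = bioavailability(res.auc_0_t, profile.dose_per_kg, auc_iv, dose_iv)
    return res


_SUMMARY_PARAMS = (
    "lambda_z",
    "t_half",
    "t_max",
    "c_max",
    "auc_0_t",
    "aumc_0_t",
    "mrt_0_t",
    "vd",
    "cl",
    "f_pct",
)


def summarize(
    results: Sequence[NCAResult],
    sd_convention: str = "population",
) -> pd.DataFrame:
    """Mean +/- SD per parameter across subjects of one route."""
    if len(results) < 2:
        raise InsufficientDataError("summary requires >= 2 subjects")
    routes = {r.route for r in results}
    if len(routes) != 1:
        raise ValueError(f"mixed routes in one summary: {sorted(routes)}")
    route = routes.pop()
    ddof = {"population": 0, "sample": 1}[sd_convention]
    rows = []
    for param in _SUMMARY_PARAMS:
        vals = [getattr(r, param) for r in results]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "parameter": param,
                "route": route,
                "n": arr.size,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=ddof)),
            }
        )
    return pd.DataFrame(rows)
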