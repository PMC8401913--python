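"""Synthetic inputs with known ground truth for every pipeline stage.

One-compartment IV-bolus and Bateman oral profiles on sparse sampling
schedules, IS-normalized calibration/QC plates around a configurable linear
response, and Gaussian MRM chromatogram peaks over white baseline noise.
Measurement error is multiplicative lognormal in a median-preserving
parameterization (factor exp(sigma*Z), sigma = sqrt(ln(1 + cv^2))), so the
noisy *median* equals the noise-free value and the mean carries the usual
exp(sigma^2/2) lognormal bias.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nca import ConcentrationTimeProfile
from .signal import ChromatogramTrace

__all__ = [
    "PKSimConfig",
    "ChromSimConfig",
    "IV_SCHEDULE_MIN",
    "ORAL_SCHEDULE_MIN",
    "simulate_iv_profile",
    "simulate_oral_profile",
    "simulate_calibration_plate",
    "simulate_qc_plate",
    "simulate_chromatogram",
    "response_ratio",
    "bateman",
]

#: sparse mouse sampling schedules (minutes post-dose)
IV_SCHEDULE_MIN = (5.0, 15.0, 30.0, 60.0, 90.0, 120.0)
ORAL_SCHEDULE_MIN = (15.0, 30.0, 60.0, 90.0, 120.0, 240.0)

#: default calibration line (response ratio per ng/mL, ratio)
DEFAULT_SLOPE = 0.0053
DEFAULT_INTERCEPT = -0.0015

#: quantification range endpoints used for default BLQ flagging, ng/mL
DEFAULT_LLOQ = 4.0

#: analyte channel and IS channel (precursor m/z, product m/z)
ANALYTE_CHANNEL = (425.0, 247.0)
IS_CHANNEL = (435.0, 339.0)

NG_PER_MG = 1e6


@dataclass
class PKSimConfig:
    """Ground-truth one-compartment parameters and study design.

    IV defaults echo the reported Cmax scale (dose 2 mg/kg to a 0.02 kg
    mouse, V = 14.4 mL, k = 0.014/min); oral requires ``ka`` and ``f_abs``.
    """

    route: str  # iv_bolus | oral
    dose_per_kg: float = 2.0  # mg/kg
    body_weight: float = 0.02  # kg
    volume_ml: float = 14.4  # apparent volume V, mL
    k_elim: float = 0.014  # elimination rate, 1/min
    ka: float | None = None  # absorption rate, 1/min (oral)
    f_abs: float | None = None  # absorbed fraction (oral)
    schedule: tuple[float, ...] | None = None  # sampling times, min
    error_cv: float = 0.0  # multiplicative lognormal CV
    n_subjects: int = 3
    seed: int = 0
    lloq: float = DEFAULT_LLOQ  # ng/mL, for BLQ flagging

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "oral"):
            raise ConfigurationError(f"unknown route {self.route!r}")
        if min(self.dose_per_kg, self.body_weight, self.volume_ml, self.k_elim) <= 0:
            raise ConfigurationError("dose, weight, volume and rates must be positive")
        if self.error_cv < 0:
            raise ConfigurationError("error_cv must be non-negative")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.route == "oral":
            if self.ka is None or self.f_abs is None:
                raise ConfigurationError("oral route requires ka and f_abs")
            if self.ka <= 0:
                raise ConfigurationError("ka must be positive")
            if self.ka == self.k_elim:
                raise ConfigurationError(
                    "ka must differ from k (degenerate Bateman form unsupported)"
                )
            if not 0 < self.f_abs <= 1:
                raise ConfigurationError("f_abs must be in (0, 1]")
        if self.schedule is None:
            self.schedule = IV_SCHEDULE_MIN if self.route == "iv_bolus" else ORAL_SCHEDULE_MIN
        sched = np.asarray(self.schedule, dtype=float)
        if np.any(sched <= 0) or np.any(np.diff(sched) <= 0):
            raise ConfigurationError("schedule must be strictly increasing and positive")
        self.schedule = tuple(float(t) for t in sched)

    @property
    def dose_amount_ng(self) -> float:
        return self.dose_per_kg * self.body_weight * NG_PER_MG


@dataclass
class ChromSimConfig:
    """Gaussian-peak-over-noise model for one MRM channel."""

    channel: tuple[float, float] = ANALYTE_CHANNEL
    retention_time: float = 5.0  # min
    peak_sigma: float = 0.08  # min
    peak_height: float = 1000.0  # intensity units
    baseline_noise_sd: float = 5.0  # intensity units
    sampling_interval: float = 0.01  # min
    run_length: float = 10.0  # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0:
            raise ConfigurationError("peak_sigma must be positive")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be positive")
        if self.run_length <= self.retention_time:
            raise ConfigurationError("run_length must exceed retention_time")
        if self.baseline_noise_sd < 0:
            raise ConfigurationError("baseline_noise_sd must be non-negative")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, n))


def bateman(t, f_abs: float, dose_ng: float, volume_ml: float, ka: float, k: float):
    """First-order absorption / first-order elimination concentration, ng/mL."""
    t = np.asarray(t, dtype=float)
    return (
        f_abs * dose_ng * ka / (volume_ml * (ka - k))
        * (np.exp(-k * t) - np.exp(-ka * t))
    )


def _make_profiles(cfg: PKSimConfig, noise_free: np.ndarray, prefix: str):
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.schedule)
    profiles = []
    for i in range(cfg.n_subjects):
        conc = noise_free * _lognormal_factors(rng, cfg.error_cv, t.size)
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=f"{prefix}{i + 1:02d}",
                route=cfg.route,
                dose_per_kg=cfg.dose_per_kg,
                body_weight=cfg.body_weight,
                times=t,
                concs=conc,
                blq=conc < cfg.lloq,
            )
        )
    return profiles


def simulate_iv_profile(cfg: PKSimConfig) -> list[ConcentrationTimeProfile]:
    """IV-bolus profiles: C(t) = (dose/V) * exp(-k t), with per-point noise."""
    if cfg.route != "iv_bolus":
        raise ConfigurationError("simulate_iv_profile requires route='iv_bolus'")
    t = np.asarray(cfg.schedule)
    clean = cfg.dose_amount_ng / cfg.volume_ml * np.exp(-cfg.k_elim * t)
    return _make_profiles(cfg, clean, "iv")


def simulate_oral_profile(cfg: PKSimConfig) -> list[ConcentrationTimeProfile]:
    """Oral profiles following the Bateman function, with per-point noise."""
    if cfg.route != "oral":
        raise ConfigurationError("simulate_oral_profile requires route='oral'")
    t = np.asarray(cfg.schedule)
    clean = bateman(t, cfg.f_abs, cfg.dose_amount_ng, cfg.volume_ml, cfg.ka, cfg.k_elim)
    return _make_profiles(cfg, clean, "po")


def response_ratio(slope: float, intercept: float, conc: float) -> float:
    """Noise-free analyte/IS response ratio for a concentration."""
    return slope * conc + intercept


def _plate_rows(
    rng: np.random.Generator,
    slope: float,
    intercept: float,
    levels: Sequence[float],
    replicates: int,
    noise_cv: float,
    *,
    role: str,
    condition: str,
    run_id: str,
    is_nominal: float,
    is_cv: float,
    bias: float,
) -> list[dict]:
    rows = []
    for level in levels:
        if level <= 0:
            raise ConfigurationError(f"plate level must be positive, got {level}")
        for _ in range(replicates):
            measured = level * bias * _lognormal_factors(rng, noise_cv, 1)[0]
            ratio = response_ratio(slope, intercept, measured)
            is_resp = is_nominal * _lognormal_factors(rng, is_cv, 1)[0]
            rows.append(
                {
                    "role": role,
                    "nominal_ng_per_ml": float(level),
                    "analyte_response": ratio * is_resp,
                    "is_response": is_resp,
                    "run_id": run_id,
                    "condition": condition,
                }
            )
    return rows


def simulate_calibration_plate(
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    levels: Sequence[float] = (4.0, 12.0, 75.0, 120.0, 150.0, 300.0),
    replicates: int = 1,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    run_id: str = "run1",
    is_nominal: float = 2.0e5,
    is_cv: float = 0.02,
) -> pd.DataFrame:
    """Calibration standards on the configured line with multiplicative noise.

    The response ratio per well is ``slope*conc + intercept`` perturbed
    multiplicatively; the IS response fluctuates around ``is_nominal`` with
    its own small CV. Deterministic per seed.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = _plate_rows(
        rng, slope, intercept, levels, replicates, noise_cv,
        role="cal", condition="", run_id=run_id,
        is_nominal=is_nominal, is_cv=is_cv, bias=1.0,
    )
    return pd.DataFrame(rows)


def simulate_qc_plate(
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    levels: Sequence[float] = (4.0, 10.0, 120.0, 230.0),
    replicates: int = 6,
    noise_cv: float = 0.02,
    seed: int = 0,
    *,
    run_ids: Sequence[str] = ("run1",),
    role: str = "qc",
    condition: str = "fresh",
    bias: float = 1.0,
    is_nominal: float = 2.0e5,
    is_cv: float = 0.02,
) -> pd.DataFrame:
    """QC / stability / dilution wells at the given levels.

    ``bias`` scales the true measured concentration (e.g. to emulate
    degradation in a stressed stability set, or a 1/3 dilution).
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for run_id in run_ids:
        rows.extend(
            _plate_rows(
                rng, slope, intercept, levels, replicates, noise_cv,
                role=role, condition=condition, run_id=run_id,
                is_nominal=is_nominal, is_cv=is_cv, bias=bias,
            )
        )
    return pd.DataFrame(rows)


def simulate_chromatogram(cfg: ChromSimConfig) -> ChromatogramTrace:
    """Gaussian peak at the retention time plus i.i.d. Gaussian baseline noise."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.run_length / cfg.sampling_interval)) + 1
    t = np.arange(n) * cfg.sampling_interval
    signal = cfg.peak_height * np.exp(
        -((t - cfg.retention_time) ** 2) / (2.0 * cfg.peak_sigma**2)
    )
    if cfg.baseline_noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.baseline_noise_sd, n)
    return ChromatogramTrace(times=t, intensities=signal, channel=cfg.channel)
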