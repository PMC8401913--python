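"""Plain-CSV readers/writers for the pipeline's three table schemas."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nca import ConcentrationTimeProfile
from .signal import ChromatogramTrace

__all__ = [
    "PROFILE_COLUMNS",
    "PLATE_COLUMNS",
    "CHROM_COLUMNS",
    "profiles_to_frame",
    "write_profiles",
    "read_profiles",
    "write_plate",
    "read_plate",
    "write_chromatogram",
    "read_chromatogram",
]

PROFILE_COLUMNS = [
    "subject_id",
    "route",
    "dose_mg_per_kg",
    "body_weight_kg",
    "time_min",
    "conc_ng_per_ml",
    "blq",
]

PLATE_COLUMNS = [
    "role",
    "nominal_ng_per_ml",
    "analyte_response",
    "is_response",
    "run_id",
    "condition",
]

CHROM_COLUMNS = ["time_min", "intensity", "channel_q1_mz", "channel_q3_mz"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")


def profiles_to_frame(profiles: Sequence[ConcentrationTimeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concs, p.blq):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "route": p.route,
                    "dose_mg_per_kg": p.dose_per_kg,
                    "body_weight_kg": p.body_weight,
                    "time_min": float(t),
                    "conc_ng_per_ml": float(c),
                    "blq": int(b),
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles(profiles: Sequence[ConcentrationTimeProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[ConcentrationTimeProfile]:
    df = pd.read_csv(path)
    _check_columns(df, PROFILE_COLUMNS, "profile CSV")
    profiles = []
    for subject_id, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_min")
        bw = grp["body_weight_kg"].iloc[0]
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(subject_id),
                route=str(grp["route"].iloc[0]),
                dose_per_kg=float(grp["dose_mg_per_kg"].iloc[0]),
                body_weight=None if pd.isna(bw) else float(bw),
                times=grp["time_min"].to_numpy(float),
                concs=grp["conc_ng_per_ml"].to_numpy(float),
                blq=grp["blq"].to_numpy().astype(bool),
            )
        )
    return profiles


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    _check_columns(plate, PLATE_COLUMNS, "plate table")
    plate.to_csv(path, index=False)


def read_plate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _check_columns(df, PLATE_COLUMNS, "plate CSV")
    df["condition"] = df["condition"].fillna("")
    return df


def write_chromatogram(trace: ChromatogramTrace, path: str | Path) -> None:
    q1, q3 = trace.channel if trace.channel is not None else (np.nan, np.nan)
    pd.DataFrame(
        {
            "time_min": trace.times,
            "intensity": trace.intensities,
            "channel_q1_mz": q1,
            "channel_q3_mz": q3,
        }
    ).to_csv(path, index=False)


def read_chromatogram(path: str | Path) -> ChromatogramTrace:
    df = pd.read_csv(path)
    _check_columns(df, CHROM_COLUMNS, "chromatogram CSV")
    channel = None
    if not df["channel_q1_mz"].isna().all():
        channel = (float(df["channel_q1_mz"].iloc[0]), float(df["channel_q3_mz"].iloc[0]))
    return ChromatogramTrace(
        times=df["time_min"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        channel=channel,
    )
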