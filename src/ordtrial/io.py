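"""CSV / YAML interchange for cohorts, trials, and long-format rows.

Wide cohort schema (one row per participant):
    id, arm (optional), left_ml, right_ml,
    base_L_C5..base_L_T1, base_R_C5..base_R_T1,
    fu_L_C5..fu_L_T1, fu_R_C5..fu_R_T1

Long schema (one row per below-level muscle):
    participant_id, side, segment, motor_level, y_base, y_auto, y_out, arm
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .anatomy import SEGMENTS, Constellation, lev_code
from .ordinal import ROW_COLUMNS
from .simulate import ParticipantRecord

_SIDE_TAG = {"left": "L", "right": "R"}

BASE_COLUMNS = [f"base_{_SIDE_TAG[s]}_{seg}" for s in ("left", "right") for seg in SEGMENTS]
FU_COLUMNS = [f"fu_{_SIDE_TAG[s]}_{seg}" for s in ("left", "right") for seg in SEGMENTS]


def records_to_wide(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "id": rec.id,
            "arm": rec.arm,
            "left_ml": rec.constellation.left_ml,
            "right_ml": rec.constellation.right_ml,
        }
        row.update(dict(zip(BASE_COLUMNS, np.asarray(rec.baseline, dtype=int))))
        if rec.followup is not None:
            row.update(dict(zip(FU_COLUMNS, np.asarray(rec.followup, dtype=int))))
        rows.append(row)
    return pd.DataFrame(rows)


def wide_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    missing = [c for c in ["id", "left_ml", "right_ml", *BASE_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"wide cohort table missing columns: {missing}")
    has_fu = all(c in df.columns for c in FU_COLUMNS)
    records = []
    for _, row in df.iterrows():
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                arm=int(row["arm"]) if "arm" in df.columns and not pd.isna(row.get("arm")) else 0,
                constellation=Constellation(str(row["left_ml"]), str(row["right_ml"])),
                baseline=row[BASE_COLUMNS].to_numpy(dtype=int),
                followup=row[FU_COLUMNS].to_numpy(dtype=int) if has_fu else None,
            )
        )
    return records


def write_trial_csv(records, path) -> None:
    records_to_wide(records).to_csv(path, index=False)


def read_trial_csv(path) -> list[ParticipantRecord]:
    return wide_to_records(pd.read_csv(path))


def read_long_csv(path) -> pd.DataFrame:
    """Long-format rows; recomputes the lev code column from
    (motor_level, segment)."""
    df = pd.read_csv(path)
    required = ["participant_id", "side", "segment", "motor_level", "y_base", "y_auto", "y_out", "arm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"long table missing columns: {missing}")
    df = df.dropna(subset=["y_base", "y_auto", "y_out"]).copy()
    df["lev"] = [
        lev_code(ml, seg) for ml, seg in zip(df["motor_level"], df["segment"])
    ]
    for col in ("y_base", "y_auto", "y_out", "arm"):
        df[col] = df[col].astype(int)
    return df[ROW_COLUMNS]


def write_long_csv(rows: pd.DataFrame, path) -> None:
    out = rows.drop(columns=["lev"])
    out.to_csv(path, index=False)


def load_population_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
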