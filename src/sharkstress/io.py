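"""Plain-CSV readers/writers for the pipeline's tabular interchange formats.

Column conventions
------------------
roster          shark_id, mass_kg, total_length_mm, temperature_c, pco2_uatm, group_id
o2 trace        time_s, o2_mg_l, phase
accel trace     time_s, x_g, y_g, z_g
turns           shark_id, trial_side, turn_direction
titration       acid_ml, ph
trait table     shark_id, mass, temperature, pco2, group_id, <trait columns>
effects         trait, term, mean, ci_low, ci_high, significant
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behaviour import AccelTrace, TurnRecord
from .carbonate import TitrationCurve
from .respirometry import O2Trace
from .synthetic import Shark

__all__ = [
    "write_roster",
    "read_roster",
    "write_o2_trace",
    "read_o2_trace",
    "write_accel_trace",
    "read_accel_trace",
    "write_turns",
    "read_turns",
    "read_titration",
    "write_titration",
    "read_trait_table",
    "write_trait_table",
]


def write_roster(roster: list[Shark], path: str | Path) -> None:
    pd.DataFrame(
        {
            "shark_id": [s.id for s in roster],
            "mass_kg": [s.mass for s in roster],
            "total_length_mm": [s.total_length for s in roster],
            "temperature_c": [s.temperature for s in roster],
            "pco2_uatm": [s.pco2 for s in roster],
            "group_id": [s.group_id for s in roster],
        }
    ).to_csv(path, index=False)


def read_roster(path: str | Path) -> list[Shark]:
    df = pd.read_csv(path)
    return [
        Shark(
            id=row.shark_id,
            mass=row.mass_kg,
            total_length=row.total_length_mm,
            temperature=row.temperature_c,
            pco2=row.pco2_uatm,
            group_id=row.group_id,
        )
        for row in df.itertuples()
    ]


def write_o2_trace(trace: O2Trace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "o2_mg_l": trace.o2, "phase": trace.phase}
    ).to_csv(path, index=False)


def read_o2_trace(
    path: str | Path,
    volume: float,
    mass: float,
    animal_volume: float | None = None,
    temperature: float = 28.0,
) -> O2Trace:
    """Trace CSVs carry no chamber geometry; supply it at read time."""
    df = pd.read_csv(path)
    return O2Trace(
        time=df["time_s"].to_numpy(float),
        o2=df["o2_mg_l"].to_numpy(float),
        phase=df["phase"].to_numpy(str),
        volume=volume,
        mass=mass,
        animal_volume=animal_volume,
        temperature=temperature,
    )


def write_accel_trace(trace: AccelTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "x_g": trace.x, "y_g": trace.y, "z_g": trace.z}
    ).to_csv(path, index=False)


def read_accel_trace(
    path: str | Path, sampling_rate: float = 25.0, clock_start: float = 0.0
) -> AccelTrace:
    df = pd.read_csv(path)
    return AccelTrace(
        time=df["time_s"].to_numpy(float),
        x=df["x_g"].to_numpy(float),
        y=df["y_g"].to_numpy(float),
        z=df["z_g"].to_numpy(float),
        sampling_rate=sampling_rate,
        clock_start=clock_start,
    )


def write_turns(records: list[TurnRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        sides = rec.maze_sides or [""] * len(rec.turns)
        for side, turn in zip(sides, rec.turns):
            rows.append(
                {"shark_id": rec.shark_id, "trial_side": side, "turn_direction": turn}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_turns(path: str | Path) -> list[TurnRecord]:
    df = pd.read_csv(path)
    records = []
    for shark_id, grp in df.groupby("shark_id", sort=False):
        records.append(
            TurnRecord(
                shark_id=str(shark_id),
                turns=list(grp["turn_direction"]),
                maze_sides=list(grp["trial_side"]) if "trial_side" in grp else None,
            )
        )
    return records


def write_titration(curve: TitrationCurve, path: str | Path) -> None:
    pd.DataFrame({"acid_ml": curve.acid_volumes, "ph": curve.ph}).to_csv(
        path, index=False
    )


def read_titration(
    path: str | Path,
    sample_volume: float = 50.0,
    acid_concentration: float = 0.1,
    temperature: float = 25.0,
    salinity: float = 35.0,
) -> TitrationCurve:
    df = pd.read_csv(path)
    return TitrationCurve(
        acid_volumes=df["acid_ml"].to_numpy(float),
        ph=df["ph"].to_numpy(float),
        sample_volume=sample_volume,
        acid_concentration=acid_concentration,
        temperature=temperature,
        salinity=salinity,
    )


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"shark_id", "temperature", "pco2", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns {sorted(missing)}")
    return df
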