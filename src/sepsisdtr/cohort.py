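"""Patient-day cohort containers and CSV round-tripping.

The on-disk cohort format is a flat CSV with one row per patient-day:

    patient_id, day, age, icu_type, hr, mbp, rr, temp, urine_ml, mv,
    vasopressor, fluid_ml_per_kg, death_time, discharge_time, status

Baseline fields (age, icu_type, outcome columns) are repeated on every row
of a patient. ``status`` is ``died`` or ``discharged_alive`` and exactly one
of ``death_time`` / ``discharge_time`` is populated, in days from ICU entry
(beginning of day 1 is time 0). In memory the same cohort exists in three
forms: the long frame above, a list of :class:`Trajectory`, and a wide
per-patient frame with ``<var>_d<day>`` columns used to build stage designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MalformedTrajectoryError, SchemaError
from .terms import ICU_TYPES

FLUID_CUTOFF = 40.0  # ml/kg/day; at or above is the liberal strategy

COHORT_COLUMNS = [
    "patient_id", "day", "age", "icu_type", "hr", "mbp", "rr", "temp",
    "urine_ml", "mv", "vasopressor", "fluid_ml_per_kg",
    "death_time", "discharge_time", "status",
]

_NUMERIC = ["day", "age", "hr", "mbp", "rr", "temp", "urine_ml", "mv",
            "vasopressor", "fluid_ml_per_kg"]

#: decision days and stage boundaries: stage k spans [2(k-1), 2k) days,
#: stage 3 open-ended
STAGE_STARTS = {1: 0.0, 2: 2.0, 3: 4.0}
STAGE_SPANS = {1: 2.0, 2: 2.0, 3: math.inf}
DECISION_DAYS = {1: 1, 2: 3, 3: 5}
HORIZON_DAYS = 7


@dataclass
class DailyRecord:
    """One ICU day of vitals, support flags and fluid intake."""

    day: int
    hr: float
    mbp: float
    rr: float
    temp: float
    urine_ml: float
    mv: int
    vasopressor: int
    fluid_ml_per_kg: float
    paco2: float | None = None
    wbc: float | None = None
    band_pct: float | None = None

    @property
    def fluid_strategy(self) -> int:
        """1 (liberal) iff daily intake is at or above 40 ml/kg."""
        return int(self.fluid_ml_per_kg >= FLUID_CUTOFF)


@dataclass
class Trajectory:
    """A patient's baseline attributes, daily records and outcome."""

    patient_id: str
    age: float
    icu_type: str
    daily_records: list[DailyRecord] = field(default_factory=list)
    death_time: float | None = None
    discharge_time: float | None = None

    def __post_init__(self):
        if (self.death_time is None) == (self.discharge_time is None):
            raise MalformedTrajectoryError(
                f"patient {self.patient_id!r}: exactly one of death_time/"
                "discharge_time must be present")
        if self.outcome_time <= 0:
            raise MalformedTrajectoryError(
                f"patient {self.patient_id!r}: outcome time must be positive")

    @property
    def died(self) -> bool:
        return self.death_time is not None

    @property
    def status(self) -> str:
        return "died" if self.died else "discharged_alive"

    @property
    def outcome_time(self) -> float:
        return self.death_time if self.died else self.discharge_time

    def record(self, day: int) -> DailyRecord | None:
        for r in self.daily_records:
            if r.day == day:
                return r
        return None


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long patient-day frame for a list of trajectories."""
    rows = []
    for t in trajs:
        for r in t.daily_records:
            rows.append({
                "patient_id": t.patient_id, "day": r.day, "age": t.age,
                "icu_type": t.icu_type, "hr": r.hr, "mbp": r.mbp, "rr": r.rr,
                "temp": r.temp, "urine_ml": r.urine_ml, "mv": r.mv,
                "vasopressor": r.vasopressor,
                "fluid_ml_per_kg": r.fluid_ml_per_kg,
                "death_time": t.death_time if t.died else np.nan,
                "discharge_time": np.nan if t.died else t.discharge_time,
                "status": t.status,
            })
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    validate_cohort_frame(df)
    out = []
    for pid, g in df.sort_values(["patient_id", "day"]).groupby("patient_id", sort=True):
        first = g.iloc[0]
        died = first["status"] == "died"
        recs = [DailyRecord(day=int(r.day), hr=r.hr, mbp=r.mbp, rr=r.rr,
                            temp=r.temp, urine_ml=r.urine_ml, mv=int(r.mv),
                            vasopressor=int(r.vasopressor),
                            fluid_ml_per_kg=r.fluid_ml_per_kg)
                for r in g.itertuples()]
        out.append(Trajectory(
            patient_id=str(pid), age=float(first["age"]),
            icu_type=str(first["icu_type"]), daily_records=recs,
            death_time=float(first["death_time"]) if died else None,
            discharge_time=None if died else float(first["discharge_time"])))
    return out


def validate_cohort_frame(df: pd.DataFrame) -> None:
    """Schema and trajectory-shape validation of a long cohort frame.

    Raises :class:`SchemaError` for structural table defects (columns,
    types, duplicates) and :class:`MalformedTrajectoryError` for per-patient
    inconsistencies (day gaps, records beyond the outcome, bad times).
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise SchemaError(f"cohort table has unknown columns: {unknown}")
    for c in _NUMERIC:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()].tolist()[:5]
            raise SchemaError(f"column {c!r} is not numeric (rows {bad})")
    dup = df.duplicated(subset=["patient_id", "day"])
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise SchemaError(f"duplicated (patient_id, day) rows at index {rows}")
    bad_icu = set(df["icu_type"].unique()) - set(ICU_TYPES)
    if bad_icu:
        raise SchemaError(f"unknown icu_type labels: {sorted(bad_icu)}")

    for pid, g in df.groupby("patient_id"):
        first = g.iloc[0]
        status = first["status"]
        if status not in ("died", "discharged_alive"):
            raise SchemaError(f"patient {pid!r}: bad status {status!r}")
        has_death = np.isfinite(g["death_time"]).any()
        has_disch = np.isfinite(g["discharge_time"]).any()
        if has_death == has_disch:
            raise MalformedTrajectoryError(
                f"patient {pid!r}: exactly one of death_time/discharge_time required")
        if (status == "died") != has_death:
            raise MalformedTrajectoryError(f"patient {pid!r}: status/outcome mismatch")
        outcome = float(first["death_time"] if has_death else first["discharge_time"])
        if not outcome > 0:
            raise MalformedTrajectoryError(
                f"patient {pid!r}: outcome time {outcome} must be positive")
        days = sorted(g["day"].astype(int))
        expected_last = math.ceil(min(outcome, HORIZON_DAYS))
        if days != list(range(1, len(days) + 1)):
            raise MalformedTrajectoryError(
                f"patient {pid!r}: day sequence {days} has gaps or does not start at 1")
        if days[-1] > max(expected_last, 1):
            raise MalformedTrajectoryError(
                f"patient {pid!r}: daily records extend past the outcome time "
                f"(last day {days[-1]}, outcome {outcome})")
        if days[-1] < math.ceil(min(outcome, 5)):
            raise MalformedTrajectoryError(
                f"patient {pid!r}: daily records stop at day {days[-1]} before "
                f"the outcome at {outcome}")


def cohort_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: baseline columns plus ``<var>_d<day>`` columns.

    Adds the derived daily ``lf_d<day>`` liberal-fluid indicator
    (intake at or above 40 ml/kg/day), ``outcome_time`` and ``died``.
    """
    base = df.groupby("patient_id").first()[
        ["age", "icu_type", "death_time", "discharge_time", "status"]].copy()
    base["died"] = (base["status"] == "died").astype(int)
    base["outcome_time"] = np.where(base["died"] == 1, base["death_time"],
                                    base["discharge_time"])
    daily = df.copy()
    daily["lf"] = (daily["fluid_ml_per_kg"] >= FLUID_CUTOFF).astype(float)
    wide = daily.pivot(index="patient_id", columns="day",
                       values=["hr", "mbp", "rr", "temp", "urine_ml", "mv",
                               "vasopressor", "fluid_ml_per_kg", "lf"])
    wide.columns = [f"{var}_d{int(day)}" for var, day in wide.columns]
    return base.join(wide)


def load_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; rows normalized by (patient_id, day)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "icu_type": str, "status": str},
                     float_precision="round_trip")
    validate_cohort_frame(df)
    return df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")
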