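"""Three-stage decision structure over patient-day trajectories.

Decisions are made on ICU days 1, 3 and 5. Stage k spans days
[2k-1, 2k] — time [2(k-1), 2k) from ICU entry — with stage 3 open-ended.
The stage survival time T_k runs from the stage start to the next stage
boundary, or to death/alive-discharge if that happens first; patients
discharged alive are censored and never enter later stages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (DECISION_DAYS, FLUID_CUTOFF, STAGE_SPANS, STAGE_STARTS,
                     DailyRecord, Trajectory, trajectories_to_frame,
                     cohort_to_wide)
from .errors import MalformedTrajectoryError
from .terms import ModelSpec, evaluate_terms

logger = logging.getLogger(__name__)

RESTRICTED, LIBERAL = 0, 1


@dataclass(frozen=True)
class ScreeningThresholds:
    """Systemic inflammatory response (SIRS) criteria thresholds."""

    temp_low: float = 36.0
    temp_high: float = 38.0
    hr_min: float = 90.0
    rr_min: float = 20.0
    paco2_max: float = 32.0
    wbc_high: float = 12000.0
    wbc_low: float = 4000.0
    band_pct_min: float = 10.0
    criteria_required: int = 2

    def __post_init__(self):
        if not (self.temp_low < self.temp_high and self.wbc_low < self.wbc_high):
            raise ValueError("screening thresholds are inconsistent")


@dataclass
class StageRecord:
    """One patient's record for one decision stage."""

    patient_id: str
    stage: int
    entered: bool
    a: int | None = None
    daily_actions: dict[int, int] = field(default_factory=dict)
    T: float | None = None
    event: int = 0
    censored: int = 0
    features: dict[str, float] = field(default_factory=dict)
    optimal_action: int | None = None
    t_tilde: float | None = None


def sirs_criteria_count(record: DailyRecord, thresholds: ScreeningThresholds
                        = ScreeningThresholds()) -> int:
    """Number of SIRS criteria met; missing WBC/PaCO2 degrade to not-met."""
    t = thresholds
    count = 0
    if record.temp <= t.temp_low or record.temp >= t.temp_high:
        count += 1
    if record.hr >= t.hr_min:
        count += 1
    paco2_low = record.paco2 is not None and record.paco2 < t.paco2_max
    if record.paco2 is None:
        logger.debug("PaCO2 missing on day %s; criterion degraded to RR only",
                     record.day)
    if record.rr >= t.rr_min or paco2_low:
        count += 1
    if record.wbc is None and record.band_pct is None:
        logger.debug("WBC/bands missing on day %s; criterion not met", record.day)
    wbc_abn = record.wbc is not None and (record.wbc > t.wbc_high
                                          or record.wbc < t.wbc_low)
    band_abn = record.band_pct is not None and record.band_pct > t.band_pct_min
    if wbc_abn or band_abn:
        count += 1
    return count


def screen_sirs(record: DailyRecord, infection_flag: bool,
                thresholds: ScreeningThresholds = ScreeningThresholds()) -> bool:
    """Sepsis screen: suspected/documented infection plus >= 2 SIRS criteria."""
    if not infection_flag:
        return False
    return sirs_criteria_count(record, thresholds) >= thresholds.criteria_required


def dichotomize_fluid(intake: float) -> int:
    """Liberal (1) iff daily intake >= 40 ml/kg/day, else restricted (0)."""
    if intake < 0:
        raise ValueError(f"fluid intake must be nonnegative, got {intake}")
    return LIBERAL if intake >= FLUID_CUTOFF else RESTRICTED


def build_stage_records(traj: Trajectory) -> list[StageRecord]:
    """Stage records for one trajectory (entered stages only).

    T_k is measured from the stage start to the earlier of the next stage
    boundary and the outcome; ``event`` marks death within the stage,
    ``censored`` alive discharge within the stage. A patient enters stage
    k+1 iff still in the ICU strictly after the boundary.
    """
    outcome = traj.outcome_time
    if outcome <= 0:
        raise MalformedTrajectoryError(
            f"patient {traj.patient_id!r}: nonpositive outcome time")
    actions: dict[int, int] = {}
    for r in traj.daily_records:
        if r.day <= 5:
            actions[r.day] = dichotomize_fluid(r.fluid_ml_per_kg)
    records = []
    for k in (1, 2, 3):
        start, span = STAGE_STARTS[k], STAGE_SPANS[k]
        if outcome <= start:
            break
        day = DECISION_DAYS[k]
        if day not in actions:
            raise MalformedTrajectoryError(
                f"patient {traj.patient_id!r}: no fluid record on decision day {day}")
        T = min(outcome - start, span)
        within = outcome <= start + span
        records.append(StageRecord(
            patient_id=traj.patient_id, stage=k, entered=True,
            a=actions[day], daily_actions=dict(actions), T=T,
            event=int(traj.died and within),
            censored=int((not traj.died) and within)))
    return records


def assemble_features(traj: Trajectory, stage: int, spec: ModelSpec) -> dict[str, float]:
    """Evaluated blip and treatment-free term values for one patient-stage.

    Raises :class:`MissingDataError` naming patient, day and variable if a
    required covariate was not observed; nothing is imputed.
    """
    wide = cohort_to_wide(trajectories_to_frame([traj]))
    seen = {}
    for terms in (spec.psi_terms, spec.beta_terms):
        df = evaluate_terms(wide, terms, context=f"stage {stage} features")
        for name in df.columns:
            seen[name] = float(df.iloc[0][name])
    return seen


def stage_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Vectorized stage records for a whole cohort.

    One row per entered patient-stage with columns ``patient_id``, ``stage``,
    ``a`` (decision-day strategy), ``T``, ``event``, ``censored`` and
    ``died_final`` (the patient's eventual status, used by the censoring
    weights). ``wide`` is the per-patient table from
    :func:`sepsisdtr.cohort.cohort_to_wide`.
    """
    frames = []
    outcome = wide["outcome_time"].to_numpy(float)
    died = wide["died"].to_numpy(int)
    for k in (1, 2, 3):
        start, span = STAGE_STARTS[k], STAGE_SPANS[k]
        entered = outcome > start
        if not entered.any():
            continue
        col = f"lf_d{DECISION_DAYS[k]}"
        if col not in wide.columns:
            raise MalformedTrajectoryError(
                f"stage {k}: no fluid strategy recorded on day {DECISION_DAYS[k]}")
        a = wide.loc[entered, col].to_numpy(float)
        if np.isnan(a).any():
            pid = wide.index[entered][np.isnan(a)][0]
            raise MalformedTrajectoryError(
                f"patient {pid!r}: missing fluid on decision day {DECISION_DAYS[k]}")
        T = np.minimum(outcome[entered] - start, span)
        within = outcome[entered] <= start + span if math.isfinite(span) \
            else np.ones(entered.sum(), bool)
        frames.append(pd.DataFrame({
            "patient_id": wide.index[entered],
            "stage": k,
            "a": a.astype(int),
            "T": T,
            "event": (died[entered] == 1) & within,
            "censored": (died[entered] == 0) & within,
            "died_final": died[entered],
        }))
    out = pd.concat(frames, ignore_index=True)
    out["event"] = out["event"].astype(int)
    out["censored"] = out["censored"].astype(int)
    return out
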