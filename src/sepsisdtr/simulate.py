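"""Seeded synthetic ICU cohorts with known ground-truth regime structure.

The generator emulates the statistical structure the staged regime analysis
assumes, not ICU physiology: daily vitals follow patient-centred AR(1)
processes, a stochastic behaviour policy assigns the daily liberal (>= 40
ml/kg/day) or restricted fluid strategy from current covariates and the
previous day's strategy, and stage survival times are drawn from log-normal
accelerated failure time models

    log T_k = beta_k' h_kbeta + a_k psi_k' h_kpsi + eps_k,
    eps_k ~ Normal(0, sigma_k),

with the decision-day strategy a_k entering through a stage-specific blip
psi_k' h_kpsi (quadratic mean blood pressure at stage 1, prior urine output
and prior strategy at stage 2, a day-3 x day-4 strategy interaction at
stage 3). Death occurs within stage k when the drawn T_k is shorter than
the two-day stage span (stage 3 is open-ended); alive discharge is an
independent exponential clock that can only ring after day 1 and censors
the survival time. Everything is driven by one ``numpy`` Generator seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (COHORT_COLUMNS, DECISION_DAYS, FLUID_CUTOFF,
                     frame_to_trajectories)
from .terms import ICU_TYPES, ModelSpec, default_stage_specs, design_matrix


def _default_icu_probs() -> dict[str, float]:
    # unit mix resembling a large multi-centre ICU cohort (Med-Surg dominant)
    return dict(zip(ICU_TYPES, (0.06, 0.02, 0.01, 0.06, 0.13, 0.66, 0.02, 0.04)))


def _default_daily() -> dict[str, tuple[float, float, float]]:
    # variable -> (population mean, between-patient SD, within-day SD)
    return {
        "hr": (109.0, 15.0, 8.0),
        "mbp": (57.0, 10.0, 6.0),
        "rr": (29.0, 6.0, 3.0),
        "temp": (37.3, 0.6, 0.3),
        "urine_ml": (800.0, 400.0, 250.0),
    }


def _default_policy() -> dict[str, float]:
    # log-odds of the liberal strategy; covariates centred so the day-1
    # marginal rate is ~50% (balanced arms)
    return {"const": 0.0, "mbp": -0.4, "hr": 0.3, "mv": 0.5, "prev_lf": 0.8}


def _default_psi() -> dict[int, dict[str, float]]:
    return {
        1: {"const": -1.25, "age_s": -0.05, "mbp1_s": 0.70, "mbp1_s2": -0.11,
            "hr1_s": 0.08, "mv1": 0.35},
        2: {"const": 0.10, "mbp3_s": -0.16, "urine2_k": 0.18, "lf1": 0.24,
            "mv3": 0.50},
        3: {"const": -0.45, "mv5": 0.65, "hr5_s": 0.03, "lf3": 0.11,
            "lf4": 0.43, "lf3x4": -0.46},
    }


def _default_beta() -> dict[int, dict[str, float]]:
    return {
        1: {"const": 0.95, "mbp1_s": 0.10, "hr1_s": -0.06, "mv1": -0.30},
        2: {"const": 0.60, "mbp3_s": 0.10, "mv3": -0.30},
        3: {"const": 0.30, "mbp5_s": 0.10, "mv5": -0.30},
    }


@dataclass
class SimParams:
    """Generating parameters for a synthetic cohort.

    ``psi`` / ``beta`` are keyed by the term names of the stage model specs
    (by default :func:`sepsisdtr.terms.default_stage_specs`), so the truth
    is expressed in exactly the vocabulary the estimator fits.
    """

    seed: int = 0
    age_mean: float = 65.0
    age_sd: float = 15.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    icu_probs: dict[str, float] = field(default_factory=_default_icu_probs)
    daily: dict[str, tuple[float, float, float]] = field(default_factory=_default_daily)
    autocorr: float = 0.6
    mv_rate: float = 0.25
    vasopressor_rate: float = 0.35
    policy: dict[str, float] = field(default_factory=_default_policy)
    psi: dict[int, dict[str, float]] = field(default_factory=_default_psi)
    beta: dict[int, dict[str, float]] = field(default_factory=_default_beta)
    sigma: dict[int, float] = field(default_factory=lambda: {1: 0.4, 2: 0.4, 3: 0.4})
    # per-stage log-odds of alive discharge within the stage; ventilated
    # patients are less likely to be discharged. Discharge status is drawn
    # given current covariates, independently of the stage survival time,
    # so alive discharge is noninformative given the modelled covariates.
    discharge_logit: dict[int, float] = field(
        default_factory=lambda: {1: -2.4, 2: -2.4, 3: -1.6})
    discharge_mv_coef: float = -0.7
    horizon: int = 7
    min_stage_time: float = 0.04
    specs: dict[int, ModelSpec] = field(default_factory=default_stage_specs)

    def __post_init__(self):
        if self.age_sd <= 0 or self.autocorr < 0 or self.autocorr >= 1:
            raise ValueError("age_sd must be > 0 and autocorr in [0, 1)")
        for k, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma[{k}] must be nonnegative")
        for v, (_, bsd, wsd) in self.daily.items():
            if bsd <= 0 or wsd <= 0:
                raise ValueError(f"daily SDs for {v!r} must be strictly positive")
        if not (0 < self.mv_rate < 1 and 0 < self.vasopressor_rate < 1):
            raise ValueError("Bernoulli rates must lie in (0, 1)")
        tot = sum(self.icu_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"icu_probs must sum to 1 (got {tot})")


def default_params() -> SimParams:
    """The default study conditions (balanced day-1 arms, nonzero blips)."""
    return SimParams()


def _policy_logits(p: SimParams, d: int, mbp, hr, mv, prev_lf):
    c = p.policy
    z = (c["const"]
         + c["mbp"] * (mbp - p.daily["mbp"][0]) / 20.0
         + c["hr"] * (hr - p.daily["hr"][0]) / 20.0
         + c["mv"] * (mv - p.mv_rate))
    if d > 1:
        z = z + c["prev_lf"] * (prev_lf - 0.5)
    return z


def simulate_frame(params: SimParams, n: int, seed: int | None = None) -> pd.DataFrame:
    """Simulate ``n`` patients; returns the long patient-day cohort frame.

    Identical ``(params, n, seed)`` give byte-identical frames. ``seed``
    defaults to ``params.seed``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    H = params.horizon
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), *params.age_bounds)
    labels = list(params.icu_probs)
    icu = rng.choice(labels, p=[params.icu_probs[l] for l in labels], size=n)

    daily = {}
    for var, (mu, bsd, wsd) in params.daily.items():
        m = rng.normal(mu, bsd, n)
        z = np.empty((n, H))
        z[:, 0] = rng.normal(0.0, wsd, n)
        rho = params.autocorr
        innov_sd = wsd * math.sqrt(1.0 - rho ** 2)
        for d in range(1, H):
            z[:, d] = rho * z[:, d - 1] + rng.normal(0.0, innov_sd, n)
        x = m[:, None] + z
        if var == "urine_ml":
            x = np.clip(x, 0.0, None)
        daily[var] = x
    daily["mv"] = (rng.random((n, H)) < params.mv_rate).astype(float)
    daily["vasopressor"] = (rng.random((n, H)) < params.vasopressor_rate).astype(float)

    lf = np.empty((n, H))
    fluid = np.empty((n, H))
    for d in range(1, H + 1):
        prev = lf[:, d - 2] if d > 1 else None
        logit = _policy_logits(params, d, daily["mbp"][:, d - 1],
                               daily["hr"][:, d - 1], daily["mv"][:, d - 1], prev)
        pr = 1.0 / (1.0 + np.exp(-logit))
        lf[:, d - 1] = (rng.random(n) < pr).astype(float)
        lib_amt = FLUID_CUTOFF + rng.gamma(2.0, 15.0, n)
        res_amt = FLUID_CUTOFF * rng.beta(2.0, 2.0, n)
        fluid[:, d - 1] = np.where(lf[:, d - 1] == 1.0, lib_amt, res_amt)

    wide = pd.DataFrame({"age": age, "icu_type": icu},
                        index=pd.RangeIndex(n, name="patient_id"))
    for var, x in daily.items():
        for d in range(1, H + 1):
            wide[f"{var}_d{d}"] = x[:, d - 1]
    for d in range(1, H + 1):
        wide[f"lf_d{d}"] = lf[:, d - 1]

    T = {}
    for k in (1, 2, 3):
        spec = params.specs[k]
        Xb, bnames = design_matrix(wide, spec.beta_terms, context=f"stage {k} beta")
        Xp, pnames = design_matrix(wide, spec.psi_terms, context=f"stage {k} psi")
        b = np.array([params.beta[k].get(nm, 0.0) for nm in bnames])
        psi = np.array([params.psi[k][nm] for nm in pnames])
        a_k = lf[:, DECISION_DAYS[k] - 1]
        eps = rng.normal(0.0, params.sigma[k], n) if params.sigma[k] > 0 else np.zeros(n)
        logT = Xb @ b + a_k * (Xp @ psi) + eps
        T[k] = np.maximum(np.exp(logT), params.min_stage_time)

    # Resolve stages in order: alive discharge (drawn from covariates,
    # independent of the stage time) preempts within-stage death; otherwise
    # death occurs if the drawn stage time is shorter than the stage span.
    # Stage-1 discharge can only happen after day 1.
    disch_draw, disch_u = {}, {}
    for k in (1, 2, 3):
        mv_k = daily["mv"][:, DECISION_DAYS[k] - 1]
        logit = params.discharge_logit[k] + params.discharge_mv_coef * mv_k
        q = 1.0 / (1.0 + np.exp(-logit))
        disch_draw[k] = rng.random(n) < q
        disch_u[k] = rng.random(n)

    outcome = np.empty(n)
    died = np.zeros(n, bool)
    resolved = np.zeros(n, bool)
    for k, start in ((1, 0.0), (2, 2.0), (3, 4.0)):
        span = np.inf if k == 3 else 2.0
        in_stage = ~resolved
        t_cap = np.minimum(T[k], span)
        can_disch = disch_draw[k] & ((t_cap > 1.0) if k == 1 else np.ones(n, bool))
        cens = in_stage & can_disch
        lo = 1.0 if k == 1 else 0.0
        outcome[cens] = start + lo + disch_u[k][cens] * (t_cap[cens] - lo)
        dies = in_stage & ~can_disch & (T[k] < span if k != 3 else np.ones(n, bool))
        outcome[dies] = start + T[k][dies]
        died[dies] = True
        resolved |= cens | dies

    last_day = np.ceil(np.minimum(outcome, H)).astype(int)
    last_day = np.maximum(last_day, 1)

    pid = np.array([f"p{i:06d}" for i in range(n)])
    frames = []
    for d in range(1, H + 1):
        keep = last_day >= d
        if not keep.any():
            break
        frames.append(pd.DataFrame({
            "patient_id": pid[keep], "day": d, "age": age[keep],
            "icu_type": icu[keep], "hr": daily["hr"][keep, d - 1],
            "mbp": daily["mbp"][keep, d - 1], "rr": daily["rr"][keep, d - 1],
            "temp": daily["temp"][keep, d - 1],
            "urine_ml": daily["urine_ml"][keep, d - 1],
            "mv": daily["mv"][keep, d - 1].astype(int),
            "vasopressor": daily["vasopressor"][keep, d - 1].astype(int),
            "fluid_ml_per_kg": fluid[keep, d - 1],
            "death_time": np.where(died[keep], outcome[keep], np.nan),
            "discharge_time": np.where(died[keep], np.nan, outcome[keep]),
            "status": np.where(died[keep], "died", "discharged_alive"),
        }))
    df = pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
    return df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def simulate_cohort(params: SimParams, n: int, seed: int | None = None):
    """Simulate ``n`` patients as a list of :class:`Trajectory`."""
    df = simulate_frame(params, n, seed)
    if len(df) == 0:
        return []
    return frame_to_trajectories(df)


def params_to_dict(params: SimParams) -> dict:
    d = asdict(params)
    d.pop("specs")  # model specs are code-level objects, not config values
    return d
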