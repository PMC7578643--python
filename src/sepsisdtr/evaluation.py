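"""Regime evaluation: optimal-vs-received cross tables and regime value.

The cross table counts, per stage, how the recommended action relates to
the action actually received; the off-diagonal cells are patients treated
discordantly with the fitted rule (e.g. given liberal fluid when restricted
predicted longer survival). Regime value compares each patient's observed
survival time with the counterfactual time they would have attained had
every stage decision followed the regime, using the nested multiplicative
adjustment exp(psi_k' h_k [a_k_opt - a_k]) from stage 3 inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .estimator import optimal_action
from .rules import Regime
from .staging import stage_table

ARMS = ("restricted", "liberal")


@dataclass
class CrossTab:
    """2x2 received-vs-optimal counts for one stage, with percentages."""

    stage: int
    counts: dict[tuple[str, str], int]
    total: int = 0
    pct: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        self.total = int(sum(self.counts.values()))
        if self.total:
            self.pct = {k: round(100.0 * v / self.total, 1)
                        for k, v in self.counts.items()}

    @classmethod
    def from_counts(cls, stage: int, rr: int, rl: int, lr: int, ll: int) -> "CrossTab":
        """Build from the four cells: received-restricted/optimal-restricted,
        received-restricted/optimal-liberal, received-liberal/optimal-restricted,
        received-liberal/optimal-liberal."""
        return cls(stage=stage, counts={
            ("restricted", "restricted"): int(rr),
            ("restricted", "liberal"): int(rl),
            ("liberal", "restricted"): int(lr),
            ("liberal", "liberal"): int(ll),
        })

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in ARMS:
            for opt in ARMS:
                rows.append({"stage": self.stage, "received": rec, "optimal": opt,
                             "count": self.counts[(rec, opt)],
                             "pct": self.pct.get((rec, opt), 0.0)})
        return pd.DataFrame(rows)


def crosstab(records: pd.DataFrame, stage: int | None = None) -> CrossTab:
    """Cross table from annotated stage records (columns ``a`` and
    ``optimal_action``); ``stage`` selects one stage of a combined table."""
    df = records if stage is None else records[records["stage"] == stage]
    if stage is None:
        stage = int(df["stage"].iloc[0])
    cells = {}
    for rec_code, rec in enumerate(ARMS):
        for opt_code, opt in enumerate(ARMS):
            cells[(rec, opt)] = int(((df["a"] == rec_code)
                                     & (df["optimal_action"] == opt_code)).sum())
    return CrossTab(stage=stage, counts=cells)


@dataclass
class RegimeValueReport:
    """Observed vs counterfactual-under-regime survival times."""

    per_patient: pd.DataFrame  # patient_id, observed, counterfactual
    observed_median: float
    observed_iqr: tuple[float, float]
    counterfactual_median: float
    counterfactual_iqr: tuple[float, float]
    statistic: float
    pvalue: float
    n_nonzero: int
    degenerate: bool


def compare_survival(observed, counterfactual):
    """Paired Wilcoxon signed-rank on observed vs counterfactual times.

    Returns ``(statistic, pvalue, n_nonzero, degenerate)``; if every pair
    is tied the result is the degenerate p = 1 flag.
    """
    diff = np.asarray(counterfactual, float) - np.asarray(observed, float)
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 0.0, 1.0, 0, True
    stat, p = stats.wilcoxon(nz)
    return float(stat), float(p), int(len(nz)), False


def regime_value(wide: pd.DataFrame, regime: Regime,
                 stages: pd.DataFrame | None = None) -> RegimeValueReport:
    """Evaluate a regime on a cohort: counterfactual time under the regime.

    For each patient the observed total time is inflated stage by stage,
    innermost (stage 3) first: the remaining time from stage k is
    multiplied by exp(score_k * (a_k_opt - a_k)). Patients already treated
    concordantly at every entered stage keep their observed time exactly.
    """
    for k in (1, 2, 3):
        if k not in regime.rules:
            raise ConfigurationError(f"regime is missing stage {k}")
    stages = stage_table(wide) if stages is None else stages
    by_stage = {k: g.set_index("patient_id") for k, g in stages.groupby("stage")}

    remaining = None  # counterfactual remaining time from next stage on
    for k in (3, 2, 1):
        sk = by_stage.get(k)
        if sk is None:
            continue
        score = regime.rule(k).score_frame(wide.loc[sk.index])
        a_opt = optimal_action(score)
        a = sk["a"].to_numpy(int)
        T = sk["T"].to_numpy(float)
        if remaining is not None:
            cont = remaining.reindex(sk.index)
            R = np.where(cont.notna(), T + cont.fillna(0.0).to_numpy(), T)
        else:
            R = T
        remaining = pd.Series(R * np.exp(score * (a_opt - a)), index=sk.index)

    observed = wide["outcome_time"].astype(float)
    counterfactual = remaining.reindex(observed.index)
    per = pd.DataFrame({"patient_id": observed.index,
                        "observed": observed.to_numpy(),
                        "counterfactual": counterfactual.to_numpy()})
    stat, p, n_nonzero, degen = compare_survival(per["observed"],
                                                 per["counterfactual"])
    q = per.quantile([0.25, 0.5, 0.75], numeric_only=True)
    return RegimeValueReport(
        per_patient=per,
        observed_median=float(q.loc[0.5, "observed"]),
        observed_iqr=(float(q.loc[0.25, "observed"]), float(q.loc[0.75, "observed"])),
        counterfactual_median=float(q.loc[0.5, "counterfactual"]),
        counterfactual_iqr=(float(q.loc[0.25, "counterfactual"]),
                            float(q.loc[0.75, "counterfactual"])),
        statistic=stat, pvalue=p, n_nonzero=n_nonzero, degenerate=degen)
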