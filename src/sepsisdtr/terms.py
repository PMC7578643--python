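"""Model terms for staged blip and treatment-free regressions.

A stage model regresses log stage survival time on a *treatment-free* part
(``beta`` terms, the outcome model absent current treatment) and a *blip*
part (``psi`` terms, interacted with the current binary fluid strategy).
Terms are declarative: a source variable, the ICU day it is read from, and
a transform (identity, per-constant scaling, scale-then-square, a pairwise
product of two other terms, or a categorical dummy against a reference
level).  The same specs drive the synthetic generator, feature assembly,
fitting, and the executable decision rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MissingDataError

#: ICU unit labels; the first is the reference level for dummy coding.
ICU_TYPES = (
    "CCU-CTICU",
    "CSICU",
    "CTICU",
    "Cardiac ICU",
    "MICU",
    "Med-Surg ICU",
    "Neuro ICU",
    "SICU",
)

#: Daily variables as they appear in the patient-day cohort table.
DAILY_VARIABLES = ("hr", "mbp", "rr", "temp", "urine_ml", "mv", "vasopressor",
                   "fluid_ml_per_kg", "lf")


@dataclass(frozen=True)
class TermSpec:
    """One model term: a named, transformed view of a cohort variable.

    Parameters
    ----------
    name : str
        Unique term label, used as the coefficient key.
    variable : str or None
        Source variable (``age``, ``icu_type`` or a daily variable).
        ``None`` for the intercept and for product terms.
    day : int or None
        1-based ICU day the variable is read from; ``None`` for baseline
        variables (age, unit type).
    transform : str
        One of ``const``, ``identity``, ``scale``, ``scale_square``,
        ``dummy``, ``product``.
    scale : float
        Divisor for ``scale`` / ``scale_square`` (e.g. 20 for per-20-mmHg).
    level : str or None
        Category level for ``dummy`` terms (reference level is omitted).
    product : tuple of (str, str) or None
        Names of the two already-defined terms whose product this term is.
    forced : bool
        Never removed by backward elimination (intercept and, by default,
        age and mean blood pressure terms).
    """

    name: str
    variable: str | None = None
    day: int | None = None
    transform: str = "identity"
    scale: float = 1.0
    level: str | None = None
    product: tuple[str, str] | None = None
    forced: bool = False

    def __post_init__(self):
        if self.transform in ("scale", "scale_square") and self.scale == 0:
            raise ValueError(f"term {self.name!r}: scale constant must be nonzero")
        if self.transform == "product" and (self.product is None or len(self.product) != 2):
            raise ValueError(f"term {self.name!r}: product requires two referenced terms")

    def column(self) -> str | None:
        """Wide-table column this term reads, or None for const/product."""
        if self.transform in ("const", "product"):
            return None
        if self.day is None:
            return self.variable
        return f"{self.variable}_d{self.day}"


def term_to_dict(t: TermSpec) -> dict:
    d = {"name": t.name, "variable": t.variable, "day": t.day,
         "transform": t.transform, "scale": t.scale, "level": t.level,
         "product": list(t.product) if t.product else None, "forced": t.forced}
    return d


def term_from_dict(d: dict) -> TermSpec:
    d = dict(d)
    if d.get("product"):
        d["product"] = tuple(d["product"])
    return TermSpec(**d)


def spec_to_dict(spec: "ModelSpec") -> dict:
    return {"stage": spec.stage, "alpha": spec.alpha,
            "psi": [term_to_dict(t) for t in spec.psi_terms],
            "beta": [term_to_dict(t) for t in spec.beta_terms]}


def spec_from_dict(d: dict) -> "ModelSpec":
    return ModelSpec(stage=int(d["stage"]),
                     psi_terms=[term_from_dict(t) for t in d["psi"]],
                     beta_terms=[term_from_dict(t) for t in d["beta"]],
                     alpha=float(d.get("alpha", 0.05)))


def intercept(forced: bool = True) -> TermSpec:
    return TermSpec(name="const", transform="const", forced=forced)


def icu_dummies(day: int | None = None, forced: bool = False) -> list[TermSpec]:
    """Dummy terms for the seven non-reference ICU unit types."""
    return [
        TermSpec(name=f"icu[{lvl}]", variable="icu_type", transform="dummy",
                 level=lvl, forced=forced)
        for lvl in ICU_TYPES[1:]
    ]


@dataclass
class ModelSpec:
    """Per-stage model specification: blip and treatment-free term lists."""

    stage: int
    psi_terms: list[TermSpec] = field(default_factory=list)
    beta_terms: list[TermSpec] = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self):
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        for role, terms in (("psi", self.psi_terms), ("beta", self.beta_terms)):
            names = [t.name for t in terms]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {role} term names in stage {self.stage}")
            if "const" not in names:
                raise ValueError(f"stage {self.stage} {role} terms must include an intercept")

    def drop_psi(self, name: str) -> "ModelSpec":
        """Copy of this spec without the named blip term."""
        return replace(self, psi_terms=[t for t in self.psi_terms if t.name != name])


def evaluate_terms(wide: pd.DataFrame, terms: list[TermSpec],
                   context: str = "design") -> pd.DataFrame:
    """Evaluate terms on a wide per-patient table (one row per patient).

    Columns of ``wide`` are baseline variables plus ``<var>_d<day>`` daily
    columns. Raises :class:`MissingDataError` naming the first offending
    patient/day/variable if a required value is absent — there is no silent
    imputation.
    """
    out = pd.DataFrame(index=wide.index)
    for t in terms:
        if t.transform == "const":
            out[t.name] = 1.0
            continue
        if t.transform == "product":
            a, b = t.product
            for ref in (a, b):
                if ref not in out.columns:
                    raise ValueError(f"product term {t.name!r} references undefined term {ref!r}")
            out[t.name] = out[a] * out[b]
            continue
        col = t.column()
        if col not in wide.columns:
            raise MissingDataError(
                f"{context}: variable {t.variable!r} (day {t.day}) not present in cohort",
                variable=t.variable, day=t.day)
        x = wide[col]
        if x.isna().any():
            pid = wide.index[x.isna()][0]
            raise MissingDataError(
                f"{context}: missing {t.variable!r} on day {t.day} for patient {pid!r}",
                patient_id=pid, day=t.day, variable=t.variable)
        if t.transform == "dummy":
            out[t.name] = (x == t.level).astype(float)
        elif t.transform == "identity":
            out[t.name] = x.astype(float)
        elif t.transform == "scale":
            out[t.name] = x.astype(float) / t.scale
        elif t.transform == "scale_square":
            out[t.name] = (x.astype(float) / t.scale) ** 2
        else:
            raise ValueError(f"unknown transform {t.transform!r}")
    return out


def evaluate_terms_mapping(features: dict, terms: list[TermSpec],
                           context: str = "rule") -> dict[str, float]:
    """Evaluate terms on a single named-value map (keys ``var`` or ``var_<day>``)."""
    row = {}
    for t in terms:
        if t.transform == "const":
            row[t.name] = 1.0
            continue
        if t.transform == "product":
            a, b = t.product
            row[t.name] = row[a] * row[b]
            continue
        key = t.variable if t.day is None else f"{t.variable}_{t.day}"
        if key not in features and t.variable in features:
            key = t.variable
        if key not in features:
            raise MissingDataError(
                f"{context}: feature {key!r} required by term {t.name!r} is missing",
                day=t.day, variable=t.variable)
        x = float(features[key]) if t.transform != "dummy" else features[key]
        if t.transform == "dummy":
            row[t.name] = 1.0 if x == t.level else 0.0
        elif t.transform == "identity":
            row[t.name] = x
        elif t.transform == "scale":
            row[t.name] = x / t.scale
        elif t.transform == "scale_square":
            row[t.name] = (x / t.scale) ** 2
    return row


def design_matrix(wide: pd.DataFrame, terms: list[TermSpec],
                  context: str = "design") -> tuple[np.ndarray, list[str]]:
    """Term matrix as a float ndarray plus column names."""
    df = evaluate_terms(wide, terms, context=context)
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# Default stage specifications.
#
# Decision days are 1, 3 and 5; blip covariates follow the structure of the
# fitted rules (quadratic mean blood pressure at stage 1, prior urine output
# and prior strategy at stage 2, a day-3 x day-4 strategy interaction at
# stage 3). Treatment-free terms mirror a parsimonious subset of the same
# pool. Heart rate and blood pressure are scaled per 20 units, age per 10
# years, urine per litre, for well-conditioned designs.
# ---------------------------------------------------------------------------

def default_stage_specs() -> dict[int, ModelSpec]:
    s1 = ModelSpec(
        stage=1,
        psi_terms=[
            intercept(),
            TermSpec("age_s", "age", transform="scale", scale=10.0, forced=True),
            TermSpec("mbp1_s", "mbp", day=1, transform="scale", scale=20.0, forced=True),
            TermSpec("mbp1_s2", "mbp", day=1, transform="scale_square", scale=20.0, forced=True),
            TermSpec("hr1_s", "hr", day=1, transform="scale", scale=20.0),
            TermSpec("mv1", "mv", day=1),
        ],
        # treatment-free part mirrors the blip pool (h_psi inside h_beta,
        # the condition under which the balancing weights confer double
        # robustness against treatment-free misspecification)
        beta_terms=[
            intercept(),
            TermSpec("age_s", "age", transform="scale", scale=10.0),
            TermSpec("mbp1_s", "mbp", day=1, transform="scale", scale=20.0),
            TermSpec("mbp1_s2", "mbp", day=1, transform="scale_square", scale=20.0),
            TermSpec("hr1_s", "hr", day=1, transform="scale", scale=20.0),
            TermSpec("mv1", "mv", day=1),
        ],
    )
    s2 = ModelSpec(
        stage=2,
        psi_terms=[
            intercept(),
            TermSpec("mbp3_s", "mbp", day=3, transform="scale", scale=20.0, forced=True),
            TermSpec("urine2_k", "urine_ml", day=2, transform="scale", scale=1000.0),
            TermSpec("lf1", "lf", day=1),
            TermSpec("mv3", "mv", day=3),
        ],
        beta_terms=[
            intercept(),
            TermSpec("mbp3_s", "mbp", day=3, transform="scale", scale=20.0),
            TermSpec("urine2_k", "urine_ml", day=2, transform="scale", scale=1000.0),
            TermSpec("lf1", "lf", day=1),
            TermSpec("mv3", "mv", day=3),
        ],
    )
    s3 = ModelSpec(
        stage=3,
        psi_terms=[
            intercept(),
            TermSpec("mv5", "mv", day=5),
            TermSpec("hr5_s", "hr", day=5, transform="scale", scale=20.0),
            TermSpec("lf3", "lf", day=3),
            TermSpec("lf4", "lf", day=4),
            TermSpec("lf3x4", transform="product", product=("lf3", "lf4")),
        ],
        beta_terms=[
            intercept(),
            TermSpec("mbp5_s", "mbp", day=5, transform="scale", scale=20.0),
            TermSpec("mv5", "mv", day=5),
            TermSpec("hr5_s", "hr", day=5, transform="scale", scale=20.0),
            TermSpec("lf3", "lf", day=3),
            TermSpec("lf4", "lf", day=4),
            TermSpec("lf3x4", transform="product", product=("lf3", "lf4")),
        ],
    )
    return {1: s1, 2: s2, 3: s3}
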