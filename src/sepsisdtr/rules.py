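"""Executable stage decision rules and the published three-stage fixture.

A :class:`DecisionRule` is a stage's blip function made executable: a set
of model terms with coefficients. Its score psi' h_psi is the expected gain
in log stage survival time from the liberal over the restricted fluid
strategy for a patient with history h; the rule recommends liberal iff the
score is strictly positive.

:func:`published_rules` ships the published three-stage fluid rules from a
large multi-centre ICU sepsis cohort at full equation precision, as a
fixture for rule application and diagnostics (they are not re-derivable
without the restricted source database).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDataError, NoVertexError
from .staging import LIBERAL, RESTRICTED
from .terms import (TermSpec, evaluate_terms, evaluate_terms_mapping,
                    intercept, term_from_dict, term_to_dict)


@dataclass
class DecisionRule:
    """A stage's blip coefficients over declared terms."""

    stage: int
    terms: list[TermSpec]
    coef: dict[str, float]

    def __post_init__(self):
        names = {t.name for t in self.terms}
        unresolved = set(self.coef) - names
        if unresolved:
            raise ConfigurationError(
                f"stage {self.stage} rule: coefficients without terms: {sorted(unresolved)}")

    def score(self, features: Mapping) -> float:
        """Blip score psi' h_psi for one patient's named feature values."""
        row = evaluate_terms_mapping(dict(features), self.terms,
                                     context=f"stage {self.stage} rule")
        return float(sum(self.coef.get(name, 0.0) * val for name, val in row.items()))

    def score_frame(self, wide: pd.DataFrame) -> np.ndarray:
        """Vectorized blip scores on a wide per-patient frame."""
        df = evaluate_terms(wide, self.terms, context=f"stage {self.stage} rule")
        beta = np.array([self.coef.get(c, 0.0) for c in df.columns])
        return df.to_numpy(float) @ beta

    def recommend(self, features: Mapping) -> int:
        """1 (liberal) iff the blip score is strictly positive."""
        return LIBERAL if self.score(features) > 0 else RESTRICTED


def blip_score(rule: DecisionRule, features: Mapping) -> float:
    return rule.score(features)


def recommend(rule: DecisionRule, features: Mapping) -> int:
    return rule.recommend(features)


def quadratic_vertex(rule: DecisionRule, variable: str) -> float:
    """Axis of symmetry, in native units, of a concave quadratic rule term.

    For a rule containing b*(x/s) + c*(x/s)^2 with c < 0, the score is
    maximal at x = s * b / (2|c|). Raises :class:`NoVertexError` when the
    rule has no squared term for ``variable`` or the parabola does not
    open downward.
    """
    linear = square = None
    for t in rule.terms:
        if t.variable == variable and t.transform in ("scale", "identity"):
            linear = t
        if t.variable == variable and t.transform == "scale_square":
            square = t
    if square is None:
        raise NoVertexError(f"rule stage {rule.stage}: no quadratic term for {variable!r}")
    c = rule.coef.get(square.name, 0.0)
    if c >= 0:
        raise NoVertexError(
            f"rule stage {rule.stage}: quadratic term for {variable!r} is not concave")
    b = rule.coef.get(linear.name, 0.0) if linear is not None else 0.0
    scale = square.scale
    return scale * b / (2.0 * abs(c))


@dataclass
class Regime:
    """Stage rules (normally all of 1-3) plus provenance and diagnostics.

    A fit on a cohort where nobody reaches a later decision point yields a
    regime without that stage; evaluating a regime requires all three.
    """

    rules: dict[int, DecisionRule]
    provenance: str = "fitted"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rules or not set(self.rules) <= {1, 2, 3}:
            raise ConfigurationError(
                f"regime stages must be a nonempty subset of 1-3, got {sorted(self.rules)}")

    def rule(self, stage: int) -> DecisionRule:
        return self.rules[stage]


# ---------------------------------------------------------------------------
# Published rule fixture. Coefficients are the equation-precision values
# (4-5 significant digits); the companion table's 3-decimal roundings are
# used only as cross-checks in the test suite. Unit-type dummies are coded
# against the CCU-CTICU reference. Day-5 heart rate and blood pressure
# enter unscaled, unlike day 1's per-20 scaling — scaling is per-term.
# ---------------------------------------------------------------------------

def _day1_rule() -> DecisionRule:
    terms = [
        intercept(),
        TermSpec("age", "age"),
        TermSpec("icu[CSICU]", "icu_type", transform="dummy", level="CSICU"),
        TermSpec("icu[CTICU]", "icu_type", transform="dummy", level="CTICU"),
        TermSpec("icu[Cardiac ICU]", "icu_type", transform="dummy", level="Cardiac ICU"),
        TermSpec("icu[MICU]", "icu_type", transform="dummy", level="MICU"),
        TermSpec("icu[Med-Surg ICU]", "icu_type", transform="dummy", level="Med-Surg ICU"),
        TermSpec("icu[Neuro ICU]", "icu_type", transform="dummy", level="Neuro ICU"),
        TermSpec("icu[SICU]", "icu_type", transform="dummy", level="SICU"),
        TermSpec("hr1_s", "hr", day=1, transform="scale", scale=20.0),
        TermSpec("mbp1_s", "mbp", day=1, transform="scale", scale=20.0),
        TermSpec("mbp1_s2", "mbp", day=1, transform="scale_square", scale=20.0),
        TermSpec("mv1", "mv", day=1),
    ]
    coef = {
        "const": -1.2478, "age": -0.00669,
        "icu[CSICU]": 0.4129, "icu[CTICU]": 0.0775, "icu[Cardiac ICU]": 0.2146,
        "icu[MICU]": -0.1976, "icu[Med-Surg ICU]": -0.0742,
        "icu[Neuro ICU]": 1.4847, "icu[SICU]": 0.4396,
        "hr1_s": 0.0853, "mbp1_s": 0.7074, "mbp1_s2": -0.1139, "mv1": 0.3567,
    }
    return DecisionRule(stage=1, terms=terms, coef=coef)


def _day3_rule() -> DecisionRule:
    terms = [
        intercept(),
        TermSpec("temp3", "temp", day=3),
        TermSpec("mbp3_s", "mbp", day=3, transform="scale", scale=20.0),
        TermSpec("urine2_k", "urine_ml", day=2, transform="scale", scale=1000.0),
        TermSpec("urine1_k", "urine_ml", day=1, transform="scale", scale=1000.0),
        TermSpec("mv3", "mv", day=3),
        TermSpec("lf2", "lf", day=2),
        TermSpec("lf1", "lf", day=1),
    ]
    coef = {
        "const": 0.1160, "temp3": -0.0037, "mbp3_s": -0.1630,
        "urine2_k": 0.1754, "urine1_k": 0.0190, "mv3": 0.5338,
        "lf2": 0.1514, "lf1": 0.2415,
    }
    return DecisionRule(stage=2, terms=terms, coef=coef)


def _day5_rule() -> DecisionRule:
    terms = [
        intercept(),
        TermSpec("mv5", "mv", day=5),
        TermSpec("hr5", "hr", day=5),
        TermSpec("mbp5", "mbp", day=5),
        TermSpec("lf3", "lf", day=3),
        TermSpec("lf4", "lf", day=4),
        TermSpec("lf3x4", transform="product", product=("lf3", "lf4")),
    ]
    coef = {
        "const": -0.5573, "mv5": 0.6556, "hr5": 0.0017, "mbp5": -0.0019,
        "lf3": 0.1147, "lf4": 0.4317, "lf3x4": -0.4571,
    }
    return DecisionRule(stage=3, terms=terms, coef=coef)


def published_rules() -> Regime:
    """The published day-1/3/5 fluid rules at equation precision."""
    return Regime(rules={1: _day1_rule(), 2: _day3_rule(), 3: _day5_rule()},
                  provenance="published-fixture")


# ---------------------------------------------------------------------------
# JSON serialization (full float precision so pipelines are replayable).
# ---------------------------------------------------------------------------



def regime_to_dict(regime: Regime) -> dict:
    return {
        "provenance": regime.provenance,
        "diagnostics": regime.diagnostics,
        "stages": [
            {"stage": k, "terms": [term_to_dict(t) for t in rule.terms],
             "coef": rule.coef}
            for k, rule in sorted(regime.rules.items())
        ],
    }


def regime_from_dict(doc: dict) -> Regime:
    try:
        rules = {s["stage"]: DecisionRule(
                    stage=s["stage"],
                    terms=[term_from_dict(t) for t in s["terms"]],
                    coef={k: float(v) for k, v in s["coef"].items()})
                 for s in doc["stages"]}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed regime document: {exc}") from exc
    return Regime(rules=rules, provenance=doc.get("provenance", "loaded"),
                  diagnostics=doc.get("diagnostics", {}))


def save_regime(regime: Regime, path) -> None:
    with open(path, "w") as fh:
        json.dump(regime_to_dict(regime), fh, indent=1)


def load_regime(path) -> Regime:
    with open(path) as fh:
        return regime_from_dict(json.load(fh))
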