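"""Decision rules: scores, recommendations, vertex, fixture integrity."""

import json

import numpy as np
import pytest

import sepsisdtr as s
from sepsisdtr.rules import DecisionRule
from sepsisdtr.terms import TermSpec, intercept

# Probe patients with scores frozen from an independent longhand evaluation
# of the printed equations (coefficient x transformed feature, summed).
DAY1_PROBES = [
    (dict(age=70, icu_type="MICU", hr_1=120, mbp_1=50, mv_1=1), 0.011425, 1),
    (dict(age=70, icu_type="MICU", hr_1=120, mbp_1=90, mv_1=1), -0.168375, 0),
    (dict(age=55, icu_type="Neuro ICU", hr_1=88, mbp_1=62, mv_1=0), 1.342631, 1),
    (dict(age=80, icu_type="CCU-CTICU", hr_1=95, mbp_1=62.1, mv_1=0),
     -0.2794607475, 0),
]
DAY3_PROBES = [
    (dict(temp_3=37.0, mbp_3=70, urine_ml_2=1500, urine_ml_1=800, mv_3=1,
          lf_2=1, lf_1=0), 0.3721, 1),
    (dict(temp_3=38.5, mbp_3=55, urine_ml_2=200, urine_ml_1=100, mv_3=0,
          lf_2=0, lf_1=1), -0.19622, 0),
]
DAY5_PROBES = [
    (dict(mv_5=1, hr_5=100, mbp_5=70, lf_3=1, lf_4=1), 0.2246, 1),
    (dict(mv_5=0, hr_5=80, mbp_5=85, lf_3=0, lf_4=1), -0.1511, 0),
    (dict(mv_5=0, hr_5=110, mbp_5=60, lf_3=1, lf_4=0), -0.3696, 0),
]


@pytest.mark.parametrize("stage,probes", [(1, DAY1_PROBES), (2, DAY3_PROBES),
                                          (3, DAY5_PROBES)])
def test_fixture_scores_match_longhand_oracle(published, stage, probes):
    rule = published.rule(stage)
    for features, expected, action in probes:
        assert s.blip_score(rule, features) == pytest.approx(expected, abs=1e-6)
        assert s.recommend(rule, features) == action


def test_zero_score_recommends_restricted():
    rule = DecisionRule(stage=1, terms=[intercept()], coef={"const": 0.0})
    assert s.recommend(rule, {}) == 0
    assert s.blip_score(rule, {"anything": 1.0}) == 0.0


def test_missing_feature_names_the_term(published):
    with pytest.raises(s.MissingDataError) as exc:
        s.blip_score(published.rule(3), {"mv_5": 1})
    assert "hr" in str(exc.value)


def test_quadratic_vertex_day1(published):
    v = s.quadratic_vertex(published.rule(1), "mbp")
    assert v == pytest.approx(62.1, abs=0.05)


def test_quadratic_vertex_edge_cases(published):
    # a zero linear coefficient puts the vertex at the origin
    rule = DecisionRule(stage=1, terms=[
        intercept(),
        TermSpec("x", "mbp", day=1, transform="scale", scale=20.0),
        TermSpec("x2", "mbp", day=1, transform="scale_square", scale=20.0)],
        coef={"const": 0.0, "x": 0.0, "x2": -0.5})
    assert s.quadratic_vertex(rule, "mbp") == 0.0
    # the day-3 rule has no quadratic blood-pressure term
    with pytest.raises(s.NoVertexError):
        s.quadratic_vertex(published.rule(2), "mbp")
    # a convex (non-concave) quadratic has no interior maximum
    rule.coef["x2"] = 0.5
    with pytest.raises(s.NoVertexError):
        s.quadratic_vertex(rule, "mbp")


def test_fixture_matches_three_decimal_table(published):
    """The companion-table roundings agree with the equation coefficients
    to 3 decimals for every shared term (age is tabulated per 10 years)."""
    table = {
        1: {"const": -1.248, "icu[CSICU]": 0.413, "icu[CTICU]": 0.078,
            "icu[Cardiac ICU]": 0.215, "icu[MICU]": -0.198,
            "icu[Med-Surg ICU]": -0.074, "icu[Neuro ICU]": 1.485,
            "icu[SICU]": 0.44, "hr1_s": 0.085, "mbp1_s": 0.707,
            "mbp1_s2": -0.114, "mv1": 0.357},
        2: {"const": 0.116, "temp3": -0.004, "mbp3_s": -0.163,
            "urine2_k": 0.175, "urine1_k": 0.019, "mv3": 0.534,
            "lf2": 0.151, "lf1": 0.241},
        3: {"const": -0.557, "mv5": 0.656, "hr5": 0.002, "mbp5": -0.002,
            "lf3": 0.115, "lf4": 0.432, "lf3x4": -0.457},
    }
    for k, vals in table.items():
        coef = published.rule(k).coef
        for name, tab in vals.items():
            assert abs(coef[name] - tab) <= 5.1e-4, (k, name)
    assert abs(published.rule(1).coef["age"] * 10 - (-0.067)) <= 5.1e-4


def test_fixture_roundtrips_through_json(published, tmp_path):
    path = tmp_path / "regime.json"
    s.save_regime(published, path)
    back = s.load_regime(path)
    for features, _, _ in DAY1_PROBES:
        assert back.rule(1).score(features) == published.rule(1).score(features)
    for features, _, _ in DAY5_PROBES:
        assert back.rule(3).score(features) == published.rule(3).score(features)


def test_score_linear_in_unsquared_features(published):
    rule = published.rule(3)
    base = dict(mv_5=0, hr_5=90.0, mbp_5=70.0, lf_3=0, lf_4=0)
    bumped = dict(base, hr_5=90.0 + 12.5)
    delta = rule.score(bumped) - rule.score(base)
    assert delta == pytest.approx(rule.coef["hr5"] * 12.5, rel=1e-9)


def test_recommendation_invariant_to_positive_rescaling(published):
    rule = published.rule(1)
    scaled = DecisionRule(stage=1, terms=rule.terms,
                          coef={k: 3.7 * v for k, v in rule.coef.items()})
    for features, _, action in DAY1_PROBES:
        assert scaled.recommend(features) == action


def test_day1_score_increases_below_vertex_decreases_above(published):
    rule = published.rule(1)
    v = s.quadratic_vertex(rule, "mbp")
    base = dict(age=60, icu_type="MICU", hr_1=100, mv_1=0)
    grid = np.arange(30.0, 100.0, 2.0)
    scores = [rule.score(dict(base, mbp_1=m)) for m in grid]
    diffs = np.diff(scores)
    below = grid[:-1] + 2.0 <= v
    assert (diffs[below] > 0).all()
    assert (diffs[~below & (grid[:-1] >= v)] < 0).all()
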