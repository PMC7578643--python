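"""Blip estimation: nuisance models, weights, recovery, backward induction."""

import numpy as np
import pandas as pd
import pytest

import sepsisdtr as s
from sepsisdtr.estimator import optimal_action
from sepsisdtr.terms import ModelSpec, TermSpec, intercept, design_matrix


def test_propensity_recovers_fair_coin():
    rng = np.random.default_rng(0)
    n = 5000
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    a = rng.integers(0, 2, n)
    delta = np.ones(n, int)
    fit = s.fit_nuisance_models(a, delta, X, ["const", "x"], stage=1)
    assert np.abs(fit.propensity - 0.5).max() < 0.02
    # no censoring: uncensored probability sits at the clip bound
    assert np.allclose(fit.uncensored_prob, 0.99)


def test_single_arm_is_degenerate():
    X = np.ones((20, 1))
    with pytest.raises(s.DegenerateTreatmentError):
        s.fit_nuisance_models(np.ones(20), np.ones(20), X, ["const"], stage=2)


def test_weight_formula_cases():
    from sepsisdtr.estimator import NuisanceFit
    nf = NuisanceFit(stage=3, names=["const"], propensity_coef=None,
                     censoring_coef=None,
                     propensity=np.array([0.5, 0.5, 0.8, 0.8]),
                     uncensored_prob=np.array([1.0, 1.0, 0.8, 0.8]))
    w = s.compute_weights(np.array([1, 0, 1, 1]), np.array([1, 1, 1, 0]), nf)
    assert w[0] == w[1] == pytest.approx(0.5)       # symmetric propensity
    assert w[2] == pytest.approx(0.2 / 0.8)         # |1-0.8| / 0.8
    assert w[3] == 0.0                              # censored record


def _toy_stage_data(n, seed, sigma=0.0):
    """Hand-generated single-stage data with known coefficients."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.integers(0, 2, n).astype(float)
    a = rng.integers(0, 2, n)
    Xb = np.column_stack([np.ones(n), x])
    Xp = np.column_stack([np.ones(n), z])
    beta = np.array([0.8, 0.3])
    psi = np.array([-0.2, 0.5])
    y = Xb @ beta + a * (Xp @ psi) + sigma * rng.normal(size=n)
    spec = ModelSpec(stage=3,
                     psi_terms=[intercept(), TermSpec("z", "hr", day=5)],
                     beta_terms=[intercept(), TermSpec("x", "mbp", day=5)])
    return y, a, Xb, Xp, spec, beta, psi


def test_noiseless_fit_recovers_generating_coefficients_exactly():
    y, a, Xb, Xp, spec, beta, psi = _toy_stage_data(150, seed=3, sigma=0.0)
    w = np.full(len(y), 0.5)
    fit = s.fit_stage_blip(y, a, Xb, Xp, w, spec, ["const", "x"], ["const", "z"])
    assert fit.beta["const"] == pytest.approx(beta[0], abs=1e-10)
    assert fit.beta["x"] == pytest.approx(beta[1], abs=1e-10)
    assert fit.psi["const"] == pytest.approx(psi[0], abs=1e-10)
    assert fit.psi["z"] == pytest.approx(psi[1], abs=1e-10)
    assert fit.resid_var == pytest.approx(0.0, abs=1e-18)


def test_uniform_weights_equal_unweighted_least_squares():
    y, a, Xb, Xp, spec, *_ = _toy_stage_data(120, seed=9, sigma=0.4)
    args = (y, a, Xb, Xp)
    f1 = s.fit_stage_blip(*args, np.ones(len(y)), spec, ["const", "x"], ["const", "z"])
    f2 = s.fit_stage_blip(*args, np.full(len(y), 0.37), spec, ["const", "x"], ["const", "z"])
    X = np.hstack([Xb, a[:, None] * Xp])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    got = [f1.beta["const"], f1.beta["x"], f1.psi["const"], f1.psi["z"]]
    assert np.allclose(got, ols, atol=1e-10)
    assert np.allclose(got, [f2.beta["const"], f2.beta["x"],
                             f2.psi["const"], f2.psi["z"]], atol=1e-10)


def test_collinear_design_names_aliased_terms():
    y, a, Xb, Xp, spec, *_ = _toy_stage_data(80, seed=1, sigma=0.1)
    Xb2 = np.column_stack([Xb, Xb[:, 1]])  # duplicated column
    with pytest.raises(s.CollinearityError) as exc:
        s.fit_stage_blip(y, a, Xb2, Xp, np.ones(len(y)), spec,
                         ["const", "x", "x_copy"], ["const", "z"])
    assert exc.value.aliased


def test_balancing_property_of_absolute_residual_weights():
    """With |a - pihat| weights from a saturated propensity model on a
    binary covariate, the weighted covariate mean is equal across arms."""
    rng = np.random.default_rng(4)
    n = 400
    z = rng.integers(0, 2, n).astype(float)
    p = np.where(z == 1, 0.7, 0.3)
    a = (rng.random(n) < p).astype(int)
    X = np.column_stack([np.ones(n), z])
    nf = s.fit_nuisance_models(a, np.ones(n, int), X, ["const", "z"], stage=1)
    w = s.compute_weights(a, np.ones(n), nf)
    m1 = np.average(z[a == 1], weights=w[a == 1])
    m0 = np.average(z[a == 0], weights=w[a == 0])
    assert m1 == pytest.approx(m0, abs=1e-6)


def test_backward_elimination_removes_pure_noise_keeps_forced(params):
    """A covariate with zero true blip coefficient is dropped in >= 90% of
    replicates; a forced term survives regardless of its p-value."""
    base = s.default_stage_specs()[3]
    noise_spec = ModelSpec(
        stage=3,
        psi_terms=base.psi_terms + [
            TermSpec("rr5_s", "rr", day=5, transform="scale", scale=20.0),
            TermSpec("temp5_f", "temp", day=5, forced=True)],
        beta_terms=base.beta_terms)
    removed = kept_forced = 0
    B = 200
    for r in range(B):
        df = s.simulate_frame(params, 700, seed=20000 + r)
        wide = s.cohort_to_wide(df)
        _, _, fits = s.backward_induction(
            wide, specs={1: s.default_stage_specs()[1],
                         2: s.default_stage_specs()[2], 3: noise_spec},
            select=True)
        names = set(fits[3].psi)
        removed += "rr5_s" not in names
        kept_forced += "temp5_f" in names
    assert kept_forced == B
    assert removed >= 0.9 * B


def test_adjust_counterfactual_values():
    assert s.adjust_counterfactual(2.0, 1.0, 0.5, a=0, a_opt=1) == \
        pytest.approx(2.0 + np.exp(0.5))
    assert s.adjust_counterfactual(2.0, 1.0, 0.7, a=1, a_opt=1) == 3.0
    assert s.adjust_counterfactual(2.0, 1.0, 0.0, a=0, a_opt=1) == 3.0
    with pytest.raises(ValueError):
        s.adjust_counterfactual(2.0, 0.0, 0.5, 0, 1)


def test_backward_induction_single_stage_cohort():
    """If nobody survives to day 3 the fit reduces to a stage-1 regression."""
    rng = np.random.default_rng(8)
    rows = []
    for i in range(120):
        death = float(rng.uniform(0.2, 1.9))
        fluid = float(rng.choice([10.0, 60.0]))
        rows.append(dict(patient_id=f"q{i}", day=1,
                         age=float(rng.uniform(40, 85)), icu_type="MICU",
                         hr=100 + rng.normal() * 10, mbp=60 + rng.normal() * 8,
                         rr=25.0, temp=37.0, urine_ml=500.0, mv=int(rng.random() < 0.3),
                         vasopressor=0, fluid_ml_per_kg=fluid,
                         death_time=death, discharge_time=np.nan, status="died"))
    wide = s.cohort_to_wide(pd.DataFrame(rows))
    regime, ann, fits = s.backward_induction(wide)
    assert sorted(fits) == [1]
    assert sorted(regime.rules) == [1]
    assert set(ann["stage"]) == {1}


def test_stage2_fit_consumes_stage3_adjusted_outcomes(fitted_small):
    """The stage-2 outcome is the stage-3-optimal counterfactual remaining
    time: strictly larger than the observed T2+T3 whenever the received
    day-5 action disagrees with the fitted rule, equal otherwise."""
    ann = fitted_small.stage_records_
    s3 = ann[ann["stage"] == 3].set_index("patient_id")
    s2 = ann[ann["stage"] == 2].set_index("patient_id")
    joined = s2.join(s3, lsuffix="_2", rsuffix="_3", how="inner")
    observed_rem = joined["T_2"] + joined["T_3"]
    disagree = joined["a_3"] != joined["optimal_action_3"]
    nonzero = joined["blip_score_3"] != 0
    assert disagree.any() and (~disagree).any()
    assert (joined.loc[disagree & nonzero, "t_tilde_2"]
            > observed_rem[disagree & nonzero] + 1e-12).all()
    assert np.allclose(joined.loc[~disagree, "t_tilde_2"],
                       observed_rem[~disagree])


def test_stage3_recovery_at_n5000(params):
    """Componentwise |psi_hat - psi*| < 0.05 for stage 3 at n = 5000
    (recorded seed; the intercept's sampling error alone is ~0.14 SD at
    this size, so the check is seed-pinned by design)."""
    df = s.simulate_frame(params, 5000, seed=4)
    est = s.DynamicRegimeEstimator().fit(df)
    for name, true in params.psi[3].items():
        assert abs(est.fits_[3].psi[name] - true) < 0.05, name


def test_fitted_actions_match_true_blip_signs(params):
    """Recommendations agree with the sign of the generating blip for >= 95%
    of records whose true blip score is not near zero (misclassification is
    confined to scores near the decision boundary), and overall at stage 3
    where the stage model is exact."""
    df = s.simulate_frame(params, 5000, seed=11)
    wide = s.cohort_to_wide(df)
    est = s.DynamicRegimeEstimator().fit(df)
    ann = est.stage_records_
    for k in (1, 2, 3):
        sk = ann[ann["stage"] == k]
        Xp, pn = design_matrix(wide.loc[sk["patient_id"]], params.specs[k].psi_terms)
        true_score = Xp @ np.array([params.psi[k][n] for n in pn])
        agree = (optimal_action(true_score) == sk["optimal_action"].to_numpy())
        clear = np.abs(true_score) > 0.1
        assert agree[clear].mean() >= 0.95, k
    assert agree.mean() >= 0.95  # stage 3 overall


def test_double_robustness_to_treatment_free_misspecification():
    """With a correctly specified propensity (policy drawn from the stage-3
    blip covariates only) the stage-3 blip is recovered even when the fitted
    treatment-free model omits the real blood-pressure effect. The
    treatment-free design still contains the blip covariates, the standard
    condition for the balancing weights to confer double robustness."""
    p = s.default_params()
    p.policy = {"const": 0.0, "mbp": 0.0, "hr": 0.3, "mv": 0.5, "prev_lf": 0.8}
    base = s.default_stage_specs()
    mis3 = ModelSpec(stage=3, psi_terms=base[3].psi_terms,
                     beta_terms=[t for t in base[3].beta_terms
                                 if t.name != "mbp5_s"])
    specs = {1: base[1], 2: base[2], 3: mis3}
    bias = []
    names = list(p.psi[3])
    for r in range(50):
        df = s.simulate_frame(p, 2000, seed=40000 + r)
        est = s.DynamicRegimeEstimator(specs=specs).fit(df)
        bias.append([est.fits_[3].psi[n] - p.psi[3][n] for n in names])
    mean_bias = np.abs(np.asarray(bias).mean(axis=0))
    assert mean_bias.max() < 0.05, dict(zip(names, mean_bias))


def test_bootstrap_smoke_and_determinism(wide_small):
    cis1 = s.bootstrap_ci(wide_small, B=5, seed=99)
    cis2 = s.bootstrap_ci(wide_small, B=5, seed=99)
    for k in cis1:
        assert (cis1[k]["lo"] <= cis1[k]["hi"]).all()
        pd.testing.assert_frame_equal(cis1[k], cis2[k])
    with pytest.raises(ValueError):
        s.bootstrap_ci(wide_small, B=1, seed=0)


def test_estimator_follows_sklearn_conventions(cohort_small):
    est = s.DynamicRegimeEstimator(select=False, alpha=0.05)
    assert est.get_params()["alpha"] == 0.05
    est.set_params(alpha=0.1)
    assert est.alpha == 0.1
    est.set_params(alpha=0.05).fit(cohort_small)
    preds = est.predict(cohort_small)
    assert set(preds.columns) == {"patient_id", "stage", "blip_score",
                                  "optimal_action"}
    # predictions on the training cohort equal the fit annotations
    ann = est.stage_records_.set_index(["patient_id", "stage"])
    pr = preds.set_index(["patient_id", "stage"])
    joined = ann.join(pr, rsuffix="_pred")
    assert (joined["optimal_action"] == joined["optimal_action_pred"]).all()
    from sklearn.exceptions import NotFittedError
    with pytest.raises(NotFittedError):
        s.DynamicRegimeEstimator().predict(cohort_small)
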