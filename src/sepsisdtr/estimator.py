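"""Doubly-weighted blip estimation and backward induction.

The optimal regime is estimated stage by stage, last stage first. At stage
k the log of the (counterfactually adjusted) remaining survival time is
regressed by weighted least squares on the treatment-free design h_kbeta
and the treatment-interacted blip design a_k * h_kpsi. The weights combine

* a balancing factor |a_k - pihat(h)| from a logistic propensity model,
  which makes the blip estimate doubly robust (consistent if either the
  treatment-free outcome model or the propensity model is correct), and
* an inverse-probability-of-censoring factor delta / Khat(h), where delta
  indicates that the patient's remaining survival was fully observed
  (final status died) and Khat is a logistic model of that probability;
  alive-discharged (censored) patients get weight zero.

The fitted stage-k rule recommends the liberal strategy iff
psihat_k' h_kpsi > 0 (ties go to restricted), and earlier-stage outcomes
are inflated by exp(psihat' h [a_opt - a]) before the next fit, so each
stage is estimated under optimal continuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import cohort_to_wide, trajectories_to_frame
from .errors import (CollinearityError, DegenerateTreatmentError)
from .rules import DecisionRule, Regime
from .staging import stage_table
from .terms import ModelSpec, default_stage_specs, design_matrix

logger = logging.getLogger(__name__)

PROB_CLIP = (0.01, 0.99)


# ---------------------------------------------------------------------------
# Nuisance models and weights
# ---------------------------------------------------------------------------

@dataclass
class NuisanceFit:
    """Propensity and censoring nuisance models for one stage."""

    stage: int
    names: list[str]
    propensity_coef: np.ndarray | None
    censoring_coef: np.ndarray | None
    propensity: np.ndarray
    uncensored_prob: np.ndarray
    clip: tuple[float, float] = PROB_CLIP


def _fit_logistic(X: np.ndarray, y: np.ndarray, clip: tuple[float, float]):
    """Unpenalized logistic fit; degenerate outcomes collapse to the clip bound."""
    if y.min() == y.max():
        p = clip[1] if y[0] == 1 else clip[0]
        return None, np.full(len(y), p)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        prob = np.asarray(res.predict(X))
        coef = np.asarray(res.params)
    except Exception:  # perfect separation and friends: fall back to marginal rate
        logger.warning("logistic nuisance fit failed; using the marginal rate")
        coef, prob = None, np.full(len(y), y.mean())
    return coef, np.clip(prob, clip[0], clip[1])


def fit_nuisance_models(a: np.ndarray, delta: np.ndarray, X_psi: np.ndarray,
                        names: list[str], stage: int,
                        clip: tuple[float, float] = PROB_CLIP) -> NuisanceFit:
    """Fit P(a=1 | h_psi) and P(uncensored | h_psi) on entered records.

    Raises :class:`DegenerateTreatmentError` if all records are in one arm.
    """
    a = np.asarray(a, float)
    if a.min() == a.max():
        raise DegenerateTreatmentError(
            f"stage {stage}: all {len(a)} records received arm {int(a[0])}")
    pcoef, pprob = _fit_logistic(X_psi, a, clip)
    ccoef, cprob = _fit_logistic(X_psi, np.asarray(delta, float), clip)
    return NuisanceFit(stage=stage, names=list(names), propensity_coef=pcoef,
                       censoring_coef=ccoef, propensity=pprob,
                       uncensored_prob=cprob, clip=clip)


def compute_weights(a: np.ndarray, delta: np.ndarray,
                    nuisance: NuisanceFit) -> np.ndarray:
    """Doubly robust weights |a - pihat| * delta / Khat (0 for censored)."""
    a = np.asarray(a, float)
    delta = np.asarray(delta, float)
    return np.abs(a - nuisance.propensity) * delta / nuisance.uncensored_prob


# ---------------------------------------------------------------------------
# Weighted stage regression
# ---------------------------------------------------------------------------

@dataclass
class BlipFit:
    """One stage's fitted blip (psi) and treatment-free (beta) coefficients.

    The same term (e.g. the intercept) may appear in both parts, so every
    statistic is kept separately per role.
    """

    stage: int
    psi: dict[str, float]
    beta: dict[str, float]
    psi_se: dict[str, float]
    beta_se: dict[str, float]
    psi_ci: dict[str, tuple[float, float]]
    beta_ci: dict[str, tuple[float, float]]
    psi_pvalues: dict[str, float]
    beta_pvalues: dict[str, float]
    n_used: int
    resid_var: float
    spec: ModelSpec = None

    def psi_vector(self, names=None) -> np.ndarray:
        names = names or list(self.psi)
        return np.array([self.psi[n] for n in names])


class StageBlipRegressor(BaseEstimator, RegressorMixin):
    """Weighted least squares of log survival time on [h_beta | a*h_psi].

    ``X`` is the concatenated design (treatment-free columns first, then
    the treatment-interacted blip columns); column names are supplied at
    construction so fitted coefficients can be reported per term. Standard
    errors are HC0 sandwich estimates from :mod:`statsmodels`.

    Attributes set by :meth:`fit` follow scikit-learn conventions
    (``coef_``, ``bse_``, ``pvalues_``, ``n_features_in_``).
    """

    def __init__(self, beta_names: tuple = (), psi_names: tuple = ()):
        self.beta_names = beta_names
        self.psi_names = psi_names

    def _names(self, p: int) -> list[str]:
        names = list(self.beta_names) + list(self.psi_names)
        if len(names) != p:
            names = [f"x{j}" for j in range(p)]
        return names

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        w = np.asarray(sample_weight, float)
        if np.any(w < 0):
            raise ValueError("sample_weight must be nonnegative")
        keep = w > 0
        Xk, yk, wk = X[keep], y[keep], w[keep]
        names = self._names(X.shape[1])
        self._check_rank(Xk * np.sqrt(wk)[:, None], names)
        res = sm.WLS(yk, Xk, weights=wk).fit(cov_type="HC0")
        self.coef_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.pvalues_ = np.asarray(res.pvalues)
        ci = np.asarray(res.conf_int(alpha=0.05))
        self.ci_ = ci
        self.n_features_in_ = X.shape[1]
        self.n_used_ = int(keep.sum())
        resid = yk - Xk @ self.coef_
        self.resid_var_ = float(np.sum(wk * resid ** 2) / np.sum(wk))
        self.names_ = names
        return self

    @staticmethod
    def _check_rank(Xw: np.ndarray, names: list[str]) -> None:
        _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        tol = max(Xw.shape) * np.finfo(float).eps * (d[0] if d.size else 0.0)
        bad = piv[d <= tol] if d.size else piv
        if len(bad):
            aliased = [names[j] for j in sorted(bad)]
            raise CollinearityError(
                f"design is rank deficient; aliased terms: {aliased}", aliased=aliased)

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_


def fit_stage_blip(y: np.ndarray, a: np.ndarray, X_beta: np.ndarray,
                   X_psi: np.ndarray, weights: np.ndarray,
                   spec: ModelSpec, beta_names: list[str],
                   psi_names: list[str]) -> BlipFit:
    """Fit one stage's weighted blip regression and package the estimates."""
    a = np.asarray(a, float)
    w = np.asarray(weights, float)
    for arm in (0, 1):
        if w[a == arm].sum() <= 0:
            raise DegenerateTreatmentError(
                f"stage {spec.stage}: no positive weight in arm {arm}")
    X = np.hstack([X_beta, a[:, None] * X_psi])
    reg = StageBlipRegressor(beta_names=tuple(beta_names),
                             psi_names=tuple(psi_names)).fit(X, y, sample_weight=w)
    nb = len(beta_names)
    ci = [(lo, hi) for lo, hi in reg.ci_]
    return BlipFit(
        stage=spec.stage,
        beta=dict(zip(beta_names, reg.coef_[:nb])),
        psi=dict(zip(psi_names, reg.coef_[nb:])),
        beta_se=dict(zip(beta_names, reg.bse_[:nb])),
        psi_se=dict(zip(psi_names, reg.bse_[nb:])),
        beta_ci=dict(zip(beta_names, ci[:nb])),
        psi_ci=dict(zip(psi_names, ci[nb:])),
        beta_pvalues=dict(zip(beta_names, reg.pvalues_[:nb])),
        psi_pvalues=dict(zip(psi_names, reg.pvalues_[nb:])),
        n_used=reg.n_used_, resid_var=reg.resid_var_, spec=spec)


def select_variables(y, a, wide, weights, spec: ModelSpec,
                     alpha: float | None = None) -> ModelSpec:
    """Backward elimination of non-forced blip terms at significance alpha.

    One term per round — the least significant with p > alpha — with a
    refit after each removal; forced terms (intercept, age, blood
    pressure by default) are never removed.
    """
    alpha = spec.alpha if alpha is None else alpha
    current = spec
    while True:
        X_beta, bnames = design_matrix(wide, current.beta_terms)
        X_psi, pnames = design_matrix(wide, current.psi_terms)
        fit = fit_stage_blip(y, a, X_beta, X_psi, weights, current, bnames, pnames)
        removable = [t for t in current.psi_terms if not t.forced
                     and t.transform != "const"
                     and fit.psi_pvalues[t.name] > alpha
                     # a term consumed by a product stays until the product goes
                     and not any(p.transform == "product" and t.name in p.product
                                 for p in current.psi_terms)]
        if not removable:
            return current
        worst = max(removable, key=lambda t: fit.psi_pvalues[t.name])
        current = current.drop_psi(worst.name)


# ---------------------------------------------------------------------------
# Counterfactual adjustment and backward induction
# ---------------------------------------------------------------------------

def adjust_counterfactual(t_earlier, t_current, blip_score, a, a_opt):
    """Counterfactual remaining time t_earlier + t_current * exp(blip*(a_opt-a)).

    Equals the observed remaining time when the received action matches the
    recommendation and is never smaller otherwise (a_opt maximises the blip
    contribution by construction). Accepts scalars or arrays.
    """
    t_earlier = np.asarray(t_earlier, float)
    t_current = np.asarray(t_current, float)
    if np.any(t_current <= 0) or np.any(t_earlier < 0):
        raise ValueError("times must be positive (earlier part nonnegative)")
    shift = np.asarray(blip_score, float) * (np.asarray(a_opt, float)
                                             - np.asarray(a, float))
    out = t_earlier + t_current * np.exp(shift)
    return float(out) if out.ndim == 0 else out


def optimal_action(score) -> np.ndarray:
    """1 (liberal) iff the blip score is strictly positive; ties restricted."""
    return (np.asarray(score, float) > 0).astype(int)


def backward_induction(wide: pd.DataFrame, stages: pd.DataFrame | None = None,
                       specs: dict[int, ModelSpec] | None = None,
                       select: bool = False, alpha: float = 0.05,
                       clip: tuple[float, float] = PROB_CLIP):
    """Estimate the three-stage optimal regime on a wide cohort table.

    Returns ``(regime, annotated, fits)`` where ``annotated`` is the stage
    table with per-record blip scores, optimal actions and counterfactual
    remaining times ``t_tilde`` (remaining time had all *later* stages been
    treated optimally — the outcome each earlier fit consumes).
    """
    specs = specs or default_stage_specs()
    stages = stage_table(wide) if stages is None else stages
    stages = stages.set_index("patient_id")

    fits: dict[int, BlipFit] = {}
    rules: dict[int, DecisionRule] = {}
    ann = {}
    # remaining[pid] = counterfactual remaining time from the *next* stage on
    remaining = pd.Series(dtype=float)

    for k in (3, 2, 1):
        sk = stages[stages["stage"] == k]
        if len(sk) == 0:
            continue  # nobody survived to this decision point
        wk = wide.loc[sk.index]
        # outcome: remaining time from stage k start under optimal continuation
        t_current = sk["T"].to_numpy(float)
        cont = remaining.reindex(sk.index)
        has_next = cont.notna().to_numpy()
        # patients entering stage k+1 have T_k == span; remaining = T_k + continuation
        R = np.where(has_next, t_current + cont.fillna(0.0).to_numpy(float), t_current)
        y = np.log(R)

        spec = specs[k]
        a = sk["a"].to_numpy(int)
        delta = sk["died_final"].to_numpy(int)
        try:
            if select:
                X_psi0, pn0 = design_matrix(wk, spec.psi_terms)
                nuis0 = fit_nuisance_models(a, delta, X_psi0, pn0, k, clip)
                w0 = compute_weights(a, delta, nuis0)
                spec = select_variables(y, a, wk, w0, spec, alpha)
            X_beta, bnames = design_matrix(wk, spec.beta_terms)
            X_psi, pnames = design_matrix(wk, spec.psi_terms)
            nuis = fit_nuisance_models(a, delta, X_psi, pnames, k, clip)
            w = compute_weights(a, delta, nuis)
            fit = fit_stage_blip(y, a, X_beta, X_psi, w, spec, bnames, pnames)
        except (DegenerateTreatmentError, CollinearityError) as exc:
            raise type(exc)(f"stage {k}: {exc}") from exc

        fits[k] = fit
        rules[k] = DecisionRule(stage=k, terms=list(spec.psi_terms),
                                coef=dict(fit.psi))
        score = X_psi @ fit.psi_vector(pnames)
        a_opt = optimal_action(score)
        # counterfactual remaining time from stage k on, later stages optimal
        t_tilde = R
        ann[k] = pd.DataFrame({
            "patient_id": sk.index, "stage": k, "a": a, "T": t_current,
            "event": sk["event"].to_numpy(int),
            "censored": sk["censored"].to_numpy(int),
            "died_final": delta, "weight": w, "blip_score": score,
            "optimal_action": a_opt, "t_tilde": t_tilde,
        })
        # remaining time from stage k on had stage k ALSO been optimal,
        # consumed by the next-earlier fit
        remaining = pd.Series(R * np.exp(score * (a_opt - a)), index=sk.index)

    annotated = pd.concat([ann[k] for k in sorted(ann)], ignore_index=True)
    regime = Regime(rules=rules, provenance="fitted",
                    diagnostics={k: {"n_used": fits[k].n_used,
                                     "resid_var": fits[k].resid_var}
                                 for k in fits})
    return regime, annotated, fits


# ---------------------------------------------------------------------------
# Top-level scikit-learn estimator
# ---------------------------------------------------------------------------

class DynamicRegimeEstimator(BaseEstimator):
    """Fit a three-stage fluid regime by backward induction.

    Parameters
    ----------
    specs : dict of {int: ModelSpec}, optional
        Stage model specifications; defaults to
        :func:`sepsisdtr.terms.default_stage_specs`.
    select : bool
        Apply per-stage backward elimination of non-forced blip terms.
    alpha : float
        Significance threshold for elimination.
    clip : (float, float)
        Clipping bounds for nuisance probabilities.

    Attributes
    ----------
    regime_ : Regime
        The fitted three stage rules.
    stage_records_ : pandas.DataFrame
        Annotated stage records (scores, optimal actions, t_tilde).
    fits_ : dict of {int: BlipFit}
        Per-stage coefficient tables with sandwich standard errors.
    """

    def __init__(self, specs=None, select=False, alpha=0.05, clip=PROB_CLIP):
        self.specs = specs
        self.select = select
        self.alpha = alpha
        self.clip = clip

    @staticmethod
    def _as_wide(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if "day" in X.columns:  # long patient-day frame
                return cohort_to_wide(X)
            return X
        return cohort_to_wide(trajectories_to_frame(list(X)))

    def fit(self, X, y=None):
        wide = self._as_wide(X)
        self.regime_, self.stage_records_, self.fits_ = backward_induction(
            wide, specs=self.specs, select=self.select,
            alpha=self.alpha, clip=self.clip)
        self.n_patients_ = len(wide)
        return self

    def predict(self, X) -> pd.DataFrame:
        """Recommended action per entered patient-stage of a cohort."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "regime_")
        wide = self._as_wide(X)
        stages = stage_table(wide)
        out = []
        for k in (1, 2, 3):
            idx = stages.loc[stages["stage"] == k, "patient_id"]
            if len(idx) == 0:
                continue
            score = self.regime_.rule(k).score_frame(wide.loc[idx])
            out.append(pd.DataFrame({"patient_id": idx.to_numpy(), "stage": k,
                                     "blip_score": score,
                                     "optimal_action": optimal_action(score)}))
        return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bootstrap_ci(wide: pd.DataFrame, specs=None, B: int = 200,
                 seed: int = 0, select: bool = False, alpha: float = 0.05,
                 level: float = 0.95, max_failures: float = 0.2):
    """Percentile bootstrap over patients for the stage blip coefficients.

    Whole trajectories are resampled with replacement and the full backward
    induction rerun per replicate. Returns a dict mapping stage to a frame
    with columns ``estimate``, ``lo``, ``hi`` indexed by term. Deterministic
    given ``seed``; replicates that fail to fit are logged and skipped, and
    more than ``max_failures`` of them is an error.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    specs = specs or default_stage_specs()
    rng = np.random.default_rng(seed)
    _, _, point = backward_induction(wide, specs=specs, select=select, alpha=alpha)
    stages_fit = sorted(point)
    draws = {k: [] for k in stages_fit}
    failures = 0
    n = len(wide)
    for b in range(B):
        take = rng.integers(0, n, n)
        wb = wide.iloc[take].copy()
        wb.index = pd.Index([f"b{b}_{i}" for i in range(n)], name="patient_id")
        try:
            _, _, fits = backward_induction(wb, specs=specs, select=select,
                                            alpha=alpha)
        except Exception as exc:
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        for k in stages_fit:
            if k in fits:
                draws[k].append(fits[k].psi)
    if failures > max_failures * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    out = {}
    for k in stages_fit:
        df = pd.DataFrame(draws[k])
        tab = pd.DataFrame({
            "estimate": pd.Series(point[k].psi),
            "lo": df.quantile(lo_q),
            "hi": df.quantile(hi_q),
        })
        out[k] = tab
    return out
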