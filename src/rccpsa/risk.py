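"""Prognostic scoring and risk stratification from subtype proportions.

The RCC-R score is the assigned ccRCC proportion c of a sample.  It maps to
a prognostic index (PI) — the linear predictor of a Cox proportional-hazards
model — through the published cubic polynomial

    PI = 14.71·c − 25.46·c² + 12.21·c³ − 1.46,

whose interior maximum encodes that tumors mixing clear-cell and papillary
features carry the highest risk.  Hazard ratios are exp(PI).  This module
also refits such models (cubic polynomial or restricted cubic spline) from
survival data, compares candidate models by cross-validation, AIC and
analysis of deviance, discovers risk-group cutpoints on the PI with a
conditional-inference-style survival tree, and runs Kaplan–Meier / log-rank
analyses.  Cox fits use lifelines (Efron tie handling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LifelinesConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

from ._stats import holm_adjust  # re-exported: part of this module's public API

__all__ = [
    "PUBLISHED_RCC_R_MODEL",
    "PrognosticModel",
    "RiskGroups",
    "prognostic_index",
    "hazard_ratio",
    "fit_cox_score_model",
    "compare_models_cv",
    "compare_nested_models",
    "find_risk_cutpoints",
    "assign_risk_group",
    "km_logrank",
    "holm_adjust",
    "as_survival_frame",
    "efron_loglik",
    "restricted_cubic_spline_basis",
]

log = logging.getLogger(__name__)

RISK_LABELS = ("good", "intermediate", "poor")


class RiskError(ValueError):
    """Invalid risk-modeling request."""


# ---------------------------------------------------------------------------
# survival records


def as_survival_frame(survival) -> pd.DataFrame:
    """Coerce survival records to a DataFrame with ``time`` and ``event``.

    ``time`` is years from surgery; ``event`` is 1 for a cancer-specific
    death and 0 for censoring (deaths from other causes are censored at the
    time of death).
    """
    df = pd.DataFrame(survival).copy()
    if "time" not in df.columns or "event" not in df.columns:
        raise RiskError("survival records need 'time' and 'event' columns")
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    if (df["time"] < 0).any():
        raise RiskError("survival times must be non-negative")
    if not df["event"].isin([0, 1]).all():
        raise RiskError("event indicator must be 0 or 1")
    return df


# ---------------------------------------------------------------------------
# prognostic model


@dataclass
class PrognosticModel:
    """Mapping from a subtype score to a Cox linear predictor (PI).

    ``form`` is ``cubic_polynomial`` (coefficients β1, β2, β3 for c, c², c³
    plus a constant), ``restricted_cubic_spline`` (basis coefficients plus a
    constant, with the knot locations), ``linear`` or ``null``.  The
    constant shifts the PI only; fitted models are centered so the training
    PI has mean zero, while the published instance keeps its printed
    constant.
    """

    form: str
    coefficients: tuple[float, ...]
    knots: tuple[float, ...] = ()
    covariate: str = "ccRCC proportion"
    standard_errors: tuple[float, ...] = ()
    log_partial_likelihood: float | None = None
    n_params: int = field(default=-1)
    n_obs: int | None = None
    n_events: int | None = None

    def __post_init__(self) -> None:
        if self.form == "cubic_polynomial" and len(self.coefficients) != 4:
            raise RiskError("cubic form requires exactly 4 coefficients (β1, β2, β3, constant)")
        if self.form == "restricted_cubic_spline":
            kn = np.asarray(self.knots, dtype=float)
            if kn.size < 3 or np.any(np.diff(kn) <= 0):
                raise RiskError("RCS knots must be ≥ 3 and strictly increasing")
            if len(self.coefficients) != kn.size:  # k−1 basis terms + constant
                raise RiskError("RCS form requires (n_knots − 1) coefficients plus a constant")
        if self.form == "linear" and len(self.coefficients) != 2:
            raise RiskError("linear form requires 2 coefficients (slope, constant)")
        if self.form == "null" and len(self.coefficients) != 1:
            raise RiskError("null form carries only a constant")
        if self.n_params < 0:
            self.n_params = len(self.coefficients) - 1

    def design(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.form == "cubic_polynomial":
            return np.column_stack([c, c**2, c**3])
        if self.form == "restricted_cubic_spline":
            return restricted_cubic_spline_basis(c, np.asarray(self.knots))
        if self.form == "linear":
            return c[:, None]
        if self.form == "null":
            return np.empty((c.size, 0))
        raise RiskError(f"unknown model form {self.form!r}")

    def predict_pi(self, c) -> np.ndarray:
        c = np.atleast_1d(np.asarray(c, dtype=float))
        betas = np.asarray(self.coefficients[:-1], dtype=float)
        const = float(self.coefficients[-1])
        return self.design(c) @ betas + const


#: The published RCC-R instance: PI = 14.71·c − 25.46·c² + 12.21·c³ − 1.46.
PUBLISHED_RCC_R_MODEL = PrognosticModel(
    form="cubic_polynomial", coefficients=(14.71, -25.46, 12.21, -1.46)
)


def prognostic_index(c, model: PrognosticModel | None = None):
    """Prognostic index for a ccRCC proportion (RCC-R score) on the 0–1 scale."""
    model = model or PUBLISHED_RCC_R_MODEL
    arr = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise RiskError("the RCC-R score is a proportion; values must lie in [0, 1]")
    pi = model.predict_pi(arr)
    return float(pi[0]) if np.isscalar(c) or np.asarray(c).ndim == 0 else pi


def hazard_ratio(pi, pi_reference: float = 0.0):
    """HR = exp(PI − PI_reference); by default exponentiates the PI directly."""
    return np.exp(np.asarray(pi, dtype=float) - pi_reference) if np.ndim(pi) else float(
        np.exp(float(pi) - pi_reference)
    )


def restricted_cubic_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell-style restricted cubic spline basis (linear beyond the boundary knots).

    For k knots t₁<…<t_k the basis has k−1 columns: x itself and, for
    j = 1..k−2, the truncated-cubic combination scaled by (t_k − t₁)².
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3 or np.any(np.diff(t) <= 0):
        raise RiskError("need ≥ 3 strictly increasing knots")
    cols = [x]
    denom = (t[-1] - t[0]) ** 2
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / denom)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Efron partial likelihood (used for held-out scoring and null models)


def efron_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with Efron tie handling at fixed linear predictors."""
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    eta, time, event = eta[order], time[order], event[order]
    exp_eta = np.exp(eta)
    ll = 0.0
    n = len(time)
    i = 0
    # cumulative sum from the right gives the at-risk denominator
    suffix = np.concatenate([np.cumsum(exp_eta[::-1])[::-1], [0.0]])
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        d = len(d_idx)
        if d:
            risk_sum = suffix[i]
            tied_sum = float(exp_eta[d_idx].sum())
            ll += float(eta[d_idx].sum())
            for el in range(d):
                ll -= np.log(risk_sum - (el / d) * tied_sum)
        i = j
    return float(ll)


def efron_null_loglik(time: np.ndarray, event: np.ndarray) -> float:
    return efron_loglik(np.zeros(len(time)), time, event)


# ---------------------------------------------------------------------------
# model fitting


def _default_rcs_knots(scores: np.ndarray, knots: int) -> np.ndarray:
    if knots == 3:
        q = [0.10, 0.50, 0.90]
    elif knots == 4:
        q = [0.05, 0.35, 0.65, 0.95]
    elif knots == 5:
        q = [0.05, 0.275, 0.50, 0.725, 0.95]
    else:
        q = list(np.linspace(0.05, 0.95, knots))
    kn = np.quantile(scores, q)
    if np.any(np.diff(kn) <= 0):
        raise RiskError("degenerate score distribution: RCS knots are not distinct")
    return kn


def fit_cox_score_model(
    scores,
    form: str,
    survival,
    knots: int = 4,
    min_events: int = 10,
) -> PrognosticModel:
    """Fit a Cox model of survival on a subtype score and return it as a PI map.

    ``form`` ∈ {``cubic_polynomial``, ``restricted_cubic_spline``, ``linear``,
    ``null``}.  The partial likelihood is maximized with Efron tie handling;
    on monotone-likelihood failure a small ridge penalty (1e−4) is applied
    with a warning.  The returned constant centers the fitted PI to mean
    zero over the training samples.
    """
    surv = as_survival_frame(survival)
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(surv):
        raise RiskError("scores and survival records differ in length")
    n_events = int(surv["event"].sum())
    if n_events == 0:
        raise RiskError("no events in survival data: Cox model cannot be fitted")
    if n_events < min_events:
        raise RiskError(f"only {n_events} events; at least {min_events} required")
    if form == "null":
        return PrognosticModel(
            form="null",
            coefficients=(0.0,),
            log_partial_likelihood=efron_null_loglik(
                surv["time"].to_numpy(), surv["event"].to_numpy()
            ),
            n_params=0,
            n_obs=len(surv),
            n_events=n_events,
        )
    if np.std(scores) == 0:
        raise RiskError("scores are constant; no model can be fitted")

    knot_locs: tuple[float, ...] = ()
    template = PrognosticModel(
        form=form,
        coefficients=tuple([0.0] * {"cubic_polynomial": 4, "linear": 2}.get(form, 0))
        or tuple([0.0] * knots),
        knots=tuple(_default_rcs_knots(scores, knots))
        if form == "restricted_cubic_spline"
        else (),
    )
    knot_locs = template.knots
    X = template.design(scores)
    # The raw polynomial/spline columns are highly collinear, which stalls
    # Newton-Raphson well short of the optimum.  The partial likelihood only
    # depends on the linear predictor, so fit on an orthonormalized (QR)
    # basis and map coefficients and covariance back exactly.
    Xc = X - X.mean(axis=0)
    Q, Rm = np.linalg.qr(Xc)
    root_n = np.sqrt(len(Xc))
    Q, Rm = Q * root_n, Rm / root_n
    if np.abs(np.diag(Rm)).min() < 1e-10:
        raise RiskError("degenerate design: basis columns are collinear")
    colnames = [f"q{i}" for i in range(Q.shape[1])]
    df = pd.DataFrame(Q, columns=colnames)
    df["time"] = surv["time"].to_numpy()
    df["event"] = surv["event"].to_numpy()

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-9})
    except LifelinesConvergenceError:
        warnings.warn(
            "Cox partial likelihood is monotone (possible perfect separation); "
            "refitting with ridge penalty 1e-4",
            stacklevel=2,
        )
        cph = CoxPHFitter(penalizer=1e-4, l1_ratio=0.0)
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9})
    gamma = cph.params_.reindex(colnames).to_numpy()
    betas = np.linalg.solve(Rm, gamma)
    cov_gamma = cph.variance_matrix_.reindex(index=colnames, columns=colnames).to_numpy()
    cov_beta = np.linalg.solve(Rm, np.linalg.solve(Rm, cov_gamma).T)
    ses = np.sqrt(np.diag(cov_beta))
    const = -float((X @ betas).mean())
    return PrognosticModel(
        form=form,
        coefficients=(*betas, const),
        knots=knot_locs,
        standard_errors=tuple(ses),
        log_partial_likelihood=float(cph.log_likelihood_),
        n_params=len(betas),
        n_obs=len(surv),
        n_events=n_events,
    )


def aic(model: PrognosticModel) -> float:
    """AIC = −2·logPL + 2·(number of regression parameters)."""
    if model.log_partial_likelihood is None:
        raise RiskError("model has no stored partial likelihood (not fitted)")
    return -2.0 * model.log_partial_likelihood + 2.0 * model.n_params


# ---------------------------------------------------------------------------
# model comparison


def _stratified_folds(event: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by event status (round-robin after shuffling)."""
    assignment = np.empty(len(event), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def compare_models_cv(
    candidates: Sequence[dict],
    survival,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    default_scores=None,
    criterion: str = "aic",
    knots: int = 4,
) -> pd.DataFrame:
    """Compare candidate PI models by repeated stratified cross-validation.

    Each candidate is a dict with ``name``, ``form`` and optionally its own
    ``scores`` vector (falling back to ``default_scores``).  Reported per
    candidate: mean held-out Efron partial log-likelihood, mean held-out
    Harrell C-index, full-data AIC, and the rank under ``criterion``
    (``aic`` ascending, otherwise descending).  A candidate failing on more
    than 20 % of folds is excluded with a warning.
    """
    surv = as_survival_frame(survival).reset_index(drop=True)
    event = surv["event"].to_numpy()
    time = surv["time"].to_numpy()
    if event.sum() < folds:
        raise RiskError(f"need at least {folds} events for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    rows = []
    for cand in candidates:
        name, form = cand["name"], cand["form"]
        scores = np.asarray(
            cand.get("scores", default_scores if default_scores is not None else np.zeros(len(surv))),
            dtype=float,
        )
        ho_ll, ho_ci = [], []
        n_fail = n_total = 0
        fold_rng = np.random.default_rng(seed)  # same folds for every candidate
        for _rep in range(repeats):
            assignment = _stratified_folds(event, folds, fold_rng)
            for f in range(folds):
                test = assignment == f
                train = ~test
                n_total += 1
                try:
                    model = fit_cox_score_model(
                        scores[train], form, surv[train], knots=knots, min_events=1
                    )
                    eta = model.predict_pi(scores[test])
                    ho_ll.append(efron_loglik(eta, time[test], event[test]))
                    if form == "null":
                        ho_ci.append(0.5)
                    else:
                        try:
                            ho_ci.append(
                                concordance_index(time[test], -eta, event[test])
                            )
                        except ZeroDivisionError:
                            pass  # no comparable pairs in a tiny fold

                except (RiskError, LifelinesConvergenceError):
                    n_fail += 1
        if n_total and n_fail / n_total > 0.2:
            warnings.warn(
                f"candidate {name!r} failed on {n_fail}/{n_total} folds; excluded",
                stacklevel=2,
            )
            continue
        full = fit_cox_score_model(scores, form, surv, knots=knots)
        rows.append(
            {
                "name": name,
                "form": form,
                "cv_loglik": float(np.mean(ho_ll)) if ho_ll else np.nan,
                "cv_cindex": float(np.mean(ho_ci)) if ho_ci else np.nan,
                "aic": aic(full),
                "n_params": full.n_params,
            }
        )
    table = pd.DataFrame(rows).set_index("name")
    ascending = criterion == "aic"
    table["rank"] = table[criterion].rank(ascending=ascending, method="min").astype(int)
    return table.sort_values("rank")


_NESTED = {
    ("null", "linear"), ("null", "cubic_polynomial"), ("null", "restricted_cubic_spline"),
    ("linear", "cubic_polynomial"), ("linear", "restricted_cubic_spline"),
}


def compare_nested_models(
    model_small: PrognosticModel, model_large: PrognosticModel
) -> tuple[float, int, float]:
    """Analysis of deviance between two nested fitted Cox models.

    Returns (chi-square statistic, degrees of freedom, P-value); the
    statistic is twice the difference of Efron partial log-likelihoods and
    the df the difference in regression-parameter counts (constants are not
    parameters of the partial likelihood).
    """
    for m in (model_small, model_large):
        if m.log_partial_likelihood is None:
            raise RiskError("both models must be fitted (stored partial likelihood)")
    if model_small.n_obs != model_large.n_obs or model_small.n_events != model_large.n_events:
        raise RiskError("nested comparison requires models fitted on the same data")
    same_form = model_small.form == model_large.form
    if not same_form and (model_small.form, model_large.form) not in _NESTED:
        raise RiskError(
            f"model form {model_small.form!r} is not nested in {model_large.form!r}"
        )
    df_diff = model_large.n_params - model_small.n_params
    if df_diff < 0:
        raise RiskError("the first model must be the smaller one")
    stat = 2.0 * (model_large.log_partial_likelihood - model_small.log_partial_likelihood)
    stat = max(stat, 0.0)
    p = 1.0 if df_diff == 0 else float(sps.chi2.sf(stat, df_diff))
    return float(stat), int(df_diff), p


# ---------------------------------------------------------------------------
# risk-group discovery


def _logrank_statistic(time, event, mask) -> float:
    """Two-sample log-rank chi-square statistic (1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, mask = time[order], event[order], mask[order]
    n = len(time)
    # at-risk counts just before each position
    at_risk_total = n - np.arange(n)
    group1_suffix = np.concatenate([np.cumsum(mask[::-1])[::-1], [0]])
    observed_minus_expected = 0.0
    variance = 0.0
    i = 0
    while i < n:
        j = i
        d = d1 = 0
        while j < n and time[j] == time[i]:
            d += event[j]
            d1 += event[j] * mask[j]
            j += 1
        if d:
            n_i = at_risk_total[i]
            n1_i = group1_suffix[i]
            e1 = d * n1_i / n_i
            observed_minus_expected += d1 - e1
            if n_i > 1:
                variance += d * (n1_i / n_i) * (1 - n1_i / n_i) * (n_i - d) / (n_i - 1)
        i = j
    if variance <= 0:
        return 0.0
    return float(observed_minus_expected**2 / variance)


@dataclass
class RiskGroups:
    """PI cutpoints defining ordered risk groups.

    ``cutpoints`` are strictly increasing thresholds on the PI; the
    ``interval_labels`` list names the PI interval below the first cutpoint,
    between cutpoints, and above the last.  ``labels`` orders the group
    names by increasing hazard; ``hazard_ratios`` gives each group's HR
    versus the good (lowest-hazard) group.
    """

    cutpoints: tuple[float, ...]
    interval_labels: tuple[str, ...]
    labels: tuple[str, ...]
    group_sizes: dict[str, int]
    hazard_ratios: dict[str, float]
    split_pvalues: tuple[float, ...] = ()
    flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.interval_labels) != len(self.cutpoints) + 1:
            raise RiskError("need one interval label per PI interval")
        if len(self.cutpoints) > 1 and np.any(np.diff(self.cutpoints) <= 0):
            raise RiskError("cutpoints must be strictly increasing")


def _best_split(time, event, pi, min_leaf: int) -> tuple[float, float, float] | None:
    """Best log-rank split of a node: (threshold, statistic, Bonferroni-adjusted P)."""
    order = np.argsort(pi, kind="stable")
    sorted_pi = pi[order]
    uniq = np.unique(sorted_pi)
    if uniq.size < 2:
        return None
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    valid = [
        t for t in mids
        if min_leaf <= np.sum(pi <= t) and np.sum(pi > t) >= min_leaf
    ]
    if not valid:
        return None
    best_t, best_stat = None, -1.0
    for t in valid:
        stat = _logrank_statistic(time, event, pi <= t)
        if stat > best_stat:
            best_stat, best_t = stat, t
    p_adj = min(1.0, float(sps.chi2.sf(best_stat, 1)) * len(valid))
    return float(best_t), float(best_stat), p_adj


def find_risk_cutpoints(
    pi,
    survival,
    alpha: float = 0.05,
    min_leaf: int = 20,
    min_samples: int = 50,
    min_events: int = 10,
) -> RiskGroups:
    """Discover up to two PI cutpoints by significance-tested recursive splitting.

    At each node the candidate threshold maximizing the two-sample log-rank
    statistic is taken; the split is accepted only if its asymptotic
    chi-square P-value, Bonferroni-adjusted for the number of candidate
    thresholds at that node, is below ``alpha``.  Depth is limited to two
    (at most three leaves: after the root split, only the more significant
    child split is accepted).  Leaves are ordered by their Cox-estimated
    hazard into good / intermediate / poor.  With no significant split a
    single flagged group is returned.
    """
    surv = as_survival_frame(survival)
    pi = np.asarray(pi, dtype=float)
    if pi.size != len(surv):
        raise RiskError("PI vector and survival records differ in length")
    if pi.size < min_samples:
        raise RiskError(f"need at least {min_samples} samples")
    if surv["event"].sum() < min_events:
        raise RiskError(f"need at least {min_events} events")
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()

    root = _best_split(time, event, pi, min_leaf)
    if root is None or root[2] >= alpha:
        n = pi.size
        km_flag = RiskGroups(
            cutpoints=(),
            interval_labels=("good",),
            labels=("good",),
            group_sizes={"good": n},
            hazard_ratios={"good": 1.0},
            split_pvalues=(root[2],) if root else (),
            flagged=True,
        )
        log.info("no significant PI split; returning a single risk group")
        return km_flag
    cut1, _stat1, p1 = root
    cutpoints = [cut1]
    pvalues = [p1]

    # depth 2: split at most one child (keeps ≤ 3 leaves)
    left = pi <= cut1
    child_candidates = []
    for mask in (left, ~left):
        sub = _best_split(time[mask], event[mask], pi[mask], min_leaf)
        if sub is not None and sub[2] < alpha:
            child_candidates.append((sub[2], sub[0]))
    if child_candidates:
        child_candidates.sort()
        p2, cut2 = child_candidates[0]
        cutpoints.append(cut2)
        pvalues.append(p2)
    cutpoints = sorted(cutpoints)

    membership = np.searchsorted(cutpoints, pi, side="left")
    n_leaves = len(cutpoints) + 1
    # order leaves by hazard via a one-factor Cox fit (leaf 0 as reference)
    dummies = pd.get_dummies(pd.Categorical(membership, categories=range(n_leaves)), drop_first=True)
    df = pd.DataFrame(dummies.to_numpy().astype(float), columns=[f"leaf{i}" for i in range(1, n_leaves)])
    df["time"], df["event"] = time, event
    cph = CoxPHFitter(penalizer=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    log_hr = np.concatenate([[0.0], cph.params_.to_numpy()])
    hazard_order = np.argsort(log_hr, kind="stable")
    labels_used = RISK_LABELS[:n_leaves]
    interval_labels = [""] * n_leaves
    for rank, leaf in enumerate(hazard_order):
        interval_labels[leaf] = labels_used[rank]
    good_leaf = hazard_order[0]
    sizes = {interval_labels[i]: int(np.sum(membership == i)) for i in range(n_leaves)}
    hrs = {
        interval_labels[i]: float(np.exp(log_hr[i] - log_hr[good_leaf]))
        for i in range(n_leaves)
    }
    if n_leaves < 3:
        log.info("only %d risk groups found (labels %s)", n_leaves, labels_used)
    return RiskGroups(
        cutpoints=tuple(cutpoints),
        interval_labels=tuple(interval_labels),
        labels=tuple(labels_used),
        group_sizes=sizes,
        hazard_ratios=hrs,
        split_pvalues=tuple(pvalues),
        flagged=False,
    )


def assign_risk_group(pi, groups: RiskGroups):
    """Assign PI value(s) to risk groups; boundary values go to the lower-risk side."""
    arr = np.atleast_1d(np.asarray(pi, dtype=float))
    cuts = np.asarray(groups.cutpoints, dtype=float)
    rank_of = {lab: i for i, lab in enumerate(groups.labels)}
    out = []
    for v in arr:
        i = int(np.searchsorted(cuts, v, side="left"))
        label = groups.interval_labels[i]
        exact = np.flatnonzero(cuts == v)
        if exact.size:  # boundary: pick the lower-risk adjacent interval
            j = int(exact[0])
            lower = min(
                groups.interval_labels[j], groups.interval_labels[j + 1],
                key=lambda lab: rank_of[lab],
            )
            label = lower
        out.append(label)
    if np.ndim(pi) == 0:
        return out[0]
    return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# survival analyses


@dataclass
class KMLogrankResult:
    """Kaplan–Meier curves plus k-group log-rank test and per-group HRs."""

    curves: dict[str, pd.DataFrame]  # per group: timeline index, survival + censor marks
    statistic: float | None
    p_value: float | None
    hazard_ratios: dict[str, float]
    reference: str


def km_logrank(groups, survival, reference: str | None = None) -> KMLogrankResult:
    """Kaplan–Meier estimates per group, k-group log-rank test, and Cox HRs.

    Raises for a single non-empty group (no contrast to test); the fitted
    curves for that group are attached to the exception as ``curves``.
    """
    surv = as_survival_frame(survival)
    groups = pd.Series(np.asarray(groups, dtype=object), name="group")
    if len(groups) != len(surv):
        raise RiskError("group labels and survival records differ in length")
    surv = surv.reset_index(drop=True)
    curves: dict[str, pd.DataFrame] = {}
    for name in pd.unique(groups):
        sub = surv[(groups == name).to_numpy()]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(name))
        curve = km.survival_function_.rename(columns={str(name): "survival"})
        censor_times = sub.loc[sub["event"] == 0, "time"].to_numpy()
        curve["censored_here"] = [
            int(np.sum(censor_times == t)) for t in curve.index
        ]
        curves[str(name)] = curve
    names = sorted(curves)
    if len(names) < 2:
        err = RiskError("log-rank test requires at least 2 non-empty groups")
        err.curves = curves  # type: ignore[attr-defined]
        raise err
    lr = multivariate_logrank_test(surv["time"], groups, surv["event"])
    reference = reference if reference is not None else names[0]
    if reference not in names:
        raise RiskError(f"reference group {reference!r} not present")
    cat = pd.Categorical(groups, categories=[reference] + [g for g in names if g != reference])
    dummies = pd.get_dummies(cat, drop_first=True).astype(float)
    df = dummies.copy()
    df["time"], df["event"] = surv["time"].to_numpy(), surv["event"].to_numpy()
    hrs = {reference: 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        except LifelinesConvergenceError:
            cph = CoxPHFitter(penalizer=1e-4).fit(df, duration_col="time", event_col="event")
    for col in dummies.columns:
        hrs[str(col)] = float(np.exp(cph.params_[col]))
    return KMLogrankResult(
        curves=curves,
        statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
        hazard_ratios=hrs,
        reference=reference,
    )
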