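"""Survival analysis with component-wise likelihood-based boosting.

The pipeline mirrors how image markers are taken from a feature table to
a prognostic model:

1. univariate Cox regressions prescreen the markers by Wald p-value;
2. a Cox proportional-hazards model is fitted by component-wise
   likelihood-based boosting — each step performs, for every candidate
   covariate, a one-dimensional Newton update of the L2-penalized partial
   log-likelihood with the current linear predictor as an offset, and
   commits only the update with the largest penalized score statistic;
3. the number of boosting steps is chosen by k-fold cross-validation on
   the held-out partial likelihood;
4. the linear predictor scores patients, a time-dependent ROC picks the
   risk threshold, and the low/high-risk groups are compared with
   Kaplan-Meier curves and the log-rank test;
5. bootstrap resampling measures how stably each marker is selected;
6. a multivariate Cox fit (via lifelines) places the resulting risk score
   next to clinical covariates, with AIC/BIC for model comparison.

The partial likelihood, its componentwise score/information, the
Kaplan-Meier estimator and the log-rank test are implemented here (with
Breslow handling of ties); lifelines serves as the fitter for the
multivariate comparison model and as an independent cross-check in the
test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class SurvivalRecord(NamedTuple):
    time: float
    event: int
    covariates: dict[str, float]


def cohort_arrays(df: pd.DataFrame,
                  time_col: str = "time", event_col: str = "event",
                  ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Split a cohort frame into (covariate table, time, event)."""
    X = df.drop(columns=[time_col, event_col])
    return X, df[time_col].to_numpy(float), df[event_col].to_numpy(int)


def to_records(df: pd.DataFrame, time_col: str = "time",
               event_col: str = "event") -> list[SurvivalRecord]:
    X, t, d = cohort_arrays(df, time_col, event_col)
    return [SurvivalRecord(float(t[i]), int(d[i]),
                           dict(zip(X.columns, X.iloc[i])))
            for i in range(len(df))]


# ------------------------------------------------------- partial likelihood

def _check_times(time: np.ndarray) -> None:
    if np.any(time <= 0):
        raise ValueError("all observation times must be positive")


def cox_partial_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                       event: np.ndarray,
                       offset: np.ndarray | float = 0.0) -> float:
    """Breslow partial log-likelihood
    sum_{i: d_i=1} [eta_i - log sum_{j in R(t_i)} exp(eta_j)]
    with eta = X beta + offset and tied event times sharing one risk-set
    denominator."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    _check_times(time)
    eta = np.asarray(X, float) @ np.asarray(beta, float) + offset
    order = np.argsort(-time, kind="stable")   # decreasing time
    t_s, d_s, eta_s = time[order], event[order], eta[order]
    cum_w = np.cumsum(np.exp(eta_s))           # risk-set sums, largest t first
    ll = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        d_count = int(d_s[i:j + 1].sum())
        if d_count:
            ll += float(eta_s[i:j + 1][d_s[i:j + 1] == 1].sum())
            ll -= d_count * np.log(cum_w[j])
        i = j + 1
    return ll


def _componentwise_score_info(X: np.ndarray, time: np.ndarray,
                              event: np.ndarray, eta: np.ndarray,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Score U_j and diagonal information I_jj of the partial likelihood
    for a zero update of each single covariate, at linear predictor eta
    (Breslow ties)."""
    order = np.argsort(-time, kind="stable")
    t_s, d_s = time[order], event[order]
    Xs = X[order]
    w = np.exp(eta[order])
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = np.cumsum(w[:, None] * Xs ** 2, axis=0)
    U = np.zeros(X.shape[1])
    I = np.zeros(X.shape[1])
    i, n = 0, len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        dmask = d_s[i:j + 1] == 1
        d_count = int(dmask.sum())
        if d_count:
            m1 = S1[j] / S0[j]
            U += Xs[i:j + 1][dmask].sum(axis=0) - d_count * m1
            I += d_count * (S2[j] / S0[j] - m1 ** 2)
        i = j + 1
    return U, I


def univariate_cox_fit(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                       max_iter: int = 50, tol: float = 1e-9,
                       ) -> tuple[float, float, float]:
    """One-covariate Cox fit by Newton-Raphson; returns (beta, SE, Wald p)."""
    x = np.asarray(x, float)[:, None]
    beta = 0.0
    for _ in range(max_iter):
        eta = x[:, 0] * beta
        U, I = _componentwise_score_info(x, time, event, eta)
        if I[0] <= 0:
            raise RuntimeError("non-identifiable covariate")
        step = U[0] / I[0]
        beta += step
        if abs(step) < tol:
            break
    else:
        raise RuntimeError("univariate Cox fit did not converge")
    eta = x[:, 0] * beta
    _, I = _componentwise_score_info(x, time, event, eta)
    se = 1.0 / np.sqrt(I[0])
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return float(beta), float(se), float(p)


def univariate_screen(table: pd.DataFrame, time: np.ndarray,
                      event: np.ndarray, p_threshold: float = 0.25,
                      keep_small_p: bool = True) -> pd.DataFrame:
    """Per-feature univariate Cox Wald tests.

    With ``keep_small_p`` (default) features with p <= threshold are
    retained as candidates — small p marks association with survival.
    Returns a frame with beta, se, p and a boolean ``retained`` column;
    non-convergent features are dropped with a warning."""
    rows = []
    for name in table.columns:
        try:
            b, se, p = univariate_cox_fit(table[name].to_numpy(), time, event)
        except RuntimeError:
            warnings.warn(f"univariate fit failed for {name!r}; dropped")
            continue
        keep = (p <= p_threshold) if keep_small_p else (p > p_threshold)
        rows.append((name, b, se, p, keep))
    return pd.DataFrame(rows, columns=["feature", "beta", "se", "p",
                                       "retained"]).set_index("feature")


# ------------------------------------------------------------ boosting fit

@dataclass
class BoostedCoxModel:
    beta: pd.Series
    path: np.ndarray           # (n_steps+1, p); path[0] = 0
    penalty: float
    n_steps: int
    selected: list[str]
    early_stopped: bool = False

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        return table[self.beta.index].to_numpy(float) @ self.beta.to_numpy()


def coxboost_fit(table: pd.DataFrame, time: np.ndarray, event: np.ndarray,
                 M: int, penalty: float,
                 mandatory: Sequence[str] = ()) -> BoostedCoxModel:
    """Component-wise likelihood-based boosting for the Cox model.

    Per step, every candidate covariate j gets a one-dimensional Newton
    update of the L2-penalized partial log-likelihood (current linear
    predictor as offset): delta_j = U_j / (I_j + penalty).  The candidate
    with the largest penalized score statistic U_j^2 / (I_j + penalty) —
    the quadratic improvement of its update — is committed.  Mandatory
    covariates are refit unpenalized at every step and are never part of
    the selection competition."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    _check_times(np.asarray(time, float))
    X = table.to_numpy(float)
    names = list(table.columns)
    mand_idx = [names.index(m) for m in mandatory]
    cand_idx = np.array([k for k in range(len(names)) if k not in mand_idx])
    beta = np.zeros(len(names))
    path = np.zeros((M + 1, len(names)))
    early = False
    steps_done = 0
    for step in range(1, M + 1):
        eta = X @ beta
        for k in mand_idx:
            U, I = _componentwise_score_info(X[:, [k]], time, event, eta)
            if I[0] > 0:
                beta[k] += U[0] / I[0]
                eta = X @ beta
        U, I = _componentwise_score_info(X[:, cand_idx], time, event, eta)
        gain = U ** 2 / (I + penalty)
        if not np.any(np.abs(U) > 1e-12):
            early = True
            path = path[: step]
            break
        j = int(np.argmax(gain))
        beta[cand_idx[j]] += U[j] / (I[j] + penalty)
        path[step] = beta
        steps_done = step
    sel = [names[k] for k in cand_idx if abs(beta[k]) > 0]
    return BoostedCoxModel(pd.Series(beta, index=names), path, penalty,
                           steps_done, sel, early)


def cv_choose_steps(table: pd.DataFrame, time: np.ndarray,
                    event: np.ndarray, penalty: float,
                    M_grid: Sequence[int], folds: int = 6,
                    rng_seed: int = 0,
                    mandatory: Sequence[str] = (),
                    ) -> tuple[int, pd.DataFrame]:
    """Choose the boosting step count by k-fold cross-validation.

    Folds are stratified on the event indicator so every fold holds
    events.  For each fold a full path is fitted on the training folds and
    the held-out partial log-likelihood (computed on the validation fold
    alone) is recorded at every M in the grid; the M maximizing the mean
    held-out likelihood (equivalently minimizing its negative) wins."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    M_grid = sorted(set(int(m) for m in M_grid))
    M_max = max(M_grid)
    rng = np.random.default_rng(rng_seed)
    n = len(time)
    fold_of = np.empty(n, dtype=int)
    for group in (np.nonzero(event == 1)[0], np.nonzero(event == 0)[0]):
        perm = rng.permutation(group)
        fold_of[perm] = np.arange(len(perm)) % folds
    X = table.to_numpy(float)
    curves = np.zeros((folds, len(M_grid)))
    for f in range(folds):
        tr = fold_of != f
        va = ~tr
        model = coxboost_fit(table.iloc[tr], time[tr], event[tr],
                             M_max, penalty, mandatory)
        for mi, m in enumerate(M_grid):
            b = model.path[min(m, len(model.path) - 1)]
            curves[f, mi] = cox_partial_loglik(b, X[va], time[va], event[va])
    mean_curve = curves.mean(axis=0)
    m_opt = int(M_grid[int(np.argmax(mean_curve))])
    curve_df = pd.DataFrame({"M": M_grid, "mean_heldout_loglik": mean_curve})
    return m_opt, curve_df


# ------------------------------------------------- risk scoring / KM / tROC

@dataclass
class RiskModelReport:
    scores: np.ndarray
    threshold: float
    groups: np.ndarray          # "low" / "high"
    auc: float
    eval_time: float
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def time_dependent_auc(scores: np.ndarray, time: np.ndarray,
                       event: np.ndarray, eval_time: float) -> float:
    """Cumulative/dynamic AUC at ``eval_time`` on the subjects informative
    there: cases experienced the event by eval_time, controls are still
    at risk beyond it; subjects censored before eval_time are excluded.
    Ties in score count one half."""
    cases = (event == 1) & (time <= eval_time)
    controls = time > eval_time
    if not cases.any():
        raise ValueError("no events before eval_time")
    if not controls.any():
        raise ValueError("no subjects at risk beyond eval_time")
    sc, sn = scores[cases], scores[controls]
    diff = sc[:, None] - sn[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (len(sc) * len(sn)))


def risk_scores_and_threshold(model: BoostedCoxModel, table: pd.DataFrame,
                              time: np.ndarray, event: np.ndarray,
                              eval_time: float | None = None,
                              ) -> RiskModelReport:
    """Score subjects by the fitted linear predictor, pick the risk
    threshold maximizing the Youden index of the time-dependent ROC at
    ``eval_time`` (median follow-up by default), and compare the low- and
    high-risk groups by Kaplan-Meier curves and the log-rank test."""
    scores = model.linear_predictor(table)
    if eval_time is None:
        eval_time = float(np.median(time))
    auc = time_dependent_auc(scores, time, event, eval_time)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("all risk scores identical: single group")
        groups = np.full(len(scores), "low")
        return RiskModelReport(scores, float(uniq[0]), groups, 0.5,
                               eval_time)
    cands = (uniq[1:] + uniq[:-1]) / 2
    cases = (event == 1) & (time <= eval_time)
    controls = time > eval_time
    best_thr, best_youden = cands[0], -np.inf
    for thr in cands:
        tpr = np.mean(scores[cases] > thr)
        fpr = np.mean(scores[controls] > thr)
        if tpr - fpr > best_youden:
            best_youden, best_thr = tpr - fpr, thr
    groups = np.where(scores > best_thr, "high", "low")
    report = RiskModelReport(scores, float(best_thr), groups, auc, eval_time)
    if (groups == "high").any() and (groups == "low").any():
        curves, chi2, p = km_logrank(time, event, groups)
        report.km_curves = curves
        report.logrank_chi2 = chi2
        report.logrank_p = p
    return report


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) estimate; one row per distinct event
    time with columns time, at_risk, events, survival."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t_s, d_s = time[order], event[order]
    n = len(t_s)
    rows = []
    surv = 1.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        d = int(d_s[i:j + 1].sum())
        at_risk = n - i
        if d:
            surv *= 1.0 - d / at_risk
            rows.append((t_s[i], at_risk, d, surv))
        i = j + 1
    return pd.DataFrame(rows, columns=["time", "at_risk", "events",
                                       "survival"])


def km_logrank(time: np.ndarray, event: np.ndarray, groups: np.ndarray,
               ) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the two-sample log-rank test
    (1 df chi-square)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("log-rank comparison needs exactly two groups")
    g1 = groups == labels[0]
    curves = {str(lab): km_curve(time[groups == lab], event[groups == lab])
              for lab in labels}
    if event[g1].sum() == 0 or event[~g1].sum() == 0:
        warnings.warn("a group has zero events; log-rank still computed")
    event_times = np.unique(time[event == 1])
    O1 = E1 = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n_all = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d_all = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        O1 += d1
        E1 += d_all * n1 / n_all
        if n_all > 1:
            V += d_all * (n1 / n_all) * (1 - n1 / n_all) \
                 * (n_all - d_all) / (n_all - 1)
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    return curves, float(chi2), p


# --------------------------------------------------- bootstrap / reporting

def bootstrap_selection(table: pd.DataFrame, time: np.ndarray,
                        event: np.ndarray, B: int, penalty: float, M: int,
                        rng_seed: int = 0) -> pd.Series:
    """Selection frequency of each feature over B with-replacement
    resamples of the cohort, each refit with the boosting procedure.
    Replicates that draw no events are redrawn."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = len(time)
    counts = pd.Series(0.0, index=table.columns)
    for _ in range(B):
        while True:
            idx = rng.integers(n, size=n)
            if event[idx].sum() > 0:
                break
        model = coxboost_fit(table.iloc[idx], time[idx], event[idx],
                             M, penalty)
        counts[model.selected] += 1.0
    return counts / B


@dataclass
class MultivariateCoxReport:
    table: pd.DataFrame      # coef, hazard_ratio, se, p per covariate
    aic: float
    bic: float
    log_likelihood: float


def multivariate_cox_report(covariates: pd.DataFrame, time: np.ndarray,
                            event: np.ndarray,
                            risk_score: np.ndarray | None = None,
                            ) -> MultivariateCoxReport:
    """Multivariate Cox fit of clinical covariates, optionally including
    the image-marker risk score, with AIC = -2l + 2k and
    BIC = -2l + k log(#events).  The fit itself is delegated to
    lifelines."""
    from lifelines import CoxPHFitter

    df = covariates.copy()
    if risk_score is not None:
        df.insert(0, "risk_score", np.asarray(risk_score, float))
    df["__time"] = np.asarray(time, float)
    df["__event"] = np.asarray(event, int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="__time", event_col="__event")
    summary = pd.DataFrame({
        "coef": cph.params_,
        "hazard_ratio": np.exp(cph.params_),
        "se": cph.standard_errors_,
        "p": cph.summary["p"],
    })
    ll = float(cph.log_likelihood_)
    k = len(cph.params_)
    n_events = int(np.asarray(event).sum())
    aic = -2 * ll + 2 * k
    bic = -2 * ll + k * np.log(n_events)
    return MultivariateCoxReport(summary, float(aic), float(bic), ll)
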