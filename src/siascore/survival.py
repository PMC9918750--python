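"""Survival and association analytics for immune scores.

Kaplan-Meier curves with log-rank tests, Cox proportional-hazards
models (Efron tie handling, dummy coding against fixed reference
levels), likelihood-ratio comparison of nested models, bootstrap AUC of
a risk score for the event-during-follow-up outcome, time-dependent
AUC with inverse-probability-of-censoring weighting
(cumulative-case / dynamic-control definition), Wald-chi-square relative
contributions of model terms, optimal-cut-off dichotomisation, and
responder comparisons (Mann-Whitney, ROC, Spearman).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger("siascore")

__all__ = [
    "ModelFit",
    "km_logrank",
    "cox_fit",
    "lrt_compare",
    "bootstrap_auc",
    "time_dependent_auc",
    "wald_contributions",
    "optimal_cutoff_dichotomize",
    "responder_tests",
    "mann_whitney",
]

#: Reference level per categorical covariate; hazard ratios are
#: expressed against these.
REFERENCE_LEVELS = {
    "sia_stratum": "low",
    "is_category": "Low",
    "t_stage": "T1",
    "n_stage": "N0",
    "age_group": "<=75",
    "sex": "female",
    "msi": "proficient",
}

CATEGORY_ORDERS = {
    "sia_stratum": ["low", "intermediate", "high"],
    "is_category": ["Low", "Intermediate", "High"],
    "t_stage": ["T1", "T2", "T3", "T4"],
    "n_stage": ["N0", "N+"],
    "age_group": ["<=75", ">75"],
    "sex": ["female", "male"],
    "msi": ["proficient", "deficient", "missing"],
}


@dataclass
class ModelFit:
    """A fitted Cox model with per-term summaries.

    ``summary`` has one row per design column: coef, se, HR, 95% CI,
    Wald p.  ``term_columns`` maps each model term to its dummy columns
    so that multi-level terms can be tested jointly.
    """

    summary: pd.DataFrame
    log_likelihood: float
    covariance: pd.DataFrame
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0

    def hr(self, column: str) -> float:
        return float(self.summary.loc[column, "HR"])


def _design_matrix(records: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, dict]:
    """Dummy-code categorical terms against their reference levels."""
    cols = {}
    term_columns: dict[str, list[str]] = {}
    for term in terms:
        if term not in records.columns:
            raise KeyError(f"term {term!r} not found in records")
        series = records[term]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            cols[term] = series.astype(float)
            term_columns[term] = [term]
            continue
        levels = CATEGORY_ORDERS.get(term)
        if levels is None:
            levels = sorted(series.dropna().unique(), key=str)
        ref = REFERENCE_LEVELS.get(term, levels[0])
        present = [lv for lv in levels if lv in set(series.dropna().unique())]
        names = []
        for lv in present:
            if lv == ref:
                continue
            name = f"{term}:{lv}"
            cols[name] = (series == lv).astype(float)
            names.append(name)
        term_columns[term] = names
    return pd.DataFrame(cols, index=records.index), term_columns


def cox_fit(records: pd.DataFrame, terms: list[str],
            duration_col: str = "os_time", event_col: str = "os_event") -> ModelFit:
    """Fit a Cox proportional-hazards model (Efron ties).

    Categorical terms are dummy-coded against the configured reference
    levels (low stratum, T1, N0, age <=75, female, MMR proficient);
    hazard ratios and 95% Wald confidence intervals are reported per
    design column.
    """
    if records[event_col].sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    design, term_columns = _design_matrix(records, terms)
    data = design.copy()
    data["_T"] = records[duration_col].astype(float)
    data["_E"] = records[event_col].astype(int)
    cph = CoxPHFitter()
    cph.fit(data, duration_col="_T", event_col="_E")
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "HR": np.exp(s["coef"]),
        "HR_lower95": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
        "HR_upper95": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
        "p": s["p"],
        "wald_chi2": (s["coef"] / s["se(coef)"]) ** 2,
    })
    return ModelFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        covariance=cph.variance_matrix_,
        term_columns=term_columns,
        n=len(records),
        n_events=int(records[event_col].sum()),
    )


def cox_linear_predictor(fit: ModelFit, records: pd.DataFrame) -> pd.Series:
    design, _ = _design_matrix(records, list(fit.term_columns))
    design = design[fit.summary.index]
    return design @ fit.summary["coef"]


def km_logrank(records: pd.DataFrame, group_col: str,
               duration_col: str = "os_time", event_col: str = "os_event"):
    """Kaplan-Meier curves per group and the k-group log-rank test.

    Returns ``(curves, p_value)`` where ``curves`` maps each group label
    to its fitted :class:`~lifelines.KaplanMeierFitter`.
    """
    groups = records[group_col].dropna()
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    curves = {}
    for label in labels:
        sub = records.loc[groups[groups == label].index]
        if len(sub) == 0:
            raise ValueError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter(label=str(label))
        kmf.fit(sub[duration_col], sub[event_col])
        curves[label] = kmf
    sub = records.loc[groups.index]
    res = multivariate_logrank_test(
        sub[duration_col], groups, sub[event_col]
    )
    return curves, float(res.p_value)


def logrank_two_sample(time, event, in_group_b) -> tuple[float, float]:
    """Two-group log-rank statistic and p value (chi-square, 1 df).

    Lightweight counting-process implementation used by the cut-off
    scan, where thousands of tests are evaluated.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    b = np.asarray(in_group_b, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, b = time[order], event[order], b[order]
    n = len(time)
    event_times, first_idx = np.unique(time[event], return_index=True)

    # at-risk counts just before each event time
    at_risk_total = n - np.searchsorted(time, event_times, side="left")
    cum_b = np.concatenate([[0], np.cumsum(b)])
    at_risk_b = cum_b[n] - cum_b[np.searchsorted(time, event_times, side="left")]
    # deaths at each event time
    d_total = np.array([np.sum(event & (time == t)) for t in event_times])
    d_b = np.array([np.sum(event & b & (time == t)) for t in event_times])

    frac = at_risk_b / at_risk_total
    expected = d_total * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_total * frac * (1 - frac) * (at_risk_total - d_total) \
            / np.maximum(at_risk_total - 1, 1)
    observed_minus_expected = (d_b - expected).sum()
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = observed_minus_expected ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def lrt_compare(fit_nested: ModelFit, fit_full: ModelFit) -> tuple[float, float]:
    """Likelihood-ratio test between two nested Cox fits.

    Lambda = 2 (l_full - l_nested) ~ chi-square with df = difference in
    the number of estimated coefficients.
    """
    nested_terms = set(fit_nested.term_columns)
    full_terms = set(fit_full.term_columns)
    if not nested_terms <= full_terms:
        raise ValueError("models are not nested: "
                         f"{sorted(nested_terms - full_terms)} only in 'nested'")
    if fit_nested.n != fit_full.n:
        raise ValueError("nested and full fits use different record counts")
    ddf = len(fit_full.summary) - len(fit_nested.summary)
    lam = 2.0 * (fit_full.log_likelihood - fit_nested.log_likelihood)
    if lam < 0:
        if lam < -1e-6:
            warnings.warn(f"negative LRT statistic {lam:.3g} clipped to 0")
        lam = 0.0
    p = float(stats.chi2.sf(lam, df=max(ddf, 1))) if ddf > 0 else 1.0
    if ddf == 0:
        p = 1.0
    return float(lam), p


def bootstrap_auc(outcome, score, n_boot: int = 1000, seed: int = 0) -> dict:
    """Bootstrap distribution of the rank AUC of ``score`` vs ``outcome``.

    ``outcome`` is the binary event-during-follow-up indicator; the
    score is typically a Cox linear predictor (higher = higher risk) or
    a raw marker.  Patients are resampled with replacement, stratified
    on outcome so every resample contains both classes.  Returns the
    median and the 2.5/97.5 percentiles of the replicate AUCs.
    """
    outcome = np.asarray(outcome, dtype=bool)
    score = np.asarray(score, dtype=float)
    if outcome.all() or not outcome.any():
        raise ValueError("outcome has a single class; AUC undefined")
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(outcome)
    idx_neg = np.flatnonzero(~outcome)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_pos, size=idx_pos.size, replace=True),
            rng.choice(idx_neg, size=idx_neg.size, replace=True),
        ])
        aucs[i] = roc_auc_score(outcome[take], score[take])
    return {
        "median": float(np.median(aucs)),
        "lower": float(np.percentile(aucs, 2.5)),
        "upper": float(np.percentile(aucs, 97.5)),
        "aucs": aucs,
    }


def _censoring_survival_left(time, event):
    """Left-continuous KM estimate G(t-) of the censoring distribution.

    Returns a function mapping times to G(t-); censoring is the flipped
    event indicator.
    """
    time = np.asarray(time, dtype=float)
    cens = ~np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    t_sorted, c_sorted = time[order], cens[order]
    uniq = np.unique(t_sorted[c_sorted]) if c_sorted.any() else np.array([])
    n = len(t_sorted)
    surv_vals = []
    g = 1.0
    for t in uniq:
        at_risk = n - np.searchsorted(t_sorted, t, side="left")
        d = np.sum(c_sorted & (t_sorted == t))
        g *= 1.0 - d / at_risk
        surv_vals.append(g)
    surv_vals = np.array(surv_vals)

    def g_left(ts):
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        if uniq.size == 0:  # no censoring at all
            return np.ones_like(ts)
        # number of censoring times strictly below each t
        k = np.searchsorted(uniq, ts, side="left")
        return np.where(k == 0, 1.0, surv_vals[np.maximum(k - 1, 0)])

    return g_left


def time_dependent_auc(records: pd.DataFrame, score, eval_times,
                       duration_col: str = "os_time",
                       event_col: str = "os_event") -> pd.Series:
    """Cumulative-case / dynamic-control AUC(t) with IPCW.

    At horizon t, cases are subjects with an observed event by t and
    controls are subjects still at risk beyond t.  Cases are weighted by
    the inverse of the Kaplan-Meier censoring survival G(T_i-); with no
    censoring this reduces exactly to the proportion of concordant
    (case, control) score pairs.  Horizons at or beyond the last
    observed time are dropped with a warning.
    """
    time = records[duration_col].to_numpy(float)
    event = records[event_col].to_numpy(bool)
    score = np.asarray(score, dtype=float)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    t_max = time.max()
    keep = eval_times < t_max
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} evaluation time(s) beyond the last observed "
            f"time {t_max:g} dropped"
        )
    eval_times = eval_times[keep]
    g_left = _censoring_survival_left(time, event)

    out = {}
    for t in eval_times:
        case = (time <= t) & event
        control = time > t
        if not case.any() or not control.any():
            out[t] = np.nan
            continue
        w = 1.0 / g_left(time[case])
        s_case, s_ctrl = score[case], score[control]
        # concordant pairs: case score above control score; ties half
        gt = (s_case[:, None] > s_ctrl[None, :]).astype(float)
        gt += 0.5 * (s_case[:, None] == s_ctrl[None, :])
        num = (w[:, None] * gt).sum()
        den = w.sum() * control.sum()
        out[t] = num / den
    return pd.Series(out, name="tAUC")


def wald_contributions(fit: ModelFit) -> pd.Series:
    """Relative contribution of each model term by Wald chi-square.

    A term's chi-square is the quadratic form beta' V^-1 beta over its
    dummy columns (so multi-level factors are tested jointly); the
    returned proportions sum to 1.
    """
    if len(fit.term_columns) < 2:
        raise ValueError("need a multivariable fit with at least 2 terms")
    chi2 = {}
    for term, cols in fit.term_columns.items():
        if not cols:
            continue
        beta = fit.summary.loc[cols, "coef"].to_numpy()
        vblock = fit.covariance.loc[cols, cols].to_numpy()
        try:
            sol = np.linalg.solve(vblock, beta)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular covariance block for term {term!r}") from exc
        chi2[term] = float(beta @ sol)
    total = sum(chi2.values())
    return pd.Series({k: v / total for k, v in chi2.items()}, name="proportion")


def optimal_cutoff_dichotomize(values: pd.Series, records: pd.DataFrame,
                               duration_col: str = "os_time",
                               event_col: str = "os_event",
                               window: tuple[float, float] = (0.10, 0.90)) -> dict:
    """Dichotomise a score at the cut-off minimising the log-rank p.

    Candidate cut-offs are the observed score values inside the quantile
    window (default 10th-90th percentile).  The minimised p value is
    optimistically biased by the scan over candidates and is reported
    with an explicit caveat rather than corrected, mirroring common
    optimal-cut-off practice.
    """
    v = values.dropna()
    if v.nunique() < 2:
        raise ValueError("all score values identical; no cut-off possible")
    if records.loc[v.index, event_col].sum() < 1:
        raise ValueError("need events to evaluate cut-offs")
    lo, hi = np.quantile(v, window)
    candidates = np.unique(v[(v >= lo) & (v <= hi)])
    if candidates.size == 0:
        candidates = np.array([lo])
    time = records.loc[v.index, duration_col].to_numpy(float)
    event = records.loc[v.index, event_col].to_numpy(bool)

    best = None
    for c in candidates:
        high = (v > c).to_numpy()
        if not high.any() or high.all():
            continue
        _, p = logrank_two_sample(time, event, high)
        if best is None or p < best[1]:
            best = (float(c), p)
    if best is None:
        raise ValueError("no cut-off produced two non-empty groups")
    cutoff, p = best
    labels = pd.Series(np.where(v > cutoff, "high", "low"), index=v.index,
                       name="group").reindex(values.index)
    return {
        "cutoff": cutoff,
        "labels": labels,
        "logrank_p": p,
        "note": ("p value minimised over candidate cut-offs; "
                 "optimistically biased, no multiple-testing correction applied"),
    }


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test: exact for small tie-free samples (n <= 20
    total), normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def responder_tests(scores: pd.Series, response: pd.Series,
                    responder_label="responder",
                    response_order=None,
                    n_boot: int = 1000, seed: int = 0) -> dict:
    """Compare scores between therapy response groups.

    Returns the Mann-Whitney U and p (responders vs the rest), the ROC
    AUC for discriminating responders with a bootstrap percentile CI,
    and the Spearman rank correlation of the score against the ordinal
    response coding (``response_order``, worst to best; defaults to the
    binary coding).
    """
    aligned = pd.DataFrame({"score": scores, "response": response}).dropna()
    is_resp = aligned["response"] == responder_label
    if is_resp.all() or not is_resp.any():
        raise ValueError("both response groups must be non-empty")
    u, p = mann_whitney(aligned.loc[is_resp, "score"],
                        aligned.loc[~is_resp, "score"])
    boot = bootstrap_auc(is_resp.to_numpy(), aligned["score"].to_numpy(),
                         n_boot=n_boot, seed=seed)
    auc = roc_auc_score(is_resp, aligned["score"])
    if response_order is None:
        ordinal = is_resp.astype(int)
    else:
        coding = {lab: i for i, lab in enumerate(response_order)}
        ordinal = aligned["response"].map(coding)
    rho, rho_p = stats.spearmanr(aligned["score"], ordinal)
    return {
        "mannwhitney_u": u, "mannwhitney_p": p,
        "roc_auc": float(auc),
        "roc_auc_ci": (boot["lower"], boot["upper"]),
        "spearman_rho": float(rho), "spearman_p": float(rho_p),
    }
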