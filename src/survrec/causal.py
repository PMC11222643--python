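"""Recommendation-quality evaluation with inverse-probability-of-treatment
weighting.

Patients whose actual treatment matched the model's recommendation (the
"Consis." group) are compared with those whose treatment contradicted it
("Inconsis.").  Because consistency-group membership is not randomized,
group comparisons are debiased with IPTW: a main-effects logistic model
of group membership on the adjusted baseline covariates yields stabilized
weights w = P(G = g) / P(G = g | X), truncated at the 1st/99th weight
percentiles.  The survival advantage of following recommendations is then
summarized by the hazard ratio (raw form covariate-adjusted, IPTW form
weighted with robust variance), the 10-year risk difference, the
difference in 10-year restricted mean survival time, the log-rank test
(raw and weighted), and the per-arm integrated Brier score of the
underlying survival model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

__all__ = ["WeightVector", "EffectReport", "fit_propensity", "smd",
           "weighted_cox_hr", "km_risk_difference", "rmst_difference",
           "integrated_brier", "ipcw_brier", "logrank",
           "evaluate_recommender", "ADJUSTED_COVARIATES"]

#: baseline covariates adjusted in the propensity and multivariate models
#: (treatment variables are post-exposure and deliberately excluded)
ADJUSTED_COVARIATES = ["age", "tumor_size_mm", "positive_nodes", "grade",
                       "histology", "location", "laterality", "race",
                       "marriage", "income"]


@dataclass
class WeightVector:
    propensity: np.ndarray      # P(observed group | X)
    weights: np.ndarray         # stabilized, truncated
    truncated: np.ndarray       # bool per patient
    marginal: float             # P(G = 1)


def fit_propensity(design: np.ndarray, group, stabilized: bool = True,
                   truncate: tuple = (1.0, 99.0)) -> WeightVector:
    """Main-effects logistic model for group membership; stabilized
    weights truncated at the given weight percentiles.

    Near-perfect separation (fitted probabilities indistinguishable from
    0 or 1) raises a ``ValueError`` advising covariate reduction.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.atleast_2d(np.asarray(design, float))
    g = np.asarray(group).astype(int)
    if g.min() == g.max():
        raise ValueError("both groups must be non-empty")
    lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(X, g)
    p1 = lr.predict_proba(X)[:, 1]
    perfectly_classified = np.all((p1 > 0.5) == (g == 1))
    all_extreme = np.all(np.minimum(p1, 1 - p1) < 1e-6)
    if perfectly_classified and all_extreme:
        raise ValueError(
            "propensity model separates the groups perfectly; "
            "reduce or coarsen the adjusted covariates")
    p1 = np.clip(p1, 1e-6, 1 - 1e-6)
    e = np.where(g == 1, p1, 1 - p1)          # P(observed group | X)
    marginal = g.mean()
    numer = np.where(g == 1, marginal, 1 - marginal) if stabilized else 1.0
    w = numer / e
    lo, hi = np.percentile(w, truncate)
    truncated = (w < lo) | (w > hi)
    w = np.clip(w, lo, hi)
    return WeightVector(propensity=e, weights=w, truncated=truncated,
                        marginal=float(marginal))


def _wmean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = np.average(x, weights=w)
    v = np.average((x - m) ** 2, weights=w)
    return float(m), float(v)


def smd(values, group, weights=None) -> float:
    """Standardized mean difference (group 1 minus group 0), using
    pooled-variance standardization; binary covariates use the
    proportion variance p(1-p)."""
    x = np.asarray(values, float)
    g = np.asarray(group).astype(int)
    if g.min() == g.max():
        raise ValueError("both groups must be non-empty")
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    binary = set(np.unique(x)) <= {0.0, 1.0}
    stats_ = {}
    for lev in (0, 1):
        m, v = _wmean_var(x[g == lev], w[g == lev])
        if binary:
            v = m * (1 - m)
        stats_[lev] = (m, v)
    denom = np.sqrt((stats_[0][1] + stats_[1][1]) / 2)
    diff = stats_[1][0] - stats_[0][0]
    if denom == 0:
        if abs(diff) < 1e-12:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(diff / denom)


def weighted_cox_hr(times, events, group, covariates=None, weights=None,
                    penalizer: float = 0.0):
    """Hazard ratio of group 1 vs group 0 with 95% CI.

    Unweighted: a multivariate Cox fit adjusting for ``covariates``.
    Weighted: the IPTW fit of the group effect alone, with robust
    (sandwich) variance.  ``penalizer`` adds a small ridge penalty,
    useful when rare dummy levels make the adjusted fit ill-conditioned
    at small n.
    """
    df = pd.DataFrame({"time": np.asarray(times, float),
                       "event": np.asarray(events, int),
                       "group": np.asarray(group).astype(int)})
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        keep = cov.std(axis=0) > 0
        for j in np.flatnonzero(keep):
            df[f"x{j}"] = cov[:, j]
    kwargs = {}
    if weights is not None:
        df["w"] = np.asarray(weights, float)
        kwargs = {"weights_col": "w", "robust": True}
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", **kwargs)
    except Exception as exc:
        raise ValueError(f"Cox fit failed (monotone likelihood or "
                         f"separation?): {exc}") from exc
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return (float(np.exp(coef)), float(np.exp(coef - 1.96 * se)),
            float(np.exp(coef + 1.96 * se)))


def _km_surv_at(times, events, w, tau: float) -> float:
    km = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # lifelines warns on float weights
        km.fit(times, events, weights=w)
    sf = km.survival_function_.iloc[:, 0]
    usable = sf.index[sf.index <= tau]
    if len(usable) == 0:
        return 1.0
    if times.max() < 0.95 * tau:
        warnings.warn("follow-up ends well before the horizon; survival "
                      "taken at the last observed time", stacklevel=3)
    return float(sf.loc[usable[-1]])


def _km_rmst(times, events, w, tau: float) -> float:
    km = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # lifelines warns on float weights
        km.fit(times, events, weights=w)
        return float(restricted_mean_survival_time(km, t=tau))


def _group_metric(times, events, group, weights, tau, fn):
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group).astype(int)
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    return {lev: fn(t[g == lev], e[g == lev], w[g == lev], tau)
            for lev in (0, 1)}


def km_risk_difference(times, events, group, tau: float = 120.0,
                       weights=None, n_boot: int = 0, seed: int = 0):
    """10-year risk difference in percentage points:
    RD = 100 * [(1 - S_0(tau)) - (1 - S_1(tau))] with group 1 = Consis.
    Positive values mean the inconsistent group dies more.  Optional
    percentile-bootstrap CI (resampling patients)."""
    def point(t, e, g, w):
        s = _group_metric(t, e, g, w, tau, _km_surv_at)
        return 100.0 * ((1 - s[0]) - (1 - s[1]))
    return _with_bootstrap(point, times, events, group, weights, n_boot, seed)


def rmst_difference(times, events, group, tau: float = 120.0,
                    weights=None, n_boot: int = 0, seed: int = 0):
    """Difference in 10-year restricted mean survival time (months),
    group 1 (Consis.) minus group 0 (Inconsis.)."""
    def point(t, e, g, w):
        r = _group_metric(t, e, g, w, tau, _km_rmst)
        return r[1] - r[0]
    return _with_bootstrap(point, times, events, group, weights, n_boot, seed)


def _with_bootstrap(point_fn, times, events, group, weights, n_boot, seed):
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group).astype(int)
    w = None if weights is None else np.asarray(weights, float)
    est = point_fn(t, e, g, np.ones_like(t) if w is None else w)
    if n_boot <= 0:
        return est, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(t), len(t))
        if g[idx].min() == g[idx].max():
            continue
        reps.append(point_fn(t[idx], e[idx], g[idx],
                             np.ones(len(idx)) if w is None else w[idx]))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return est, float(lo), float(hi)


def logrank(times, events, group, weights=None):
    """Log-rank test (chi-square with 1 df).  The weighted variant plugs
    IPTW weights into the at-risk and event sums (adjusted log-rank).
    Returns ``(statistic, p_value)``."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group).astype(int)
    if g.min() == g.max():
        raise ValueError("both groups must be non-empty")
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    if e.sum() == 0:
        warnings.warn("no events: log-rank p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    event_times = np.unique(t[e == 1])
    O_minus_E, V = 0.0, 0.0
    for et in event_times:
        at_risk = t >= et
        Y = w[at_risk].sum()
        Y1 = w[at_risk & (g == 1)].sum()
        died = (t == et) & (e == 1)
        d = w[died].sum()
        d1 = w[died & (g == 1)].sum()
        if Y <= 0 or Y1 in (0.0, Y):
            continue
        O_minus_E += d1 - d * Y1 / Y
        if Y > 1:
            V += d * (Y1 / Y) * (1 - Y1 / Y) * (Y - d) / (Y - 1)
    if V <= 0:
        return 0.0, 1.0
    stat = O_minus_E ** 2 / V
    return float(stat), float(stats.chi2.sf(stat, df=1))


def ipcw_brier(times, events, surv_matrix, grid, tau: float = 120.0) -> float:
    """Integrated Brier score with inverse-probability-of-censoring
    weights, averaged over [0, tau].

    ``surv_matrix`` holds each subject's predicted survival on ``grid``.
    If the censoring KM reaches 0 before ``tau``, integration stops at
    the last usable time (warned)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    S = np.atleast_2d(np.asarray(surv_matrix, float))
    grid = np.asarray(grid, float)
    mask = grid <= tau + 1e-9
    grid = grid[mask]
    S = S[:, mask]

    km_c = KaplanMeierFitter()
    km_c.fit(t, 1 - e)
    cens_sf = km_c.survival_function_.iloc[:, 0]

    def G(x):
        x = np.asarray(x, float)
        idx = np.searchsorted(cens_sf.index.to_numpy(), x, side="right") - 1
        vals = np.r_[1.0, cens_sf.to_numpy()]
        return vals[idx + 1]

    # G evaluated just before the subject's own time (left limit)
    G_tm = G(np.maximum(t - 1e-9, 0))
    usable = G(grid) > 0
    if not usable.all():
        warnings.warn("censoring survival reaches 0 before the horizon; "
                      "integrating to the last usable time", stacklevel=2)
        grid, S = grid[usable], S[:, usable]
    Gg = G(grid)

    died = ((t[:, None] <= grid[None, :]) & (e[:, None] == 1))
    alive = t[:, None] > grid[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (S ** 2 * died / np.where(G_tm[:, None] > 0,
                                            G_tm[:, None], np.inf)
                   + (1 - S) ** 2 * alive / Gg[None, :])
    bs = contrib.mean(axis=0)
    if len(grid) < 2:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


def integrated_brier(model, design, times, events, treatment, grid,
                     tau: float = 120.0) -> dict:
    """Per-treatment-arm IBS of a fitted risk model on factual outcomes:
    arm 0 (untreated) patients scored against the model's untreated
    curves, arm 1 against the treated curves."""
    from .models import predict_survival

    a = np.asarray(treatment, int)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    X = np.atleast_2d(np.asarray(design, float))
    curves = predict_survival(model, X, grid)
    out = {}
    for arm, S in ((0, curves.S0), (1, curves.S1)):
        m = a == arm
        if m.sum() == 0:
            out[arm] = float("nan")
            continue
        out[arm] = ipcw_brier(t[m], e[m], S[m], grid, tau)
    return out


# ---------------------------------------------------------------------------
# full recommendation evaluation
# ---------------------------------------------------------------------------

@dataclass
class EffectReport:
    """Consistency-group comparison, raw and IPTW-adjusted (the layout of
    a per-model results row: HR / RD / DRMST with CIs, log-rank p-values,
    per-arm IBS, and the covariate-balance table)."""

    n_consis: int
    n_inconsis: int
    hr: tuple
    hr_iptw: tuple
    rd: tuple
    rd_iptw: tuple
    drmst: tuple
    drmst_iptw: tuple
    logrank_p: float
    logrank_p_iptw: float
    ibs_untreated: float = float("nan")
    ibs_treated: float = float("nan")
    smd_before: dict = field(default_factory=dict)
    smd_after: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        def triple(t):
            return {"estimate": t[0], "ci_low": t[1], "ci_high": t[2]}
        return {
            "n_consis": self.n_consis, "n_inconsis": self.n_inconsis,
            "HR": triple(self.hr), "IPTW_HR": triple(self.hr_iptw),
            "RD_percent": triple(self.rd), "IPTW_RD_percent": triple(self.rd_iptw),
            "DRMST_months": triple(self.drmst),
            "IPTW_DRMST_months": triple(self.drmst_iptw),
            "logrank_p": self.logrank_p, "IPTW_logrank_p": self.logrank_p_iptw,
            "IBS_untreated": self.ibs_untreated, "IBS_treated": self.ibs_treated,
            "max_abs_SMD_before": (max(abs(v) for v in self.smd_before.values())
                                   if self.smd_before else float("nan")),
            "max_abs_SMD_after": (max(abs(v) for v in self.smd_after.values())
                                  if self.smd_after else float("nan")),
            "degenerate": self.degenerate,
        }


def evaluate_recommender(cohort: pd.DataFrame, recommended, *,
                         tau: float = 120.0, n_boot: int = 200, seed: int = 0,
                         model=None, design=None, grid=None) -> EffectReport:
    """Full pipeline from recommendations to the debiased effect report.

    ``recommended`` is the per-row 0/1 chemotherapy recommendation (from
    any model or rule).  Consistency labels are formed against the actual
    treatment, a propensity model for consistency-group membership is fit
    on the adjusted baseline covariates, and every metric is computed raw
    and IPTW-weighted.  RD and DRMST CIs use a patient-level bootstrap
    with the propensity model refit in every replicate; HR CIs are
    analytic (robust variance for the weighted fit).  When ``model`` (and
    its ``design`` matrix and time ``grid``) is given, per-arm IBS of the
    model's own survival curves is included.
    """
    from .ite import consistency_labels
    from .preprocess import encode_covariates

    rec = np.asarray(recommended, int)
    actual = cohort["treatment"].to_numpy(int)
    consis = consistency_labels(rec, actual).astype(int)
    t = cohort["time_months"].to_numpy(float)
    e = cohort["event"].to_numpy(int)

    dm = encode_covariates(cohort, scheme="onehot_drop")
    X = dm.matrix

    if consis.min() == consis.max():
        nan3 = (float("nan"),) * 3
        return EffectReport(
            n_consis=int(consis.sum()), n_inconsis=int(len(consis) - consis.sum()),
            hr=nan3, hr_iptw=nan3, rd=nan3, rd_iptw=nan3, drmst=nan3,
            drmst_iptw=nan3, logrank_p=float("nan"),
            logrank_p_iptw=float("nan"), degenerate=True)

    wv = fit_propensity(X, consis)
    w = wv.weights

    smd_before = {name: smd(X[:, j], consis)
                  for j, name in enumerate(dm.feature_names)}
    smd_after = {name: smd(X[:, j], consis, weights=w)
                 for j, name in enumerate(dm.feature_names)}

    # light ridge on the adjusted fit: rare dummy levels at desk-scale n
    # otherwise break Newton-Raphson without changing the group effect
    hr = weighted_cox_hr(t, e, consis, covariates=X, penalizer=0.01)
    hr_iptw = weighted_cox_hr(t, e, consis, weights=w)
    rd = km_risk_difference(t, e, consis, tau=tau)[:1]
    rd_iptw = km_risk_difference(t, e, consis, tau=tau, weights=w)[:1]
    drmst = rmst_difference(t, e, consis, tau=tau)[:1]
    drmst_iptw = rmst_difference(t, e, consis, tau=tau, weights=w)[:1]

    # joint bootstrap for the four KM-based intervals, propensity refit
    # in every replicate
    boots = {k: [] for k in ("rd", "rd_iptw", "drmst", "drmst_iptw")}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, len(t), len(t))
        if consis[idx].min() == consis[idx].max():
            continue
        try:
            wb = fit_propensity(X[idx], consis[idx]).weights
        except ValueError:
            continue
        tb, eb, gb = t[idx], e[idx], consis[idx]
        ones = np.ones(len(idx))
        s = _group_metric(tb, eb, gb, ones, tau, _km_surv_at)
        boots["rd"].append(100 * ((1 - s[0]) - (1 - s[1])))
        s = _group_metric(tb, eb, gb, wb, tau, _km_surv_at)
        boots["rd_iptw"].append(100 * ((1 - s[0]) - (1 - s[1])))
        r = _group_metric(tb, eb, gb, ones, tau, _km_rmst)
        boots["drmst"].append(r[1] - r[0])
        r = _group_metric(tb, eb, gb, wb, tau, _km_rmst)
        boots["drmst_iptw"].append(r[1] - r[0])

    def ci(key, est):
        if n_boot <= 0 or not boots[key]:
            return (est[0], float("nan"), float("nan"))
        lo, hi = np.percentile(boots[key], [2.5, 97.5])
        return (est[0], float(lo), float(hi))

    ibs = {0: float("nan"), 1: float("nan")}
    if model is not None and design is not None:
        g = np.arange(0.0, tau + 1.0) if grid is None else grid
        ibs = integrated_brier(model, design, t, e,
                               cohort["treatment"].to_numpy(int), g, tau)

    return EffectReport(
        n_consis=int(consis.sum()),
        n_inconsis=int(len(consis) - consis.sum()),
        hr=hr, hr_iptw=hr_iptw,
        rd=ci("rd", rd), rd_iptw=ci("rd_iptw", rd_iptw),
        drmst=ci("drmst", drmst), drmst_iptw=ci("drmst_iptw", drmst_iptw),
        logrank_p=logrank(t, e, consis)[1],
        logrank_p_iptw=logrank(t, e, consis, weights=w)[1],
        ibs_untreated=ibs[0], ibs_treated=ibs[1],
        smd_before=smd_before, smd_after=smd_after)
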