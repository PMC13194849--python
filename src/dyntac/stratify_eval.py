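"""Single-marker risk stratification and model evaluation.

Covers Kaplan-Meier estimation, the two-group log-rank test, the data-driven
optimal log-rank cutoff (an exploratory, optimism-prone procedure - see
:func:`optimal_logrank_cutoff`), cumulative/dynamic time-dependent ROC,
IPCW Brier / calibration at a horizon, survival decision-curve analysis and
the descriptive two-group comparison battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.special import gammaln

from .errors import InvalidInputError

__all__ = [
    "km_estimate",
    "logrank_test",
    "optimal_logrank_cutoff",
    "StratificationResult",
    "td_auc",
    "TdAucResult",
    "calibration_at",
    "CalibrationResult",
    "decision_curve",
    "compare_groups",
    "MONTH_DAYS",
]

#: days per month used to convert 12/18/24-month horizons to days
MONTH_DAYS = 30.4375


def _check_surv(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise InvalidInputError("time and event must be matching non-empty 1-D arrays")
    if np.all(t <= 0):
        raise InvalidInputError("all survival times are <= 0")
    return t, e


def km_estimate(time, event, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood (log-log) CIs."""
    t, e = _check_surv(time, event)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)
    ci = kmf.confidence_interval_survival_function_
    return pd.DataFrame(
        {
            "time": kmf.survival_function_.index.values,
            "survival": kmf.survival_function_["KM_estimate"].values,
            "ci_lo": ci.iloc[:, 0].values,
            "ci_hi": ci.iloc[:, 1].values,
        }
    )


def _km_at(time, event, horizon) -> float:
    """KM survival probability at ``horizon`` (1.0 if no events by then)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    uniq, counts = np.unique(t[(e == 1) & (t <= horizon)], return_counts=True)
    if uniq.size == 0:
        return 1.0
    t_sorted = np.sort(t)
    n_risk = t.size - np.searchsorted(t_sorted, uniq, side="left")
    return float(np.prod(1.0 - counts / n_risk))


def logrank_test(time_a, event_a, time_b, event_b):
    """Two-group log-rank chi-square (1 df); returns (statistic, p)."""
    ta, ea = _check_surv(time_a, event_a)
    tb, eb = _check_surv(time_b, event_b)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class StratificationResult:
    cutoff: float
    low_marker: np.ndarray  # True where marker <= cutoff
    statistic: float
    p_value: float
    low_marker_is_high_risk: bool
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    n_cutoffs_scanned: int


def optimal_logrank_cutoff(marker, time, event, min_group_frac: float = 0.15,
                           min_group_n: int = 3) -> StratificationResult:
    """Cutoff maximizing the two-group log-rank statistic.

    Scans midpoints between consecutive distinct marker values whose induced
    split leaves at least ``min_group_frac`` of patients (and ``min_group_n``)
    on each side. The resulting p-value is optimistically biased because the
    cutoff is chosen on the same data; treat it as exploratory.
    """
    m = np.asarray(marker, dtype=float)
    t, e = _check_surv(time, event)
    if m.shape != t.shape:
        raise InvalidInputError("marker and survival arrays must align")
    distinct = np.unique(m)
    if distinct.size < 2:
        raise InvalidInputError("marker must take at least 2 distinct values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = m.size
    min_n = max(min_group_n, int(np.ceil(min_group_frac * n)))
    best = None
    scanned = 0
    for c in mids:
        low = m <= c
        if low.sum() < min_n or (~low).sum() < min_n:
            continue
        scanned += 1
        stat, p = logrank_test(t[low], e[low], t[~low], e[~low])
        if best is None or stat > best[0]:
            best = (stat, p, float(c), low)
    if best is None:
        raise InvalidInputError("no admissible cutoff under the group-size constraint")
    stat, p, cutoff, low = best
    km_lo = km_estimate(t[low], e[low])
    km_hi = km_estimate(t[~low], e[~low])
    horizon = float(np.median(t))
    low_worse = _km_at(t[low], e[low], horizon) < _km_at(t[~low], e[~low], horizon)
    return StratificationResult(
        cutoff=cutoff,
        low_marker=low,
        statistic=stat,
        p_value=p,
        low_marker_is_high_risk=bool(low_worse),
        km_low=km_lo,
        km_high=km_hi,
        n_cutoffs_scanned=scanned,
    )


@dataclass(frozen=True)
class TdAucResult:
    auc: float
    horizon: float
    roc: pd.DataFrame  # threshold, tpr, fpr
    ci: tuple | None = None


def _td_roc_points(m, t, e, horizon):
    s_all = _km_at(t, e, horizon)
    if s_all >= 1.0 - 1e-12:
        raise InvalidInputError("no cases by the requested horizon")
    if s_all <= 1e-12:
        raise InvalidInputError("no controls remain at the requested horizon")
    thr = np.unique(m)
    pts = [(np.inf, 0.0, 0.0)]
    for c in thr[::-1]:
        pos = m > c
        neg = ~pos
        s_pos = _km_at(t[pos], e[pos], horizon) if pos.any() else 1.0
        s_neg = _km_at(t[neg], e[neg], horizon) if neg.any() else 1.0
        p_pos = pos.mean()
        sens = (1.0 - s_pos) * p_pos / (1.0 - s_all)
        spec = s_neg * (1.0 - p_pos) / s_all
        pts.append((float(c), float(np.clip(sens, 0, 1)), float(np.clip(1 - spec, 0, 1))))
    pts.append((-np.inf, 1.0, 1.0))
    return pd.DataFrame(pts, columns=["threshold", "tpr", "fpr"])


def td_auc(marker, time, event, horizon, n_bootstrap_ci: int = 0, seed: int = 0) -> TdAucResult:
    """Cumulative-case / dynamic-control time-dependent AUC at one horizon.

    Kaplan-Meier based estimator: cases are patients with an event by the
    horizon, controls those event-free past it, with censoring absorbed by
    subset KM estimates. Larger marker values are treated as higher risk
    (negate the marker for inversely oriented biomarkers). On uncensored
    data this reduces exactly to the Mann-Whitney rank statistic.
    """
    m = np.asarray(marker, dtype=float)
    t, e = _check_surv(time, event)
    if m.shape != t.shape:
        raise InvalidInputError("marker and survival arrays must align")
    if not (t.min() <= horizon <= t.max()):
        raise InvalidInputError("horizon outside the observed follow-up range")
    roc = _td_roc_points(m, t, e, horizon)
    # rows are already ordered by decreasing threshold, i.e. increasing FPR
    auc = float(np.trapezoid(roc["tpr"].values, roc["fpr"].values))
    ci = None
    if n_bootstrap_ci > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7DAC)))
        draws = []
        attempts = 0
        while len(draws) < n_bootstrap_ci and attempts < n_bootstrap_ci * 10:
            attempts += 1
            idx = rng.integers(0, m.size, size=m.size)
            try:
                r = _td_roc_points(m[idx], t[idx], e[idx], horizon)
            except InvalidInputError:
                continue
            draws.append(float(np.trapezoid(r["tpr"].values, r["fpr"].values)))
        if draws:
            ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return TdAucResult(auc=auc, horizon=float(horizon), roc=roc, ci=ci)


def _censor_km_factory(time, event):
    """KM of the censoring distribution G(t) = P(censoring time > t)."""
    t = np.asarray(time, dtype=float)
    c = 1 - np.asarray(event, dtype=int)  # censoring "events"
    uniq = np.unique(t[c == 1])
    surv = []
    s = 1.0
    for u in uniq:
        n_risk = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (c == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)
    if uniq.size == 0:  # no censoring at all

        def G(x, left_limit=False):
            x = np.asarray(x, dtype=float)
            out = np.ones_like(x)
            return out if out.ndim else 1.0

        return G

    def G(x, left_limit=False):
        x = np.asarray(x, dtype=float)
        side = "left" if left_limit else "right"
        idx = np.searchsorted(uniq, x, side=side)
        out = np.where(idx == 0, 1.0, surv[np.clip(idx - 1, 0, max(len(surv) - 1, 0))])
        return out if out.ndim else float(out)

    return G


def ipcw_brier(pred_risk, time, event, horizon) -> float:
    """Inverse-probability-of-censoring weighted Brier score at ``horizon``."""
    p = np.asarray(pred_risk, dtype=float)
    t, e = _check_surv(time, event)
    G = _censor_km_factory(t, e)
    y_event = (t <= horizon) & (e == 1)
    y_alive = t > horizon
    w = np.zeros_like(p)
    w[y_event] = 1.0 / np.maximum(G(t[y_event], left_limit=True), 1e-12)
    w[y_alive] = 1.0 / max(float(G(np.array([horizon]))[0]), 1e-12)
    sq = np.where(y_event, (1.0 - p) ** 2, p**2)
    return float(np.mean(w * sq))


@dataclass(frozen=True)
class CalibrationResult:
    brier: float
    intercept: float
    slope: float
    curve: pd.DataFrame  # bin, mean_predicted, observed
    slope_defined: bool
    ci: dict | None = None


def _calibration_core(p, t, e, horizon, n_bins):
    brier = ipcw_brier(p, t, e, horizon)
    # miscalibration-in-the-large: observed vs expected events by the horizon
    obs_risk = 1.0 - _km_at(t, e, horizon)
    expected = float(np.mean(p))
    intercept = float(np.log(max(obs_risk, 1e-12) / max(expected, 1e-12)))
    slope_defined = np.unique(p).size > 1
    if slope_defined:
        x = np.log(-np.log(np.clip(1.0 - p, 1e-12, 1 - 1e-12)))
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"x": x, "time": t, "event": e})
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
            slope = float(cph.params_["x"])
        except Exception:
            slope, slope_defined = np.nan, False
    else:
        slope = np.nan
    # binned curve: mean predicted vs KM-observed risk per quantile bin
    ranks = pd.qcut(pd.Series(p).rank(method="first"), q=n_bins, labels=False)
    rows = []
    for b in range(n_bins):
        sel = ranks.values == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(np.mean(p[sel])),
                "observed": float(1.0 - _km_at(t[sel], e[sel], horizon)),
                "n": int(sel.sum()),
            }
        )
    return brier, intercept, slope, slope_defined, pd.DataFrame(rows)


def calibration_at(pred_risk, time, event, horizon, n_bins: int = 5,
                   n_bootstrap: int = 0, seed: int = 0) -> CalibrationResult:
    """Calibration of predicted event risks at a fixed horizon.

    Reports the IPCW Brier score, calibration intercept (log observed/expected
    events), calibration slope (Cox coefficient on the complementary-log-log
    of predicted survival; 1 when perfectly calibrated) and a quantile-binned
    predicted-vs-observed curve. ``n_bootstrap`` > 0 adds percentile CIs.
    """
    p = np.asarray(pred_risk, dtype=float)
    t, e = _check_surv(time, event)
    if np.any((p <= 0) | (p >= 1)):
        raise InvalidInputError("predicted risks must lie strictly in (0,1)")
    brier, intercept, slope, slope_defined, curve = _calibration_core(p, t, e, horizon, n_bins)
    if not slope_defined:
        warnings.warn("degenerate (constant) predictions: calibration slope undefined",
                      stacklevel=2)
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA11)))
        draws = {"brier": [], "intercept": [], "slope": []}
        attempts = 0
        while len(draws["brier"]) < n_bootstrap and attempts < n_bootstrap * 10:
            attempts += 1
            idx = rng.integers(0, p.size, size=p.size)
            if np.all(e[idx] == 0):
                continue
            try:
                b, i, s, ok, _ = _calibration_core(p[idx], t[idx], e[idx], horizon, n_bins)
            except (InvalidInputError, ValueError):
                continue
            draws["brier"].append(b)
            draws["intercept"].append(i)
            if ok and np.isfinite(s):
                draws["slope"].append(s)
        ci = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in draws.items()
            if v
        }
    return CalibrationResult(brier=brier, intercept=intercept, slope=slope,
                             curve=curve, slope_defined=slope_defined, ci=ci)


def decision_curve(pred_risk, time, event, horizon, thresholds) -> pd.DataFrame:
    """Net benefit of risk-threshold policies for survival data.

    NB(pt) = TP/n - FP/n * pt/(1-pt), with event status among test-positives
    estimated by the subset Kaplan-Meier at the horizon. Includes treat-all
    and treat-none comparators.
    """
    p = np.asarray(pred_risk, dtype=float)
    t, e = _check_surv(time, event)
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0:
        raise InvalidInputError("threshold grid must be non-empty")
    if np.any((thr <= 0) | (thr >= 1)):
        raise InvalidInputError("thresholds must lie strictly in (0,1)")
    n = p.size
    risk_all = 1.0 - _km_at(t, e, horizon)
    rows = []
    for pt in thr:
        odds = pt / (1.0 - pt)
        pos = p >= pt
        if pos.any():
            s_pos = _km_at(t[pos], e[pos], horizon)
            tp = (1.0 - s_pos) * pos.sum() / n
            fp = s_pos * pos.sum() / n
            nb = tp - fp * odds
        else:
            nb = 0.0
        nb_all = risk_all - (1.0 - risk_all) * odds
        rows.append({"threshold": float(pt), "nb_model": float(nb),
                     "nb_all": float(nb_all), "nb_none": 0.0})
    return pd.DataFrame(rows)


def compare_marker_across_groups(values, labels) -> dict:
    """Kruskal-Wallis comparison of a continuous marker across >=2 groups."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(labels)
    groups = [v[g == lev] for lev in pd.unique(g)]
    if len(groups) < 2 or any(len(x) == 0 for x in groups):
        raise InvalidInputError("need >=2 non-empty groups")
    stat, p = stats.kruskal(*groups)
    return {"test": "kruskal_wallis", "statistic": float(stat), "p": float(p),
            "n_groups": len(groups)}


def _fisher_mc_p(table: np.ndarray, n_draws: int, seed: int) -> float:
    """Monte-Carlo Fisher p for an r x c table with fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)

    def logp(tab):
        tab = np.asarray(tab)
        return (
            gammaln(rows + 1).sum()
            + gammaln(cols + 1).sum()
            - gammaln(tab.sum() + 1)
            - gammaln(tab + 1).sum()
        )

    lp_obs = logp(table)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    draws = sampler.rvs(n_draws, random_state=rng)
    lps = np.array([logp(d) for d in draws])
    return float((1 + np.sum(lps <= lp_obs + 1e-9)) / (1 + n_draws))


def compare_groups(df: pd.DataFrame, group: np.ndarray, categorical=(),
                   alpha: float = 0.05, mc_draws: int = 100_000, seed: int = 0
                   ) -> pd.DataFrame:
    """Per-variable two-group comparison battery.

    Continuous variables: Shapiro-Wilk on each group at ``alpha``; if both
    pass, a two-sided t-test, otherwise a two-sided Mann-Whitney U.
    Categorical variables: Fisher's exact test (2x2 exact; larger tables by
    seeded Monte-Carlo with ``mc_draws`` samples). Descriptives are mean+-SD
    for normal variables and median (IQR) otherwise.
    """
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise InvalidInputError("compare_groups expects exactly two groups")
    a_mask, b_mask = g == levels[0], g == levels[1]
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        raise InvalidInputError("both groups must be non-empty")
    categorical = set(categorical)
    rows = []
    for col in df.columns:
        x = df[col].values
        if col in categorical or df[col].dtype == object or df[col].dtype.name == "category":
            tab = pd.crosstab(pd.Series(g, name="group"), pd.Series(x, name=col)).values
            if tab.shape == (2, 2):
                _, p = stats.fisher_exact(tab, alternative="two-sided")
                test = "fisher_exact"
            else:
                p = _fisher_mc_p(tab, mc_draws, seed)
                test = "fisher_mc"
            desc = " / ".join(str(v) for v in pd.Series(x).value_counts().index[:4])
            rows.append({"variable": col, "test": test, "p": float(p), "descriptive": desc})
            continue
        xa = np.asarray(x[a_mask], dtype=float)
        xb = np.asarray(x[b_mask], dtype=float)
        if min(xa.size, xb.size) < 3:
            raise InvalidInputError(f"need >=3 observations per group for '{col}'")
        normal = (
            stats.shapiro(xa).pvalue > alpha
            and stats.shapiro(xb).pvalue > alpha
            and np.unique(xa).size > 1
            and np.unique(xb).size > 1
        )
        if normal:
            _, p = stats.ttest_ind(xa, xb)
            desc = (f"{xa.mean():.2f}+-{xa.std():.2f} vs "
                    f"{xb.mean():.2f}+-{xb.std():.2f}")
            test = "t_test"
        else:
            _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            qa = np.percentile(xa, [50, 25, 75])
            qb = np.percentile(xb, [50, 25, 75])
            desc = (f"{qa[0]:.2f} ({qa[1]:.2f},{qa[2]:.2f}) vs "
                    f"{qb[0]:.2f} ({qb[1]:.2f},{qb[2]:.2f})")
            test = "mann_whitney_u"
        rows.append({"variable": col, "test": test, "p": float(p), "descriptive": desc})
    return pd.DataFrame(rows).set_index("variable")
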