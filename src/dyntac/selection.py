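"""Stable feature selection and Cox modelling.

Pipeline: bootstrap resampling -> L1-penalized Cox path with cross-validated
1-SE lambda per resample -> selection frequencies -> multivariate Cox on the
stable set -> optimism-corrected concordance and proportional-hazards checks.

Features are z-scored inside every fit (and re-scored within each bootstrap
resample), so coefficients are per-SD and selection is invariant to affine
rescaling of any input column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import concordance_index
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .errors import ConvergenceError, DegenerateInputError, InvalidInputError

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "CoxModel",
    "cox_log_partial_likelihood",
    "lasso_cox_cv",
    "bootstrap_selection",
    "fit_cox",
    "optimism_corrected_cindex",
    "ph_test",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the bootstrap-LASSO-Cox procedure."""

    n_bootstrap: int = 1000
    cv_folds: int = 5
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-4  # four decades below the all-zero lambda
    stability_threshold: float = 0.50  # strict: stable means frequency > threshold
    seed: int = 0
    fold_retry_cap: int = 10
    coxnet_tol: float = 1e-5  # selection patterns are insensitive below this

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise InvalidInputError("n_bootstrap must be >= 1")
        if self.cv_folds < 2:
            raise InvalidInputError("cv_folds must be >= 2")
        if not 0 < self.stability_threshold < 1:
            raise InvalidInputError("stability_threshold must be in (0,1)")


@dataclass(frozen=True)
class SelectionResult:
    frequencies: pd.Series  # per-feature selection frequency in [0,1]
    threshold: float
    n_bootstrap: int

    @property
    def stable_features(self) -> list:
        return list(self.frequencies.index[self.frequencies > self.threshold])


def _as_arrays(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise InvalidInputError("time and event must be matching 1-D arrays")
    if np.any(t <= 0):
        raise InvalidInputError("survival times must be positive")
    return t, e


def cox_log_partial_likelihood(time, event, lp) -> float:
    """Breslow-ties Cox log partial likelihood for fixed linear predictors."""
    t, e = _as_arrays(time, event)
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(t, kind="stable")
    t, e, lp = t[order], e[order], lp[order]
    # risk set at time u = {i : t_i >= u}; iterate unique event times
    ll = 0.0
    exp_lp = np.exp(lp)
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        events = (t == u) & (e == 1)
        d = int(events.sum())
        ll += float(lp[events].sum()) - d * float(np.log(exp_lp[at_risk].sum()))
    return ll


def _breslow_loglik_matrix(time, event, LP: np.ndarray) -> np.ndarray:
    """Column-wise Breslow log partial likelihood for an (n, m) predictor matrix."""
    t, e = _as_arrays(time, event)
    order = np.argsort(t, kind="stable")
    t, e, LP = t[order], e[order], LP[order]
    exp_lp = np.exp(LP)
    ll = np.zeros(LP.shape[1])
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        events = (t == u) & (e == 1)
        d = int(events.sum())
        ll += LP[events].sum(axis=0) - d * np.log(exp_lp[at_risk].sum(axis=0))
    return ll


def _standardize(X: pd.DataFrame):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (X.loc[:, keep] - mu[keep]) / sd[keep]
    return Z, mu, sd, list(X.columns[~keep])


def _stratified_folds(event: np.ndarray, k: int, rng: np.random.Generator):
    """Event-stratified fold assignment; every fold gets events when possible."""
    idx_e = np.flatnonzero(event == 1)
    idx_c = np.flatnonzero(event == 0)
    rng.shuffle(idx_e)
    rng.shuffle(idx_c)
    folds = [[] for _ in range(k)]
    for j, i in enumerate(idx_e):
        folds[j % k].append(i)
    for j, i in enumerate(idx_c):
        folds[(k - 1 - j % k)].append(i)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def lasso_cox_cv(X: pd.DataFrame, time, event, config: SelectionConfig | None = None,
                 rng: np.random.Generator | None = None) -> list:
    """Feature subset selected by CV'd L1-penalized Cox with the 1-SE rule.

    Fits the full L1 path on standardized features, scores each penalty by
    held-out Breslow partial-likelihood deviance over event-stratified CV
    folds, picks the largest penalty within one standard error of the best,
    and returns the features with nonzero coefficients there.
    """
    cfg = config or SelectionConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t, e = _as_arrays(time, event)
    if e.sum() < 2:
        raise DegenerateInputError("need at least 2 events for penalized Cox selection")
    Z, _, _, dropped = _standardize(X)
    if Z.shape[1] == 0:
        return []
    y = Surv.from_arrays(event=e.astype(bool), time=t)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        n_alphas=cfg.lambda_grid_size,
        alpha_min_ratio=cfg.lambda_min_ratio,
        fit_baseline_model=False,
        tol=cfg.coxnet_tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Z.values, y)
    alphas = np.asarray(path.alphas_)

    folds = None
    for _ in range(cfg.fold_retry_cap):
        cand = _stratified_folds(e, cfg.cv_folds, rng)
        if all(e[f].sum() >= 1 and e[np.setdiff1d(np.arange(len(e)), f)].sum() >= 2
               for f in cand):
            folds = cand
            break
    if folds is None:
        raise DegenerateInputError("could not build CV folds with events in every fold")

    dev = np.full((cfg.cv_folds, alphas.size), np.nan)
    all_idx = np.arange(len(e))
    for k, test in enumerate(folds):
        train = np.setdiff1d(all_idx, test)
        Zt = Z.values[train]
        # re-standardize within the training fold
        mu = Zt.mean(axis=0)
        sd = Zt.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False,
                                   tol=cfg.coxnet_tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                m.fit((Zt - mu) / sd, Surv.from_arrays(e[train].astype(bool), t[train]))
            except Exception:
                continue
        fitted = np.asarray(m.alphas_)
        coefs = m.coef_  # (n_features, n_fitted)
        Ztest = (Z.values[test] - mu) / sd
        lps = Ztest @ coefs
        fold_dev = -2.0 * _breslow_loglik_matrix(t[test], e[test], lps)
        # map back onto the requested grid (coxnet may truncate the path)
        pos = {round(float(a), 12): j for j, a in enumerate(fitted)}
        for j, a in enumerate(alphas):
            jj = pos.get(round(float(a), 12))
            if jj is not None:
                dev[k, j] = fold_dev[jj]

    fold_ok = ~np.all(np.isnan(dev), axis=1)
    if not fold_ok.any():
        raise ConvergenceError("no CV fold produced a penalized fit")
    dev = dev[fold_ok]
    # only penalties scored by every surviving fold are comparable
    valid = ~np.any(np.isnan(dev), axis=0)
    if not valid.any():
        raise ConvergenceError("no penalty value could be cross-validated")
    mean = dev[:, valid].mean(axis=0)
    k_eff = dev.shape[0]
    se = dev[:, valid].std(axis=0, ddof=1) / np.sqrt(k_eff) if k_eff > 1 else np.zeros_like(mean)
    a_valid = alphas[valid]
    i_min = int(np.argmin(mean))
    limit = mean[i_min] + se[i_min]
    # alphas are in decreasing order: the first qualifying index is the
    # largest (most parsimonious) penalty within one SE of the minimum
    i_sel = int(np.flatnonzero(mean <= limit)[0])
    coef = path.coef_[:, int(np.argmin(np.abs(alphas - a_valid[i_sel])))]
    return [c for c, b in zip(Z.columns, np.abs(coef) > 1e-12) if b]


def bootstrap_selection(X: pd.DataFrame, time, event,
                        config: SelectionConfig | None = None) -> SelectionResult:
    """Selection frequencies over bootstrap resamples of the patients."""
    cfg = config or SelectionConfig()
    t, e = _as_arrays(time, event)
    n = len(t)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB007)))
    counts = pd.Series(0.0, index=X.columns)
    done = 0
    attempts = 0
    max_attempts = cfg.n_bootstrap * 20
    while done < cfg.n_bootstrap:
        attempts += 1
        if attempts > max_attempts:
            raise ConvergenceError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        if e[idx].sum() < max(2, cfg.cv_folds):
            continue
        try:
            sel = lasso_cox_cv(X.iloc[idx].reset_index(drop=True), t[idx], e[idx],
                               cfg, rng=rng)
        except (DegenerateInputError, ConvergenceError):
            continue
        for name in sel:
            counts[name] += 1.0
        done += 1
    freq = counts / cfg.n_bootstrap
    return SelectionResult(frequencies=freq, threshold=cfg.stability_threshold,
                           n_bootstrap=cfg.n_bootstrap)


@dataclass(frozen=True)
class CoxModel:
    """Fitted multivariate Cox model on z-scored covariates."""

    fitter: CoxPHFitter
    feature_names: list
    means: pd.Series
    sds: pd.Series
    summary: pd.DataFrame  # coef, hr, CIs, p per covariate
    llr_stat: float
    llr_p: float
    c_apparent: float
    train_frame: pd.DataFrame = field(repr=False, default=None)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.feature_names] - self.means) / self.sds

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.transform(X)
        return Z.values @ self.fitter.params_.values

    def predicted_event_risk(self, X: pd.DataFrame, horizon_days: float) -> np.ndarray:
        """1 - S(horizon | x) with a Breslow baseline."""
        Z = self.transform(X)
        sf = self.fitter.predict_survival_function(Z, times=[horizon_days])
        return 1.0 - sf.iloc[0].values


def fit_cox(X: pd.DataFrame, time, event) -> CoxModel:
    """Multivariate Cox PH fit (Efron ties) on standardized covariates."""
    if X.shape[1] == 0:
        raise InvalidInputError("feature subset must be non-empty")
    t, e = _as_arrays(time, event)
    if e.sum() < X.shape[1]:
        warnings.warn(
            f"only {int(e.sum())} events for {X.shape[1]} covariates; "
            "estimates may be unstable",
            stacklevel=2,
        )
    Z, mu, sd, dropped = _standardize(X)
    if dropped:
        raise DegenerateInputError(f"constant covariates cannot enter a Cox model: {dropped}")
    df = Z.copy()
    df["time"] = t
    df["event"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/Warning variants
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "coef_lo95": summ["coef lower 95%"],
            "coef_hi95": summ["coef upper 95%"],
            "hr_lo95": np.exp(summ["coef lower 95%"]),
            "hr_hi95": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    lrt = cph.log_likelihood_ratio_test()
    c_app = concordance_index(t, -cph.predict_partial_hazard(Z).values, e)
    return CoxModel(
        fitter=cph,
        feature_names=list(Z.columns),
        means=mu[Z.columns],
        sds=sd[Z.columns],
        summary=out,
        llr_stat=float(lrt.test_statistic),
        llr_p=float(lrt.p_value),
        c_apparent=float(c_app),
        train_frame=df,
    )


def optimism_corrected_cindex(X: pd.DataFrame, time, event, n_bootstrap: int = 1000,
                              seed: int = 0):
    """Harrell's bootstrap optimism correction of the concordance index.

    Returns (apparent, corrected, (ci_lo, ci_hi)); the CI is the percentile
    interval of apparent-minus-optimism over resamples.
    """
    if n_bootstrap < 1:
        raise InvalidInputError("n_bootstrap must be >= 1")
    t, e = _as_arrays(time, event)
    base = fit_cox(X, t, e)
    apparent = base.c_apparent
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC1DE)))
    n = len(t)
    optimisms = []
    attempts = 0
    while len(optimisms) < n_bootstrap and attempts < n_bootstrap * 10:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        if e[idx].sum() < 2 or any(X.iloc[idx][c].nunique() < 2 for c in X.columns):
            continue
        try:
            m = fit_cox(X.iloc[idx].reset_index(drop=True), t[idx], e[idx])
        except (ConvergenceError, DegenerateInputError):
            continue
        c_boot = m.c_apparent
        c_orig = concordance_index(t, -m.linear_predictor(X), e)
        optimisms.append(c_boot - c_orig)
    if not optimisms:
        raise ConvergenceError("no bootstrap resample produced a usable fit")
    optimisms = np.asarray(optimisms)
    corrected = apparent - float(np.mean(optimisms))
    draws = apparent - optimisms
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return apparent, corrected, ci


def ph_test(model: CoxModel) -> pd.DataFrame:
    """Schoenfeld-residual proportional-hazards tests.

    Per-covariate score tests (rank-transformed time) plus a global test
    combining all covariates through the averaged risk-set covariance; the
    global row is labelled ``GLOBAL``.
    """
    if not model.feature_names:
        raise InvalidInputError("model has no covariates to test")
    df = model.train_frame
    res = proportional_hazard_test(model.fitter, df, time_transform="rank")
    rows = {}
    for name in model.feature_names:
        stat = res.summary.loc[(name, "rank"), "test_statistic"] if isinstance(
            res.summary.index, pd.MultiIndex
        ) else res.summary.loc[name, "test_statistic"]
        p = res.summary.loc[(name, "rank"), "p"] if isinstance(
            res.summary.index, pd.MultiIndex
        ) else res.summary.loc[name, "p"]
        rows[name] = {"stat": float(stat), "p": float(p), "df": 1}

    # global test: T = u' D^{-1} u with u = S'(g - gbar) and
    # D = sum((g - gbar)^2) * S'S / d  (averaged risk-set covariance)
    res_df = model.fitter.compute_residuals(df, kind="schoenfeld")
    ev = df.loc[res_df.index]
    order = np.argsort(ev["time"].values, kind="stable")
    S = res_df[model.feature_names].values[order]
    d = S.shape[0]
    g = pd.Series(np.sort(ev["time"].values)).rank().values  # rank transform of event times
    g = g - g.mean()
    u = S.T @ g
    D = float(np.sum(g**2)) * (S.T @ S) / d
    from scipy import linalg, stats

    try:
        stat = float(u @ linalg.solve(D, u, assume_a="pos"))
    except linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(D) @ u)
    p = float(stats.chi2.sf(stat, df=len(model.feature_names)))
    rows["GLOBAL"] = {"stat": stat, "p": p, "df": len(model.feature_names)}
    return pd.DataFrame(rows).T
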