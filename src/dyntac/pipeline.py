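"""End-to-end orchestration: simulate -> fit -> features -> select -> stratify -> evaluate.

Every stochastic stage draws from a named substream of one global seed, so a
config (and its manifest hash) reproduces a report exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .curves import FrameSchedule, TacCurve
from .errors import DynTacError, InvalidInputError
from .features import (
    CONVENTIONAL_FEATURE_NAMES,
    KINETIC_FEATURE_NAMES,
    conventional_features,
    extract_feature_vector,
)
from .kinetics import FitOptions, decompose, fit_2tc
from .selection import (
    SelectionConfig,
    bootstrap_selection,
    fit_cox,
    optimism_corrected_cindex,
    ph_test,
)
from .stratify_eval import (
    MONTH_DAYS,
    calibration_at,
    decision_curve,
    optimal_logrank_cutoff,
    td_auc,
)
from .synthetic_cohort import Cohort, CohortSpec, calibrate_baseline_hazard, gen_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "fit_cohort", "feature_matrix"]

CLINICAL_COVARIATES = ("age", "sex", "smoking")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fit_options: FitOptions = field(default_factory=FitOptions)
    horizons_months: tuple = (12.0, 18.0, 24.0)
    calibrate_event_fraction: float | None = 17.0 / 32.0
    include_clinical: bool = True
    include_conventional: bool = True
    dca_thresholds: tuple = tuple(np.round(np.linspace(0.05, 0.90, 18), 4))
    n_bootstrap_cindex: int = 200
    n_bootstrap_auc_ci: int = 0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.horizons_months, dtype=float)
        if h.size == 0 or np.any(h <= 0) or not np.all(np.diff(h) > 0):
            raise InvalidInputError("horizons must be positive and increasing")


@dataclass
class PipelineResult:
    cohort: Cohort
    fits: dict  # patient_id -> {roi: FitResult}
    features: pd.DataFrame
    selection: object
    cox_model: object
    report: dict


class StageError(DynTacError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def fit_cohort(cohort: Cohort, options: FitOptions | None = None) -> dict:
    """Fit the 2TC model for both ROIs of every patient."""
    opts = options or FitOptions()
    sched = cohort.spec.schedule
    fits = {}
    for p in cohort.patients:
        per_roi = {}
        for roi, curve in p.measured.items():
            per_roi[roi] = fit_2tc(curve, p.input_function, sched, opts)
        fits[p.patient_id] = per_roi
    return fits


def feature_matrix(cohort: Cohort, fits: dict, include_clinical=True,
                   include_conventional=True) -> pd.DataFrame:
    """Per-patient feature table: 28 kinetic + 8 conventional + clinical."""
    rows = {}
    for p in cohort.patients:
        comp = {}
        for roi, fit in fits[p.patient_id].items():
            cb, cf, cm = decompose(fit)
            comp[roi] = {"Cf": cf, "Cb": cb, "Cm": cm}
        vec = extract_feature_vector(comp)
        if include_conventional:
            conv = conventional_features(p.voxels["tumor"], p.voxels["bone_marrow"],
                                         voxel_volume_ml=1.0)
            vec = pd.concat([vec, conv])
        if include_clinical:
            vec = pd.concat([vec, pd.Series({c: p.survival.covariates[c]
                                             for c in CLINICAL_COVARIATES})])
        rows[p.patient_id] = vec
    return pd.DataFrame(rows).T


def _evaluate_marker(marker: pd.Series, surv: pd.DataFrame, config: PipelineConfig) -> dict:
    """Stratify on one marker and evaluate the single-feature model."""
    t = surv["pfs_days"].values
    e = surv["event"].values
    strat = optimal_logrank_cutoff(marker.values, t, e)
    uni = fit_cox(marker.to_frame(), t, e)
    lp = uni.linear_predictor(marker.to_frame())
    horizon12 = config.horizons_months[0] * MONTH_DAYS
    risk12 = np.clip(uni.predicted_event_risk(marker.to_frame(), horizon12), 1e-6, 1 - 1e-6)
    aucs = {}
    for h_m in config.horizons_months:
        h_d = h_m * MONTH_DAYS
        try:
            res = td_auc(lp, t, e, h_d, n_bootstrap_ci=config.n_bootstrap_auc_ci,
                         seed=config.seed)
            aucs[f"{h_m:g}m"] = {"auc": res.auc, "ci": res.ci}
        except InvalidInputError as exc:
            aucs[f"{h_m:g}m"] = {"auc": None, "error": str(exc)}
    cal = calibration_at(risk12, t, e, horizon12, n_bootstrap=0)
    dca = decision_curve(risk12, t, e, horizon12, config.dca_thresholds)
    return {
        "marker": marker.name,
        "cutoff": strat.cutoff,
        "logrank_stat": strat.statistic,
        "logrank_p": strat.p_value,
        "low_marker_is_high_risk": strat.low_marker_is_high_risk,
        "td_auc": aucs,
        "calibration": {"brier": cal.brier, "intercept": cal.intercept,
                        "slope": cal.slope, "curve": cal.curve},
        "decision_curve": dca,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a synthetic cohort and assemble the report."""
    stage = "simulate"
    try:
        spec = config.cohort
        if config.seed != spec.seed:
            spec = replace(spec, seed=config.seed)
        if config.calibrate_event_fraction is not None:
            spec = calibrate_baseline_hazard(spec, config.calibrate_event_fraction)
        cohort = gen_cohort(spec, out_dir=config.out_dir)

        stage = "fit"
        fits = fit_cohort(cohort, config.fit_options)

        stage = "features"
        feats = feature_matrix(cohort, fits, config.include_clinical,
                               config.include_conventional)
        surv = cohort.survival_frame.set_index("patient_id").loc[feats.index]

        stage = "select"
        sel_cfg = replace(config.selection, seed=config.seed)
        sel = bootstrap_selection(feats, surv["pfs_days"].values, surv["event"].values,
                                  sel_cfg)
        stable = sel.stable_features
        if not stable:
            # fall back to the single most frequently selected feature
            stable = [sel.frequencies.idxmax()]

        stage = "model"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cox = fit_cox(feats[stable], surv["pfs_days"].values, surv["event"].values)
            ph = ph_test(cox)
            c_app, c_corr, c_ci = optimism_corrected_cindex(
                feats[stable], surv["pfs_days"].values, surv["event"].values,
                n_bootstrap=config.n_bootstrap_cindex, seed=config.seed,
            )

        stage = "stratify"
        # most robust feature = highest selection frequency among the stable set
        marker_name = sel.frequencies[stable].idxmax()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            evaluation = _evaluate_marker(feats[marker_name], surv.reset_index(), config)

        stage = "report"
        report = {
            "config_hash": _io.config_hash(_config_dict(config)),
            "seed": config.seed,
            "n_patients": len(cohort.patients),
            "n_events": int(surv["event"].sum()),
            "selection": {
                "frequencies": sel.frequencies.sort_values(ascending=False),
                "stable_features": stable,
                "threshold": sel.threshold,
                "n_bootstrap": sel.n_bootstrap,
            },
            "cox": {
                "summary": cox.summary,
                "llr_stat": cox.llr_stat,
                "llr_p": cox.llr_p,
                "c_apparent": c_app,
                "c_corrected": c_corr,
                "c_ci": list(c_ci),
                "ph_test": ph,
            },
            "evaluation": evaluation,
            "versions": _versions(),
        }
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            _io.write_feature_csv(out / "features.csv", feats)
            sel_df = sel.frequencies.rename("frequency").to_frame()
            sel_df["stable"] = sel_df.index.isin(stable)
            sel_df.to_csv(out / "selection.csv", index_label="feature")
            _io.write_json_report(out / "report.json", report)
            _io.write_json_report(out / "manifest.json", {
                "config": _config_dict(config),
                "config_hash": report["config_hash"],
                "versions": report["versions"],
            })
        return PipelineResult(cohort=cohort, fits=fits, features=feats, selection=sel,
                              cox_model=cox, report=report)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["cohort"]["aif"] = asdict(config.cohort.aif)
    d.pop("out_dir", None)  # paths do not affect results
    return d


def _versions() -> dict:
    import lifelines
    import scipy
    import sksurv

    from . import __version__

    return {
        "dyntac": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "scikit-survival": sksurv.__version__,
    }
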