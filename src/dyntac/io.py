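"""File dialects: TAC CSV, cohort CSV, feature CSV, JSON reports.

All files are UTF-8 CSV with a required header. TAC rows carry explicit
frame windows in seconds; blood (input-function) rows may use a finer frame
grid than tissue rows so the bolus peak survives the round trip.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import FrameSchedule, TacCurve, frame_average
from .errors import SchemaError

__all__ = [
    "TAC_COLUMNS",
    "read_tac_csv",
    "write_tac_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_cohort",
    "read_feature_csv",
    "write_feature_csv",
    "write_json_report",
    "config_hash",
]

TAC_COLUMNS = ["patient_id", "roi", "frame_start_s", "frame_end_s", "activity_kbq_per_ml"]
TAC_ROIS = {"tumor", "bone_marrow", "blood"}
COHORT_REQUIRED = ["patient_id", "pfs_days", "event"]

#: fine binning (seconds) used to serialize the blood input function
BLOOD_BIN_S = 2.0


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def write_tac_csv(path, patients) -> None:
    """Write tissue TACs (28-frame) and blood curves (fine bins) long-form.

    ``patients`` is an iterable of :class:`~dyntac.synthetic_cohort.PatientSim`
    or of ``(patient_id, {roi: TacCurve}, input_function, schedule)`` tuples.
    """
    rows = []
    for p in patients:
        pid, measured, aif = p.patient_id, p.measured, p.input_function
        sched = FrameSchedule.default_28()
        for roi, curve in measured.items():
            for s, e, v in zip(sched.starts_s, sched.ends_s, curve.values):
                rows.append((pid, roi, s, e, v))
        lo, hi = sched.span_minutes
        n_bins = int(round((hi - lo) * 60.0 / BLOOD_BIN_S))
        fine = FrameSchedule.from_durations([BLOOD_BIN_S] * n_bins, start_s=lo * 60.0)
        blood_vals = frame_average(aif, fine, n_sub=4)
        for s, e, v in zip(fine.starts_s, fine.ends_s, blood_vals):
            rows.append((pid, "blood", s, e, v))
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, index=False)


def read_tac_csv(path):
    """Parse a TAC CSV into ``{patient_id: {roi: (schedule, values)}}``.

    The blood entry is additionally exposed as a TacCurve at bin midpoints
    under the key ``blood_curve``.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAC_COLUMNS, path)
    bad_roi = ~df["roi"].isin(TAC_ROIS)
    if bad_roi.any():
        row = int(df.index[bad_roi][0]) + 2  # header is line 1
        raise SchemaError(f"{path}: line {row}: unknown roi '{df.loc[bad_roi, 'roi'].iloc[0]}'")
    for col in ("frame_start_s", "frame_end_s", "activity_kbq_per_ml"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2
            raise SchemaError(f"{path}: line {row}: non-numeric value in '{col}'")
        df[col] = vals
    out = {}
    for (pid, roi), grp in df.groupby(["patient_id", "roi"], sort=False):
        grp = grp.sort_values("frame_start_s")
        try:
            sched = FrameSchedule(grp["frame_start_s"].values, grp["frame_end_s"].values)
        except Exception as exc:
            raise SchemaError(f"{path}: invalid frame schedule for {pid}/{roi}: {exc}") from exc
        entry = out.setdefault(pid, {})
        entry[roi] = (sched, grp["activity_kbq_per_ml"].values)
        if roi == "blood":
            # pad to the exact bin edges so the curve covers the full scan span
            mids = sched.mid_minutes
            vals = grp["activity_kbq_per_ml"].values
            t_full = np.concatenate(([sched.starts_s[0] / 60.0], mids,
                                     [sched.ends_s[-1] / 60.0]))
            v_full = np.concatenate(([vals[0]], vals, [vals[-1]]))
            entry["blood_curve"] = TacCurve(t_full, v_full, "blood")
    return out


def write_cohort_csv(path, survival_frame: pd.DataFrame) -> None:
    cols = ["patient_id"] + [c for c in survival_frame.columns
                             if c not in ("patient_id", "pfs_days", "event")]
    cols += ["pfs_days", "event"]
    survival_frame[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_REQUIRED, path)
    ev = pd.to_numeric(df["event"], errors="coerce")
    if ev.isna().any() or not df["event"].isin([0, 1]).all():
        bad = int(df.index[~df["event"].isin([0, 1])][0]) + 2
        raise SchemaError(f"{path}: line {bad}: event must be 0 or 1")
    tt = pd.to_numeric(df["pfs_days"], errors="coerce")
    if tt.isna().any() or (tt <= 0).any():
        bad = int(df.index[tt.isna() | (tt <= 0)][0]) + 2
        raise SchemaError(f"{path}: line {bad}: pfs_days must be positive")
    return df


def write_feature_csv(path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=True, index_label="patient_id")


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id"], path)
    return df.set_index("patient_id")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(_jsonable(config_dict), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort's TAC/cohort CSVs plus a ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tac_csv(out / "tacs.csv", cohort.patients)
    write_cohort_csv(out / "cohort.csv", cohort.survival_frame)
    vox_rows = []
    for p in cohort.patients:
        for roi, arr in p.voxels.items():
            for j, v in enumerate(arr):
                vox_rows.append((p.patient_id, roi, j, v))
    pd.DataFrame(vox_rows, columns=["patient_id", "roi", "voxel_index", "suv"]).to_csv(
        out / "voxels.csv", index=False
    )
    truth = {
        "z_norm": {"mean": cohort.z_norm[0], "sd": cohort.z_norm[1]},
        "effect_size_log_hr_per_sd": cohort.spec.effect_size,
        "baseline_hazard_per_day": cohort.spec.baseline_hazard,
        "patients": cohort.truth_frame,
    }
    write_json_report(out / "truth.json", truth)
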