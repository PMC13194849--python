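"""TAC feature operators and conventional SUV-based metrics.

Fourteen kinetic features per ROI: six operators applied to the free (C_f)
and blood (C_b) component curves, and two (peak value and rise slope) to the
steadily growing metabolized curve (C_m). All slope features use the uniform
(later - earlier) / elapsed-time convention, so a declining curve yields a
negative slope. Feature names and their ordering are a frozen contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import TacCurve, tac_value_at
from .errors import InvalidInputError, OutOfRangeError

__all__ = [
    "roi_mean_tac",
    "slope_between",
    "auc_t",
    "peak_features",
    "component_features",
    "extract_feature_vector",
    "conventional_features",
    "KINETIC_FEATURE_NAMES",
    "CONVENTIONAL_FEATURE_NAMES",
]

_ROI_PREFIX = {"tumor": "T", "bone_marrow": "BM"}
_FULL_FEATURES = ("Slope_10_30", "AUC_T", "Slope_0_max", "Slope_max_60", "Time_TM", "TAC_max")
_CM_FEATURES = ("Slope_0_max", "TAC_max")

#: canonical ordering of the 28 kinetic features (14 per ROI: 6 C_f, 6 C_b, 2 C_m)
KINETIC_FEATURE_NAMES = tuple(
    f"{_ROI_PREFIX[roi]}_{comp}_{feat}"
    for roi in ("tumor", "bone_marrow")
    for comp, feats in (("Cf", _FULL_FEATURES), ("Cb", _FULL_FEATURES), ("Cm", _CM_FEATURES))
    for feat in feats
)

CONVENTIONAL_FEATURE_NAMES = (
    "T_SUVmax",
    "T_SUVmean",
    "T_SUVmin",
    "BM_SUVmax",
    "BM_SUVmean",
    "BM_SUVmin",
    "MTV",
    "TLG",
)


def roi_mean_tac(voxel_tacs) -> TacCurve:
    """Per-frame arithmetic mean over a set of voxel TACs on a shared grid."""
    curves = list(voxel_tacs)
    if not curves:
        raise InvalidInputError("need at least one voxel TAC")
    t0 = curves[0].times
    for c in curves[1:]:
        if c.times.shape != t0.shape or not np.array_equal(c.times, t0):
            raise InvalidInputError("voxel TACs must share an identical time grid")
    mean = np.mean([c.values for c in curves], axis=0)
    return TacCurve(t0, mean, "measured")


def slope_between(curve: TacCurve, t1: float = 10.0, t2: float = 30.0) -> float:
    """(TAC(t2) - TAC(t1)) / (t2 - t1): negative for a declining curve."""
    if not t2 > t1:
        raise InvalidInputError("t2 must be greater than t1")
    return (tac_value_at(curve, t2) - tac_value_at(curve, t1)) / (t2 - t1)


def auc_t(curve: TacCurve) -> float:
    """Trapezoidal area under the whole sampled curve (kBq/mL * min)."""
    return float(np.trapezoid(curve.values, curve.times))


def peak_features(curve: TacCurve, end_anchor: float = 60.0) -> dict:
    """Peak value/time and the rise / washout slopes around the peak.

    Returns ``TAC_max``, ``Time_TM`` (earliest time attaining the max),
    ``Slope_0_max`` (0 when the peak is at the first sample) and
    ``Slope_max_60`` (0 when the peak is at or past the end anchor).
    """
    i_max = int(np.argmax(curve.values))
    tac_max = float(curve.values[i_max])
    time_tm = float(curve.times[i_max])
    t0 = curve.t_min
    if time_tm > t0:
        slope_rise = (tac_max - float(curve.values[0])) / (time_tm - t0)
    else:
        slope_rise = 0.0
    if time_tm < end_anchor:
        if curve.t_max < end_anchor:
            raise OutOfRangeError(
                f"curve ends at {curve.t_max} min; cannot evaluate the peak-to-"
                f"{end_anchor:g} min slope"
            )
        slope_fall = (tac_value_at(curve, end_anchor) - tac_max) / (end_anchor - time_tm)
    else:
        slope_fall = 0.0
    return {
        "TAC_max": tac_max,
        "Time_TM": time_tm,
        "Slope_0_max": slope_rise,
        "Slope_max_60": slope_fall,
    }


def component_features(curve: TacCurve, full: bool = True) -> dict:
    """The six (or, for C_m, two) feature operators applied to one curve."""
    pf = peak_features(curve)
    if not full:
        return {"Slope_0_max": pf["Slope_0_max"], "TAC_max": pf["TAC_max"]}
    return {
        "Slope_10_30": slope_between(curve, 10.0, 30.0),
        "AUC_T": auc_t(curve),
        "Slope_0_max": pf["Slope_0_max"],
        "Slope_max_60": pf["Slope_max_60"],
        "Time_TM": pf["Time_TM"],
        "TAC_max": pf["TAC_max"],
    }


def extract_feature_vector(components: dict) -> "pd.Series":
    """Assemble the 28 kinetic features from decomposed ROI components.

    Parameters
    ----------
    components : dict
        ``{roi: {"Cf": TacCurve, "Cb": TacCurve, "Cm": TacCurve}}`` for
        ``roi`` in ``{"tumor", "bone_marrow"}``.

    Returns
    -------
    pandas.Series indexed by :data:`KINETIC_FEATURE_NAMES`.
    """
    out = {}
    for roi in ("tumor", "bone_marrow"):
        if roi not in components:
            raise InvalidInputError(f"missing ROI '{roi}'")
        for comp in ("Cf", "Cb", "Cm"):
            if comp not in components[roi]:
                raise InvalidInputError(f"missing component '{comp}' for ROI '{roi}'")
            feats = component_features(components[roi][comp], full=comp != "Cm")
            for name, val in feats.items():
                out[f"{_ROI_PREFIX[roi]}_{comp}_{name}"] = float(val)
    s = pd.Series(out).reindex(list(KINETIC_FEATURE_NAMES))
    if s.isna().any():
        raise InvalidInputError("feature assembly produced missing values")
    return s


def conventional_features(
    tumor_suv,
    marrow_suv,
    voxel_volume_ml: float,
    threshold: float = 2.5,
) -> "pd.Series":
    """SUV statistics plus MTV/TLG from voxel-level SUV arrays.

    MTV is the total volume of tumor voxels with SUV >= threshold; TLG is
    MTV times the mean SUV of those supra-threshold voxels.
    """
    t = np.asarray(tumor_suv, dtype=float)
    m = np.asarray(marrow_suv, dtype=float)
    if t.size == 0 or m.size == 0:
        raise InvalidInputError("SUV arrays must be non-empty")
    if voxel_volume_ml <= 0:
        raise InvalidInputError("voxel volume must be > 0")
    above = t >= threshold
    mtv = float(above.sum() * voxel_volume_ml)
    tlg = float(mtv * t[above].mean()) if above.any() else 0.0
    vals = {
        "T_SUVmax": float(t.max()),
        "T_SUVmean": float(t.mean()),
        "T_SUVmin": float(t.min()),
        "BM_SUVmax": float(m.max()),
        "BM_SUVmean": float(m.mean()),
        "BM_SUVmin": float(m.min()),
        "MTV": mtv,
        "TLG": tlg,
    }
    return pd.Series(vals).reindex(list(CONVENTIONAL_FEATURE_NAMES))
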