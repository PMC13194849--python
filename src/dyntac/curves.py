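"""Time-activity curves and dynamic frame schedules.

Times are minutes from the start of the dynamic acquisition unless a name
says otherwise (frame schedules are specified in seconds, as acquisition
protocols print them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, OutOfRangeError

__all__ = ["TacCurve", "FrameSchedule", "frame_average", "tac_value_at"]

#: component labels a curve may carry
COMPONENT_LABELS = ("measured", "blood", "free", "metabolized", "model")


@dataclass(frozen=True)
class TacCurve:
    """Sampled activity curve for one ROI / model component.

    Parameters
    ----------
    times : array-like
        Sample times in minutes, strictly increasing.
    values : array-like
        Activity concentration in kBq/mL at each sample time.
    label : str
        One of ``measured``, ``blood``, ``free``, ``metabolized``, ``model``.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = "measured"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise InvalidInputError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise InvalidInputError("a TacCurve needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise InvalidInputError("times and values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def t_min(self) -> float:
        return float(self.times[0])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        """Linear interpolation inside the support (see :func:`tac_value_at`)."""
        return tac_value_at(self, t)

    def with_label(self, label: str) -> "TacCurve":
        return TacCurve(self.times, self.values, label)


def tac_value_at(curve: TacCurve, t):
    """Evaluate ``curve`` at time(s) ``t`` (minutes) by linear interpolation.

    Exact at sample points; raises :class:`OutOfRangeError` outside the
    sampled support (no extrapolation).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < curve.t_min) or np.any(t_arr > curve.t_max):
        raise OutOfRangeError(
            f"query time outside curve support [{curve.t_min}, {curve.t_max}] min"
        )
    out = np.interp(t_arr, curve.times, curve.values)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# default 28-frame dynamic schedule: 6x10 s, 4x30 s, 4x60 s, 4x120 s, 10x300 s
_DEFAULT_FRAME_DURATIONS_S = (6 * (10,) + 4 * (30,) + 4 * (60,) + 4 * (120,) + 10 * (300,))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-frame timing.

    ``starts_s``/``ends_s`` are seconds from scan start; frames must be
    contiguous, non-overlapping and strictly increasing.
    """

    starts_s: np.ndarray
    ends_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = np.asarray(self.starts_s, dtype=float)
        e = np.asarray(self.ends_s, dtype=float)
        if s.ndim != 1 or e.ndim != 1 or s.shape != e.shape or s.size == 0:
            raise InvalidInputError("starts_s and ends_s must be matching 1-D arrays")
        if not np.all(e > s):
            raise InvalidInputError("every frame must have end > start")
        if not np.allclose(s[1:], e[:-1]):
            raise InvalidInputError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "starts_s", s)
        object.__setattr__(self, "ends_s", e)

    @classmethod
    def from_durations(cls, durations_s, start_s: float = 0.0) -> "FrameSchedule":
        d = np.asarray(durations_s, dtype=float)
        edges = start_s + np.concatenate(([0.0], np.cumsum(d)))
        return cls(edges[:-1], edges[1:])

    @classmethod
    def default_28(cls) -> "FrameSchedule":
        """The 65-min, 28-frame acquisition schedule (3900 s total)."""
        return cls.from_durations(_DEFAULT_FRAME_DURATIONS_S)

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_minutes(self) -> np.ndarray:
        return (self.starts_s + self.ends_s) / 2.0 / 60.0

    @property
    def span_minutes(self) -> tuple[float, float]:
        return float(self.starts_s[0] / 60.0), float(self.ends_s[-1] / 60.0)


def frame_average(curve: TacCurve, schedule: FrameSchedule, n_sub: int = 16) -> np.ndarray:
    """Average ``curve`` over each frame of ``schedule``.

    The frame value is the time integral of the (piecewise-linear) curve over
    the frame divided by the frame duration, computed by trapezoid on a
    sub-grid that includes the curve's own sample points, so the result is
    exact for piecewise-linear curves whose knots are curve samples.
    """
    lo, hi = schedule.span_minutes
    if lo < curve.t_min - 1e-9 or hi > curve.t_max + 1e-9:
        raise InvalidInputError(
            f"schedule span [{lo}, {hi}] min outside curve support "
            f"[{curve.t_min}, {curve.t_max}] min"
        )
    out = np.empty(schedule.n_frames)
    for i in range(schedule.n_frames):
        a = schedule.starts_s[i] / 60.0
        b = schedule.ends_s[i] / 60.0
        inner = curve.times[(curve.times > a) & (curve.times < b)]
        grid = np.union1d(np.linspace(a, b, n_sub + 1), inner)
        vals = np.interp(grid, curve.times, curve.values)
        out[i] = np.trapezoid(vals, grid) / (b - a)
    return out
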