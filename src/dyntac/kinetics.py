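"""Two-tissue-compartment (2TC) FDG kinetics: forward model, fitting, decomposition.

The tissue model is the irreversible-plus-dephosphorylation FDG system

    dC_f/dt = K1*C_b(t) - (k2 + k3)*C_f + k4*C_m
    dC_m/dt = k3*C_f - k4*C_m

with zero initial conditions, and the measured signal

    C_T(t) = (1 - v_b) * (C_f(t) + C_m(t)) + v_b * C_b(t).

The linear system is solved exactly for a piecewise-linear input function by
an exponential integrator (per-step matrix exponential reduced, via
eigen-decomposition, to two scalar exponential convolutions evaluated with a
first-order recursive filter). This is the package's primary route; tests
check it against independent numerical-convolution and ODE oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .curves import FrameSchedule, TacCurve, frame_average, tac_value_at
from .errors import ConvergenceError, DegenerateInputError, InvalidInputError

__all__ = [
    "KineticParams",
    "FitOptions",
    "FitResult",
    "model_curves",
    "fit_2tc",
    "decompose",
    "FrameSchedule",
    "TacCurve",
    "frame_average",
]

# physiologic FDG bounds used by the fitter (per-minute rates, unitless v_b)
DEFAULT_BOUNDS = {
    "K1": (0.0, 2.0),
    "k2": (0.0, 2.0),
    "k3": (0.0, 1.0),
    "k4": (0.0, 0.05),
    "v_b": (0.0, 0.3),
}


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the 2TC model.

    K1 is in mL/min/mL; k2, k3, k4 in 1/min; v_b is the unitless blood
    volume fraction.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    v_b: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if not 0.0 <= self.v_b < 1.0:
            raise InvalidInputError("v_b must be in [0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.v_b])


def _exp_conv_uniform(a: float, u: np.ndarray, h: float) -> np.ndarray:
    """Exact (exp(-a t) * u)(t) on a uniform grid, u piecewise linear."""
    if a > 0:
        E = np.exp(-a * h)
        F0 = (1.0 - E) / a
        F1 = (h - F0) / a
    else:
        E, F0, F1 = 1.0, h, h * h / 2.0
    du = np.diff(u)
    c = F0 * u[:-1] + (F1 / h) * du
    y = np.empty_like(u)
    y[0] = 0.0
    y[1:] = lfilter([1.0], [1.0, -E], c)
    return y


def _exp_conv_nonuniform(a: float, u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """As :func:`_exp_conv_uniform` but stepwise for an arbitrary grid."""
    hs = np.diff(t)
    y = np.zeros_like(u)
    for n, h in enumerate(hs):
        if a > 0:
            E = np.exp(-a * h)
            F0 = (1.0 - E) / a
            F1 = (h - F0) / a
        else:
            E, F0, F1 = 1.0, h, h * h / 2.0
        y[n + 1] = E * y[n] + F0 * u[n] + (F1 / h) * (u[n + 1] - u[n])
    return y


def _solve_components(p: KineticParams, t: np.ndarray, cb: np.ndarray):
    """C_f and C_m on grid ``t`` for piecewise-linear input samples ``cb``."""
    K1, k2, k3, k4 = p.K1, p.k2, p.k3, p.k4
    hs = np.diff(t)
    uniform = np.allclose(hs, hs[0], rtol=1e-9, atol=1e-12)

    def conv(a):
        if uniform:
            return _exp_conv_uniform(a, cb, float(hs[0]))
        return _exp_conv_nonuniform(a, cb, t)

    if K1 == 0.0:
        z = np.zeros_like(cb)
        return z, z.copy()
    if k3 < 1e-8:
        # metabolized pool stays empty; free pool is a single-exponential system
        cf = K1 * conv(k2)
        return cf, np.zeros_like(cb)
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4  # always >= k3^2 > 0 here
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    e1 = conv(a1)
    e2 = conv(a2)
    d = (e1 - e2) / (a2 - a1)
    cf = K1 * (e2 + (k4 - a1) * d)
    cm = K1 * k3 * d
    return cf, cm


def model_curves(p: KineticParams, input_curve: TacCurve, times=None):
    """Forward-simulate the 2TC model driven by a sampled input function.

    Parameters
    ----------
    p : KineticParams
    input_curve : TacCurve
        Blood input C_b, treated as piecewise linear between its samples.
    times : array-like, optional
        Output sample times (minutes); must lie within the input support.
        Defaults to the input grid, on which the solution is exact.

    Returns
    -------
    (C_f, C_m, C_T) : tuple of TacCurve
        Free, metabolized and modelled total curves at ``times``.
    """
    t_in = input_curve.times
    if times is None:
        t_out = t_in
    else:
        t_out = np.asarray(times, dtype=float)
        if t_out.ndim != 1 or t_out.size < 2 or not np.all(np.diff(t_out) > 0):
            raise InvalidInputError("times must be a strictly increasing 1-D grid")
        if t_out[0] < t_in[0] - 1e-12 or t_out[-1] > t_in[-1] + 1e-12:
            raise InvalidInputError("requested times extend beyond the input grid")
    cf, cm = _solve_components(p, t_in, input_curve.values)
    if times is not None and not (
        t_out.size == t_in.size and np.allclose(t_out, t_in)
    ):
        cf = np.interp(t_out, t_in, cf)
        cm = np.interp(t_out, t_in, cm)
        cb = np.interp(t_out, t_in, input_curve.values)
    else:
        cb = input_curve.values
    ct = (1.0 - p.v_b) * (cf + cm) + p.v_b * cb
    return (
        TacCurve(t_out, cf, "free"),
        TacCurve(t_out, cm, "metabolized"),
        TacCurve(t_out, ct, "model"),
    )


def _frame_avg_matrix(grid: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Linear map node-values -> frame means, exact for piecewise-linear curves."""
    n = grid.size
    W = np.zeros((schedule.n_frames, n))
    for i in range(schedule.n_frames):
        a = schedule.starts_s[i] / 60.0
        b = schedule.ends_s[i] / 60.0
        j0 = int(np.searchsorted(grid, a, side="right"))
        j1 = int(np.searchsorted(grid, b, side="left"))
        # sub-grid a, grid[j0:j1], b with interpolated endpoint values
        pts = np.concatenate(([a], grid[j0:j1], [b]))
        w = np.zeros(pts.size)
        dp = np.diff(pts)
        w[:-1] += dp / 2.0
        w[1:] += dp / 2.0
        # endpoint values are linear combinations of bracketing nodes
        row = np.zeros(n)
        row[j0 : j1] += w[1:-1]
        for pt, wt in ((a, w[0]), (b, w[-1])):
            k = int(np.clip(np.searchsorted(grid, pt, side="right") - 1, 0, n - 2))
            t0, t1 = grid[k], grid[k + 1]
            lam = (pt - t0) / (t1 - t0)
            row[k] += wt * (1.0 - lam)
            row[k + 1] += wt * lam
        W[i] = row / (b - a)
    return W


@dataclass(frozen=True)
class FitOptions:
    """Controls for :func:`fit_2tc`."""

    fix_k4: bool = False
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_grid_starts: int = 8
    n_jitter_starts: int = 4
    seed: int = 0
    max_nfev: int = 200
    ftol: float = 1e-10
    xtol: float = 1e-10


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    components: dict  # label -> TacCurve at frame midpoints
    wrss: float
    converged: bool
    n_starts: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.wrss):
            raise InvalidInputError("WRSS must be finite")


_GRID_STARTS = [
    (K1, k2, k3)
    for K1 in (0.05, 0.4)
    for k2 in (0.1, 0.8)
    for k3 in (0.01, 0.15)
]


def fit_2tc(
    measured: TacCurve,
    input_curve: TacCurve,
    schedule: FrameSchedule,
    options: FitOptions | None = None,
) -> FitResult:
    """Weighted bounded nonlinear least-squares fit of the 2TC model.

    The model curve is frame-averaged before comparison with the measured
    per-frame values; residuals are weighted by sqrt(frame duration). A fixed
    coarse grid of starting points plus seeded jittered restarts guards
    against local minima; the lowest-WRSS solution wins (ties broken toward
    lower k4).
    """
    opts = options or FitOptions()
    y = np.asarray(measured.values, dtype=float)
    if y.size != schedule.n_frames:
        raise InvalidInputError(
            f"measured TAC has {y.size} values for a {schedule.n_frames}-frame schedule"
        )
    if np.max(y) <= 0 or np.mean(y) <= 0:
        raise DegenerateInputError("measured TAC is all-zero or negative-dominated")
    lo, hi = schedule.span_minutes
    if input_curve.t_min > lo + 1e-9 or input_curve.t_max < hi - 1e-9:
        raise InvalidInputError("input function does not cover the scan span")

    t_in = input_curve.times
    cb = input_curve.values
    W = _frame_avg_matrix(t_in, schedule)
    cb_frames = W @ cb
    w = np.sqrt(schedule.durations_min)

    names = ["K1", "k2", "k3", "v_b"] if opts.fix_k4 else ["K1", "k2", "k3", "k4", "v_b"]
    lob = np.array([opts.bounds[n][0] for n in names])
    hib = np.array([opts.bounds[n][1] for n in names])

    def unpack(x) -> KineticParams:
        d = dict(zip(names, x))
        d.setdefault("k4", 0.0)
        return KineticParams(**d)

    def resid(x):
        p = unpack(x)
        cf, cm = _solve_components(p, t_in, cb)
        model_frames = (1.0 - p.v_b) * (W @ (cf + cm)) + p.v_b * cb_frames
        return w * (model_frames - y)

    starts = []
    for K1, k2, k3 in _GRID_STARTS[: opts.n_grid_starts]:
        s = {"K1": K1, "k2": k2, "k3": k3, "k4": 0.002, "v_b": 0.05}
        starts.append(np.array([s[n] for n in names]))
    rng = np.random.default_rng(opts.seed)
    for _ in range(opts.n_jitter_starts):
        u = rng.uniform(0.02, 0.8, size=len(names))
        starts.append(lob + u * (hib - lob))

    best = None
    any_ok = False
    for x0 in starts:
        x0 = np.clip(x0, lob, hib)
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=(lob, hib),
                method="trf",
                ftol=opts.ftol,
                xtol=opts.xtol,
                max_nfev=opts.max_nfev,
            )
        except Exception:  # pragma: no cover - optimizer blowup on one start
            continue
        any_ok = any_ok or sol.success
        wrss = float(2.0 * sol.cost)
        p = unpack(sol.x)
        key = (wrss, p.k4)
        if best is None or key < best[0]:
            best = (key, p, wrss)
    if best is None:
        raise ConvergenceError("no optimizer start produced a solution")

    _, p, wrss = best
    mids = schedule.mid_minutes
    cf, cm = _solve_components(p, t_in, cb)
    comp = {
        "blood": TacCurve(mids, np.interp(mids, t_in, cb), "blood"),
        "free": TacCurve(mids, np.interp(mids, t_in, cf), "free"),
        "metabolized": TacCurve(mids, np.interp(mids, t_in, cm), "metabolized"),
    }
    ctm = (1.0 - p.v_b) * (comp["free"].values + comp["metabolized"].values) + (
        p.v_b * comp["blood"].values
    )
    comp["model"] = TacCurve(mids, ctm, "model")
    return FitResult(params=p, components=comp, wrss=wrss, converged=any_ok, n_starts=len(starts))


def decompose(fit: FitResult) -> tuple[TacCurve, TacCurve, TacCurve]:
    """Return the (C_b, C_f, C_m) component curves of a converged fit."""
    if not fit.converged:
        raise ConvergenceError("cannot decompose a non-converged fit")
    return fit.components["blood"], fit.components["free"], fit.components["metabolized"]
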