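"""Analytic forward models for one- and two-tissue compartment kinetics.

The tissue impulse response of the linear compartment system is a sum of
exponentials.  For the two-tissue model with influx K1 (mL/cc/min),
efflux k2, binding k3 and dissociation k4 (all 1/min),

    theta_{1,2} = [(k2 + k3 + k4) +/- sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2

and the amplitudes follow from partial fractions with A1 + A2 = K1;
the integral of the impulse response is the total distribution volume
K1/k2 (1 + k3/k4).  The one-tissue model is the single term K1 e^{-k2 t}.

The predicted PET measurement is

    M(t) = (1 - VB) * [h (*) Cp](t - t_bolus) + VB * C_blood(t - t_bolus)

frame-averaged over each acquisition frame (PET frames integrate counts;
midpoint sampling is available behind a flag for sensitivity checks).
The convolution is computed exactly per 1-s interval assuming the input
is piecewise linear (an exponential integrator realised as a first-order
IIR recursion), not by FFT, so short grids lose no accuracy.

``ode_oracle`` provides an independent verification path: it integrates
the underlying state equations

    dC_ND/dt = K1 Cp - (k2 + k3) C_ND + k4 C_B
    dC_B/dt  = k3 C_ND - k4 C_B

directly, either by exact per-segment propagation of the augmented
linear system (matrix exponential; default) or with an adaptive stiff
solver.  It shares no numerics with :func:`predict_tac` and is intended
for tests only.

Unit convention: rate constants are per minute at every interface and
converted to per second internally, exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import CoverageError, OracleError, ParameterError
from .input_function import ArterialInputFunction
from .io import FrameSchedule, TimeActivityCurve

#: Soft upper bound on rate constants used by the fit constraint.
RATE_UPPER_BOUND = 0.9


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the compartment model, per minute.

    ``k3``/``k4`` are ``None`` for the one-tissue model and must be given
    (or omitted) together.
    """

    k1: float
    k2: float
    k3: float | None = None
    k4: float | None = None

    def __post_init__(self):
        if (self.k3 is None) != (self.k4 is None):
            raise ParameterError("k3 and k4 must be both present or both absent")
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name}: {v} must be finite and > 0")
        for name in ("k3", "k4"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ParameterError(f"{name}: {v} must be finite and >= 0")

    @property
    def is_two_tissue(self) -> bool:
        return self.k3 is not None

    def as_array(self) -> np.ndarray:
        if self.is_two_tissue:
            return np.array([self.k1, self.k2, self.k3, self.k4])
        return np.array([self.k1, self.k2])


@dataclass(frozen=True)
class NuisanceParams:
    """Fractional blood volume and input-to-tissue bolus time shift."""

    vb: float = 0.0
    t_bolus_s: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.vb <= 1.0:
            raise ParameterError(f"vb: {self.vb} outside [0, 1]")
        if not np.isfinite(self.t_bolus_s):
            raise ParameterError("t_bolus_s must be finite")


@dataclass
class ModelState:
    """Continuous compartment concentrations on the input grid."""

    time_s: np.ndarray
    c_nd: np.ndarray
    c_b: np.ndarray


def impulse_response(params: KineticParams) -> tuple[np.ndarray, np.ndarray]:
    """Sum-of-exponentials representation (amplitudes, decay rates), per minute.

    One-tissue: single term (K1, k2).  Two-tissue: two terms whose
    amplitudes sum to K1; the k3 = k4 = 0 limit collapses to the
    one-tissue response.
    """
    if not params.is_two_tissue:
        return np.array([params.k1]), np.array([params.k2])
    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:
        # (k2 - k4)^2 + k3^2 + 2 k3 (k2 + k4) >= 0: impossible for
        # admissible rates, so this is an internal consistency failure.
        raise ParameterError(f"negative discriminant {disc} for params {params}")
    root = np.sqrt(disc)
    th1 = 0.5 * (s + root)
    th2 = 0.5 * (s - root)
    if th1 - th2 < 1e-14:
        return np.array([k1]), np.array([th1])
    a1 = k1 * (th1 - k3 - k4) / (th1 - th2)
    a2 = k1 * (k3 + k4 - th2) / (th1 - th2)
    return np.array([a1, a2]), np.array([th1, th2])


def _exp_conv(amp_per_s: float, theta_per_s: float, x: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Exact convolution of A e^{-theta t} with piecewise-linear x on a
    uniform grid, via the recursion y_n = E y_{n-1} + b0 x_n + b1 x_{n-1}."""
    E = np.exp(-theta_per_s * dt)
    if theta_per_s > 1e-12:
        f1 = -np.expm1(-theta_per_s * dt) / theta_per_s
        f2 = (dt - f1) / theta_per_s
    else:  # theta -> 0 limit: pure integrator
        f1 = dt
        f2 = dt * dt / 2.0
    b0 = amp_per_s * f2 / dt
    b1 = amp_per_s * (f1 - f2 / dt)
    y, _ = lfilter([b0, b1], [1.0, -E], x, zi=np.array([-b0 * x[0]]))
    return y


def tissue_response(params: KineticParams, cp: np.ndarray, dt_s: float = 1.0) -> np.ndarray:
    """Continuous tissue concentration h (*) Cp on the input grid."""
    amps, thetas = impulse_response(params)
    out = np.zeros_like(cp, dtype=float)
    for a, th in zip(amps / 60.0, thetas / 60.0):  # per-minute -> per-second
        out += _exp_conv(a, th, cp, dt_s)
    return out


def _shift(curve: np.ndarray, time_s: np.ndarray, t_bolus_s: float) -> np.ndarray:
    """Evaluate curve(t - t_bolus): zero-padded before bolus arrival,
    edge-held past the end of the grid, linear for fractional shifts."""
    if t_bolus_s == 0.0:
        return curve
    return np.interp(time_s - t_bolus_s, time_s, curve, left=0.0, right=curve[-1])


def frame_average(
    curve: np.ndarray, time_s: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Time-average a continuous curve over each acquisition frame."""
    if schedule.end_s > time_s[-1] + 1e-9:
        raise CoverageError(
            f"frames end at {schedule.end_s} s but the input grid ends at "
            f"{time_s[-1]} s"
        )
    integral = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) / 2.0
                                                * np.diff(time_s))])
    lo = np.interp(schedule.start_s, time_s, integral)
    hi = np.interp(schedule.start_s + schedule.duration_s, time_s, integral)
    return (hi - lo) / schedule.duration_s


def predict_tac(
    params: KineticParams,
    nuisance: NuisanceParams,
    aif: ArterialInputFunction,
    schedule: FrameSchedule,
    frame_averaged: bool = True,
    roi: str = "model",
) -> TimeActivityCurve:
    """Predicted PET time-activity curve for one region.

    ``frame_averaged=False`` samples the continuous model at frame
    midpoints instead of averaging (sensitivity checks only).
    """
    t = aif.time_s
    cp = _shift(aif.plasma_parent_kbq_cc, t, nuisance.t_bolus_s)
    cb = _shift(aif.whole_blood_kbq_cc, t, nuisance.t_bolus_s)
    ct = tissue_response(params, cp)
    measured = (1.0 - nuisance.vb) * ct + nuisance.vb * cb
    if frame_averaged:
        values = frame_average(measured, t, schedule)
    else:
        if schedule.end_s > t[-1] + 1e-9:
            raise CoverageError("frames extend beyond the input grid")
        values = np.interp(schedule.mid_s, t, measured)
    return TimeActivityCurve(roi, schedule, values)


# ---------------------------------------------------------------------------
# Independent verification path
# ---------------------------------------------------------------------------

def _ode_expm(params: KineticParams, cp: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-segment propagation of the state equations.

    Augments the 2-state linear ODE with the locally-linear input
    (u' = v, v' = 0) and applies the matrix exponential of the constant
    4x4 system over each 1-s segment.
    """
    from scipy.linalg import expm

    k1 = params.k1 / 60.0
    k2 = params.k2 / 60.0
    k3 = (params.k3 or 0.0) / 60.0
    k4 = (params.k4 or 0.0) / 60.0
    A = np.array(
        [
            [-(k2 + k3), k4, k1, 0.0],
            [k3, -k4, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    P = expm(A * dt)
    p00, p01, p02, p03 = P[0]
    p10, p11, p12, p13 = P[1]
    n = len(cp)
    c_nd = np.zeros(n)
    c_b = np.zeros(n)
    x = y = 0.0
    cp_l = cp.tolist()
    nd_l, b_l = c_nd.tolist(), c_b.tolist()
    for i in range(n - 1):
        u = cp_l[i]
        v = (cp_l[i + 1] - u) / dt
        x, y = (
            p00 * x + p01 * y + p02 * u + p03 * v,
            p10 * x + p11 * y + p12 * u + p13 * v,
        )
        nd_l[i + 1] = x
        b_l[i + 1] = y
    return np.array(nd_l), np.array(b_l)


def _ode_ivp(params: KineticParams, cp: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.integrate import solve_ivp

    k1 = params.k1 / 60.0
    k2 = params.k2 / 60.0
    k3 = (params.k3 or 0.0) / 60.0
    k4 = (params.k4 or 0.0) / 60.0

    def rhs(tt, y):
        c = np.interp(tt, t, cp)
        return [k1 * c - (k2 + k3) * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]

    sol = solve_ivp(
        rhs, (t[0], t[-1]), [0.0, 0.0], t_eval=t, method="LSODA",
        rtol=1e-10, atol=1e-13, max_step=10.0,
    )
    if not sol.success:
        raise OracleError(f"stiff integrator failed: {sol.message}")
    return sol.y[0], sol.y[1]


def ode_oracle(
    params: KineticParams,
    nuisance: NuisanceParams,
    aif: ArterialInputFunction,
    schedule: FrameSchedule,
    method: str = "expm",
    return_state: bool = False,
):
    """Reference TAC via direct integration of the state equations.

    Same contract as :func:`predict_tac` but computed along an entirely
    different numerical route; used only to verify the analytic
    convolution.  ``method`` is ``"expm"`` (exact segment propagation,
    fast) or ``"ivp"`` (adaptive LSODA, slow).  With ``return_state`` the
    continuous :class:`ModelState` is returned alongside the TAC.
    """
    t = aif.time_s
    cp = _shift(aif.plasma_parent_kbq_cc, t, nuisance.t_bolus_s)
    cb = _shift(aif.whole_blood_kbq_cc, t, nuisance.t_bolus_s)
    if method == "expm":
        c_nd, c_b = _ode_expm(params, cp, float(t[1] - t[0]))
    elif method == "ivp":
        c_nd, c_b = _ode_ivp(params, cp, t)
    else:
        raise ParameterError(f"unknown oracle method {method!r}")
    measured = (1.0 - nuisance.vb) * (c_nd + c_b) + nuisance.vb * cb
    # frame averaging written out independently of frame_average()
    if schedule.end_s > t[-1] + 1e-9:
        raise CoverageError("frames extend beyond the input grid")
    vals = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.start_s, schedule.duration_s)):
        lo, hi = s, s + d
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        tt = t[mask]
        vals[i] = np.trapezoid(measured[mask], tt) / (tt[-1] - tt[0])
    tac = TimeActivityCurve("ode_oracle", schedule, vals)
    if return_state:
        return tac, ModelState(t, c_nd, c_b)
    return tac
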