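"""Logan graphical analysis for reversibly binding radioligands.

For a reversible tracer the transformed variables

    y(T) = int_0^T Ct dt / Ct(T),    x(T) = int_0^T Cp dt / Ct(T)

become linear in each other once the system is past its initial
transient, with asymptotic slope equal to the total distribution volume
VT.  The slope is estimated by ordinary least squares over the frames
whose start lies at or after ``t_star`` (default 480 s, i.e. the 8-min
point of the published 8-to-60-min window).

Numerical choices: the transform is evaluated at frame ends, where the
tissue integral is exact — a frame value is the frame average, so
value x duration is the frame's integral and the cumulative sum needs
no further quadrature; the plasma integral uses the trapezoid rule on
the 1-s input grid.  (This choice makes the equilibrium identity
Ct = V*Cp reproduce the slope V exactly; midpoint evaluation would
re-introduce quadrature error from the bolus peak.)  The regression is
unweighted, and the whole-blood contribution is not removed from the
tissue curve unless requested.  With slowly equilibrating tracers the
finite-window Logan slope systematically underestimates the
compartmental VT and converges toward it as ``t_star`` grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .errors import InsufficientDataError, WindowError
from .input_function import ArterialInputFunction
from .io import TimeActivityCurve

logger = logging.getLogger("petkin")


@dataclass
class LoganResult:
    """Slope (VT), intercept and diagnostics of the Logan regression."""

    vt_slope: float
    intercept: float
    t_star_s: float
    n_points: int
    r_squared: float


def logan_vt(
    tac: TimeActivityCurve,
    aif: ArterialInputFunction,
    t_star_s: float = 480.0,
    end_s: float | None = None,
    subtract_blood: bool = False,
) -> LoganResult:
    """Logan regression of one region against the plasma input.

    Frames with non-positive tissue activity inside the window are
    excluded with a warning (the transform divides by Ct); fewer than
    three surviving points is an error.  ``subtract_blood`` subtracts the
    whole-blood curve (sampled at frame midpoints) from the tissue curve
    before the transform; by default the blood contribution is left in,
    matching the published procedure.
    """
    sched = tac.schedule
    if end_s is None:
        end_s = sched.end_s
    if t_star_s >= sched.start_s[-1]:
        raise WindowError(
            f"t_star {t_star_s} s is beyond the last frame start "
            f"({sched.start_s[-1]} s)"
        )
    if end_s > aif.end_s + 1e-9:
        raise WindowError(
            f"analysis window end {end_s} s beyond input grid ({aif.end_s} s)"
        )

    ends = sched.start_s + sched.duration_s
    ct = tac.activity_kbq_cc.astype(float)
    if subtract_blood:
        from .kinetic_models import frame_average

        ct = ct - frame_average(aif.whole_blood_kbq_cc, aif.time_s, sched)

    # cumulative integrals at frame ends: tissue exactly from the frame
    # averages, plasma by trapezoid on the 1-s grid
    int_ct = np.cumsum(ct * sched.duration_s)
    cp = aif.plasma_parent_kbq_cc
    int_cp_grid = np.concatenate(
        [[0.0], np.cumsum((cp[1:] + cp[:-1]) / 2.0 * np.diff(aif.time_s))]
    )
    int_cp = np.interp(ends, aif.time_s, int_cp_grid)

    window = (sched.start_s >= t_star_s) & (ends <= end_s + 1e-9)
    positive = ct > 0
    dropped = window & ~positive
    if np.any(dropped):
        logger.warning(
            "logan_vt roi %r: excluded %d non-positive frame(s) in window",
            tac.roi, int(np.sum(dropped)),
        )
    sel = window & positive
    if int(np.sum(sel)) < 3:
        raise InsufficientDataError(
            f"logan_vt roi {tac.roi!r}: only {int(np.sum(sel))} usable "
            "point(s) in the linear window; >= 3 required"
        )
    x = int_cp[sel] / ct[sel]
    y = int_ct[sel] / ct[sel]
    reg = linregress(x, y)
    return LoganResult(
        vt_slope=float(reg.slope),
        intercept=float(reg.intercept),
        t_star_s=float(t_star_s),
        n_points=int(np.sum(sel)),
        r_squared=float(reg.rvalue**2),
    )
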