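"""Weighted, bounded nonlinear least-squares estimation of kinetic
parameters.

Four fitting modes, all built on the same trust-region bounded solver
(scipy ``least_squares``, numeric Jacobian):

* per-region 1TCM / 2TCM fits with the blood-volume fraction and bolus
  shift held fixed,
* a six-parameter whole-brain fit that additionally estimates VB and
  t_bolus (these are then frozen for every regional fit of the scan),
* a coupled fit across several regions sharing one K1/k2 ratio, and
* the two-session grey-/white-matter protocol built on the coupled fit.

Conventions: rate constants are constrained to (0, 0.9] per minute
(initial values K1=0.5, k2=0.1, k3=0.5, k4=0.5); the shared K1/k2 ratio
is bounded in (0, 10] since observed ratios approach 0.6 and a 0.9 cap
on a ratio has no basis.  Weights default to frame duration (all curves
are decay-corrected, so no decay term enters the weighting), normalised
to sum to the number of frames so that weighted and unweighted residual
sums stay comparable.  On non-convergence the fit is restarted from up
to five log-uniform perturbations of the standard initials (fixed seed)
and the best residual is kept; a still-unconverged fit is returned
flagged, not raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, InsufficientDataError, ParameterError
from .input_function import ArterialInputFunction
from .io import TimeActivityCurve
from .kinetic_models import KineticParams, NuisanceParams, predict_tac

logger = logging.getLogger("petkin")

WEIGHT_SCHEMES = ("duration", "uniform", "duration_sq_over_activity")


@dataclass(frozen=True)
class FitConfig:
    """Solver settings shared by every fitting mode."""

    k1_init: float = 0.5
    k2_init: float = 0.1
    k3_init: float = 0.5
    k4_init: float = 0.5
    rate_lower: float = 1e-6
    rate_upper: float = 0.9
    ratio_upper: float = 10.0
    vb_init: float = 0.05
    t_bolus_init_s: float = 0.0
    t_bolus_bound_s: float = 60.0
    weight_scheme: str = "duration"
    weight_floor: float = 1e-6
    tol: float = 1e-12
    max_nfev: int = 4000
    restarts: int = 5
    restart_seed: int = 20120423

    def __post_init__(self):
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ConfigurationError(
                f"weight_scheme {self.weight_scheme!r} not in {WEIGHT_SCHEMES}"
            )
        if not self.tol > 0:
            raise ConfigurationError("tol must be > 0")
        for name in ("k1_init", "k2_init", "k3_init", "k4_init"):
            v = getattr(self, name)
            if not self.rate_lower <= v <= self.rate_upper:
                raise ConfigurationError(f"{name}={v} outside bounds "
                                         f"({self.rate_lower}, {self.rate_upper}]")


@dataclass
class FitResult:
    """Outcome of one (or one region of a coupled) least-squares fit."""

    roi: str
    model: str
    params: KineticParams
    nuisance: NuisanceParams
    rss: float
    n_frames: int
    n_params: int
    fitted_curve: np.ndarray
    stderr: dict[str, float]
    converged: bool
    n_iter: int
    weight_scheme: str
    at_bounds: tuple[str, ...] = ()
    shared_ratio: float | None = None

    @property
    def degenerate(self) -> bool:
        """True when K1 collapsed onto a bound (e.g. an all-zero TAC)."""
        return "k1" in self.at_bounds


def compute_weights(
    tac: TimeActivityCurve, scheme: str = "duration", floor: float = 1e-6
) -> np.ndarray:
    """Per-frame weights, normalised to sum to the number of frames.

    ``duration``: w_i proportional to frame duration (the default; longer
    frames integrate more counts).  ``uniform``: all ones, so the
    weighted RSS equals the unweighted RSS.  ``duration_sq_over_activity``:
    w_i proportional to d_i^2 / max(activity, floor), an approximate
    inverse-variance weighting under counting statistics.
    """
    d = tac.schedule.duration_s
    if scheme == "duration":
        w = d.astype(float)
    elif scheme == "uniform":
        w = np.ones_like(d, dtype=float)
    elif scheme == "duration_sq_over_activity":
        w = d.astype(float) ** 2 / np.maximum(tac.activity_kbq_cc, floor)
    else:
        raise ConfigurationError(f"unknown weight scheme {scheme!r}")
    return w * (len(w) / w.sum())


def _param_names(model: str) -> list[str]:
    return ["k1", "k2"] if model == "1tcm" else ["k1", "k2", "k3", "k4"]


def _make_params(model: str, x: np.ndarray) -> KineticParams:
    if model == "1tcm":
        return KineticParams(k1=float(x[0]), k2=float(x[1]))
    return KineticParams(*(float(v) for v in x[:4]))


def _solve(fun, x0, bounds, x_scale, config: FitConfig):
    """least_squares with multi-start restarts on non-convergence."""
    def run(start):
        return least_squares(
            fun, start, bounds=bounds, x_scale=x_scale, method="trf",
            ftol=config.tol, xtol=config.tol, gtol=config.tol,
            max_nfev=config.max_nfev,
        )

    best = run(np.asarray(x0, dtype=float))
    if best.status > 0:
        return best, True
    rng = np.random.default_rng(config.restart_seed)
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
    for i in range(config.restarts):
        pert = np.asarray(x0) * 10.0 ** rng.uniform(-0.5, 0.5, size=len(x0))
        pert = np.clip(pert, lo + 1e-12, hi - 1e-12)
        res = run(pert)
        if res.cost < best.cost:
            best = res
        if res.status > 0:
            logger.info("fit converged after %d restart(s)", i + 1)
            return best, True
    logger.warning("fit did not converge after %d restarts", config.restarts)
    return best, False


def _stderr(res, n: int, p: int, names: list[str]) -> dict[str, float]:
    """Standard errors from the weighted Jacobian at the solution."""
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)
    return dict(zip(names, (float(v) for v in se)))


def _at_bounds(x, lo, hi, names, rtol=1e-6) -> tuple[str, ...]:
    out = []
    for v, a, b, n in zip(x, lo, hi, names):
        span = max(b - a, 1e-12)
        if v - a <= rtol * span or b - v <= rtol * span:
            out.append(n)
    return tuple(out)


def fit_region(
    tac: TimeActivityCurve,
    aif: ArterialInputFunction,
    model: str = "2tcm",
    nuisance: NuisanceParams = NuisanceParams(),
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Bounded weighted fit of a single region with fixed VB / t_bolus."""
    if model not in ("1tcm", "2tcm"):
        raise ParameterError(f"model must be '1tcm' or '2tcm', got {model!r}")
    names = _param_names(model)
    y = tac.activity_kbq_cc
    w = compute_weights(tac, config.weight_scheme, config.weight_floor)
    sw = np.sqrt(w)

    def residuals(x):
        pred = predict_tac(_make_params(model, x), nuisance, aif, tac.schedule)
        return sw * (pred.activity_kbq_cc - y)

    x0 = [config.k1_init, config.k2_init]
    if model == "2tcm":
        x0 += [config.k3_init, config.k4_init]
    lo = [config.rate_lower] * len(x0)
    hi = [config.rate_upper] * len(x0)
    res, converged = _solve(residuals, x0, (lo, hi), [0.1] * len(x0), config)
    params = _make_params(model, res.x)
    bounds_hit = _at_bounds(res.x, lo, hi, names)
    if bounds_hit:
        logger.warning("roi %r: active bound(s) at solution: %s", tac.roi, bounds_hit)
    fitted = predict_tac(params, nuisance, aif, tac.schedule).activity_kbq_cc
    return FitResult(
        roi=tac.roi,
        model=model,
        params=params,
        nuisance=nuisance,
        rss=float(np.sum(w * (fitted - y) ** 2)),
        n_frames=len(y),
        n_params=len(x0),
        fitted_curve=fitted,
        stderr=_stderr(res, len(y), len(x0), names),
        converged=converged,
        n_iter=int(res.nfev),
        weight_scheme=config.weight_scheme,
        at_bounds=bounds_hit,
    )


def fit_whole_brain(
    tac_wb: TimeActivityCurve,
    aif: ArterialInputFunction,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Six-parameter whole-brain 2TCM fit: K1, k2, k3, k4, VB, t_bolus.

    The fitted VB and t_bolus are meant to be frozen (via
    ``result.nuisance``) for every regional fit of the same scan.
    """
    names = ["k1", "k2", "k3", "k4", "vb", "t_bolus_s"]
    y = tac_wb.activity_kbq_cc
    w = compute_weights(tac_wb, config.weight_scheme, config.weight_floor)
    sw = np.sqrt(w)

    def residuals(x):
        params = _make_params("2tcm", x)
        nuis = NuisanceParams(vb=float(x[4]), t_bolus_s=float(x[5]))
        pred = predict_tac(params, nuis, aif, tac_wb.schedule)
        return sw * (pred.activity_kbq_cc - y)

    x0 = [config.k1_init, config.k2_init, config.k3_init, config.k4_init,
          config.vb_init, config.t_bolus_init_s]
    lo = [config.rate_lower] * 4 + [0.0, -config.t_bolus_bound_s]
    hi = [config.rate_upper] * 4 + [1.0, config.t_bolus_bound_s]
    res, converged = _solve(
        residuals, x0, (lo, hi), [0.1, 0.1, 0.1, 0.1, 0.05, 10.0], config
    )
    params = _make_params("2tcm", res.x)
    nuis = NuisanceParams(vb=float(res.x[4]), t_bolus_s=float(res.x[5]))
    bounds_hit = _at_bounds(res.x, lo, hi, names)
    if bounds_hit:
        logger.warning("whole-brain fit: active bound(s) at solution: %s", bounds_hit)
    fitted = predict_tac(params, nuis, aif, tac_wb.schedule).activity_kbq_cc
    return FitResult(
        roi=tac_wb.roi,
        model="2tcm6",
        params=params,
        nuisance=nuis,
        rss=float(np.sum(w * (fitted - y) ** 2)),
        n_frames=len(y),
        n_params=6,
        fitted_curve=fitted,
        stderr=_stderr(res, len(y), 6, names),
        converged=converged,
        n_iter=int(res.nfev),
        weight_scheme=config.weight_scheme,
        at_bounds=bounds_hit,
    )


def fit_coupled_shared_ratio(
    tacs: list[TimeActivityCurve],
    aif: ArterialInputFunction,
    nuisance: NuisanceParams = NuisanceParams(),
    config: FitConfig = FitConfig(),
) -> list[FitResult]:
    """Joint 2TCM fit over regions sharing one K1/k2 ratio.

    Free parameters: one global ratio R = K1/k2 plus per-region
    (k2, k3, k4); K1 is reconstructed as R * k2.  Every returned
    :class:`FitResult` reports the identical ``shared_ratio``; the
    per-region ``rss`` is that region's weighted residual sum.
    """
    if not tacs:
        raise InsufficientDataError("fit_coupled_shared_ratio: no regions given")
    n_reg = len(tacs)
    ys = [t.activity_kbq_cc for t in tacs]
    sws = [np.sqrt(compute_weights(t, config.weight_scheme, config.weight_floor))
           for t in tacs]

    def unpack(x):
        R = float(x[0])
        sets = []
        for i in range(n_reg):
            k2, k3, k4 = (float(v) for v in x[1 + 3 * i : 4 + 3 * i])
            sets.append(KineticParams(k1=R * k2, k2=k2, k3=k3, k4=k4))
        return R, sets

    def residuals(x):
        _, sets = unpack(x)
        parts = [
            sw * (predict_tac(p, nuisance, aif, tac.schedule).activity_kbq_cc - y)
            for p, tac, y, sw in zip(sets, tacs, ys, sws)
        ]
        return np.concatenate(parts)

    r0 = min(config.k1_init / config.k2_init, 0.5 * config.ratio_upper)
    x0 = [r0] + [config.k2_init, config.k3_init, config.k4_init] * n_reg
    lo = [1e-6] + [config.rate_lower] * (3 * n_reg)
    hi = [config.ratio_upper] + [config.rate_upper] * (3 * n_reg)
    x_scale = [0.3] + [0.1] * (3 * n_reg)
    res, converged = _solve(residuals, x0, (lo, hi), x_scale, config)
    if res.jac is not None and np.linalg.matrix_rank(res.jac) < len(x0):
        logger.warning("coupled fit: joint Jacobian is rank-deficient")
    R, sets = unpack(res.x)
    all_names = ["shared_ratio"] + [
        f"{n}[{t.roi}]" for t in tacs for n in ("k2", "k3", "k4")
    ]
    joint_se = _stderr(res, sum(len(y) for y in ys), len(res.x), all_names)
    results = []
    for i, (params, tac, y, sw) in enumerate(zip(sets, tacs, ys, sws)):
        fitted = predict_tac(params, nuisance, aif, tac.schedule).activity_kbq_cc
        se = {"shared_ratio": joint_se["shared_ratio"]}
        for n in ("k2", "k3", "k4"):
            se[n] = joint_se[f"{n}[{tac.roi}]"]
        results.append(
            FitResult(
                roi=tac.roi,
                model="2tcm_coupled",
                params=params,
                nuisance=nuisance,
                rss=float(np.sum(sw**2 * (fitted - y) ** 2)),
                n_frames=len(y),
                n_params=3 + 1,  # per-region share of the joint problem
                fitted_curve=fitted,
                stderr=se,
                converged=converged,
                n_iter=int(res.nfev),
                weight_scheme=config.weight_scheme,
                at_bounds=_at_bounds(
                    res.x[1 + 3 * i : 4 + 3 * i],
                    lo[1 + 3 * i : 4 + 3 * i],
                    hi[1 + 3 * i : 4 + 3 * i],
                    ["k2", "k3", "k4"],
                ),
                shared_ratio=R,
            )
        )
    return results


def run_two_session_procedure(
    tacs: dict[str, TimeActivityCurve],
    gm_rois: list[str],
    wm_rois: list[str],
    typical_gm_roi: str,
    aif: ArterialInputFunction,
    nuisance: NuisanceParams = NuisanceParams(),
    config: FitConfig = FitConfig(),
) -> dict[str, FitResult]:
    """Two-session coupled protocol.

    Session 1 couples all grey-matter regions together with the
    typical-GM region; session 2 couples the white-matter regions with
    the same typical-GM region (to carry the ratio coupling over), but
    the typical-GM parameters retained in the output are those from
    session 1.
    """
    if typical_gm_roi not in tacs:
        raise ConfigurationError(
            f"typical grey-matter region {typical_gm_roi!r} not among TACs"
        )
    missing = [r for r in list(gm_rois) + list(wm_rois) if r not in tacs]
    if missing:
        raise ConfigurationError(f"regions not among TACs: {missing}")

    session1_rois = list(dict.fromkeys(list(gm_rois) + [typical_gm_roi]))
    out: dict[str, FitResult] = {}
    res1 = fit_coupled_shared_ratio(
        [tacs[r] for r in session1_rois], aif, nuisance, config
    )
    for r in res1:
        out[r.roi] = r

    if not wm_rois:
        logger.warning("two-session procedure: no white-matter regions; "
                       "session 2 skipped")
        return out
    session2_rois = list(dict.fromkeys(list(wm_rois) + [typical_gm_roi]))
    res2 = fit_coupled_shared_ratio(
        [tacs[r] for r in session2_rois], aif, nuisance, config
    )
    for r in res2:
        if r.roi != typical_gm_roi:  # session-1 typical-GM values retained
            out[r.roi] = r
    return out
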