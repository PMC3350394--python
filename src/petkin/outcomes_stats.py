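"""Outcome measures, model selection and test-retest reliability.

Outcome measures
    VT    = K1/k2 (1 + k3/k4)   total distribution volume (mL/cc);
            K1/k2 for the one-tissue model
    BPND  = k3/k4               binding potential relative to the
            nondisplaceable compartment (the plasma free fraction is not
            part of the calculation)
    %ID(t) = C(t) * V_brain / (dose * 1000) * 100
            percentage of the injected dose in the brain (C in kBq/cc,
            V_brain in mL, dose in MBq)

Model selection
    AIC = n ln(RSS/n) + 2 (p + 1), the Gaussian least-squares form with
    the noise variance counted as a parameter; only differences between
    models fitted to the same data are meaningful.  The nested 1TCM/2TCM
    comparison additionally uses the one-tailed (right) F test
    F = [(RSS1 - RSS2)/(p2 - p1)] / [RSS2/(n - p2)].

Test-retest statistics
    error% = 100 (test - retest) / mean(test, retest), the symmetric
    convention (a test-denominator variant is selectable); CV% is the SD
    over the group mean per occasion; the intraclass correlation uses
    one-way ANOVA mean squares, ICC = (MSBS - MSWS)/(MSBS + (n-1) MSWS)
    with n = 2 repeats.  ICC may be negative when within-subject
    variation exceeds between-subject variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_distribution

from .errors import InsufficientDataError, ParameterError
from .fitting import FitResult
from .io import StudyMeta, TimeActivityCurve
from .kinetic_models import KineticParams

logger = logging.getLogger("petkin")


def bp_nd(params: KineticParams) -> float:
    """Binding potential BPND = k3/k4 (two-tissue parameters required)."""
    if not params.is_two_tissue:
        raise ParameterError("bp_nd requires two-tissue parameters (k3, k4)")
    if params.k4 == 0:
        raise ParameterError("bp_nd undefined: k4 = 0")
    return params.k3 / params.k4


def vt(params: KineticParams) -> float:
    """Total distribution volume VT = K1/k2 (1 + k3/k4); K1/k2 for 1TCM."""
    if params.k2 == 0:
        raise ParameterError("vt undefined: k2 = 0")
    if not params.is_two_tissue:
        return params.k1 / params.k2
    if params.k4 == 0:
        raise ParameterError("vt undefined: k4 = 0")
    return params.k1 / params.k2 * (1.0 + params.k3 / params.k4)


def aic(rss: float, n_frames: int, n_params: int) -> float:
    """Akaike information criterion for a Gaussian least-squares fit."""
    if rss <= 0:
        raise ParameterError(f"aic undefined for rss = {rss} (<= 0)")
    if n_frames <= n_params:
        raise ParameterError(
            f"aic: n_frames ({n_frames}) must exceed n_params ({n_params})"
        )
    return n_frames * np.log(rss / n_frames) + 2.0 * (n_params + 1)


@dataclass
class ModelComparison:
    """Nested 1TCM-vs-2TCM selection by AIC and one-tailed F test."""

    aic_1t: float
    aic_2t: float
    f_stat: float
    p_value: float
    preferred: str
    alpha: float = 0.05


def f_test_nested(fit_1t: FitResult, fit_2t: FitResult, alpha: float = 0.05) -> ModelComparison:
    """Compare nested compartment models fitted to the same data.

    The two-tissue model is preferred only when its AIC is lower *and*
    the F test is significant at ``alpha``.  A (rare, noise-driven) RSS
    increase under the richer model yields F < 0, reported as p = 1 with
    a warning.
    """
    if fit_1t.n_frames != fit_2t.n_frames:
        raise ParameterError("f_test_nested: fits use different numbers of frames")
    if fit_1t.weight_scheme != fit_2t.weight_scheme:
        raise ParameterError("f_test_nested: fits use different weight schemes")
    p1, p2 = fit_1t.n_params, fit_2t.n_params
    if not p1 < p2:
        raise ParameterError(f"f_test_nested: models not nested ({p1} !< {p2})")
    n = fit_1t.n_frames
    rss1, rss2 = fit_1t.rss, fit_2t.rss
    if rss2 > rss1:
        logger.warning("f_test_nested: RSS increased under the larger model")
        f_stat, p_value = float((rss1 - rss2) / (p2 - p1) / (rss2 / (n - p2))), 1.0
    else:
        f_stat = float((rss1 - rss2) / (p2 - p1) / (rss2 / (n - p2)))
        p_value = float(f_distribution.sf(f_stat, p2 - p1, n - p2))
    a1 = aic(rss1, n, p1)
    a2 = aic(rss2, n, p2)
    preferred = "2tcm" if (a2 < a1 and p_value < alpha) else "1tcm"
    return ModelComparison(
        aic_1t=float(a1), aic_2t=float(a2), f_stat=f_stat,
        p_value=p_value, preferred=preferred, alpha=alpha,
    )


def percent_injected_dose(
    tac_wb: TimeActivityCurve, meta: StudyMeta
) -> tuple[np.ndarray, float]:
    """Whole-brain %ID per frame and its peak value.

    %ID(t) = C(t) [kBq/cc] * brain volume [mL] / (dose [MBq] * 1000) * 100.
    """
    if meta.injected_dose_mbq <= 0:
        raise ParameterError("injected dose must be > 0")
    pid = (
        tac_wb.activity_kbq_cc
        * meta.brain_volume_ml
        / (meta.injected_dose_mbq * 1000.0)
        * 100.0
    )
    return pid, float(np.max(pid))


def trt_error(test_value: float, retest_value: float, denominator: str = "mean") -> float:
    """Test-retest difference in percent.

    ``denominator="mean"`` (default): 100 (test - retest)/mean(test, retest),
    antisymmetric under swapping the scans.  ``denominator="test"`` uses
    the test value instead.
    """
    if not (np.isfinite(test_value) and np.isfinite(retest_value)):
        raise ParameterError("trt_error: non-finite input")
    if denominator == "mean":
        denom = (test_value + retest_value) / 2.0
    elif denominator == "test":
        denom = test_value
    else:
        raise ParameterError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ParameterError("trt_error undefined: zero denominator")
    return 100.0 * (test_value - retest_value) / denom


@dataclass
class IccResult:
    """Intraclass correlation with its one-way ANOVA components."""

    icc: float
    ms_bs: float
    ms_ws: float
    n_repeats: int = 2


def icc(pairs) -> IccResult:
    """One-way ICC from per-subject (test, retest) pairs.

    MSBS is the between-subject mean square of subject means (times the
    number of repeats), MSWS the within-subject mean square; the ICC is
    (MSBS - MSWS)/(MSBS + (n-1) MSWS) with n = 2.  The value is 1 for
    zero within-pair variance and can be negative when within-subject
    scatter dominates.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("icc expects an array of (test, retest) pairs")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("icc: non-finite value in pairs")
    k = arr.shape[0]
    if k < 2:
        raise InsufficientDataError(f"icc: {k} subject(s); >= 2 required")
    n = 2
    subj_means = arr.mean(axis=1)
    grand = subj_means.mean()
    ms_bs = n * np.sum((subj_means - grand) ** 2) / (k - 1)
    ms_ws = np.sum((arr - subj_means[:, None]) ** 2) / (k * (n - 1))
    if ms_ws == 0:
        value = 1.0
    else:
        value = (ms_bs - ms_ws) / (ms_bs + (n - 1) * ms_ws)
    return IccResult(icc=float(value), ms_bs=float(ms_bs), ms_ws=float(ms_ws))


def trt_table(
    values: pd.DataFrame,
    value_col: str = "value",
    denominator: str = "mean",
) -> pd.DataFrame:
    """Per-region test-retest summary table.

    ``values`` is tidy with columns ``subject``, ``region``, ``scan``
    (holding ``"test"`` / ``"retest"``) and ``value_col``.  Subjects with
    an incomplete pair for a region are dropped from that region with a
    warning.  Output: one row per region with test/retest mean, SD and
    CV%, the grand mean, per-subject error statistics (mean, SD, min,
    max) and the ICC with its mean-square components.
    """
    required = {"subject", "region", "scan", value_col}
    missing = required - set(values.columns)
    if missing:
        raise ParameterError(f"trt_table: missing columns {sorted(missing)}")
    rows = []
    for region, grp in values.groupby("region", sort=True):
        wide = grp.pivot_table(
            index="subject", columns="scan", values=value_col, aggfunc="first"
        )
        for scan in ("test", "retest"):
            if scan not in wide.columns:
                wide[scan] = np.nan
        incomplete = wide[wide[["test", "retest"]].isna().any(axis=1)]
        if len(incomplete):
            logger.warning(
                "trt_table region %r: dropping %d subject(s) with incomplete "
                "pairs: %s", region, len(incomplete), list(incomplete.index),
            )
        wide = wide.dropna(subset=["test", "retest"])
        if len(wide) < 2:
            raise InsufficientDataError(
                f"trt_table region {region!r}: {len(wide)} complete pair(s)"
            )
        test = wide["test"].to_numpy()
        retest = wide["retest"].to_numpy()
        errors = np.array(
            [trt_error(t, r, denominator) for t, r in zip(test, retest)]
        )
        icc_res = icc(np.column_stack([test, retest]))
        rows.append(
            {
                "region": region,
                "n_subjects": len(wide),
                "test_mean": test.mean(),
                "test_sd": test.std(ddof=1),
                "test_cv_pct": 100.0 * test.std(ddof=1) / test.mean(),
                "retest_mean": retest.mean(),
                "retest_sd": retest.std(ddof=1),
                "retest_cv_pct": 100.0 * retest.std(ddof=1) / retest.mean(),
                "mean": (test.mean() + retest.mean()) / 2.0,
                "error_pct_mean": errors.mean(),
                "error_pct_sd": errors.std(ddof=1),
                "error_pct_min": errors.min(),
                "error_pct_max": errors.max(),
                "icc": icc_res.icc,
                "ms_bs": icc_res.ms_bs,
                "ms_ws": icc_res.ms_ws,
            }
        )
    return pd.DataFrame(rows).set_index("region")
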