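"""Exponential strength-recovery model.

After an exhaustive push, muscle strength regrows toward baseline MVC as

    MS(t) = MS0 + (MVC - MS0) * (1 - exp(-RR * t))

where MS0 is the strength at exhaustion (t = 0) and RR > 0 is the recovery
rate in 1/min. Rearranging gives a regression through the origin,

    y(t) = ln((MVC - MS0) / (MVC - MS(t))) = RR * t,

so RR is estimated as the no-intercept OLS slope of the transformed
observations pooled across trials, exactly as a single group-level
coefficient. The model's closed form also inverts to the time needed to
reach any target fraction of MVC, which is how work/rest recommendations
are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import statsmodels.api as sm

from .data import RecoverySeries
from .errors import DomainError, FitError

#: Group-level recovery rate reported for exhaustive pushing tasks, 1/min.
REFERENCE_RR = 0.132


@dataclass(frozen=True)
class RecoveryModelFit:
    """Fitted recovery rate with diagnostics.

    ``excluded_points`` counts observations at or above MVC, which have no
    finite log transform (measurement noise can exceed MVC even though the
    model cannot).
    """

    rr: float
    r_squared: float
    n_points: int
    excluded_points: int


def transform_recovery(
    series: RecoverySeries,
    mvc: float | None = None,
    ms0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Log-transform one recovery series into (t, y) regression points.

    y(t) = ln((MVC - MS0)/(MVC - MS_t)) for each t > 0 with MS_t < MVC.
    The 0-min point is omitted (its transform is identically zero and
    carries no information through the origin); points at or above MVC are
    excluded and counted.

    Returns ``(t, y, n_excluded)``.
    """
    mvc = series.trial.mvc if mvc is None else mvc
    ms0 = series.trial.ms0 if ms0 is None else ms0
    if ms0 >= mvc:
        raise DomainError(
            f"ms0 {ms0} must be below mvc {mvc}; no strength deficit to recover"
        )
    mask_t = series.times > 0
    t = series.times[mask_t]
    ms = series.ms[mask_t]
    finite = ms < mvc
    excluded = int(np.sum(~finite))
    t = t[finite]
    ms = ms[finite]
    y = np.log((mvc - ms0) / (mvc - ms))
    return t, y, excluded


def fit_rr(
    series: Iterable[RecoverySeries] | RecoverySeries,
    mvc: float | None = None,
    ms0: float | None = None,
) -> RecoveryModelFit:
    """Estimate the recovery rate by pooled regression through the origin.

    All transformed (t, y) points across the given series are concatenated
    and the no-intercept OLS slope y = RR * t is fitted; R^2 is the
    uncentered convention. Passing a single series gives a per-trial fit.

    ``mvc``/``ms0`` override the per-trial values (useful when transforming
    against group means); by default each series uses its own trial's.
    """
    if isinstance(series, RecoverySeries):
        series = [series]
    ts, ys = [], []
    excluded = 0
    for s in series:
        t, y, n_exc = transform_recovery(s, mvc=mvc, ms0=ms0)
        ts.append(t)
        ys.append(y)
        excluded += n_exc
    t_all = np.concatenate(ts) if ts else np.empty(0)
    y_all = np.concatenate(ys) if ys else np.empty(0)
    if len(t_all) == 0:
        raise FitError("no usable recovery observations after transformation")
    res = sm.OLS(y_all, t_all[:, None]).fit()
    from .met import _safe_r_squared

    return RecoveryModelFit(
        rr=float(res.params[0]),
        r_squared=_safe_r_squared(res),
        n_points=len(t_all),
        excluded_points=excluded,
    )


def predict_ms(rr: float, mvc: float, ms0: float, t: float | np.ndarray) -> float | np.ndarray:
    """Predicted strength (N) after t minutes of rest.

    MS(0) = ms0 exactly; MS(t) -> mvc as t -> infinity.
    """
    if rr <= 0:
        raise DomainError(f"rr must be > 0, got {rr}")
    if not 0 < ms0 <= mvc:
        raise DomainError(f"require 0 < ms0 <= mvc, got ms0={ms0}, mvc={mvc}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError(f"time must be >= 0, got {t}")
    out = ms0 + (mvc - ms0) * (1.0 - np.exp(-rr * t_arr))
    return float(out) if np.isscalar(t) else out


def time_to_fraction(
    rr: float,
    ms0_frac: float,
    target_frac: float,
    lenient: bool = False,
) -> float:
    """Minutes of rest for strength to reach ``target_frac`` of MVC.

    Closed-form inversion of the recovery model on the fraction scale:

        t = -(1/RR) * ln(1 - (target - ms0_frac) / (1 - ms0_frac))

    The asymptote is MVC itself, so a target fraction >= 1 is unreachable.
    A target at or below the starting fraction raises unless ``lenient``,
    in which case 0.0 is returned (already recovered).
    """
    if rr <= 0:
        raise DomainError(f"rr must be > 0, got {rr}")
    if not 0 < ms0_frac < 1:
        raise DomainError(f"ms0_frac must be in (0, 1), got {ms0_frac}")
    if target_frac >= 1:
        raise DomainError(
            f"target fraction {target_frac} is at or above the MVC asymptote"
        )
    if target_frac <= ms0_frac:
        if lenient:
            return 0.0
        raise DomainError(
            f"target fraction {target_frac} already reached at t=0 (ms0_frac={ms0_frac})"
        )
    return float(-np.log(1.0 - (target_frac - ms0_frac) / (1.0 - ms0_frac)) / rr)
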