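"""Maximum-endurance-time (MET) models: candidate forms, log-linearized
fits, model selection and prediction.

Two candidate functional forms relate MET (minutes a static push can be
sustained) to the relative load f_MVC = push force / MVC:

* exponential:  MET = k * exp(c * f_MVC)
* power:        MET = k * f_MVC ** c

Taking natural logs turns both into straight lines in ln(MET):

* exponential:  ln MET = ln k + c * f_MVC
* power:        ln MET = ln k + c * ln f_MVC

Each form is fitted by ordinary least squares on the log scale, with or
without an intercept. A no-intercept fit forces the line through the
origin (so k = 1), and its R^2 is the uncentered convention
1 - SSR / sum(y^2); intercept fits use the usual centered R^2. The best
of the four candidates is the one with the highest R^2.

External endurance models from the literature can be registered by name
as plain callables f_MVC -> minutes and run through the same validation
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .data import FatigueTrial
from .errors import DomainError, SampleSizeError, SingularFitError

FORMS = ("exponential", "power")


def compute_fmvc(load: float, mvc: float) -> float:
    """Relative load f_MVC = load / MVC, valid on (0, 1].

    A load above MVC has no defined endurance time (the push cannot be
    sustained at all) and raises :class:`DomainError`.
    """
    if load <= 0 or mvc <= 0:
        raise DomainError(f"load and mvc must be > 0, got load={load}, mvc={mvc}")
    if load > mvc:
        raise DomainError(f"load {load} N exceeds MVC {mvc} N; endurance is undefined")
    return load / mvc


@dataclass(frozen=True)
class MetModelFit:
    """A fitted MET model.

    ``k`` is the multiplier (1.0 for no-intercept fits), ``c`` the exponent
    (power form) or rate (exponential form), both on the natural-log scale
    of the fit. ``residual_log_sd`` is the residual SD in log-minutes.
    """

    form: str
    with_intercept: bool
    k: float
    c: float
    r_squared: float
    n: int
    residual_log_sd: float

    def predict(self, fmvc: float | np.ndarray) -> float | np.ndarray:
        return predict_met(self, fmvc)


def _safe_r_squared(res) -> float:
    """R^2 clipped to [0, 1]; a 0/0 (zero total sum of squares) counts as a
    perfect fit when the residuals vanish and 0 otherwise."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = res.rsquared
    if not np.isfinite(r2):
        return 1.0 if np.isclose(res.ssr, 0.0) else 0.0
    return float(np.clip(r2, 0.0, 1.0))


def _design(fmvc: np.ndarray, form: str) -> np.ndarray:
    if form == "power":
        return np.log(fmvc)
    if form == "exponential":
        return fmvc
    raise DomainError(f"unknown model form {form!r}; expected one of {FORMS}")


def fit_met_xy(
    fmvc: Sequence[float],
    met: Sequence[float],
    form: str = "power",
    with_intercept: bool = False,
) -> MetModelFit:
    """Fit one candidate MET form to (f_MVC, MET) pairs by log-scale OLS."""
    fmvc = np.asarray(fmvc, dtype=float)
    met = np.asarray(met, dtype=float)
    if fmvc.shape != met.shape or fmvc.ndim != 1:
        raise DomainError("fmvc and met must be 1-d arrays of equal length")
    if np.any(met <= 0):
        raise DomainError("all MET values must be > 0")
    if np.any((fmvc <= 0) | (fmvc > 1)):
        raise DomainError("all f_MVC values must be in (0, 1]")
    n = len(fmvc)
    n_params = 2 if with_intercept else 1
    if n < max(2, n_params + 1 if with_intercept else 2):
        raise SampleSizeError(
            f"need at least {3 if with_intercept else 2} trials, got {n}"
        )
    x = _design(fmvc, form)
    y = np.log(met)
    if with_intercept and np.ptp(x) == 0:
        raise SingularFitError("f_MVC is constant across trials; slope is unidentified")
    if not with_intercept and np.all(x == 0):
        raise SingularFitError("all transformed f_MVC are zero; slope is unidentified")
    design = sm.add_constant(x) if with_intercept else x[:, None]
    res = sm.OLS(y, design).fit()
    if with_intercept:
        intercept, slope = res.params
        k = float(np.exp(intercept))
    else:
        slope = res.params[0]
        k = 1.0
    dof = n - n_params
    resid_sd = float(np.sqrt(res.ssr / dof)) if dof > 0 else float("nan")
    # statsmodels reports the uncentered R^2 automatically for no-constant fits
    return MetModelFit(
        form=form,
        with_intercept=with_intercept,
        k=k,
        c=float(slope),
        r_squared=_safe_r_squared(res),
        n=n,
        residual_log_sd=resid_sd,
    )


def fit_met(
    trials: Iterable[FatigueTrial],
    form: str = "power",
    with_intercept: bool = False,
) -> MetModelFit:
    """Fit one candidate MET form to a set of fatigue trials."""
    trials = list(trials)
    fmvc = [compute_fmvc(t.condition.push_force, t.mvc) for t in trials]
    met = [t.met for t in trials]
    return fit_met_xy(fmvc, met, form=form, with_intercept=with_intercept)


def fit_candidates(trials: Iterable[FatigueTrial]) -> list[MetModelFit]:
    """Fit all four candidate models (2 forms x intercept yes/no)."""
    trials = list(trials)
    return [
        fit_met(trials, form=form, with_intercept=wi)
        for form in FORMS
        for wi in (True, False)
    ]


def select_best(fits: Sequence[MetModelFit]) -> MetModelFit:
    """Pick the candidate with the highest R^2.

    Ties prefer the more parsimonious no-intercept fit, then the power form.
    """
    if not fits:
        raise DomainError("select_best requires at least one fit")
    return max(
        fits,
        key=lambda f: (f.r_squared, not f.with_intercept, f.form == "power"),
    )


def predict_met(fit: MetModelFit, fmvc: float | np.ndarray) -> float | np.ndarray:
    """Predicted endurance time (min) at relative load fmvc in (0, 1]."""
    arr = np.asarray(fmvc, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise DomainError(f"f_MVC must be in (0, 1], got {fmvc}")
    if fit.form == "power":
        out = fit.k * arr**fit.c
    else:
        out = fit.k * np.exp(fit.c * arr)
    return float(out) if np.isscalar(fmvc) else out


# --- external-model registry -------------------------------------------------

#: User-supplied endurance models from the literature: name -> (f_MVC -> min).
_EXTERNAL_MODELS: dict[str, Callable[[float], float]] = {}


def register_model(name: str, fn: Callable[[float], float]) -> None:
    """Register a named external MET model (a mapping f_MVC -> minutes).

    Published endurance models can be plugged in here for side-by-side
    deviation comparisons; none ship with the package.
    """
    if not callable(fn):
        raise DomainError("external model must be callable")
    _EXTERNAL_MODELS[name] = fn


def get_model(name: str) -> Callable[[float], float]:
    if name not in _EXTERNAL_MODELS:
        raise DomainError(
            f"no external model named {name!r}; registered: {sorted(_EXTERNAL_MODELS)}"
        )
    return _EXTERNAL_MODELS[name]


def registered_models() -> list[str]:
    return sorted(_EXTERNAL_MODELS)
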