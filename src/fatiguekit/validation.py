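"""Model-validation statistics: deviation summaries, correlation,
intraclass correlation, and Bland-Altman agreement.

The headline fit metrics are the absolute deviation AD = |predicted -
measured| and the relative deviation RD = AD / measured (reported in
percent), summarised as mean +/- sample SD. Agreement between measured
and predicted values is quantified with Pearson's r, the two-way
random-effects absolute-agreement single-measures intraclass correlation
ICC(2,1), and a Bland-Altman analysis with limits of agreement at
bias +/- 2 SD of the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import FatigueTrial, RecoverySeries
from .errors import DomainError
from .met import MetModelFit, predict_met
from .recovery import predict_ms


@dataclass(frozen=True)
class DeviationSummary:
    """Mean +/- sample SD of absolute and relative (percent) deviations."""

    ad_mean: float
    ad_sd: float
    rd_mean: float
    rd_sd: float
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """Correlation and Bland-Altman agreement between measured and predicted."""

    pearson_r: float
    icc: float
    bias: float
    loa_low: float
    loa_high: float
    outside_loa: int
    icc_degenerate: bool = False


@dataclass
class ValidationReport:
    """Full hold-out validation: deviations, agreement, per-record table."""

    deviation: DeviationSummary
    agreement: AgreementReport
    records: pd.DataFrame = field(repr=False)


def deviation_summary(
    predicted: Sequence[float], measured: Sequence[float]
) -> DeviationSummary:
    """Per-pair AD = |pred - meas| and RD = AD/meas * 100 %, summarised.

    SDs use the sample (n-1) denominator; with a single pair they are 0.
    """
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if pred.shape != meas.shape or pred.ndim != 1 or len(pred) == 0:
        raise DomainError("predicted and measured must be equal-length 1-d sequences")
    if np.any(meas == 0):
        raise DomainError("measured values must be non-zero for relative deviation")
    ad = np.abs(pred - meas)
    rd = ad / np.abs(meas) * 100.0
    ddof = 1 if len(ad) > 1 else 0
    return DeviationSummary(
        ad_mean=float(ad.mean()),
        ad_sd=float(ad.std(ddof=ddof)),
        rd_mean=float(rd.mean()),
        rd_sd=float(rd.std(ddof=ddof)),
        n=len(ad),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; zero variance in either input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise DomainError("need equal-length sequences of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y)[0])


def icc_agreement(x: Sequence[float], y: Sequence[float]) -> tuple[float, bool]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    The n pairs form an n x 2 subject-by-method table. Unlike Pearson's r,
    this penalises a systematic offset between the two methods, which is
    the right notion of agreement for measured-vs-predicted comparisons.

    Returns ``(icc, degenerate)``; a table with no variance at all has ICC
    defined as 1.0 by convention, flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise DomainError("need equal-length sequences of at least 3 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 1.0, True
    import pingouin as pg

    n = len(x)
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "method": np.repeat(["measured", "predicted"], n),
            "score": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="method", ratings="score"
        )
    # absolute-agreement single-measures row (McGraw & Wong ICC(A,1) == ICC(2,1))
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
    icc2 = table.loc[mask, "ICC"].iloc[0]
    if not np.isfinite(icc2):
        return 1.0, True
    return float(icc2), False


def bland_altman(
    measured: Sequence[float],
    predicted: Sequence[float],
    sd_multiplier: float = 2.0,
) -> tuple[float, float, float, int]:
    """Bland-Altman agreement of measured vs predicted values.

    Differences are measured - predicted; the limits of agreement are
    bias +/- ``sd_multiplier`` * SD(differences) with the multiplier
    defaulting to exactly 2 (1.96 is available by argument).

    Returns ``(bias, loa_low, loa_high, n_outside)``.
    """
    meas = np.asarray(measured, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if meas.shape != pred.shape or meas.ndim != 1 or len(meas) < 2:
        raise DomainError("need equal-length 1-d sequences of at least 2 values")
    d = meas - pred
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - sd_multiplier * sd, bias + sd_multiplier * sd
    outside = int(np.sum((d < loa_low) | (d > loa_high)))
    return bias, loa_low, loa_high, outside


def _agreement(measured: np.ndarray, predicted: np.ndarray) -> AgreementReport:
    bias, lo, hi, outside = bland_altman(measured, predicted)
    icc, degenerate = icc_agreement(measured, predicted)
    if np.ptp(measured) == 0 or np.ptp(predicted) == 0:
        r = 1.0 if np.allclose(measured, predicted) else float("nan")
    else:
        r = pearson_r(measured, predicted)
    return AgreementReport(
        pearson_r=r,
        icc=icc,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        outside_loa=outside,
        icc_degenerate=degenerate,
    )


def validate_met_model(
    model: MetModelFit | Callable[[float], float],
    trials: Iterable[FatigueTrial],
) -> ValidationReport:
    """Validate an endurance model on hold-out trials.

    ``model`` is either a fitted :class:`MetModelFit` or any callable
    f_MVC -> minutes (e.g. a registered literature model). Each trial's
    endurance is predicted from its relative load and compared with the
    measured value.
    """
    trials = list(trials)
    if not trials:
        raise DomainError("validation requires at least one hold-out trial")
    fmvc = np.array([t.fmvc for t in trials])
    measured = np.array([t.met for t in trials])
    if isinstance(model, MetModelFit):
        predicted = np.asarray(predict_met(model, fmvc), dtype=float)
    else:
        predicted = np.array([float(model(f)) for f in fmvc])
    records = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "push_force_N": [t.condition.push_force for t in trials],
            "tool": [t.condition.tool_label for t in trials],
            "fmvc": fmvc,
            "measured_met_min": measured,
            "predicted_met_min": predicted,
        }
    )
    return ValidationReport(
        deviation=deviation_summary(predicted, measured),
        agreement=_agreement(measured, predicted),
        records=records,
    )


def validate_recovery_model(
    rr: float, series: Iterable[RecoverySeries]
) -> ValidationReport:
    """Validate a recovery rate on hold-out recovery series.

    Strength is predicted at every observed minute (including the anchored
    0-min point) from each trial's own MVC and MS0, and compared with the
    measured strengths pooled across series.
    """
    series = list(series)
    if not series:
        raise DomainError("validation requires at least one hold-out series")
    rows = []
    for s in series:
        pred = predict_ms(rr, s.trial.mvc, s.trial.ms0, s.times)
        for t, m, p in zip(s.times, s.ms, np.atleast_1d(pred)):
            rows.append(
                {
                    "participant_id": s.trial.participant_id,
                    "push_force_N": s.trial.condition.push_force,
                    "tool": s.trial.condition.tool_label,
                    "t_min": t,
                    "measured_ms_N": m,
                    "predicted_ms_N": p,
                }
            )
    records = pd.DataFrame(rows)
    measured = records["measured_ms_N"].to_numpy()
    predicted = records["predicted_ms_N"].to_numpy()
    return ValidationReport(
        deviation=deviation_summary(predicted, measured),
        agreement=_agreement(measured, predicted),
        records=records,
    )
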