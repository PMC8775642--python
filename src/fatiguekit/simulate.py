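"""Synthetic cohort, fatigue-trial and recovery-trajectory generator.

Emulates the statistical structure the analysis pipeline assumes, so every
fitting and validation stage can be exercised without access to the original
participant data:

* body mass ~ Normal(68.17, 10.54) kg, truncated at 40 kg (a young male
  cohort);
* per-condition MVC ~ Normal(96, 17) N truncated at 40 N, so that a 40 N
  push never exceeds the baseline strength;
* MET follows a power law in relative load, MET = k * f_MVC^c with
  multiplicative lognormal noise (c defaults to -1.15) — multiplicative
  noise keeps MET positive and reproduces the right skew of endurance
  times;
* post-exertion strength MS0 is a clipped-normal fraction of MVC
  (58.4 +/- 10.1 % MVC);
* recovery follows MS(t) = MS0 + (MVC - MS0)(1 - exp(-RR t)) with additive
  strength noise that is zero at t = 0, so the series anchors exactly at
  MS0;
* CR-10 perceived exertion is a clipped linear function of the strength
  fraction MS/MVC, with coefficients solved from the endpoints of the mean
  time course (7.93 at 58.8 % MVC, 1.43 at 82.1 % MVC), giving the strong
  negative CR-10/strength correlation seen in practice.

Each generator operation draws from its own named random stream derived
from the top-level seed, so adding a generator never perturbs the draws of
an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import Condition, FatigueTrial, Participant, RecoverySeries
from .errors import DomainError

#: Cohort anthropometrics: body mass mean/SD in kg, truncation floor.
BODY_MASS_MEAN = 68.17
BODY_MASS_SD = 10.54
BODY_MASS_FLOOR = 40.0

#: CR-10 at exhaustion: mean and SD of the rating when participants stop.
CR10_EXHAUSTION_MEAN = 7.93
CR10_EXHAUSTION_SD = 0.55

#: Named substreams so each generator op has an independent RNG.
_STREAMS = {"cohort": 0, "fatigue": 1, "recovery": 2}

DEFAULT_CONDITIONS = (
    Condition(20.0, "small"),
    Condition(20.0, "large"),
    Condition(40.0, "small"),
    Condition(40.0, "large"),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    mvc_mean, mvc_sd, mvc_floor : float
        Baseline strength distribution, N; truncated normal.
    true_exponent, true_k : float
        Power-law MET model MET = k * f_MVC^c used to generate endurance
        times (dimensionless).
    met_noise_sd : float
        SD of the lognormal multiplicative MET noise, log-minutes.
    ms0_frac_mean, ms0_frac_sd : float
        Post-exertion strength as a fraction of MVC (clipped to
        [0.2, 0.95] so logs stay defined and f_MVC <= 1).
    rr_true : float
        Recovery rate, 1/min.
    recovery_noise_sd : float
        Additive strength noise during recovery, N (zero at t = 0).
    cr10_intercept, cr10_slope, cr10_noise_sd : float
        Linear map from strength fraction to CR-10 score.
    """

    n_participants: int = 17
    mvc_mean: float = 96.0
    mvc_sd: float = 17.0
    mvc_floor: float = 40.0
    true_exponent: float = -1.15
    true_k: float = 1.0
    met_noise_sd: float = 0.35
    ms0_frac_mean: float = 0.584
    ms0_frac_sd: float = 0.101
    rr_true: float = 0.132
    recovery_noise_sd: float = 2.0
    cr10_intercept: float = 24.333433476394848
    cr10_slope: float = -27.896995708154504
    cr10_noise_sd: float = 0.5
    seed: int = 0
    recovery_times: tuple[float, ...] = tuple(float(t) for t in range(7))
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS

    def __post_init__(self):
        if self.n_participants < 1:
            raise DomainError("n_participants must be >= 1")
        for name in ("mvc_sd", "met_noise_sd", "ms0_frac_sd", "recovery_noise_sd",
                     "cr10_noise_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not 0 < self.ms0_frac_mean < 1:
            raise DomainError("ms0_frac_mean must be in (0, 1)")
        if self.rr_true <= 0:
            raise DomainError("rr_true must be > 0")
        if self.mvc_floor <= 0:
            raise DomainError("mvc_floor must be > 0")

    def noise_free(self) -> "GeneratorParams":
        """A copy with every noise SD set to zero (exact model trajectories)."""
        return replace(
            self,
            mvc_sd=0.0,
            met_noise_sd=0.0,
            ms0_frac_sd=0.0,
            recovery_noise_sd=0.0,
            cr10_noise_sd=0.0,
        )


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, max(mean, floor))
    a = (floor - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: GeneratorParams) -> list[Participant]:
    """Draw participants with body mass and one MVC per condition.

    Deterministic given ``params.seed``.
    """
    rng = _stream(params.seed, "cohort")
    n = params.n_participants
    masses = _truncated_normal(rng, BODY_MASS_MEAN, BODY_MASS_SD, BODY_MASS_FLOOR, n)
    cohort = []
    for i in range(n):
        mvcs = _truncated_normal(
            rng, params.mvc_mean, params.mvc_sd, params.mvc_floor, len(params.conditions)
        )
        cohort.append(
            Participant(
                id=f"P{i + 1:02d}",
                body_mass=float(masses[i]),
                mvc_by_condition={c.key: float(m) for c, m in zip(params.conditions, mvcs)},
            )
        )
    return cohort


def generate_fatigue_trial(
    participant: Participant,
    condition: Condition,
    params: GeneratorParams,
    rng: np.random.Generator,
    infeasible: str = "resample",
) -> FatigueTrial:
    """Generate one exhaustive push for a participant under a condition.

    MET = true_k * f_MVC^true_exponent * exp(eps), eps ~ N(0, met_noise_sd);
    MS0 = MVC * clip(N(ms0_frac_mean, ms0_frac_sd), 0.2, 0.95);
    CR-10 at exhaustion ~ clip(N(7.93, 0.55), 0, 10).

    If the cached MVC does not exceed the push force, the ``infeasible``
    policy applies: ``"resample"`` redraws MVC until feasible, ``"error"``
    raises.
    """
    mvc = participant.mvc_by_condition.get(condition.key)
    if mvc is None:
        mvc = float(
            _truncated_normal(rng, params.mvc_mean, params.mvc_sd, params.mvc_floor, 1)[0]
        )
    while mvc <= condition.push_force:
        if infeasible == "error":
            raise DomainError(
                f"push force {condition.push_force} N is not below MVC {mvc} N "
                f"for participant {participant.id}"
            )
        mvc = float(
            _truncated_normal(rng, params.mvc_mean, params.mvc_sd, params.mvc_floor, 1)[0]
        )
    fmvc = condition.push_force / mvc
    eps = rng.normal(0.0, params.met_noise_sd) if params.met_noise_sd > 0 else 0.0
    met = params.true_k * fmvc**params.true_exponent * np.exp(eps)
    frac = rng.normal(params.ms0_frac_mean, params.ms0_frac_sd)
    frac = float(np.clip(frac, 0.2, 0.95))
    cr10_0 = float(np.clip(rng.normal(CR10_EXHAUSTION_MEAN, CR10_EXHAUSTION_SD), 0.0, 10.0))
    return FatigueTrial(
        participant_id=participant.id,
        condition=condition,
        mvc=mvc,
        met=float(met),
        ms0=frac * mvc,
        cr10_0=cr10_0,
    )


def generate_recovery_series(
    trial: FatigueTrial, params: GeneratorParams, rng: np.random.Generator
) -> RecoverySeries:
    """Generate the per-minute recovery trajectory for one trial.

    Strength follows the exponential recovery model with additive noise
    (zero at t = 0) and is clipped to (0, MVC]; CR-10 is the clipped linear
    map of the noisy strength fraction.
    """
    t = np.asarray(params.recovery_times, dtype=float)
    deficit = trial.mvc - trial.ms0
    ms = trial.ms0 + deficit * (1.0 - np.exp(-params.rr_true * t))
    if params.recovery_noise_sd > 0:
        eta = rng.normal(0.0, params.recovery_noise_sd, size=len(t))
        eta[0] = 0.0
        ms = ms + eta
    ms = np.clip(ms, np.finfo(float).tiny, trial.mvc)
    cr10 = params.cr10_intercept + params.cr10_slope * ms / trial.mvc
    if params.cr10_noise_sd > 0:
        zeta = rng.normal(0.0, params.cr10_noise_sd, size=len(t))
        cr10 = cr10 + zeta
    cr10 = np.clip(cr10, 0.0, 10.0)
    return RecoverySeries(trial=trial, times=t, ms=ms, cr10=cr10)


@dataclass
class SyntheticDataset:
    """A complete synthetic study: cohort, trials, recovery series."""

    participants: list[Participant]
    trials: list[FatigueTrial]
    recovery: list[RecoverySeries]
    params: GeneratorParams = field(repr=False, default=None)


def generate_dataset(params: GeneratorParams) -> SyntheticDataset:
    """Generate the full factorial study: every participant x condition."""
    cohort = generate_cohort(params)
    fatigue_rng = _stream(params.seed, "fatigue")
    recovery_rng = _stream(params.seed, "recovery")
    trials = []
    series = []
    for participant in cohort:
        for condition in params.conditions:
            trial = generate_fatigue_trial(participant, condition, params, fatigue_rng)
            trials.append(trial)
            series.append(generate_recovery_series(trial, params, recovery_rng))
    return SyntheticDataset(cohort, trials, series, params)
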