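"""Domain types and dataset partitions for fatigue/recovery trials.

The experimental unit is an exhaustive static push with a hand-held tool:
the participant pushes at a fixed force until exhaustion (yielding the
maximum endurance time, MET), and strength plus Borg CR-10 perceived
exertion are then tracked once per minute of rest.

Units are fixed throughout the package: forces and strengths in newtons,
times in minutes, masses in kilograms. There is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, PartitionError, RecordError

#: Default tool weights in kg, keyed by tool label.
TOOL_WEIGHTS: dict[str, float] = {"small": 1.5, "large": 5.6}

#: Tolerance (N) for the 0-min recovery observation to match the trial's MS0.
MS0_CONSISTENCY_TOL = 1e-6


@dataclass(frozen=True)
class Condition:
    """One experimental condition: target push force and tool.

    Parameters
    ----------
    push_force : float
        Target push force in newtons (default conditions use 20 or 40 N).
    tool_label : str
        ``"small"`` or ``"large"``.
    tool_weight : float
        Tool mass in kg; defaults are 1.5 kg (small) and 5.6 kg (large).
    """

    push_force: float
    tool_label: str
    tool_weight: float = 0.0

    def __post_init__(self):
        if self.push_force <= 0:
            raise RecordError(f"push_force must be > 0, got {self.push_force}")
        if self.tool_weight == 0.0 and self.tool_label in TOOL_WEIGHTS:
            object.__setattr__(self, "tool_weight", TOOL_WEIGHTS[self.tool_label])
        if self.tool_weight <= 0:
            raise RecordError(f"tool_weight must be > 0, got {self.tool_weight}")

    @property
    def key(self) -> tuple[float, str]:
        return (self.push_force, self.tool_label)


@dataclass
class Participant:
    """A study participant; ``mvc_by_condition`` caches per-condition MVC (N)."""

    id: str
    body_mass: float
    stature: float | None = None
    mvc_by_condition: dict[tuple[float, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.body_mass <= 0:
            raise RecordError(f"body_mass must be > 0, got {self.body_mass}")
        for key, mvc in self.mvc_by_condition.items():
            if mvc <= 0:
                raise RecordError(f"cached MVC for {key} must be > 0, got {mvc}")


@dataclass
class FatigueTrial:
    """One exhaustive push: condition, baseline MVC, endurance time, and
    post-exertion state.

    Attributes
    ----------
    mvc : float
        Maximum voluntary contraction before the push, N.
    met : float
        Maximum endurance time, min.
    ms0 : float
        Muscle strength immediately after exhaustion, N (0 < ms0 <= mvc).
    cr10_0 : float
        Borg CR-10 rating at exhaustion, in [0, 10].
    """

    participant_id: str
    condition: Condition
    mvc: float
    met: float
    ms0: float
    cr10_0: float

    def __post_init__(self):
        if self.mvc <= 0:
            raise RecordError(f"mvc must be > 0, got {self.mvc}")
        if not 0 < self.ms0 <= self.mvc:
            raise RecordError(f"require 0 < ms0 <= mvc, got ms0={self.ms0}, mvc={self.mvc}")
        if not 0 < self.condition.push_force <= self.mvc:
            raise RecordError(
                f"push_force {self.condition.push_force} exceeds mvc {self.mvc} (f_MVC > 1)"
            )
        if self.met <= 0:
            raise RecordError(f"met must be > 0, got {self.met}")
        if not 0 <= self.cr10_0 <= 10:
            raise RecordError(f"cr10_0 must be in [0, 10], got {self.cr10_0}")

    @property
    def fmvc(self) -> float:
        """Relative load f_MVC = push force / MVC."""
        return self.condition.push_force / self.mvc

    @property
    def key(self) -> tuple[str, float, str]:
        return (self.participant_id, self.condition.push_force, self.condition.tool_label)


@dataclass
class RecoverySeries:
    """Per-minute strength and CR-10 observations after exhaustion.

    ``times`` must start at 0 and be strictly increasing; the 0-min strength
    must equal the trial's MS0 (within ``MS0_CONSISTENCY_TOL``) because the
    end of the fatigue test is the start of recovery.
    """

    trial: FatigueTrial
    times: np.ndarray
    ms: np.ndarray
    cr10: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ms = np.asarray(self.ms, dtype=float)
        self.cr10 = np.asarray(self.cr10, dtype=float)
        if not (len(self.times) == len(self.ms) == len(self.cr10)):
            raise RecordError("times, ms and cr10 must have equal length")
        if len(self.times) == 0:
            raise RecordError("recovery series must have at least one observation")
        if np.any(np.diff(self.times) <= 0):
            raise RecordError("times must be strictly increasing")
        if self.times[0] != 0:
            raise RecordError(f"times must start at 0, got {self.times[0]}")
        if abs(self.ms[0] - self.trial.ms0) > MS0_CONSISTENCY_TOL:
            raise RecordError(
                f"0-min strength {self.ms[0]} does not match trial ms0 {self.trial.ms0}"
            )
        if np.any(self.ms <= 0):
            raise RecordError("all strengths must be > 0")
        if np.any((self.cr10 < 0) | (self.cr10 > 10)):
            raise RecordError("all CR-10 scores must be in [0, 10]")


# --- relative-weight grouping -----------------------------------------------

#: Default relative-weight bins in percent of body mass: (low, high, label).
DEFAULT_RW_BINS: tuple[tuple[float, float, str], ...] = (
    (1.9, 4.7, "L"),
    (4.8, 7.5, "N"),
    (7.6, 10.3, "H"),
)


@dataclass(frozen=True)
class RwGroup:
    """Tool weight relative to body weight, as percent, with its bin label.

    ``in_gap`` flags values that fell between or outside the (rounded) bins
    and were assigned to the nearest bin.
    """

    rw: float
    label: str
    in_gap: bool = False
    bin_edges: tuple[tuple[float, float, str], ...] = DEFAULT_RW_BINS


def assign_rw_group(
    tool_weight: float,
    body_mass: float,
    bin_edges: tuple[tuple[float, float, str], ...] = DEFAULT_RW_BINS,
) -> RwGroup:
    """Compute relative weight RW = 100 * tool_weight / body_mass and bin it.

    Values in the gaps between the rounded bin edges (or beyond the outer
    edges) map to the nearest bin with ``in_gap=True`` rather than erroring:
    the published bin edges are rounded to one decimal.
    """
    if tool_weight <= 0 or body_mass <= 0:
        raise DomainError(
            f"masses must be > 0, got tool_weight={tool_weight}, body_mass={body_mass}"
        )
    rw = 100.0 * tool_weight / body_mass
    for low, high, label in bin_edges:
        if low <= rw <= high:
            return RwGroup(rw=rw, label=label, bin_edges=bin_edges)
    # nearest bin by distance to the closed interval; exact ties (e.g. the
    # midpoint of a gap between rounded edges) go to the lower bin
    def dist(bin_: tuple[float, float, str]) -> float:
        low, high, _ = bin_
        return max(low - rw, rw - high, 0.0)

    nearest = min(bin_edges, key=dist)
    return RwGroup(rw=rw, label=nearest[2], in_gap=True, bin_edges=bin_edges)


# --- A/B split ---------------------------------------------------------------

#: Default membership map for the fit/validate split: condition key -> group.
DEFAULT_AB_MAP: dict[tuple[float, str], str] = {
    (20.0, "small"): "A",
    (40.0, "large"): "A",
    (20.0, "large"): "B",
    (40.0, "small"): "B",
}


def split_ab(
    trials: list[FatigueTrial],
    membership: dict[tuple[float, str], str] | None = None,
) -> tuple[list[FatigueTrial], list[FatigueTrial]]:
    """Partition trials into fitting group A and validation group B.

    The default split crosses force with tool so each group sees both force
    levels and both tools: A = {(20 N, small), (40 N, large)},
    B = {(20 N, large), (40 N, small)}. A custom ``membership`` map
    (condition key -> "A" | "B") overrides it.

    Raises
    ------
    PartitionError
        If a trial's condition is not in the membership map.
    """
    mapping = DEFAULT_AB_MAP if membership is None else membership
    group_a: list[FatigueTrial] = []
    group_b: list[FatigueTrial] = []
    for trial in trials:
        key = (float(trial.condition.push_force), trial.condition.tool_label)
        group = mapping.get(key)
        if group == "A":
            group_a.append(trial)
        elif group == "B":
            group_b.append(trial)
        else:
            raise PartitionError(
                f"condition {key} is not assigned to a group; "
                f"known conditions: {sorted(mapping)}"
            )
    return group_a, group_b


def is_close(a: float, b: float, tol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)
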