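"""End-to-end analysis: simulate or load data, split into fitting and
validation groups, fit the endurance and recovery models on group A,
validate both on group B, and write machine-readable JSON reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import Condition, FatigueTrial, split_ab
from .errors import DomainError
from .io import read_recovery, read_trials
from .met import fit_candidates, select_best
from .recovery import fit_rr, time_to_fraction
from .simulate import GeneratorParams, generate_dataset
from .validation import validate_met_model, validate_recovery_model

log = logging.getLogger("fatiguekit")


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    Exactly one data source: either CSV paths (``trials_path`` and
    ``recovery_path``) or synthetic-generator parameters (``generator``).
    """

    trials_path: str | None = None
    recovery_path: str | None = None
    generator: GeneratorParams | None = None
    membership: dict | None = None
    recovery_mode: str = "pooled"
    target_fraction: float = 0.95
    ms0_fraction: float | None = None
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        have_paths = self.trials_path is not None
        have_gen = self.generator is not None
        if have_paths == have_gen:
            raise DomainError(
                "exactly one of trials_path/recovery_path or generator must be set"
            )
        if not 0 < self.target_fraction < 1:
            raise DomainError("target_fraction must be in (0, 1)")


def load_config(path: str | Path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML or JSON file.

    Recognised keys mirror the dataclass fields; ``generator`` may be a
    mapping of :class:`GeneratorParams` fields. ``membership`` entries are
    ``[push_force, tool, group]`` triples.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise DomainError(f"config {path} must be a mapping")
    if isinstance(raw.get("generator"), dict):
        gen = dict(raw["generator"])
        if "conditions" in gen:
            gen["conditions"] = tuple(Condition(**c) for c in gen["conditions"])
        raw["generator"] = GeneratorParams(**gen)
    if isinstance(raw.get("membership"), list):
        raw["membership"] = {
            (float(force), str(tool)): str(group)
            for force, tool, group in raw["membership"]
        }
    return AnalysisConfig(**raw)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(_to_jsonable(dataclasses.asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def summarize_conditions(trials: list[FatigueTrial]) -> pd.DataFrame:
    """Per-condition endurance summary: n, mean, sample SD of MET, grouped
    by (push force, tool), plus pooled rows per force level.

    With a single trial in a cell the SD is reported as NaN.
    """
    if not trials:
        raise DomainError("summarize_conditions requires at least one trial")
    df = pd.DataFrame(
        {
            "push_force_N": [t.condition.push_force for t in trials],
            "tool": [t.condition.tool_label for t in trials],
            "met_min": [t.met for t in trials],
        }
    )
    per_cell = (
        df.groupby(["push_force_N", "tool"])["met_min"]
        .agg(n="count", met_mean="mean", met_sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    pooled = (
        df.groupby("push_force_N")["met_min"]
        .agg(n="count", met_mean="mean", met_sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    pooled.insert(1, "tool", "all")
    return pd.concat([per_cell, pooled], ignore_index=True)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline and write the report bundle to ``out_dir``.

    Outputs: ``met_fit.json`` (all candidate fits and the selection),
    ``recovery_fit.json``, ``validation.json`` (group-B validation of
    both models), ``recovery_time.json`` (minutes to the target strength
    fraction) and ``run_log.json``. Idempotent for a fixed seed.

    Returns the bundle as a dict keyed by report name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        dataset = generate_dataset(config.generator)
        trials, series = dataset.trials, dataset.recovery
    else:
        trials = read_trials(config.trials_path)
        series = (
            read_recovery(config.recovery_path, trials) if config.recovery_path else []
        )

    group_a, group_b = split_ab(trials, membership=config.membership)
    log.info("split: %d trials in group A, %d in group B", len(group_a), len(group_b))
    keys_a = {t.key for t in group_a}
    keys_b = {t.key for t in group_b}
    series_a = [s for s in series if s.trial.key in keys_a]
    series_b = [s for s in series if s.trial.key in keys_b]

    # --- fit on group A
    candidates = fit_candidates(group_a)
    best = select_best(candidates)
    met_report = {"candidates": candidates, "selected": best}

    recovery_report = {}
    if series_a:
        if config.recovery_mode == "per_trial":
            fits = [fit_rr(s) for s in series_a]
            pooled = fit_rr(series_a)
            recovery_report = {"pooled": pooled, "per_trial": fits}
        else:
            pooled = fit_rr(series_a)
            recovery_report = {"pooled": pooled}
        log.info("recovery fit: RR=%.4f /min on %d points (%d excluded)",
                 pooled.rr, pooled.n_points, pooled.excluded_points)

    # --- validate on group B
    validation_report = {}
    if group_b:
        validation_report["met"] = validate_met_model(best, group_b)
    if series_b and recovery_report:
        validation_report["recovery"] = validate_recovery_model(pooled.rr, series_b)

    # --- recovery-time extrapolation
    recovery_time_report = {}
    if recovery_report:
        if config.ms0_fraction is not None:
            ms0_frac = config.ms0_fraction
        else:
            ms0_frac = float(np.mean([t.ms0 / t.mvc for t in trials]))
        minutes = time_to_fraction(pooled.rr, ms0_frac, config.target_fraction)
        recovery_time_report = {
            "rr_per_min": pooled.rr,
            "ms0_fraction": ms0_frac,
            "target_fraction": config.target_fraction,
            "minutes": minutes,
        }

    run_log = {
        "seed": config.seed,
        "fatiguekit_version": __version__,
        "config_hash": _config_hash(config),
        "n_trials": len(trials),
        "n_recovery_series": len(series),
        "group_sizes": {"A": len(group_a), "B": len(group_b)},
    }

    bundle = {
        "met_fit": met_report,
        "recovery_fit": recovery_report,
        "validation": validation_report,
        "recovery_time": recovery_time_report,
        "run_log": run_log,
    }
    written = []
    try:
        for name, payload in bundle.items():
            path = out_dir / f"{name}.json"
            _write_json(payload, path)
            written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return bundle
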