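"""Seeded smart-home event-log simulator with planted ground truth.

Emulates a CASAS-style cognitive-assessment session: two cohorts of
residents (healthy and dementia) each perform the same set of scripted
activities in a home instrumented with motion (Mxx), door (Dxx), item
(Ixx), temperature (Txx), light (LLxxx), utility (AD1-x) and power
(P001) sensors.  Each activity span triggers a small set of *planted*
informative sensors at an elevated Poisson rate and every other sensor
at a low background rate, with event times uniform within the span.
The dementia profile stretches activity durations, raises the rate of
off-task "wander" events, and aborts spans early more often — the
qualitative signature of impaired task completion, encoded as tunable
parameters.

The planted map is the ground truth for selection-recovery experiments;
the per-participant manifests carry labels, cohorts and completeness
for recognition experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from keysense.events import Annotation, EventLog, SensorEvent, write_casas_log, read_casas_log
from keysense.instances import FeatureMatrix, build_feature_matrix, segment_activities
from keysense.pkfs import SelectionResult

__all__ = [
    "ResidentProfile",
    "SimulationConfig",
    "default_inventory",
    "default_planted",
    "healthy_profile",
    "dementia_profile",
    "null_config",
    "matched_cohort_config",
    "simulate_participant",
    "make_cohort_dataset",
    "planted_recall",
]

_BASE_TS = datetime(2011, 6, 15, 8, 0, 0)

_FAMILY_VALUES = {
    "M": "ON",
    "D": "OPEN",
    "I": "PRESENT",
    "T": "21.5",
    "L": "55",
    "A": "ON",   # AD1-x utility sensors
    "P": "1200",
}


def default_inventory() -> list[str]:
    """62 sensor ids across the CASAS-style families."""
    inv = [f"M{i:03d}" for i in range(1, 31)]
    inv += [f"D{i:03d}" for i in range(1, 11)]
    inv += [f"I{i:03d}" for i in range(1, 9)]
    inv += [f"T{100 + i}" for i in range(1, 6)]
    inv += [f"LL{i:03d}" for i in range(1, 6)]
    inv += ["AD1-A", "AD1-B", "AD1-C", "P001"]
    return inv


def default_planted(
    inventory: list[str] | None = None, activities: tuple[int, ...] = tuple(range(1, 9))
) -> dict[int, tuple[str, ...]]:
    """Five disjoint informative sensors per activity, drawn from the
    motion/door pool."""
    inv = inventory if inventory is not None else default_inventory()
    pool = [s for s in inv if s[0] in ("M", "D")]
    if len(pool) < 5 * len(activities):
        raise ValueError("inventory too small for 5 planted sensors per activity")
    return {
        a: tuple(pool[5 * i : 5 * i + 5]) for i, a in enumerate(activities)
    }


@dataclass
class SimulationConfig:
    """Study-level knobs: cohort sizes, home inventory, planted signal,
    and the cohort behavioral parameters."""

    n_healthy: int = 65
    n_dementia: int = 14
    activities: tuple[int, ...] = tuple(range(1, 9))
    inventory: list[str] = field(default_factory=default_inventory)
    planted: dict[int, tuple[str, ...]] | None = None
    planted_rate: float = 8.0
    background_rate: float = 0.4
    base_duration_s: float = 120.0
    duration_step_s: float = 30.0  # per-activity increment; 0 → identical durations
    duration_sigma: float = 0.2  # log-normal dispersion (ln scale)
    dementia_duration_mult: float = 1.5
    healthy_wander: float = 0.5  # off-task events per minute
    dementia_wander: float = 2.5  # 5x the healthy rate
    healthy_incomplete: float = 0.02
    dementia_incomplete: float = 0.3
    dementia_repetition: float = 1.5  # task-sensor re-trigger multiplier
    gap_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_dementia < 0:
            raise ValueError("need >= 1 healthy participant, >= 0 dementia")
        if self.planted is None:
            self.planted = default_planted(self.inventory, self.activities)
        for a, sensors in self.planted.items():
            if not set(sensors) <= set(self.inventory):
                raise ValueError(f"planted sensors for activity {a} not in inventory")


@dataclass
class ResidentProfile:
    """One cohort's generative behavior, expanded per activity.

    ``sensor_rates`` gives each sensor's expected trigger count for a
    span of the activity's *nominal* (cohort-independent) duration; the
    realized count scales with the actual span length, so slower
    residents accumulate proportionally more triggers and aborted spans
    proportionally fewer.
    """

    cohort: str
    activity_durations: dict[int, tuple[float, float]]  # median_s, ln-sigma
    nominal_durations: dict[int, float]  # cohort-independent reference medians
    sensor_rates: dict[int, dict[str, float]]  # activity -> sensor -> Poisson mean
    wander_rate: float  # expected off-task events per minute
    incomplete_prob: float

    def __post_init__(self) -> None:
        if not 0 <= self.incomplete_prob <= 1:
            raise ValueError("incomplete_prob must lie in [0, 1]")
        if self.wander_rate < 0:
            raise ValueError("wander_rate must be >= 0")
        for rates in self.sensor_rates.values():
            if any(r < 0 for r in rates.values()):
                raise ValueError("sensor rates must be >= 0")


def _profile(config: SimulationConfig, cohort: str) -> ResidentProfile:
    mult = config.dementia_duration_mult if cohort == "dementia" else 1.0
    nominal = {
        a: config.base_duration_s + config.duration_step_s * i
        for i, a in enumerate(config.activities)
    }
    durations = {a: (mult * nominal[a], config.duration_sigma) for a in config.activities}
    # confusion and re-doing of sub-tasks re-triggers the task's sensors:
    # the dementia profile scales every in-activity rate up
    repeat = config.dementia_repetition if cohort == "dementia" else 1.0
    rates = {}
    for a in config.activities:
        planted = set(config.planted.get(a, ()))
        rates[a] = {
            s: repeat
            * (config.planted_rate if s in planted else config.background_rate)
            for s in config.inventory
        }
    return ResidentProfile(
        cohort=cohort,
        activity_durations=durations,
        nominal_durations=nominal,
        sensor_rates=rates,
        wander_rate=config.dementia_wander if cohort == "dementia" else config.healthy_wander,
        incomplete_prob=config.dementia_incomplete
        if cohort == "dementia"
        else config.healthy_incomplete,
    )


def healthy_profile(config: SimulationConfig | None = None) -> ResidentProfile:
    return _profile(config or SimulationConfig(), "healthy")


def dementia_profile(config: SimulationConfig | None = None) -> ResidentProfile:
    return _profile(config or SimulationConfig(), "dementia")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Zero-signal control: no planted sensors, identical duration
    distributions across activities.  Activity labels are then pure
    noise to the recognizer."""
    return SimulationConfig(
        planted={a: () for a in overrides.get("activities", tuple(range(1, 9)))},
        duration_step_s=0.0,
        seed=seed,
        **overrides,
    )


def matched_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort null control: dementia behavioral parameters set equal to
    the healthy ones, so the cohorts differ only by label."""
    cfg = SimulationConfig(seed=seed, **overrides)
    return replace(
        cfg,
        dementia_duration_mult=1.0,
        dementia_wander=cfg.healthy_wander,
        dementia_incomplete=cfg.healthy_incomplete,
        dementia_repetition=1.0,
    )


def _value_for(sensor_id: str) -> str:
    return _FAMILY_VALUES.get(sensor_id[0], "ON")


def _ms(seconds: float) -> timedelta:
    return timedelta(milliseconds=round(seconds * 1000))


def simulate_participant(
    profile: ResidentProfile,
    activities: tuple[int, ...],
    seed: int,
    start_ts: datetime = _BASE_TS,
) -> tuple[EventLog, dict]:
    """One participant's annotated session.

    Activities run back-to-back with an off-task gap between them.  For
    each activity: a duration is drawn log-normally (truncated early
    with probability ``incomplete_prob``), the start marker rides the
    first event of the span, each sensor fires Poisson-many times at
    uniform times within the span, wander events are superimposed at
    ``wander_rate`` per minute (inside the span and in the following
    gap), and the end marker rides the last event.  Deterministic given
    the seed.

    Returns the event log and a truth manifest (cohort, per-activity
    completeness).
    """
    rng = np.random.default_rng(seed)
    events: list[SensorEvent] = []
    completeness: dict[int, bool] = {}
    inventory = sorted(profile.sensor_rates[activities[0]])
    t = start_ts
    for a in activities:
        median, sigma = profile.activity_durations[a]
        duration = float(median * np.exp(sigma * rng.standard_normal()))
        complete = True
        if rng.random() < profile.incomplete_prob:
            complete = False
            duration *= rng.uniform(0.2, 0.6)
        duration = max(duration, 2.0)
        completeness[a] = complete

        rates = profile.sensor_rates[a]
        time_scale = duration / profile.nominal_durations[a]
        span_events: list[tuple[float, str]] = []
        for sensor in inventory:
            lam = rates[sensor] * time_scale
            if lam <= 0:
                continue
            for offset in rng.uniform(0.001, duration - 0.001, rng.poisson(lam)):
                span_events.append((float(offset), sensor))
        n_wander = rng.poisson(profile.wander_rate * duration / 60.0)
        for offset in rng.uniform(0.001, duration - 0.001, n_wander):
            span_events.append((float(offset), inventory[rng.integers(len(inventory))]))
        span_events.sort(key=lambda p: p[0])

        marker_sensor = span_events[0][1] if span_events else inventory[0]
        events.append(
            SensorEvent(t, marker_sensor, _value_for(marker_sensor), Annotation(a, "start"))
        )
        for offset, sensor in span_events:
            events.append(SensorEvent(t + _ms(offset), sensor, _value_for(sensor)))
        end_sensor = span_events[-1][1] if span_events else inventory[0]
        events.append(
            SensorEvent(
                t + _ms(duration), end_sensor, _value_for(end_sensor), Annotation(a, "end")
            )
        )

        # off-task events in the inter-activity gap: outside every span,
        # the segmenter must discard them
        n_gap = rng.poisson(profile.wander_rate * 0.5)
        for offset in rng.uniform(0.001, 0.5 * 60.0, n_gap):
            sensor = inventory[rng.integers(len(inventory))]
            events.append(SensorEvent(t + _ms(duration + offset), sensor, _value_for(sensor)))
        t = t + _ms(duration + 60.0)

    manifest = {
        "cohort": profile.cohort,
        "activities": list(activities),
        "completeness": completeness,
    }
    return EventLog(events=events, source_name=f"sim-{profile.cohort}-{seed}"), manifest


def make_cohort_dataset(config: SimulationConfig) -> tuple[FeatureMatrix, dict]:
    """Simulate the full cohort and run the ingestion pipeline end to end.

    Every participant's log is serialized and re-parsed through the
    event-log reader, segmented, and assembled into one labeled feature
    matrix; row count = participants x activities (incomplete spans
    still yield instances, flagged incomplete).  The truth manifest
    carries the planted map and the per-participant cohort/completeness
    records.
    """
    rng = np.random.default_rng(config.seed)
    instances = []
    participants: dict[str, dict] = {}
    roster = [("healthy", f"h{i + 1:03d}") for i in range(config.n_healthy)]
    roster += [("dementia", f"d{i + 1:03d}") for i in range(config.n_dementia)]
    for cohort, pid in roster:
        profile = _profile(config, cohort)
        pseed = int(rng.integers(0, 2**31 - 1))
        log, manifest = simulate_participant(profile, config.activities, pseed)
        log = read_casas_log(write_casas_log(log).splitlines(), source_name=pid)
        instances.extend(
            segment_activities(log, pid, cohort, completeness=manifest["completeness"])
        )
        participants[pid] = manifest
    matrix = build_feature_matrix(instances, config.inventory)
    truth = {
        "planted": {a: list(s) for a, s in config.planted.items()},
        "participants": participants,
        "seed": config.seed,
    }
    return matrix, truth


def planted_recall(selection: SelectionResult, truth: dict) -> float:
    """Fraction of the planted informative sensors recovered by the
    selection's union set."""
    planted = {s for sensors in truth["planted"].values() for s in sensors}
    if not planted:
        raise ValueError("no planted sensors in the truth manifest")
    return len(planted & set(selection.union_set)) / len(planted)
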