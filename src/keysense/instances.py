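"""Segmenting annotated event logs into activity instances and building
the instance-by-feature count matrix.

An *activity instance* is one participant's one attempt at one activity:
all sensor events between the activity's start and end markers, reduced
to per-sensor trigger counts plus three summary features (duration in
seconds, number of distinct sensors triggered, and a completeness flag).
Activities may interleave; an event falling inside two open spans is
credited to both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from keysense.events import EventLog

__all__ = [
    "SUMMARY_FEATURES",
    "ActivityInstance",
    "FeatureMatrix",
    "SegmentationError",
    "segment_activities",
    "build_feature_matrix",
]

#: Summary columns appended after the per-sensor count columns.
SUMMARY_FEATURES = ("duration_s", "unique_sensor_events", "completeness")


class SegmentationError(ValueError):
    """Raised when start/end activity markers are not properly paired."""


@dataclass
class ActivityInstance:
    """One segmented activity span with its per-sensor trigger counts.

    Every in-span event of a sensor counts once regardless of its value
    (ON and OFF transitions both count as triggers).
    """

    class_label: int
    participant_id: str
    cohort: str
    start_ts: datetime
    end_ts: datetime
    sensor_counts: Counter = field(default_factory=Counter)
    completeness: bool = True

    def __post_init__(self) -> None:
        if self.end_ts < self.start_ts:
            raise ValueError("end_ts must be >= start_ts")
        if any(c < 0 for c in self.sensor_counts.values()):
            raise ValueError("sensor counts must be non-negative")

    @property
    def duration_s(self) -> float:
        return (self.end_ts - self.start_ts).total_seconds()

    @property
    def unique_sensor_events(self) -> int:
        return sum(1 for c in self.sensor_counts.values() if c > 0)


@dataclass
class FeatureMatrix:
    """Instances-by-features table with class / cohort / participant labels.

    ``data`` holds the numeric feature columns only; labels ride alongside
    and are never numeric columns.  Sensors absent from an instance carry
    an explicit zero.
    """

    data: pd.DataFrame
    class_labels: np.ndarray
    cohorts: np.ndarray
    participant_ids: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.data)
        self.class_labels = np.asarray(self.class_labels)
        self.cohorts = np.asarray(self.cohorts)
        self.participant_ids = np.asarray(self.participant_ids)
        for name, arr in (
            ("class_labels", self.class_labels),
            ("cohorts", self.cohorts),
            ("participant_ids", self.participant_ids),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} rows")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def take_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        """Row subset (positional), labels kept aligned."""
        idx = np.asarray(idx)
        return FeatureMatrix(
            data=self.data.iloc[idx].reset_index(drop=True),
            class_labels=self.class_labels[idx],
            cohorts=self.cohorts[idx],
            participant_ids=self.participant_ids[idx],
        )

    def with_data(self, data: pd.DataFrame) -> "FeatureMatrix":
        """Same rows/labels, different feature columns."""
        if len(data) != self.n_rows:
            raise ValueError("replacement data must keep the row count")
        return FeatureMatrix(
            data=data.reset_index(drop=True),
            class_labels=self.class_labels,
            cohorts=self.cohorts,
            participant_ids=self.participant_ids,
        )


def segment_activities(
    log: EventLog,
    participant_id: str,
    cohort: str,
    completeness: Union[bool, Mapping[int, bool]] = True,
) -> list[ActivityInstance]:
    """Cut an annotated log into activity instances.

    Walks the event stream keeping the set of currently-open activity
    spans.  Every event (including the marker events themselves) is
    credited to every span open at its timestamp; events outside all
    spans are discarded.  ``completeness`` is supplied by the caller —
    either one flag for the whole session or a per-activity mapping —
    because finishing "all eight actions" is session-level knowledge the
    segmenter cannot infer.

    Raises
    ------
    SegmentationError
        On an end marker without an open start, a start while the same
        activity is already open, or a span left open at end of log.
    """
    open_spans: dict[int, ActivityInstance] = {}
    instances: list[ActivityInstance] = []

    def complete_flag(activity_id: int) -> bool:
        if isinstance(completeness, Mapping):
            return bool(completeness.get(activity_id, True))
        return bool(completeness)

    for event in log:
        ann = event.annotation
        if ann is not None and ann.marker == "start":
            if ann.activity_id in open_spans:
                raise SegmentationError(
                    f"activity {ann.activity_id} started again at "
                    f"{event.timestamp} while still open"
                )
            open_spans[ann.activity_id] = ActivityInstance(
                class_label=ann.activity_id,
                participant_id=participant_id,
                cohort=cohort,
                start_ts=event.timestamp,
                end_ts=event.timestamp,
                completeness=complete_flag(ann.activity_id),
            )
        for span in open_spans.values():
            span.sensor_counts[event.sensor_id] += 1
        if ann is not None and ann.marker == "end":
            span = open_spans.pop(ann.activity_id, None)
            if span is None:
                raise SegmentationError(
                    f"end marker for activity {ann.activity_id} at "
                    f"{event.timestamp} without an open start"
                )
            span.end_ts = event.timestamp
            instances.append(span)
    if open_spans:
        open_ids = sorted(open_spans)
        raise SegmentationError(f"unclosed activity span(s) at end of log: {open_ids}")
    return instances


def build_feature_matrix(
    instances: Sequence[ActivityInstance],
    sensor_inventory: Sequence[str],
) -> FeatureMatrix:
    """Assemble the count matrix: one row per instance, one column per
    inventory sensor (canonical lexicographic order, zeros for sensors
    the instance never triggered) followed by the summary features.

    Raises
    ------
    ValueError
        If no instances are given or an instance references a sensor
        outside the inventory.
    """
    if not instances:
        raise ValueError("need at least one instance")
    inventory = sorted(set(sensor_inventory))
    known = set(inventory)
    for inst in instances:
        extra = set(inst.sensor_counts) - known
        if extra:
            raise ValueError(
                f"instance for activity {inst.class_label} of "
                f"{inst.participant_id} references sensors outside the "
                f"inventory: {sorted(extra)}"
            )
    rows = np.zeros((len(instances), len(inventory) + len(SUMMARY_FEATURES)))
    col_of = {s: j for j, s in enumerate(inventory)}
    for i, inst in enumerate(instances):
        for s, c in inst.sensor_counts.items():
            rows[i, col_of[s]] = c
        rows[i, len(inventory)] = inst.duration_s
        rows[i, len(inventory) + 1] = inst.unique_sensor_events
        rows[i, len(inventory) + 2] = 1.0 if inst.completeness else 0.0
    data = pd.DataFrame(rows, columns=inventory + list(SUMMARY_FEATURES))
    return FeatureMatrix(
        data=data,
        class_labels=np.array([i.class_label for i in instances]),
        cohorts=np.array([i.cohort for i in instances]),
        participant_ids=np.array([i.participant_id for i in instances]),
    )
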