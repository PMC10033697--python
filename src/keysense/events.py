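"""Reading and writing CASAS-style annotated sensor event logs.

A log is plain text, one sensor event per line::

    2011-06-15 08:00:01.000  M013  ON
    2011-06-15 08:00:03.250  D007  OPEN  19-start

Fields are whitespace-separated: calendar date, time of day (optionally
with fractional seconds), sensor id, sensor value, and an optional
activity annotation ``<activity_id>-start`` / ``<activity_id>-end``
marking the boundary of an activity span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator, Optional

__all__ = [
    "Annotation",
    "SensorEvent",
    "EventLog",
    "LogParseError",
    "read_casas_log",
    "write_casas_log",
]

_TS_FORMATS = ("%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S")


class LogParseError(ValueError):
    """Raised for a malformed event-log line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class Annotation:
    """Activity span marker attached to a sensor event."""

    activity_id: int
    marker: str  # "start" or "end"

    def __post_init__(self) -> None:
        if self.marker not in ("start", "end"):
            raise ValueError(f"marker must be 'start' or 'end', got {self.marker!r}")


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped sensor reading, optionally annotated with an
    activity boundary marker."""

    timestamp: datetime
    sensor_id: str
    value: str
    annotation: Optional[Annotation] = None

    def __post_init__(self) -> None:
        if not self.sensor_id:
            raise ValueError("sensor_id must be non-empty")


@dataclass
class EventLog:
    """An ordered sequence of sensor events from one source.

    Events are kept sorted by timestamp (non-decreasing); construction
    stable-sorts if needed so ties preserve input order.
    """

    events: list[SensorEvent] = field(default_factory=list)
    source_name: str = ""

    def __post_init__(self) -> None:
        ts = [e.timestamp for e in self.events]
        if any(a > b for a, b in zip(ts, ts[1:])):
            self.events = sorted(self.events, key=lambda e: e.timestamp)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SensorEvent]:
        return iter(self.events)


def _parse_timestamp(date_tok: str, time_tok: str, lineno: int) -> datetime:
    raw = f"{date_tok} {time_tok}"
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(raw, fmt)
        except ValueError:
            continue
    raise LogParseError(lineno, f"unparseable timestamp {raw!r}")


def _parse_annotation(tok: str, lineno: int) -> Annotation:
    head, sep, tail = tok.partition("-")
    if not sep:
        raise LogParseError(lineno, f"malformed annotation {tok!r}")
    try:
        activity_id = int(head)
    except ValueError:
        raise LogParseError(lineno, f"non-integer activity id in {tok!r}") from None
    marker = tail.lower()
    if marker not in ("start", "end"):
        raise LogParseError(lineno, f"unknown marker {tail!r} (want start/end)")
    return Annotation(activity_id, marker)


def read_casas_log(stream: Iterable[str], source_name: str = "") -> EventLog:
    """Parse a CASAS-style event log from an iterable of text lines.

    Each non-blank line must carry at least ``date time sensor_id value``
    and may end with an ``<int>-start`` / ``<int>-end`` activity marker.
    Blank lines are skipped.  Out-of-order timestamps are tolerated with
    a warning and a stable sort (real deployments show clock jitter).

    Raises
    ------
    LogParseError
        On a malformed line, naming its 1-based line number.
    """
    events: list[SensorEvent] = []
    prev_ts: Optional[datetime] = None
    disorder = False
    for lineno, line in enumerate(stream, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) < 4 or len(tokens) > 5:
            raise LogParseError(
                lineno, f"expected 4 or 5 fields, got {len(tokens)}: {line.strip()!r}"
            )
        ts = _parse_timestamp(tokens[0], tokens[1], lineno)
        annotation = _parse_annotation(tokens[4], lineno) if len(tokens) == 5 else None
        events.append(SensorEvent(ts, tokens[2], tokens[3], annotation))
        if prev_ts is not None and ts < prev_ts:
            disorder = True
        prev_ts = ts
    if disorder:
        warnings.warn(
            f"{source_name or 'event log'}: out-of-order timestamps; stable-sorting",
            stacklevel=2,
        )
    return EventLog(events=events, source_name=source_name)


def write_casas_log(log: EventLog) -> str:
    """Serialize an event log back to text; inverse of :func:`read_casas_log`.

    The writer emits tab-separated fields and always prints timestamps
    with 3 fractional-second digits, so parse(write(log)) reproduces the
    log field-for-field.
    """
    lines = []
    for e in log.events:
        ts = e.timestamp.strftime("%Y-%m-%d %H:%M:%S.%f")[:-3]
        date_tok, time_tok = ts.split(" ")
        fields = [date_tok, time_tok, e.sensor_id, e.value]
        if e.annotation is not None:
            fields.append(f"{e.annotation.activity_id}-{e.annotation.marker}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")
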