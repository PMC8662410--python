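"""Stream metadata, in-process outlet/inlet transport, and clock-offset measurement.

This layer provides the contract the recorder depends on: streams are
self-describing (:class:`StreamInfo` carries everything a recorder needs,
so it can stay ignorant of sensor semantics), delivery from an outlet to
each connected inlet is ordered and lossless, and the offset between the
consumer's clock and a source's clock can be measured at any time with an
NTP-style round-trip exchange.

Sign convention (used everywhere in this package): ``offset`` is
*consumer clock minus source clock*, so that

    synchronized_timestamp = raw_source_timestamp + offset

maps a source timestamp onto the consumer (recorder) clock.
"""

from __future__ import annotations

import fnmatch
import statistics
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

__all__ = [
    "CHANNEL_FORMATS",
    "StreamInfo",
    "TimedSample",
    "ClockProbe",
    "ClockOffsetRecord",
    "OffsetSeries",
    "StreamRegistry",
    "StreamOutlet",
    "StreamInlet",
    "Clock",
    "estimate_offset",
    "measure_offset",
    "offset_at",
    "match_streams",
]

CHANNEL_FORMATS = ("float32", "double64", "int32", "string")

#: default per-inlet (and per-outlet history) queue capacity, in samples
DEFAULT_QUEUE_CAPACITY = 32768


class Clock(Protocol):
    """Anything with a ``now() -> float`` returning seconds on some monotonic epoch."""

    def now(self) -> float: ...


@dataclass(frozen=True)
class StreamInfo:
    """Metadata identifying one stream.

    Parameters
    ----------
    name:
        Human-readable stream name (e.g. ``"SineWave-A"``).
    stream_type:
        Content type, e.g. ``"EEG"``, ``"rotation"``, ``"gravity"``,
        ``"accelerometer"``, ``"sine"``.
    channel_count:
        Number of channels per sample, >= 1.
    nominal_srate:
        Declared sampling rate in Hz; 0 marks an irregular stream.
    channel_format:
        One of ``float32 | double64 | int32 | string``.
    source_id:
        Identifier unique per physical source (device + sensor).
    uid:
        Identifier unique per outlet instance.
    """

    name: str
    stream_type: str
    channel_count: int
    nominal_srate: float
    channel_format: str = "float32"
    source_id: str = ""
    uid: str = ""

    def __post_init__(self) -> None:
        if self.channel_count < 1:
            raise ValueError(f"channel_count must be >= 1, got {self.channel_count}")
        if self.nominal_srate < 0:
            raise ValueError(f"nominal_srate must be >= 0, got {self.nominal_srate}")
        if self.channel_format not in CHANNEL_FORMATS:
            raise ValueError(
                f"channel_format must be one of {CHANNEL_FORMATS}, got {self.channel_format!r}"
            )


@dataclass(frozen=True)
class TimedSample:
    """One multichannel sample with its timestamp on the *source* clock."""

    values: tuple
    timestamp: float


@dataclass(frozen=True)
class ClockProbe:
    """One NTP-style round trip.

    t0: consumer clock at request send; t1: source clock at request receive;
    t2: source clock at reply send; t3: consumer clock at reply receive.
    """

    t0: float
    t1: float
    t2: float
    t3: float

    def __post_init__(self) -> None:
        if self.t3 < self.t0 or self.t2 < self.t1:
            raise ValueError("probe times out of order (t3 >= t0 and t2 >= t1 required)")

    def raw_offset(self) -> float:
        """Per-probe estimate of (source clock - consumer clock)."""
        return ((self.t1 - self.t0) + (self.t2 - self.t3)) / 2.0

    def round_trip_time(self) -> float:
        return (self.t3 - self.t0) - (self.t2 - self.t1)


@dataclass(frozen=True)
class ClockOffsetRecord:
    """Offset (consumer - source) observed at ``collection_time`` on the consumer clock."""

    collection_time: float
    offset: float


@dataclass
class OffsetSeries:
    """Time-ordered clock-offset records for one stream."""

    stream_uid: str = ""
    records: list[ClockOffsetRecord] = field(default_factory=list)

    def append(self, record: ClockOffsetRecord) -> None:
        if self.records and record.collection_time <= self.records[-1].collection_time:
            raise ValueError(
                "offset records must have strictly increasing collection_time "
                f"({record.collection_time} after {self.records[-1].collection_time})"
            )
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __bool__(self) -> bool:
        return bool(self.records)


def estimate_offset(probes: Sequence[ClockProbe]) -> ClockOffsetRecord:
    """Combine round-trip probes into one offset record.

    The per-probe raw offset ``((t1-t0)+(t2-t3))/2`` estimates source-consumer
    under symmetric transport delay; the record's offset is the *negated
    median* of these, i.e. consumer-source, which is robust to occasional
    asymmetric-delay outliers. ``collection_time`` is the consumer clock at
    the median probe.
    """
    if not probes:
        raise ValueError("at least one probe required")
    raw = sorted(p.raw_offset() for p in probes)
    med = statistics.median(raw)
    mid_times = sorted((p.t0 + p.t3) / 2.0 for p in probes)
    collection = statistics.median(mid_times)
    return ClockOffsetRecord(collection_time=collection, offset=-med)


def measure_offset(
    inlet: "StreamInlet",
    n_probes: int = 5,
    probe_spacing: float = 0.010,
) -> ClockOffsetRecord:
    """Measure the consumer-source offset for an inlet's stream.

    Issues ``n_probes`` round trips spaced ``probe_spacing`` seconds apart
    through the inlet's probe link and reduces them with
    :func:`estimate_offset`.

    Raises
    ------
    ProbeTimeout
        propagated from the probe link; callers treat this as "sync degraded"
        (skip this cycle, keep the previous series), not as fatal.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    probes = [inlet.probe(ahead=k * probe_spacing) for k in range(n_probes)]
    return estimate_offset(probes)


class ProbeTimeout(RuntimeError):
    """A clock probe went unanswered within its deadline."""


def offset_at(series: OffsetSeries, t: float) -> float:
    """Offset at consumer-clock time ``t``, by piecewise-linear interpolation.

    Constant extrapolation beyond the first/last record. Raises on an empty
    series: without any offset record no synchronization is possible.
    """
    recs = series.records
    if not recs:
        raise ValueError("cannot interpolate an empty offset series")
    if t <= recs[0].collection_time:
        return recs[0].offset
    if t >= recs[-1].collection_time:
        return recs[-1].offset
    # binary search for the bracketing pair
    lo, hi = 0, len(recs) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if recs[mid].collection_time <= t:
            lo = mid
        else:
            hi = mid
    a, b = recs[lo], recs[hi]
    w = (t - a.collection_time) / (b.collection_time - a.collection_time)
    return a.offset + w * (b.offset - a.offset)


class StreamRegistry:
    """In-process stand-in for network stream discovery.

    Outlets register themselves under their ``(source_id, uid)`` key and
    become discoverable through :meth:`resolve_streams`.
    """

    def __init__(self) -> None:
        self._outlets: dict[tuple[str, str], StreamOutlet] = {}

    def register(self, outlet: "StreamOutlet") -> None:
        key = (outlet.info.source_id, outlet.info.uid)
        if key in self._outlets:
            raise ValueError(f"outlet with (source_id, uid)={key} already registered")
        self._outlets[key] = outlet

    def unregister(self, outlet: "StreamOutlet") -> None:
        self._outlets.pop((outlet.info.source_id, outlet.info.uid), None)

    def resolve_streams(self, timeout: float = 0.0) -> list[StreamInfo]:
        """All currently registered streams (empty list if none)."""
        return [o.info for o in self._outlets.values()]

    def find_outlet(self, uid: str) -> "StreamOutlet":
        for o in self._outlets.values():
            if o.info.uid == uid:
                return o
        raise KeyError(f"no outlet with uid {uid!r}")


def match_streams(
    infos: Iterable[StreamInfo], patterns: Sequence[str] | None
) -> list[StreamInfo]:
    """Select streams whose name, type or source_id matches any glob pattern.

    ``patterns=None`` (or an empty list) selects everything, mirroring a
    recorder that initially selects all detected streams.
    """
    infos = list(infos)
    if not patterns:
        return infos
    out = []
    for info in infos:
        for pat in patterns:
            if (
                fnmatch.fnmatch(info.name, pat)
                or fnmatch.fnmatch(info.stream_type, pat)
                or fnmatch.fnmatch(info.source_id, pat)
            ):
                out.append(info)
                break
    return out


class StreamOutlet:
    """Sending endpoint of a stream.

    Samples pushed here are appended, in push order, to the queue of every
    connected inlet; they are also retained in a bounded history buffer so
    that an inlet connecting later still receives them.
    """

    def __init__(
        self,
        info: StreamInfo,
        registry: StreamRegistry,
        clock: Clock | None = None,
        capacity: int = DEFAULT_QUEUE_CAPACITY,
    ) -> None:
        self.info = info
        self.clock = clock
        self._registry = registry
        self._inlets: list[StreamInlet] = []
        self._history: deque[TimedSample] = deque(maxlen=capacity)
        self._last_timestamp: float | None = None
        self.closed = False
        registry.register(self)

    # -- sending ---------------------------------------------------------
    def push_sample(self, values: Sequence, timestamp: float | None = None) -> None:
        if timestamp is None:
            if self.clock is None:
                raise ValueError(f"outlet {self.info.name!r} has no clock to timestamp with")
            timestamp = self.clock.now()
        self.push_chunk([TimedSample(tuple(values), timestamp)])

    def push_chunk(self, samples: Sequence[TimedSample]) -> int:
        """Push samples; returns the number accepted."""
        if self.closed:
            raise RuntimeError(f"outlet {self.info.name!r} is closed")
        for s in samples:
            if len(s.values) != self.info.channel_count:
                raise ValueError(
                    f"stream {self.info.name!r}: sample has {len(s.values)} values, "
                    f"expected {self.info.channel_count}"
                )
            if self._last_timestamp is not None and s.timestamp < self._last_timestamp:
                raise ValueError(
                    f"stream {self.info.name!r}: timestamps must be non-decreasing"
                )
            self._last_timestamp = s.timestamp
            self._history.append(s)
            for inlet in self._inlets:
                inlet._enqueue(s)
        return len(samples)

    def close(self) -> None:
        self.closed = True
        self._registry.unregister(self)

    # -- wiring ----------------------------------------------------------
    def _attach(self, inlet: "StreamInlet", replay_history: bool) -> None:
        if replay_history:
            for s in self._history:
                inlet._enqueue(s)
        self._inlets.append(inlet)


def open_outlet(
    info: StreamInfo,
    registry: StreamRegistry,
    clock: Clock | None = None,
    capacity: int = DEFAULT_QUEUE_CAPACITY,
) -> StreamOutlet:
    """Open an outlet and make it discoverable in ``registry``."""
    return StreamOutlet(info, registry, clock=clock, capacity=capacity)


class StreamInlet:
    """Receiving endpoint connected to one outlet.

    ``probe_link`` is an optional callable ``(ahead: float) -> ClockProbe``
    performing one round trip against the source, ``ahead`` seconds after
    "now"; it is wired by whoever owns the transport (the simulator, for
    virtual devices). Without a probe link, probing assumes the outlet and
    inlet share one clock and returns zero-delay probes.
    """

    def __init__(
        self,
        outlet: StreamOutlet,
        clock: Clock | None = None,
        capacity: int = DEFAULT_QUEUE_CAPACITY,
        probe_link: Callable[[float], ClockProbe] | None = None,
        replay_history: bool = True,
    ) -> None:
        self.outlet = outlet
        self.info = outlet.info
        self.clock = clock
        self._queue: deque[TimedSample] = deque(maxlen=capacity)
        self._probe_link = probe_link
        outlet._attach(self, replay_history=replay_history)

    def _enqueue(self, sample: TimedSample) -> None:
        self._queue.append(sample)

    def pull_chunk(self, max_samples: int | None = None) -> list[TimedSample]:
        """Pull up to ``max_samples`` queued samples (all, if None), FIFO."""
        n = len(self._queue) if max_samples is None else min(max_samples, len(self._queue))
        return [self._queue.popleft() for _ in range(n)]

    def queued(self) -> int:
        return len(self._queue)

    def probe(self, ahead: float = 0.0) -> ClockProbe:
        if self._probe_link is not None:
            return self._probe_link(ahead)
        # same-process, same-clock degenerate case
        clk = self.clock or self.outlet.clock
        if clk is None:
            raise ProbeTimeout(f"stream {self.info.name!r}: no clock available for probing")
        t = clk.now() + ahead
        return ClockProbe(t, t, t, t)
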