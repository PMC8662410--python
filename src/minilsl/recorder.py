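"""Fault-tolerant multi-stream recorder.

The recorder discovers streams in a registry, lets the caller select a
subset, and writes them into one XDF file. Its behaviour under both normal
and degraded conditions follows a small set of rules:

* incoming samples are buffered per stream and flushed to the file every
  ``flush_interval`` (default 500 ms), each flush reaching the OS, so an
  abnormal termination loses at most one buffer interval of data;
* the offset between the recorder's clock (the master) and each source's
  clock is measured every ``offset_interval`` (default 5 s), written as
  clock-offset chunks as the recording runs, and repeated in the footer;
* a silent stream simply produces no sample chunks — the recording keeps
  going and resumes writing when samples reappear;
* a regular stop writes one footer per stream (sample count, first/last
  timestamp, measured rate, full offset series) and closes the file; a
  kill leaves a footerless but loadable file.

All scheduling runs on an injected clock/event loop, so in tests simulated
time makes the timing rules exact assertions; nothing in the recorder
depends on what the streams contain.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .streaming import (
    Clock,
    OffsetSeries,
    ProbeTimeout,
    StreamInfo,
    StreamInlet,
    StreamRegistry,
    TimedSample,
    match_streams,
    measure_offset,
)
from .xdf import FooterStats, XdfWriter, open_writer

__all__ = [
    "RecorderConfig",
    "RecordingSession",
    "make_filename",
]

log = logging.getLogger(__name__)

_TIMESTAMP_FMT = "%Y-%m-%d_%H-%M-%S"


@dataclass
class RecorderConfig:
    """Tunable recorder behaviour.

    flush_interval: seconds between buffer flushes to disk (default 0.5).
    offset_interval: seconds between clock-offset measurements (default 5).
    boundary_interval: seconds between recovery-marker chunks (default 10).
    n_probes: round trips per offset measurement (median-combined).
    """

    flush_interval: float = 0.5
    offset_interval: float = 5.0
    boundary_interval: float = 10.0
    n_probes: int = 5
    filename_base: str = "recording"

    def __post_init__(self) -> None:
        if self.flush_interval <= 0:
            raise ValueError("flush_interval must be > 0")
        if self.offset_interval <= 0:
            raise ValueError("offset_interval must be > 0")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> tuple["RecorderConfig", list[str]]:
        """Parse a ``key=value`` config file; returns (config, stream patterns)."""
        kwargs: dict = {}
        patterns: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key in ("flush_interval", "offset_interval", "boundary_interval"):
                    kwargs[key] = float(val)
                elif key == "n_probes":
                    kwargs[key] = int(val)
                elif key == "filename_base":
                    kwargs[key] = val
                elif key == "streams":
                    patterns = [p.strip() for p in val.split(",") if p.strip()]
        return cls(**kwargs), patterns


def make_filename(
    base: str,
    now: _dt.datetime | None = None,
    directory: str | os.PathLike = ".",
) -> str:
    """Unique recording path: ``base_YYYY-MM-DD_HH-MM-SS.xdf``.

    The timestamp suffix prevents accidental overwrites across runs; if the
    name still collides (same base and second), ``_2``, ``_3``, ... are
    appended until the name is free. Path separators and other unsafe
    characters in ``base`` are stripped; an empty base falls back to
    ``"recording"``.
    """
    now = now or _dt.datetime.now()
    base = re.sub(r"[\\/\0:*?\"<>|]", "", base).strip()
    if not base:
        base = "recording"
    stem = f"{base}_{now.strftime(_TIMESTAMP_FMT)}"
    candidate = os.path.join(directory, stem + ".xdf")
    k = 2
    while os.path.exists(candidate):
        candidate = os.path.join(directory, f"{stem}_{k}.xdf")
        k += 1
    return candidate


@dataclass
class _StreamState:
    stream_id: int
    info: StreamInfo
    inlet: StreamInlet
    series: OffsetSeries
    samples_received: int = 0
    first_timestamp: float | None = None
    last_timestamp: float | None = None
    skipped_offset_cycles: int = 0


@dataclass
class RecordingSession:
    """Lifecycle: idle -> recording -> stopped | killed.

    ``inlet_factory(info)`` must return a connected :class:`StreamInlet`
    for a selected stream; this is where the transport (and, for virtual
    devices, the probe link) is wired in.
    """

    registry: StreamRegistry
    config: RecorderConfig
    clock: Clock
    inlet_factory: Callable[[StreamInfo], StreamInlet]
    directory: str = "."
    state: str = "idle"
    path: str | None = None
    selected: list[StreamInfo] = field(default_factory=list)
    flush_times: list[float] = field(default_factory=list)
    _writer: XdfWriter | None = None
    _streams: list[_StreamState] = field(default_factory=list)
    _cancels: list[Callable[[], None]] = field(default_factory=list)
    _now_fn: Callable[[], float] | None = None  # wall-ish time for filenames only

    # -- selection -------------------------------------------------------
    def select(self, patterns: Sequence[str] | None = None) -> list[StreamInfo]:
        """Resolve streams and select those matching the patterns (all, if none)."""
        if self.state != "idle":
            raise RuntimeError("stream selection only before start()")
        self.selected = match_streams(self.registry.resolve_streams(), patterns)
        return self.selected

    # -- lifecycle -------------------------------------------------------
    def start(
        self,
        loop=None,
        now: _dt.datetime | None = None,
    ) -> str:
        """Open the file, write stream headers, take the t=0 offsets.

        With an event ``loop``, flush/offset/boundary cycles are scheduled
        periodically; without one the caller drives :meth:`flush_cycle` and
        :meth:`offset_cycle` manually.
        """
        if self.state != "idle":
            raise RuntimeError(f"cannot start from state {self.state!r}")
        path = make_filename(self.config.filename_base, now=now, directory=self.directory)
        try:
            self._writer = open_writer(path)
        except OSError as exc:
            log.error("recording not started: %s", exc)
            return ""
        self.path = path
        for k, info in enumerate(self.selected, start=1):
            inlet = self.inlet_factory(info)
            self._writer.write_stream_header(k, info)
            self._streams.append(
                _StreamState(stream_id=k, info=info, inlet=inlet, series=OffsetSeries(info.uid))
            )
        self.state = "recording"
        self.offset_cycle()  # initial synchronization at t=0
        if loop is not None:
            cfg = self.config
            t0 = loop.t
            self._cancels.append(
                loop.call_periodic(t0 + cfg.flush_interval, cfg.flush_interval, self.flush_cycle)
            )
            self._cancels.append(
                loop.call_periodic(t0 + cfg.offset_interval, cfg.offset_interval, self.offset_cycle)
            )
            self._cancels.append(
                loop.call_periodic(
                    t0 + cfg.boundary_interval, cfg.boundary_interval, self._boundary_cycle
                )
            )
        return path

    def flush_cycle(self) -> int:
        """Write each stream's buffered samples as one chunk; returns samples written."""
        if self.state != "recording":
            return 0
        total = 0
        for st in self._streams:
            samples = st.inlet.pull_chunk()
            if not samples:
                continue  # silent stream: no chunk this cycle, recording continues
            self._write_samples(st, samples)
            total += len(samples)
        self.flush_times.append(self.clock.now())
        log.debug("flush: %d samples across %d streams", total, len(self._streams))
        return total

    def _write_samples(self, st: _StreamState, samples: list[TimedSample]) -> None:
        assert self._writer is not None
        try:
            self._writer.write_samples(st.stream_id, samples)
        except OSError as exc:  # disk full etc.: degrade gracefully, keep what we have
            log.error("write failure (%s); stopping recording", exc)
            self.stop()
            return
        st.samples_received += len(samples)
        if st.first_timestamp is None:
            st.first_timestamp = samples[0].timestamp
        st.last_timestamp = samples[-1].timestamp

    def offset_cycle(self) -> int:
        """Measure and record one clock offset per stream; returns records written."""
        if self.state != "recording":
            return 0
        assert self._writer is not None
        written = 0
        for st in self._streams:
            try:
                rec = measure_offset(st.inlet, n_probes=self.config.n_probes)
            except ProbeTimeout:
                st.skipped_offset_cycles += 1  # sync degraded, not fatal
                log.debug("offset probe timeout on %s", st.info.name)
                continue
            st.series.append(rec)
            self._writer.write_clock_offset(st.stream_id, rec.collection_time, rec.offset)
            written += 1
        log.debug("offset cycle: %d records", written)
        return written

    def _boundary_cycle(self) -> None:
        if self.state == "recording" and self._writer is not None:
            self._writer.write_boundary()

    def stop(self) -> str | None:
        """Final flush, footers for every stream, close. Always safe."""
        if self.state != "recording":
            return self.path
        self.state = "stopping"
        for cancel in self._cancels:
            cancel()
        for st in self._streams:  # final flush
            samples = st.inlet.pull_chunk()
            if samples:
                self._write_samples(st, samples)
        assert self._writer is not None
        footers = {st.stream_id: self._footer_for(st) for st in self._streams}
        self._writer.finalize(footers)
        self.state = "stopped"
        return self.path

    def _footer_for(self, st: _StreamState) -> FooterStats:
        n = st.samples_received
        first = st.first_timestamp if st.first_timestamp is not None else 0.0
        last = st.last_timestamp if st.last_timestamp is not None else first
        if n >= 2 and last > first:
            measured = (n - 1) / (last - first)
        else:  # degenerate: too few samples to measure, fall back to nominal
            measured = st.info.nominal_srate
        return FooterStats(
            first_timestamp=first,
            last_timestamp=last,
            sample_count=n,
            measured_srate=measured,
            offsets=st.series,
        )

    def kill(self) -> str | None:
        """Abnormal termination: no final flush, no footer; file stays loadable."""
        if self.state != "recording":
            return self.path
        for cancel in self._cancels:
            cancel()
        assert self._writer is not None
        self._writer.abandon()
        self.state = "killed"
        return self.path

    # -- introspection ---------------------------------------------------
    def stream_states(self) -> list[_StreamState]:
        return list(self._streams)

    def offset_counts(self) -> dict[str, int]:
        return {st.info.name: len(st.series) for st in self._streams}
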