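"""Shared fixtures: simulation wiring and randomized recording generation."""

from __future__ import annotations

import numpy as np
import pytest

from minilsl.recorder import RecorderConfig, RecordingSession
from minilsl.simulate import EventLoop, TransportDelay, VirtualClock, device_probe_link
from minilsl.streaming import StreamInfo, StreamInlet, StreamRegistry, TimedSample
from minilsl.xdf import FooterStats, open_writer


@pytest.fixture
def loop():
    return EventLoop()


@pytest.fixture
def registry():
    return StreamRegistry()


def make_session(
    registry,
    loop,
    device,
    directory,
    consumer_clock=None,
    flush_interval=0.5,
    offset_interval=5.0,
    base="test",
    seed=0,
):
    """Wire a recording session to one virtual device, mirroring live use."""
    consumer = consumer_clock or VirtualClock(loop)

    def inlet_factory(info):
        outlet = registry.find_outlet(info.uid)
        link = device_probe_link(
            loop, consumer, device, TransportDelay(seed=seed + 1), seed=seed + 2
        )
        return StreamInlet(outlet, clock=consumer, probe_link=link)

    cfg = RecorderConfig(
        flush_interval=flush_interval, offset_interval=offset_interval, filename_base=base
    )
    session = RecordingSession(
        registry=registry,
        config=cfg,
        clock=consumer,
        inlet_factory=inlet_factory,
        directory=str(directory),
    )
    session.select(None)
    return session


FORMATS = ("float32", "double64", "int32", "string")


def random_recording(rng: np.random.Generator, max_streams=3, max_samples=120):
    """Randomized multi-stream recording content for roundtrip tests.

    Values are drawn in each format's exactly-representable domain so that
    write -> read can be compared bit-exactly.
    """
    n_streams = int(rng.integers(1, max_streams + 1))
    streams = {}
    for sid in range(1, n_streams + 1):
        fmt = FORMATS[int(rng.integers(0, len(FORMATS)))]
        cc = int(rng.integers(1, 5))
        srate = float(rng.choice([0.0, 50.0, 100.0, 250.0]))
        info = StreamInfo(
            name=f"stream{sid}",
            stream_type=str(rng.choice(["EEG", "sine", "accelerometer", "markers"])),
            channel_count=cc,
            nominal_srate=srate,
            channel_format=fmt,
            source_id=f"src{sid}",
            uid=f"uid{sid}",
        )
        n = int(rng.integers(0, max_samples))
        t0 = float(rng.uniform(0, 100))
        if srate > 0 and rng.random() < 0.5:
            ts = t0 + np.arange(n) / srate  # regular: exercises deduced timestamps
        else:
            ts = t0 + np.sort(rng.uniform(0, 10, size=n))
        if fmt == "float32":
            vals = rng.standard_normal((n, cc)).astype(np.float32)
            samples = [TimedSample(tuple(float(v) for v in row), float(t))
                       for row, t in zip(vals, ts)]
        elif fmt == "double64":
            vals = rng.standard_normal((n, cc))
            samples = [TimedSample(tuple(float(v) for v in row), float(t))
                       for row, t in zip(vals, ts)]
        elif fmt == "int32":
            vals = rng.integers(-(2**31), 2**31 - 1, size=(n, cc), dtype=np.int32)
            samples = [TimedSample(tuple(int(v) for v in row), float(t))
                       for row, t in zip(vals, ts)]
        else:
            samples = [
                TimedSample(
                    tuple(f"s{rng.integers(0, 10**6)}" for _ in range(cc)), float(t)
                )
                for t in ts
            ]
        offsets = []
        tcur = 0.0
        for _ in range(int(rng.integers(0, 6))):
            tcur += float(rng.uniform(0.5, 5.0))
            offsets.append((tcur, float(rng.normal(0, 0.5))))
        streams[sid] = {"info": info, "samples": samples, "offsets": offsets}
    return streams


def write_recording(path, streams, with_footers=True, chunk_size=16):
    """Write generated recording content through the package writer."""
    w = open_writer(path)
    for sid, st in streams.items():
        w.write_stream_header(sid, st["info"])
    for sid, st in streams.items():
        samples = st["samples"]
        for i in range(0, len(samples), chunk_size):
            w.write_samples(sid, samples[i : i + chunk_size])
        for t, off in st["offsets"]:
            w.write_clock_offset(sid, t, off)
    if with_footers:
        footers = {}
        for sid, st in streams.items():
            samples = st["samples"]
            n = len(samples)
            first = samples[0].timestamp if n else 0.0
            last = samples[-1].timestamp if n else 0.0
            srate = (n - 1) / (last - first) if n >= 2 and last > first else st[
                "info"
            ].nominal_srate
            from minilsl.streaming import ClockOffsetRecord, OffsetSeries

            series = OffsetSeries(st["info"].uid)
            for t, off in st["offsets"]:
                series.append(ClockOffsetRecord(t, off))
            footers[sid] = FooterStats(
                first_timestamp=first,
                last_timestamp=last,
                sample_count=n,
                measured_srate=srate,
                offsets=series,
            )
        w.finalize(footers)
    else:
        w.abandon()
    return path
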