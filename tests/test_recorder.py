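"""Recorder lifecycle, timing cadences, conservation and fault semantics."""

import datetime as dt

import numpy as np
import pytest

from conftest import make_session
from minilsl.recorder import RecorderConfig, make_filename
from minilsl.simulate import (
    EventLoop,
    VirtualClock,
    VirtualDevice,
    pause_fault,
    sine_source,
)
from minilsl.streaming import StreamRegistry
from minilsl.xdf import read_xdf, validate_file

NOW = dt.datetime(2021, 11, 16, 13, 5, 0)


class TestFilenames:
    def test_base_plus_timestamp(self, tmp_path):
        p = make_filename("run", NOW, tmp_path)
        assert p.endswith("run_2021-11-16_13-05-00.xdf")

    def test_collision_suffix(self, tmp_path):
        p1 = make_filename("run", NOW, tmp_path)
        open(p1, "w").close()
        p2 = make_filename("run", NOW, tmp_path)
        assert p2.endswith("run_2021-11-16_13-05-00_2.xdf")
        open(p2, "w").close()
        assert make_filename("run", NOW, tmp_path).endswith("_3.xdf")

    def test_separators_stripped_and_empty_base_defaults(self, tmp_path):
        assert "recording_" in make_filename("", NOW, tmp_path)
        p = make_filename("a/b\\c", NOW, tmp_path)
        assert "abc_" in p and "/b" not in p.split(str(tmp_path))[-1].replace("/abc", "")


def _sine_device(loop, rate=100.0, seed=0, channels=3, jitter=0.0):
    clock = VirtualClock(loop, offset0=0.8, drift_ppm=25.0, jitter_sd=jitter, seed=seed)
    src = sine_source(
        channels=channels, nominal_srate=rate, freqs=[2.0, 5.0, 9.0][:channels],
        name="S", source_id="dev",
    )
    return VirtualDevice([src], clock, seed=seed), src


class TestLifecycle:
    def test_selection_subset_writes_matching_headers(self, tmp_path):
        loop = EventLoop()
        registry = StreamRegistry()
        for name, sid in (("a", "s1"), ("b", "s2"), ("c", "s3")):
            clock = VirtualClock(loop)
            dev = VirtualDevice(
                [sine_source(channels=2, freqs=[1.0, 2.0], name=name, source_id=sid)],
                clock,
            )
            dev.schedule(loop, registry, 1.0)
        # build a session selecting 2 of the 3 resolved streams
        from minilsl.recorder import RecordingSession
        from minilsl.streaming import StreamInlet

        consumer = VirtualClock(loop)
        session = RecordingSession(
            registry=registry,
            config=RecorderConfig(filename_base="sel"),
            clock=consumer,
            inlet_factory=lambda info: StreamInlet(
                registry.find_outlet(info.uid), clock=consumer
            ),
            directory=str(tmp_path),
        )
        selected = session.select(["a", "b"])
        assert len(selected) == 2
        session.start(loop, now=NOW)
        loop.run_until(1.0)
        path = session.stop()
        rec = read_xdf(path)
        assert sorted(s.info.name for s in rec.streams.values()) == ["a", "b"]

    def test_zero_streams_yields_header_only_file(self, tmp_path, loop, registry):
        from minilsl.recorder import RecordingSession

        session = RecordingSession(
            registry=registry,
            config=RecorderConfig(filename_base="empty"),
            clock=VirtualClock(loop),
            inlet_factory=lambda info: None,
            directory=str(tmp_path),
        )
        session.select(None)
        session.start(loop, now=NOW)
        path = session.stop()
        rec = read_xdf(path)
        assert rec.streams == {}

    def test_start_twice_errors(self, tmp_path, loop, registry):
        device, _ = _sine_device(loop)
        device.schedule(loop, registry, 1.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        with pytest.raises(RuntimeError):
            session.start(loop, now=NOW)

    def test_config_from_key_value_file(self, tmp_path):
        cfg_file = tmp_path / "rec.cfg"
        cfg_file.write_text(
            "# recorder settings\nflush_interval = 0.25\noffset_interval=2.5\n"
            "filename_base = trial\nstreams = phone-*, *accel*\n"
        )
        cfg, patterns = RecorderConfig.from_file(cfg_file)
        assert cfg.flush_interval == 0.25
        assert cfg.offset_interval == 2.5
        assert cfg.filename_base == "trial"
        assert patterns == ["phone-*", "*accel*"]


class TestTiming:
    def test_flush_cadence_matches_interval(self, tmp_path, loop, registry):
        device, _ = _sine_device(loop)
        device.schedule(loop, registry, 20.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(20.0)
        session.stop()
        spacing = np.diff(session.flush_times)
        assert abs(np.median(spacing) - 0.5) < 0.005  # within 1 %

    def test_offset_cadence_and_t0_measurement(self, tmp_path, loop, registry):
        device, src = _sine_device(loop)
        device.schedule(loop, registry, 60.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(60.0)
        path = session.stop()
        rec = read_xdf(path)
        records = rec.by_name("S").offsets.records
        # one at t=0 plus one per 5 s: 13 +- 1
        assert abs(len(records) - 13) <= 1
        times = [r.collection_time for r in records]
        assert abs(np.median(np.diff(times)) - 5.0) < 0.05
        assert times[0] < 1.0  # immediate measurement at start

    def test_offset_loop_independent_of_flush_interval(self, tmp_path, registry):
        counts = []
        for flush in (0.25, 1.0):
            loop = EventLoop()
            reg = StreamRegistry()
            device, _ = _sine_device(loop)
            device.schedule(loop, reg, 30.0)
            session = make_session(reg, loop, device, tmp_path, flush_interval=flush,
                                   base=f"f{flush}")
            session.start(loop, now=NOW)
            loop.run_until(30.0)
            session.stop()
            counts.append(sum(session.offset_counts().values()))
        assert counts[0] == counts[1]

    def test_one_cycle_collects_about_half_second_of_samples(self, tmp_path, loop, registry):
        device, _ = _sine_device(loop, rate=100.0)
        device.schedule(loop, registry, 2.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(now=NOW)  # caller-driven: no scheduled cycles
        loop.run_until(0.5)
        n = session.flush_cycle()
        assert 45 <= n <= 55  # ~50 samples of a 100 Hz stream per 0.5 s


class TestConservation:
    def test_no_loss_no_duplication_on_stop(self, tmp_path, loop, registry):
        device, src = _sine_device(loop, rate=100.0, jitter=2e-4)
        device.schedule(loop, registry, 60.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(60.0)
        path = session.stop()
        rec = read_xdf(path)
        s = rec.by_name("S")
        ledger = device.ledger[src.info.uid]
        assert s.sample_count == len(ledger)
        assert s.footer is not None and s.footer.sample_count == len(ledger)
        assert np.array_equal(s.timestamps, [e.timestamp for e in ledger])
        validate_file(path)

    def test_footer_measured_srate(self, tmp_path, loop, registry):
        device, _ = _sine_device(loop, rate=100.0)
        device.schedule(loop, registry, 60.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(60.0)
        rec = read_xdf(session.stop())
        f = rec.by_name("S").footer
        assert f.sample_count == pytest.approx(6000, abs=5)
        assert f.measured_srate == pytest.approx(100.0, abs=0.5)

    def test_single_sample_falls_back_to_nominal_rate(self, tmp_path, loop, registry):
        device, _ = _sine_device(loop, rate=100.0)
        device.schedule(loop, registry, 0.001)  # just the t=0 emission
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(0.001)
        rec = read_xdf(session.stop())
        f = rec.by_name("S").footer
        assert f.sample_count == 1
        assert f.measured_srate == 100.0  # nominal fallback


class TestFaultTolerance:
    def test_paused_stream_writes_no_chunks_but_offsets_continue(
        self, tmp_path, loop, registry
    ):
        device, src = _sine_device(loop, rate=100.0)
        device.inject_fault(pause_fault(5.0, 10.0))
        device.schedule(loop, registry, 30.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(30.0)
        rec = read_xdf(session.stop())
        s = rec.by_name("S")
        # offsets kept coming during the silence: 0,5,...,30 -> 7
        assert len(s.offsets.records) == 7
        dt_max = np.max(np.diff(s.timestamps))
        assert 9.5 < dt_max < 10.5  # the pause is visible as one gap

    def test_kill_loses_at_most_one_flush_interval(self, tmp_path):
        # randomized kill times; trailing loss bounded by the buffer interval
        rng = np.random.default_rng(123)
        for trial in range(20):
            loop = EventLoop()
            registry = StreamRegistry()
            device, src = _sine_device(loop, rate=100.0, seed=trial)
            device.schedule(loop, registry, 30.0)
            session = make_session(registry, loop, device, tmp_path, seed=trial,
                                   base=f"kill{trial}")
            session.start(loop, now=NOW)
            kill_t = float(rng.uniform(1.0, 29.0))
            loop.run_until(kill_t)
            path = session.kill()
            rec = read_xdf(path)
            s = rec.by_name("S")
            assert s.footer is None  # no footer after abnormal termination
            ledger = [e for e in device.ledger[src.info.uid] if e.t_true <= kill_t]
            n_rec = s.sample_count
            if ledger and n_rec < len(ledger):
                # span of the missing tail: first to last lost sample
                loss = ledger[-1].t_true - ledger[n_rec].t_true
            else:
                loss = 0.0
            assert loss <= 0.5 + 1e-9

    def test_kill_before_first_flush_leaves_readable_header_file(
        self, tmp_path, loop, registry
    ):
        device, _ = _sine_device(loop)
        device.schedule(loop, registry, 10.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(0.2)  # before the first 0.5 s flush
        path = session.kill()
        rec = read_xdf(path)
        assert rec.by_name("S").sample_count == 0

    def test_stop_after_stop_is_safe(self, tmp_path, loop, registry):
        device, _ = _sine_device(loop)
        device.schedule(loop, registry, 1.0)
        session = make_session(registry, loop, device, tmp_path)
        session.start(loop, now=NOW)
        loop.run_until(1.0)
        p1 = session.stop()
        assert session.stop() == p1
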