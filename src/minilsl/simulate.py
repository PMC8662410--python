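"""Virtual devices: clocks with offset/drift/jitter, signal sources, faults.

Everything runs on *simulated* time driven by a deterministic event loop,
so a "60 s recording" completes in milliseconds and every run is a pure
function of its configuration and seed. Real sensor hardware is replaced
by three ingredients:

* :class:`VirtualClock` — a device clock related to true time ``t`` by
  ``device_time(t) = t * (1 + drift_ppm * 1e-6) + offset0 + eps``, with
  per-read Gaussian noise ``eps`` clamped so reads never decrease.
* signal sources — a sine generator (the multi-channel test-signal app)
  and sensor sources sharing one physical motion ground truth, split into
  hardware sensors (direct measurement plus device noise) and software
  sensors (a device-specific smoothed/gained view, which is why software
  sensors agree less well across devices).
* :class:`LoadModel` — effective sampling rate as a non-increasing
  function of how many sensors the device streams concurrently, mirroring
  an OS that throttles all sensors alike under load.

The emission schedule replaces constant-delay polling threads: a source
with effective rate ``r`` emits near ``k / r`` with configurable timing
jitter, and timestamps each sample with its device clock.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .streaming import (
    ClockProbe,
    StreamInfo,
    StreamOutlet,
    StreamRegistry,
    TimedSample,
    open_outlet,
)

__all__ = [
    "EventLoop",
    "VirtualClock",
    "IdealClock",
    "TransportDelay",
    "make_probe_link",
    "device_probe_link",
    "SensorSpec",
    "LoadModel",
    "LOAD_PRESETS",
    "VirtualSource",
    "sine_source",
    "sensor_source",
    "make_motion_signal",
    "VirtualDevice",
    "run_virtual_device",
    "Fault",
    "pause_fault",
    "terminate_fault",
]


# ---------------------------------------------------------------------------
# simulated time
# ---------------------------------------------------------------------------


class EventLoop:
    """Deterministic discrete-event scheduler over simulated true time."""

    def __init__(self, start: float = 0.0) -> None:
        self._t = start
        self._heap: list[tuple[float, int, Callable[[], None]]] = []
        self._seq = 0

    @property
    def t(self) -> float:
        """Current simulated true time, seconds."""
        return self._t

    def call_at(self, when: float, callback: Callable[[], None]) -> None:
        if when < self._t:
            raise ValueError(f"cannot schedule in the past ({when} < {self._t})")
        heapq.heappush(self._heap, (when, self._seq, callback))
        self._seq += 1

    def call_periodic(
        self, start: float, interval: float, callback: Callable[[], None]
    ) -> Callable[[], None]:
        """Schedule ``callback`` at start, start+interval, ...; returns a canceller."""
        cancelled = False

        def fire() -> None:
            if cancelled:
                return
            callback()
            if not cancelled:
                self.call_at(self._t + interval, fire)

        def cancel() -> None:
            nonlocal cancelled
            cancelled = True

        self.call_at(start, fire)
        return cancel

    def run_until(self, t_end: float) -> None:
        """Process all events with time <= t_end, then set the clock to t_end."""
        while self._heap and self._heap[0][0] <= t_end:
            when, _, cb = heapq.heappop(self._heap)
            self._t = when
            cb()
        self._t = t_end


# ---------------------------------------------------------------------------
# clocks and transport
# ---------------------------------------------------------------------------


class VirtualClock:
    """Simulated device clock: initial offset, linear drift, per-read jitter.

    Reads are clamped monotone non-decreasing, as a real monotonic clock
    would be. With ``jitter_sd=0`` the clock is an exact affine map of true
    time.
    """

    def __init__(
        self,
        loop: EventLoop,
        offset0: float = 0.0,
        drift_ppm: float = 0.0,
        jitter_sd: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.loop = loop
        self.offset0 = offset0
        self.drift_ppm = drift_ppm
        self.jitter_sd = jitter_sd
        self._rng = np.random.default_rng(seed)
        self._last_read = -math.inf

    def read_at(self, t_true: float) -> float:
        """Device time at true time ``t_true`` (one noisy, monotone read)."""
        v = t_true * (1.0 + self.drift_ppm * 1e-6) + self.offset0
        if self.jitter_sd > 0:
            v += self._rng.normal(0.0, self.jitter_sd)
        if v < self._last_read:
            v = self._last_read
        self._last_read = v
        return v

    def ideal_at(self, t_true: float) -> float:
        """Noise-free device time (the clock's generating line)."""
        return t_true * (1.0 + self.drift_ppm * 1e-6) + self.offset0

    def now(self) -> float:
        return self.read_at(self.loop.t)


def IdealClock(loop: EventLoop) -> VirtualClock:
    """A drift- and jitter-free clock equal to simulated true time."""
    return VirtualClock(loop, offset0=0.0, drift_ppm=0.0, jitter_sd=0.0)


@dataclass
class TransportDelay:
    """One-way transport delay model for clock probes.

    ``sample()`` draws ``max(floor, base + N(0, jitter_sd^2) + asymmetry)``
    where ``asymmetry`` is added on the forward leg only, letting tests
    construct biased links.
    """

    base: float = 0.002
    jitter_sd: float = 0.0005
    asymmetry: float = 0.0
    floor: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def sample(self, forward: bool) -> float:
        d = self.base + (self.asymmetry if forward else 0.0)
        if self.jitter_sd > 0:
            d += self._rng.normal(0.0, self.jitter_sd)
        return max(self.floor, d)


def make_probe_link(
    loop: EventLoop,
    consumer_clock: VirtualClock,
    source_clock: VirtualClock,
    delay: TransportDelay | None = None,
    processing: float = 1e-4,
    seed: int = 0,
) -> Callable[[float], ClockProbe]:
    """Build a probe function simulating one NTP round trip per call.

    A probe issued ``ahead`` seconds after the loop's current time reads
    the consumer clock, crosses the link (forward delay), is handled by the
    source (fixed processing time, two source-clock reads), and crosses
    back (return delay). Probing does not advance the loop; exchanges are
    modelled as instantaneous from the scheduler's viewpoint.

    Probe-side clock reads are independent noisy observations of each
    clock's generating line (noise drawn from the link's own generator);
    they deliberately do not touch the clocks' monotone read state, which
    belongs to the devices' own sequential timestamping.
    """
    delay = delay or TransportDelay()
    rng = np.random.default_rng(seed)

    def read(clock: VirtualClock, t: float) -> float:
        v = clock.ideal_at(t)
        if clock.jitter_sd > 0:
            v += rng.normal(0.0, clock.jitter_sd)
        return v

    def probe(ahead: float = 0.0) -> ClockProbe:
        tau = loop.t + ahead
        d1 = delay.sample(forward=True)
        d2 = delay.sample(forward=False)
        t0 = read(consumer_clock, tau)
        t1 = read(source_clock, tau + d1)
        t2 = max(read(source_clock, tau + d1 + processing), t1)
        t3 = max(read(consumer_clock, tau + d1 + processing + d2), t0)
        return ClockProbe(t0, t1, t2, t3)

    return probe


def device_probe_link(
    loop: EventLoop,
    consumer_clock: VirtualClock,
    device: "VirtualDevice",
    delay: TransportDelay | None = None,
    processing: float = 1e-4,
    seed: int = 0,
) -> Callable[[float], ClockProbe]:
    """Probe link that honours the device's fault schedule.

    A terminated device no longer answers probes (:class:`ProbeTimeout`);
    a merely paused one keeps answering, so synchronization survives sample
    silence.
    """
    from .streaming import ProbeTimeout

    inner = make_probe_link(loop, consumer_clock, device.clock, delay, processing, seed=seed)

    def probe(ahead: float = 0.0) -> ClockProbe:
        if not device.answers_probes_at(loop.t + ahead):
            raise ProbeTimeout("source terminated; probe unanswered")
        return inner(ahead)

    return probe


# ---------------------------------------------------------------------------
# sensor specs and load
# ---------------------------------------------------------------------------

SENSOR_KINDS = ("rotation", "gravity", "accelerometer", "sine", "generic")
_DEFAULT_CHANNELS = {"rotation": 3, "gravity": 3, "accelerometer": 3, "sine": 10, "generic": 1}
#: software sensors derive their values indirectly and differ across devices
_SOFTWARE_KINDS = {"rotation"}


@dataclass(frozen=True)
class SensorSpec:
    """What one virtual sensor is: kind, channels, nominal rate, realization."""

    sensor_kind: str
    channels: int = 0
    nominal_srate: float = 100.0
    hardware: bool = True

    def __post_init__(self) -> None:
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")
        if self.channels == 0:
            object.__setattr__(self, "channels", _DEFAULT_CHANNELS[self.sensor_kind])
        expected = _DEFAULT_CHANNELS[self.sensor_kind]
        if self.sensor_kind != "generic" and self.channels != expected:
            raise ValueError(
                f"{self.sensor_kind} sensors have {expected} channels, got {self.channels}"
            )


@dataclass
class LoadModel:
    """Effective rate as a function of concurrently active sensor count.

    ``rate_per_active_sensor`` maps an active-sensor count to the effective
    rate all (non-exempt) sensors then share; lookups use the largest key
    <= the requested count. Rates must be non-increasing in load. Streams
    whose rate the OS guarantees (microphone-class audio) are exempt and
    keep ``base_rate``.
    """

    base_rate: float
    rate_per_active_sensor: dict[int, float] = field(default_factory=dict)
    exempt: bool = False

    def __post_init__(self) -> None:
        keys = sorted(self.rate_per_active_sensor)
        rates = [self.rate_per_active_sensor[k] for k in keys]
        if any(b > a for a, b in zip(rates, rates[1:])):
            raise ValueError("effective rate must be non-increasing in active sensor count")

    def effective_rate(self, active_sensors: int) -> float:
        if self.exempt or not self.rate_per_active_sensor:
            return self.base_rate
        keys = [k for k in sorted(self.rate_per_active_sensor) if k <= active_sensors]
        if not keys:
            return self.base_rate
        return self.rate_per_active_sensor[keys[-1]]


#: measured effective rates of two mid-range handsets streaming 125 Hz nominal
#: sensors: one sensor, three sensors, and every sensor except the microphone.
LOAD_PRESETS: dict[str, LoadModel] = {
    "samsung": LoadModel(base_rate=125.0, rate_per_active_sensor={1: 114.0, 3: 106.0, 6: 95.0}),
    "huawei": LoadModel(base_rate=125.0, rate_per_active_sensor={1: 118.0, 3: 116.0, 6: 111.0}),
}


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------


class VirtualSource:
    """One stream a virtual device emits: metadata, signal, effective rate.

    ``signal(t_true)`` returns the channel values at true time ``t_true``;
    stateful signals (software-sensor filters) are advanced in emission
    order, which the device guarantees.
    """

    def __init__(
        self,
        info: StreamInfo,
        signal: Callable[[float], Sequence[float]],
        effective_rate: float,
    ) -> None:
        if effective_rate <= 0:
            raise ValueError("effective_rate must be > 0")
        self.info = info
        self.signal = signal
        self.effective_rate = effective_rate


def sine_source(
    channels: int = 10,
    nominal_srate: float = 250.0,
    freqs: Sequence[float] | None = None,
    amplitude: float = 1.0,
    effective_rate: float | None = None,
    name: str = "SineWave",
    source_id: str = "sine-device",
    uid: str = "",
) -> VirtualSource:
    """Multi-channel sine generator: channel ``c`` emits ``A sin(2π f_c t)``.

    Defaults mimic a 10-channel, 250 Hz nominal test-signal app with one
    distinct frequency per channel (1..channels Hz). The effective rate may
    be configured below nominal to model device load.
    """
    if freqs is None:
        freqs = [float(c + 1) for c in range(channels)]
    freqs = [float(f) for f in freqs]
    if len(freqs) != channels:
        raise ValueError(f"need {channels} frequencies, got {len(freqs)}")
    if len(set(freqs)) != channels:
        raise ValueError("sine channel frequencies must be distinct")
    info = StreamInfo(
        name=name,
        stream_type="sine",
        channel_count=channels,
        nominal_srate=nominal_srate,
        channel_format="float32",
        source_id=source_id,
        uid=uid or f"{source_id}:{name}",
    )
    w = [2.0 * math.pi * f for f in freqs]

    def signal(t: float) -> tuple[float, ...]:
        return tuple(amplitude * math.sin(wc * t) for wc in w)

    return VirtualSource(info, signal, effective_rate or nominal_srate)


def make_motion_signal(
    channels: int = 3,
    seed: int = 0,
    n_components: int = 6,
    freq_range: tuple[float, float] = (0.2, 3.0),
    amplitude: float = 1.0,
) -> Callable[[float], np.ndarray]:
    """Smooth pseudo-random motion: per channel, a sum of seeded sinusoids.

    Emulates a person moving, walking or jumping with the devices in hand:
    band-limited, non-repeating-looking, identical for every sensor that
    observes the same physical motion.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(freq_range[0], freq_range[1], size=(channels, n_components))
    phase = rng.uniform(0, 2 * math.pi, size=(channels, n_components))
    amp = rng.uniform(0.3, 1.0, size=(channels, n_components))
    amp *= amplitude / np.sum(amp, axis=1, keepdims=True)
    w = 2.0 * math.pi * f

    def motion(t: float) -> np.ndarray:
        return np.sum(amp * np.sin(w * t + phase), axis=1)

    return motion


def sensor_source(
    spec: SensorSpec,
    motion: Callable[[float], np.ndarray],
    clock_seed: int = 0,
    device_noise_sd: float = 0.01,
    load: LoadModel | None = None,
    active_sensors: int = 1,
    effective_rate: float | None = None,
    device_id: str = "device",
    software_lag_tau: float = 0.150,
    software_gain_sd: float = 0.05,
    name: str | None = None,
) -> VirtualSource:
    """A virtual sensor observing a shared physical motion signal.

    Hardware sensors measure the motion directly plus independent device
    noise, so two devices moved together agree up to that noise. Software
    sensors return a device-interpreted quantity instead: a one-pole
    low-pass of the motion whose time constant is drawn *per device*
    around ``software_lag_tau`` (uniform in [0.3, 2.0] x tau), scaled by a
    per-device gain from N(1, software_gain_sd^2) — a deliberately simple
    stand-in for manufacturer-specific derivations. Because each device
    smooths with a different lag, two devices' software sensors agree
    noticeably less than their hardware sensors do, while one device's
    software sensor remains a faithful smooth function of the motion.

    The effective rate comes from ``load.effective_rate(active_sensors)``
    unless ``effective_rate`` overrides it.
    """
    rng = np.random.default_rng(clock_seed)
    rate = effective_rate
    if rate is None:
        rate = (load or LoadModel(base_rate=spec.nominal_srate)).effective_rate(active_sensors)
    info = StreamInfo(
        name=name or f"{device_id}-{spec.sensor_kind}",
        stream_type=spec.sensor_kind,
        channel_count=spec.channels,
        nominal_srate=spec.nominal_srate,
        channel_format="float32",
        source_id=f"{device_id}:{spec.sensor_kind}",
        uid=f"{device_id}:{spec.sensor_kind}:outlet",
    )
    if spec.hardware:
        if device_noise_sd > 0:
            def signal(t: float) -> tuple[float, ...]:
                return tuple(motion(t) + rng.normal(0.0, device_noise_sd, size=spec.channels))
        else:
            def signal(t: float) -> tuple[float, ...]:
                return tuple(motion(t))
    else:
        gain = 1.0 + software_gain_sd * rng.standard_normal()
        tau = float(rng.uniform(0.3, 2.0)) * software_lag_tau  # device-specific smoothing
        state = {"y1": None, "y2": None, "t": None}

        def signal(t: float) -> tuple[float, ...]:
            # two cascaded one-pole stages: a device-interpreted, phase-
            # distorted view of the motion rather than a direct measurement
            x = motion(t)
            if state["y1"] is None:
                state["y1"] = np.asarray(x, dtype=float)
                state["y2"] = np.asarray(x, dtype=float)
            else:
                dt = max(t - state["t"], 0.0)
                alpha = dt / (tau + dt) if dt > 0 else 0.0
                state["y1"] = state["y1"] + alpha * (x - state["y1"])
                state["y2"] = state["y2"] + alpha * (state["y1"] - state["y2"])
            state["t"] = t
            out = gain * state["y2"]
            if device_noise_sd > 0:
                out = out + rng.normal(0.0, device_noise_sd, size=spec.channels)
            return tuple(out)

    return VirtualSource(info, signal, rate)


# ---------------------------------------------------------------------------
# faults
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fault:
    """A scheduled misbehaviour of a device.

    ``pause``: sample emission stops during [t_start, t_start + t_dur) but
    the device still answers clock probes. ``terminate``: at t_start the
    device stops emitting and answering, permanently.
    """

    kind: str  # "pause" | "terminate"
    t_start: float
    t_dur: float = 0.0

    @property
    def t_end(self) -> float:
        return self.t_start + self.t_dur if self.kind == "pause" else math.inf


def pause_fault(t_start: float, t_dur: float) -> Fault:
    return Fault("pause", t_start, t_dur)


def terminate_fault(t: float) -> Fault:
    return Fault("terminate", t)


# ---------------------------------------------------------------------------
# devices
# ---------------------------------------------------------------------------


@dataclass
class LedgerEntry:
    """Ground truth for one pushed sample: true emission time + what was sent."""

    t_true: float
    timestamp: float
    values: tuple


class VirtualDevice:
    """A set of sources sharing one device clock and one fault schedule.

    ``schedule()`` opens one outlet per source on the registry and queues
    all emissions on the event loop; the ledger then records exactly what
    was pushed, for end-to-end conservation checks.
    """

    def __init__(
        self,
        sources: Sequence[VirtualSource],
        clock: VirtualClock,
        seed: int = 0,
        period_jitter_frac: float = 0.02,
    ) -> None:
        self.sources = list(sources)
        self.clock = clock
        self.seed = seed
        self.period_jitter_frac = period_jitter_frac
        self.faults: list[Fault] = []
        self.ledger: dict[str, list[LedgerEntry]] = {s.info.uid: [] for s in self.sources}
        self.outlets: dict[str, StreamOutlet] = {}

    def inject_fault(self, fault: Fault) -> None:
        """Add a pause/terminate fault; overlapping faults are rejected."""
        for f in self.faults:
            if fault.t_start < f.t_end and f.t_start < fault.t_end:
                raise ValueError(f"fault {fault} overlaps {f}")
        self.faults.append(fault)

    def _emitting_at(self, t: float) -> bool:
        for f in self.faults:
            if f.kind == "terminate" and t >= f.t_start:
                return False
            if f.kind == "pause" and f.t_start <= t < f.t_end:
                return False
        return True

    def answers_probes_at(self, t: float) -> bool:
        """Paused devices still answer clock probes; terminated ones do not."""
        return not any(f.kind == "terminate" and t >= f.t_start for f in self.faults)

    def schedule(self, loop: EventLoop, registry: StreamRegistry, duration: float) -> None:
        rng = np.random.default_rng(self.seed)
        for src in self.sources:
            outlet = open_outlet(src.info, registry, clock=self.clock)
            self.outlets[src.info.uid] = outlet
            period = 1.0 / src.effective_rate
            n = int(math.floor(duration * src.effective_rate)) + 1
            jit = (
                rng.normal(0.0, self.period_jitter_frac * period, size=n)
                if self.period_jitter_frac > 0
                else np.zeros(n)
            )
            times = np.arange(n) * period + jit
            times[0] = max(times[0], 0.0)
            times = np.maximum.accumulate(times)  # emission order never inverts
            ledger = self.ledger[src.info.uid]

            def make_emit(src=src, outlet=outlet, ledger=ledger):
                def emit() -> None:
                    t = loop.t
                    if not self._emitting_at(t):
                        return
                    values = tuple(float(v) for v in src.signal(t))
                    ts = self.clock.read_at(t)
                    outlet.push_chunk([TimedSample(values, ts)])
                    ledger.append(LedgerEntry(t, ts, values))

                return emit

            emit = make_emit()
            for t_emit in times:
                if t_emit <= duration:
                    loop.call_at(float(t_emit), emit)

    def ledger_counts(self) -> dict[str, int]:
        return {uid: len(entries) for uid, entries in self.ledger.items()}


def run_virtual_device(
    device: VirtualDevice,
    registry: StreamRegistry,
    duration: float,
    loop: EventLoop | None = None,
) -> dict[str, list[LedgerEntry]]:
    """Schedule a device and run the loop for ``duration`` simulated seconds.

    Returns the device's ledger. Reproducible: identical (config, seed)
    give identical ledgers.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    loop = loop or EventLoop()
    device.schedule(loop, registry, duration)
    loop.run_until(duration)
    return device.ledger
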