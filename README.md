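# minilsl

Synchronized multi-sensor streaming and recording, rebuilt at desk scale.

Mobile and multi-device physiological experiments (EEG plus motion
sensors, phone plus PC, several phones moved together) face one recurring
problem: every device timestamps its samples with its own clock, clocks
start out offset from each other and drift apart at parts-per-million
rates, and the operating system rarely delivers the sampling rate it was
asked for. Relating an event at `t = 317.2 s` on one device to the signal
of another is impossible without explicit synchronization.

`minilsl` implements the complete acquisition-and-synchronization stack
that solves this — stream transport with self-describing metadata,
NTP-style clock-offset measurement, fault-tolerant chunked recording to
XDF files, and post-hoc synchronization/dejittering/alignment — together
with **virtual devices** (clocks with configurable offset, drift and
jitter; sine and motion-sensor sources with load-dependent effective
rates; fault injection) so the entire stack runs and validates on a
single machine in simulated time, with no hardware and no network.

## The model

**Clock offsets.** For each stream, the recorder (the *master*) measures
its offset to the source clock by round-trip probes. One probe records
`t0` (consumer send), `t1`/`t2` (source receive/reply) and `t3`
(consumer receive); under symmetric transport delay

```
θ = ((t1 − t0) + (t2 − t3)) / 2          # source − consumer
offset = −median(θ over 5 probes)        # consumer − source
```

Offsets are measured at the start of a recording and every 5 s
thereafter, stored in the file as they are taken, and repeated in the
footer. Post hoc, each raw source timestamp is mapped onto the recorder
clock by piecewise-linear interpolation of the offset series:

```
corrected(t) = t + offset_series(t)
```

which also absorbs drift, since a drifting clock shows up as a linearly
changing offset.

**Recording.** Incoming samples are buffered for 500 ms and flushed to
the XDF file chunk by chunk, write-through. A recorder killed mid-run
(battery death, force stop) therefore loses at most one buffer interval
of data; the file on disk stays loadable, only the footer (sample count,
first/last timestamp, measured rate, offset series) is missing.

**Rates and alignment.** The effective sampling rate of a stream is
`(N − 1) / (t_last − t_first)`; nominal rates are aspirational on
phone-class devices (a 250 Hz sine source realistically achieves ~203–213
Hz, and streaming more sensors lowers the shared rate further). Noisy
timestamps can be dejittered by a per-segment least-squares line of
timestamp against sample index, and several streams are compared by
linear interpolation onto a common grid over their overlap window.

## Worked example

Run the two-device sine validation: two virtual phones stream the same
ten sine waves (1–10 Hz, one per channel, 250 Hz nominal) but reach 203
and 213 Hz effective, their clocks start 1.95 s apart and drift at +40
and −25 ppm, and one recorder captures both:

```
$ minilsl scenario s1a --seed 1
scenario s1a (seed 1, 60 s): PASS
  Sine-A: effective rate 202.99 Hz
  Sine-B: effective rate 213.01 Hz
  min channel correlation: 1.0000
  index_pairing_drift_s_per_s: 0.04697390439363708
  threshold: 0.9
```

Reading the numbers: the footers recover the configured effective rates
to 0.01 Hz; pairing samples *by index* makes the streams drift apart by
47 ms per second (the misalignment one sees without synchronization),
while after offset correction and resampling onto a common grid every
channel pair correlates at ≥ 0.9999 — the two devices' recordings are
interchangeable. `s1b`, `s2`, `s3`, `fault_pause` and `fault_kill` run
the motion-sensor, dual-recorder, same-device and fault-tolerance
scenarios the same way; the exit code reflects pass/fail.

Single recordings work the same way outside scenarios:

```
$ minilsl stream-sine --duration 10 --effective-rate 203 --seed 2 --out demo
demo_2026-09-20_17-59-30.xdf
$ minilsl inspect demo_2026-09-20_17-59-30.xdf
demo_2026-09-20_17-59-30.xdf: XDF 1.0, 1 stream(s)
  [1] SineWave (sine, 10 ch, float32, nominal 250 Hz): 2030 samples, measured 202.99 Hz, span [1.000, 10.996], 3 offsets, footer
```

The library surface mirrors the pipeline: `minilsl.streaming` (outlets,
inlets, offset estimation), `minilsl.xdf` (container writer/reader),
`minilsl.recorder` (sessions), `minilsl.loader` (synchronize, dejitter,
effective_srate, detect_gaps, align_streams), `minilsl.simulate`
(virtual clocks, sources, faults), `minilsl.scenarios`.

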