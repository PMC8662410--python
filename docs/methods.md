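# Methods

This note documents the models, estimators, simulator assumptions and
design choices behind `minilsl`, and what the desk-scale validation does
and does not demonstrate.

## Clock model and offset estimation

Every virtual device clock is an affine map of simulated true time with
per-read noise:

```
device_time(t) = t · (1 + drift_ppm · 1e−6) + offset0 + ε,   ε ~ N(0, jitter_sd²)
```

Reads are clamped monotone non-decreasing, as a real monotonic clock's
would be. Defaults used across scenarios: initial offsets of order 1 s,
drifts of ±15–40 ppm (typical for consumer crystal oscillators), read
jitter 0.2 ms.

Offsets between the recorder (master) clock and each source clock are
measured by NTP-style round trips. A probe yields
`θ = ((t1−t0)+(t2−t3))/2`, an unbiased estimate of source−consumer under
symmetric transport delay; one measurement combines **5 probes spaced
10 ms apart by their median**, which rejects occasional asymmetric-delay
outliers. The stored offset is `−median(θ)`, i.e. consumer−source, so
that `corrected = raw + offset` everywhere; the sign convention is fixed
package-wide and asserted by tests. Measurements are taken at t = 0 of a
recording (so even very short files are synchronizable) and every 5 s —
the default cadence of the synchronization layer this package models.
The round-trip count and estimator are this package's choice; the
underlying protocol does not prescribe them.

Transport delays in simulation default to 2 ms one-way with 0.5 ms
Gaussian jitter (floor 10 µs); an asymmetry term is available for
constructing biased links in tests. Probe-side clock readings are noisy
observations of the clock's generating line drawn from the probe link's
own random stream; they do not advance the device's monotone read state,
which belongs to its sequential sample timestamping.

## Offset application and drift

Post hoc, the recorded offset series is interpolated piecewise-linearly
(constant extrapolation beyond the ends) and added to raw timestamps.
Offset records are indexed by consumer time while queries arrive in
source time; the evaluation therefore does one fixed-point refinement
(`offset(t + offset(t))`), which removes the offset × drift cross-term
(nanoseconds at the simulated magnitudes, but free to correct). A global
least-squares line over the series is available as `method="linear"` for
comparison; piecewise interpolation is the default because it stays
robust when drift is not perfectly linear.

A stream with no offset records — the footerless, killed-recorder case —
is passed through unchanged and flagged `synchronized=False`.

## Cross-file comparison (two recorders, one source)

Each file's corrected axis lives on *its own* recorder's master clock,
so two files of the same source cannot be aligned directly: their axes
differ by the inter-recorder clock offset. Because an offset series
relates one consumer clock to the *source* clock, any series measured
against that source can be applied to that source's raw timestamps. For
dual-recorder comparisons the package therefore picks one file as the
reference master and re-expresses the other file's streams on it by
applying the reference file's offset series to the shared raw source
timestamps (`loader.resynchronize`). Residual disagreement is then
bounded by offset-measurement noise rather than by inter-master drift.

## Dejittering, rates, gaps

* **Dejitter**: timestamps are split into segments wherever consecutive
  spacing exceeds `max(2/nominal_srate, 0.5 s)`; within a segment they
  are replaced by the least-squares line of timestamp versus sample
  index. Sample counts and segment boundaries are preserved; a
  non-increasing fitted line (degenerate segment) falls back to the raw
  values rather than folding time. Irregular streams (nominal rate 0)
  pass through with a warning.
* **Effective rate**: `(N−1)/(t_last−t_first)`, exact for regular
  sampling; footer statistics are preferred when present since they
  cover the whole recording. Undefined below 2 samples.
* **Gaps**: inter-sample intervals above the gap threshold are reported
  with `round(gap · srate − 1)` implied missing samples each; a
  loss-free run must report zero gaps.
* **Alignment**: streams are linearly interpolated onto a shared grid
  (spacing exactly `1/target_rate`) over the intersection of their time
  ranges. Correlations are computed on the overlap minus 1 s at each
  edge, excluding interpolation edge effects. Linear interpolation was
  chosen over sinc/spline because the purpose is comparability and the
  result is deterministic and easy to verify; the method is pluggable.
  Scenario signals stay well below the alignment Nyquist rate (50 Hz
  grid vs ≤ 10 Hz sine and ≤ 3 Hz motion content).

## The recorder

Flush interval 500 ms, offset interval 5 s, recovery-marker (boundary)
chunks every 10 s — a choice the container layout permits but does not
mandate. Buffers are unbounded within a flush interval: a pathological
burst grows memory instead of dropping samples, because lossless
recording is the stack's headline property. Each chunk is flushed to the
OS as written, so after an abnormal termination (modelled by
`kill()`: no final flush, no footer) the missing data span is bounded by
the flush interval. A silent stream produces no chunks but the recording
and its offset measurements continue; a vanished stream leaves a footer
covering what was received. Write failures degrade gracefully: the
recorder attempts footers and closes rather than crashing. The measured
rate written to the footer is `(N−1)/(last−first)`, with a nominal-rate
fallback below 2 samples. Filenames append date and time
(`base_YYYY-MM-DD_HH-MM-SS.xdf`) plus a collision counter, so an
existing recording is never overwritten.

All recorder scheduling runs on an injected event loop over simulated
time; timing claims (cadences, loss bounds) are thereby exact assertions
rather than wall-clock approximations. A wall-clock run only needs a
real-time clock object and a thread driving the cycles.

## XDF container

The writer follows the public XDF 1.0 layout exactly: `XDF:` magic;
chunks framed as 1-byte length-width (1/4/8), little-endian length,
2-byte tag; tags 1–6 (FileHeader, StreamHeader, Samples, ClockOffset,
Boundary, StreamFooter); stream-scoped chunks carry a 4-byte stream id;
samples carry an explicit 8-byte double timestamp or a deduced-timestamp
flag. One deliberate tightening: a timestamp is written as deduced only
when it equals `previous + 1/nominal_srate` **exactly** in double
precision, so the reader's reconstruction is bit-identical and
roundtrips are lossless; jittered timestamps are always explicit. The
reader tolerates damage by construction — a truncated trailing chunk is
dropped with a warning, unknown tags are skipped, a missing footer is
reported rather than fatal — so any prefix of a valid file beyond the
header loads as a prefix of the samples.

The test suite cross-checks the writer and reader against an
independent, minimal decoder/encoder of the same public layout
(`tests/xdf_oracle.py`) that shares no code with the package.

## The simulator: what it emulates, what it does not

Virtual devices replace phones and laptops: each has one clock, one or
more sources, an emission schedule at the configured *effective* rate
(near `k/rate` with 2 % period jitter, order-preserving), and an exact
push ledger used for conservation checks. Everything is a pure function
of (configuration, seed).

* **Sine source**: 10 channels, 250 Hz nominal, one distinct frequency
  per channel (defaults 1–10 Hz) — a stand-in for neural-signal-sized
  test data. Effective rates of 203 and 213 Hz in scenario 1A reproduce
  what phone-class hardware realistically achieves at 250 Hz nominal.
* **Load model**: effective rate as a non-increasing step function of
  concurrently streamed sensor count; all non-exempt sensors share the
  throttled rate. Shipped presets encode measured handset behaviour at
  125 Hz nominal (one/three/all sensors: 114/106/95 Hz and
  118/116/111 Hz); audio-class streams are rate-exempt by flag, audio
  capture itself is out of scope.
* **Motion**: a shared "physical movement" signal per sensor kind — a
  seeded sum of 6 sinusoids per channel in 0.2–3 Hz, the band of
  walking/jumping movements. Hardware sensors measure it directly plus
  independent per-device Gaussian noise (sd 0.01 against signals of
  unit-order amplitude). Software sensors return a device-interpreted
  quantity: two cascaded one-pole low-pass stages whose time constant is
  drawn per device from `[0.3, 2.0] × 150 ms`, times a per-device gain
  from `N(1, 0.05²)`. This mechanism is illustrative — real manufacturer
  derivations are unpublished — but it produces the documented
  consequence: software-sensor recordings of two devices agree
  noticeably less (r ≈ 0.55–0.95 across seeds) than hardware-sensor
  recordings (r ≈ 0.999) in the same run. A fixed, device-independent
  lag cannot produce that regime, which is why the lag is per-device.
* **Faults**: `pause(t, dur)` suspends emission while clock probes keep
  answering; `terminate(t)` stops both. Overlapping faults are rejected.

Not emulated: sensor physics (IMU dynamics, gravity decomposition),
audio/GPS/camera, OS scheduling beyond the load-model lookup, network
transport beyond symmetric-delay-plus-jitter probes, packet loss.
Passing tests therefore demonstrate the correctness of the
synchronization/recording machinery under realistic clock and rate
behaviour — not the fidelity of any physical sensor model.

## Scenarios and problem sizes

Scenario durations are 60 s (two-device sine, two-device sensors,
dual-recorder) and 300 s (same-device recording), deliberately
desk-scale versions of the multi-minute hardware sessions they model;
every number the scenarios report is recomputed at run time from these
simulated durations. Pass thresholds live in one constants table
(`scenarios.THRESHOLDS`): minimum sine-channel correlation 0.9,
dual-recorder channel correlation 0.96 (treated as a lower bound), 
sensor correlation 0.9, maximum crash loss 0.5 s, cadences 5 s and
0.5 s. Scenario 2 uses a 100 Hz nominal / 94 Hz effective source — the
source's scripted generator paced slower than asked, a behaviour the
simulator reproduces as configuration; its two recorded files must also
show equal effective rates and zero gaps. Trailing crash loss is
measured against the simulator's ledger as the true-time span from the
first to the last unrecovered sample — the duration of the lost data
segment itself.

## Known limitations

* Transport is in-process; cross-host operation, discovery and
  backpressure are out of scope by design.
* Clock drift is modelled as linear; thermal wander is not simulated
  (the piecewise offset interpolation would absorb slow wander, but no
  test exercises it).
* The software-sensor transform is a plausible stand-in, not a model of
  any specific device.
* Dual-recorder correlations are near-perfect by construction once the
  files are re-mastered to one clock, because both recorders receive
  identical samples; the discriminating checks in those scenarios are
  conservation, gap-freedom and rate equality.
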