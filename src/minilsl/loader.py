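"""Post-hoc synchronization of recorded streams.

Once a recording is on disk, four steps turn per-device timestamps into
comparable time series:

1. **synchronize** — map each stream's raw source-clock timestamps onto
   the recorder clock by adding the interpolated clock offset
   (``corrected = raw + offset_at(series, t)``);
2. **dejitter** — replace noisy per-sample timestamps with the
   least-squares line of timestamp versus sample index, per contiguous
   segment (segments split at gaps);
3. **effective rate / gap detection** — ``(N - 1) / (last - first)`` and a
   scan of inter-sample intervals against a gap threshold, which is how
   "no data loss" is verified;
4. **align** — resample several streams onto one common grid (linear
   interpolation over the overlap window) so channels recorded at 203 and
   213 Hz on different devices can be correlated sample-by-sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .streaming import OffsetSeries
from .xdf import FooterStats, StreamRecording, XdfRecording

__all__ = [
    "SyncStream",
    "SynchronizedRecording",
    "GapReport",
    "AlignedStreams",
    "synchronize",
    "apply_offsets",
    "resynchronize",
    "dejitter",
    "effective_srate",
    "detect_gaps",
    "align_streams",
    "channel_correlation",
    "default_gap_threshold",
]


def default_gap_threshold(nominal_srate: float) -> float:
    """Twice the nominal sample interval, or 500 ms, whichever is larger."""
    if nominal_srate <= 0:
        return 0.5
    return max(2.0 / nominal_srate, 0.5)


@dataclass
class SyncStream:
    """One stream with raw, corrected and optionally dejittered timestamps."""

    info: "object"
    values: np.ndarray
    raw_timestamps: np.ndarray
    corrected_timestamps: np.ndarray
    offsets: OffsetSeries
    footer: FooterStats | None = None
    synchronized: bool = True  # False: no offsets on file (e.g. killed recording)
    dejittered_timestamps: np.ndarray | None = None
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def timestamps(self) -> np.ndarray:
        """Best available time axis: dejittered if present, else corrected."""
        if self.dejittered_timestamps is not None:
            return self.dejittered_timestamps
        return self.corrected_timestamps


@dataclass
class SynchronizedRecording:
    streams: dict[int, SyncStream]

    def by_name(self, name: str) -> SyncStream:
        for s in self.streams.values():
            if getattr(s.info, "name", None) == name:
                return s
        raise KeyError(f"no stream named {name!r}")


@dataclass
class GapReport:
    """Gaps (start, duration) per stream plus the implied missing-sample count."""

    gaps: list[tuple[float, float]]
    total_missing_expected_samples: int
    irregular: bool = False  # srate 0: gap analysis not defined

    @property
    def has_loss(self) -> bool:
        return bool(self.gaps)


def synchronize(
    recording: XdfRecording,
    method: str = "piecewise",
    apply_dejitter: bool = False,
) -> SynchronizedRecording:
    """Apply each stream's recorded clock-offset series to its timestamps.

    ``method="piecewise"`` interpolates the offset series piecewise-linearly
    (robust when drift is not perfectly linear); ``method="linear"`` fits
    one global least-squares line through the series instead. Streams with
    no offsets on file — the killed-recording case — are passed through
    unchanged and flagged ``synchronized=False``.
    """
    out: dict[int, SyncStream] = {}
    for sid, s in recording.streams.items():
        raw = s.timestamps
        series = s.offsets
        if not series and s.footer is not None and s.footer.offsets:
            series = s.footer.offsets
        if not series:
            sync = SyncStream(
                info=s.info,
                values=s.values,
                raw_timestamps=raw,
                corrected_timestamps=raw.copy(),
                offsets=series,
                footer=s.footer,
                synchronized=False,
            )
        else:
            corrected = raw + _offsets_on(series, raw, method)
            sync = SyncStream(
                info=s.info,
                values=s.values,
                raw_timestamps=raw,
                corrected_timestamps=corrected,
                offsets=series,
                footer=s.footer,
                synchronized=True,
            )
        if apply_dejitter and s.info.nominal_srate > 0 and len(raw) >= 2:
            dj, segs = dejitter(sync.corrected_timestamps, s.info.nominal_srate)
            sync.dejittered_timestamps = dj
            sync.segments = segs
        out[sid] = sync
    return SynchronizedRecording(out)


def _offsets_on(series: OffsetSeries, raw: np.ndarray, method: str) -> np.ndarray:
    # offset records are indexed by consumer time; raw timestamps are source
    # time. Offsets are a few seconds at most and change by ppm-scale drift,
    # so evaluating the series at source time mis-places the query by the
    # offset itself, biasing the correction by offset * drift — nanoseconds
    # here — which one fixed-point refinement removes.
    t = np.asarray(raw, dtype=float)
    if method == "linear":
        ct = np.array([r.collection_time for r in series.records])
        off = np.array([r.offset for r in series.records])
        if len(ct) == 1:
            return np.full_like(t, off[0])
        slope, intercept = np.polyfit(ct, off, 1)
        first = slope * t + intercept
        return slope * (t + first) + intercept
    if method != "piecewise":
        raise ValueError(f"unknown synchronization method {method!r}")
    # np.interp == offset_at's piecewise-linear rule, vectorized
    ct = np.array([r.collection_time for r in series.records])
    off = np.array([r.offset for r in series.records])
    first = np.interp(t, ct, off)
    return np.interp(t + first, ct, off)


def apply_offsets(
    timestamps: Sequence[float],
    series: OffsetSeries,
    method: str = "piecewise",
) -> np.ndarray:
    """Map raw source-clock timestamps onto a consumer clock via an offset series.

    This is the core correction ``corrected = raw + offset`` exposed for
    re-mastering: any offset series measured against the same source clock
    can be applied to that source's raw timestamps, so two recordings of
    one source can be expressed on one reference recorder's clock.
    """
    t = np.asarray(timestamps, dtype=float)
    return t + _offsets_on(series, t, method)


def resynchronize(stream: SyncStream, series: OffsetSeries, method: str = "piecewise") -> SyncStream:
    """A copy of ``stream`` whose corrected axis uses ``series`` instead.

    Used for cross-file comparison: re-express a stream recorded by one
    recorder on another recorder's master clock, using the latter's offset
    series for the same source.
    """
    corrected = apply_offsets(stream.raw_timestamps, series, method)
    out = SyncStream(
        info=stream.info,
        values=stream.values,
        raw_timestamps=stream.raw_timestamps,
        corrected_timestamps=corrected,
        offsets=series,
        footer=stream.footer,
        synchronized=True,
    )
    if stream.dejittered_timestamps is not None:
        nominal = getattr(stream.info, "nominal_srate", 0.0)
        if nominal > 0 and len(corrected) >= 2:
            dj, segs = dejitter(corrected, nominal)
            out.dejittered_timestamps = dj
            out.segments = segs
    return out


def dejitter(
    timestamps: Sequence[float],
    nominal_srate: float,
    gap_threshold: float | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Regularize timestamps by per-segment least-squares regression.

    The timestamp sequence is split wherever consecutive spacing exceeds
    ``gap_threshold`` (default :func:`default_gap_threshold`); within each
    segment, timestamps are replaced by the fitted line of timestamp
    against sample index. Returns the new timestamps and the segment index
    ranges ``[(start, stop), ...)`` (half-open).

    Irregular streams (``nominal_srate = 0``) are returned unchanged with a
    warning: without a rate there is no grid to regularize to.
    """
    ts = np.asarray(timestamps, dtype=float)
    if nominal_srate <= 0:
        warnings.warn("dejitter: irregular stream (nominal_srate=0), returning unchanged")
        return ts.copy(), [(0, len(ts))] if len(ts) else []
    if len(ts) < 2:
        return ts.copy(), [(0, len(ts))] if len(ts) else []
    thr = gap_threshold if gap_threshold is not None else default_gap_threshold(nominal_srate)
    breaks = np.flatnonzero(np.diff(ts) > thr) + 1
    bounds = [0, *breaks.tolist(), len(ts)]
    out = ts.copy()
    segments: list[tuple[int, int]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segments.append((a, b))
        if b - a >= 2:
            idx = np.arange(b - a, dtype=float)
            slope, intercept = np.polyfit(idx, ts[a:b], 1)
            fitted = intercept + slope * idx
            if slope <= 0:  # degenerate segment; keep raw rather than fold time
                continue
            out[a:b] = fitted
    return out, segments


def effective_srate(
    timestamps: Sequence[float] | None = None,
    footer: FooterStats | None = None,
) -> float | None:
    """Measured rate ``(N - 1) / (last - first)`` in Hz.

    Prefers footer statistics when given (they cover the whole recording
    even if the caller holds a slice); with fewer than 2 samples the rate
    is undefined and None is returned.
    """
    if footer is not None:
        if footer.sample_count < 2 or footer.last_timestamp <= footer.first_timestamp:
            return None
        return (footer.sample_count - 1) / (footer.last_timestamp - footer.first_timestamp)
    if timestamps is None:
        raise ValueError("need timestamps or a footer")
    ts = np.asarray(timestamps, dtype=float)
    if len(ts) < 2 or ts[-1] <= ts[0]:
        return None
    return (len(ts) - 1) / (ts[-1] - ts[0])


def detect_gaps(
    timestamps: Sequence[float],
    nominal_srate: float,
    gap_threshold: float | None = None,
) -> GapReport:
    """Scan inter-sample intervals for gaps (candidate data loss or pauses).

    ``total_missing_expected_samples`` counts, per gap, how many samples a
    regular stream at ``nominal_srate`` would have delivered in it:
    ``round(gap * srate - 1)``.
    """
    ts = np.asarray(timestamps, dtype=float)
    if nominal_srate <= 0:
        return GapReport(gaps=[], total_missing_expected_samples=0, irregular=True)
    thr = gap_threshold if gap_threshold is not None else default_gap_threshold(nominal_srate)
    dt = np.diff(ts)
    idx = np.flatnonzero(dt > thr)
    gaps = [(float(ts[i]), float(dt[i])) for i in idx]
    missing = int(sum(max(round(d * nominal_srate - 1), 0) for _, d in gaps))
    return GapReport(gaps=gaps, total_missing_expected_samples=missing)


@dataclass
class AlignedStreams:
    """Several streams resampled onto one shared grid."""

    grid: np.ndarray  # common timestamps, spacing exactly 1/target_rate
    matrices: list[np.ndarray]  # per input stream, (len(grid), channels)
    t_start: float
    t_end: float

    def trimmed(self, edge: float = 1.0) -> list[np.ndarray]:
        """Matrices restricted to the grid at least ``edge`` s from either end,
        dodging interpolation edge effects."""
        m = (self.grid >= self.t_start + edge) & (self.grid <= self.t_end - edge)
        if not m.any():
            raise ValueError("overlap too short for the requested edge trim")
        return [mat[m] for mat in self.matrices]


def align_streams(
    streams: Sequence[SyncStream],
    target_rate: float,
) -> AlignedStreams:
    """Resample streams onto a common grid over their overlapping time range.

    The grid starts at the latest first-timestamp, is spaced exactly
    ``1/target_rate``, and each channel is linearly interpolated onto it.
    Raises when the corrected time ranges do not overlap, naming the
    disjoint ranges.
    """
    if len(streams) < 2:
        raise ValueError("alignment needs at least 2 streams")
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    firsts = [float(s.timestamps[0]) for s in streams]
    lasts = [float(s.timestamps[-1]) for s in streams]
    t_start, t_end = max(firsts), min(lasts)
    if t_end <= t_start:
        ranges = ", ".join(
            f"{getattr(s.info, 'name', i)}: [{f:.3f}, {l:.3f}]"
            for i, (s, f, l) in enumerate(zip(streams, firsts, lasts))
        )
        raise ValueError(f"streams do not overlap in time ({ranges})")
    n = int(np.floor((t_end - t_start) * target_rate)) + 1
    grid = t_start + np.arange(n) / target_rate
    mats = []
    for s in streams:
        vals = np.asarray(s.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        cols = [np.interp(grid, s.timestamps, vals[:, c]) for c in range(vals.shape[1])]
        mats.append(np.column_stack(cols))
    return AlignedStreams(grid=grid, matrices=mats, t_start=t_start, t_end=t_end)


def channel_correlation(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; None when undefined.

    Undefined for fewer than 3 points or when either input has zero
    variance (e.g. an all-zero channel from a silent source).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        return None
    sa = a - a.mean()
    sb = b - b.mean()
    na, nb = np.sqrt(np.dot(sa, sa)), np.sqrt(np.dot(sb, sb))
    if na == 0.0 or nb == 0.0:
        return None
    return float(np.dot(sa, sb) / (na * nb))
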