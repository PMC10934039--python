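"""ECG and R-R interval input, R-peak detection, artifact correction and tachogram resampling.

The pipeline's front end: read a single-lead ECG (plain CSV or a WFDB-style
text record) or a precomputed R-R list, detect QRS complexes, form the
beat-to-beat interval series, replace isolated ectopic/paroxysmal intervals
(outside 273-1500 ms) by the mean of their neighbours, and resample the
interval-versus-time curve on a uniform grid at the mean heart rate so that
autoregressive spectral analysis can be applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import (
    DetectionError,
    FormatError,
    InsufficientDataError,
    ParseError,
    RRCleaningError,
    ValidationError,
)

# physiological acceptance window for a single R-R interval, ms
RR_MIN_MS = 273.0
RR_MAX_MS = 1500.0

FLAG_ACCEPTED = "accepted"
FLAG_REPLACED = "replaced"
FLAG_EXCLUDED = "excluded_boundary"


@dataclass
class ECGRecord:
    """Single-lead ECG voltage series sampled at ``fs`` Hz starting at ``t0`` s."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    annotations: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValidationError("ECG record has no samples")
        dur = self.duration
        for label, t in self.annotations:
            if not (self.t0 <= t <= self.t0 + dur):
                raise ValidationError(
                    f"annotation {label!r} at {t} s outside recording "
                    f"[{self.t0}, {self.t0 + dur}] s"
                )

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class RPeakTrain:
    """Strictly increasing R-peak times in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("R-peak times must be strictly increasing")


@dataclass
class RRSeries:
    """Beat-to-beat intervals (ms) with onset times (s) and per-interval quality flags.

    ``n_excluded_boundary`` counts out-of-range intervals dropped at the series
    edges during cleaning (they have no two accepted neighbours to average).
    """

    intervals: np.ndarray
    onsets: np.ndarray
    flags: np.ndarray = None
    n_excluded_boundary: int = 0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.intervals.size, FLAG_ACCEPTED, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if self.intervals.size != self.onsets.size or self.intervals.size != self.flags.size:
            raise ValidationError("intervals, onsets and flags must be equal length")
        if np.any(self.intervals <= 0):
            raise ValidationError("R-R intervals must be positive")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")

    @property
    def span(self) -> float:
        """Total time covered, s (start of first beat to end of last interval)."""
        if self.intervals.size == 0:
            return 0.0
        return float(self.onsets[-1] + self.intervals[-1] / 1000.0 - self.onsets[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "rr_ms": self.intervals, "flag": self.flags}
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Tachogram:
    """R-R intervals (ms) interpolated on a uniform grid at ``rate`` Hz."""

    values: np.ndarray
    rate: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValidationError("tachogram rate must be positive")
        if np.any(self.values <= 0):
            raise ValidationError("tachogram values must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) / self.rate

    @property
    def span(self) -> float:
        return (self.values.size - 1) / self.rate


def read_ecg(path: str | os.PathLike, format: str = "csv") -> ECGRecord:
    """Read an ECG recording.

    ``csv``: two columns ``time_s,voltage`` with a header, uniform sampling
    (<= 1 % jitter tolerated); sampling rate inferred from the median sample
    spacing. ``wfdb-style``: a text record directory with ``<name>.hea``
    (``fs`` line) and ``<name>.csv`` (voltage column). An optional sidecar
    ``<stem>.annotations.csv`` (columns ``label,time_s``) provides state marks.
    """
    if format == "csv":
        rec = _read_ecg_csv(path)
    elif format == "wfdb-style":
        rec = _read_ecg_wfdb_style(path)
    else:
        raise ValidationError(f"unknown ECG format {format!r}")
    ann = _read_annotation_sidecar(path)
    if ann:
        rec.annotations = ann
        rec.__post_init__()
    return rec


def _read_ecg_csv(path: str | os.PathLike) -> ECGRecord:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("time_s", "voltage"):
        if col not in df.columns:
            raise ParseError(f"{path}: line 1: missing required column {col!r}")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["voltage"].to_numpy(dtype=float)
    if np.any(np.isnan(t)) or np.any(np.isnan(v)):
        bad = int(np.argmax(np.isnan(t) | np.isnan(v)))
        raise ParseError(f"{path}: line {bad + 2}: non-numeric value")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise FormatError(f"{path}: line {bad + 3}: non-increasing timestamp")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise FormatError(
            f"{path}: non-uniform sampling (jitter exceeds 1% of median spacing {med:g} s)"
        )
    return ECGRecord(samples=v, fs=1.0 / med, t0=float(t[0]))


def _read_ecg_wfdb_style(path: str | os.PathLike) -> ECGRecord:
    """Minimal text-layout record reader: ``<dir>/<name>.hea`` + ``<name>.csv``.

    The header's first line is ``<name> <n_sig> <fs> <n_samp>``; the csv holds
    one ``voltage`` column. This is a plain-text stand-in layout, not the
    binary WFDB format.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        heas = [f for f in sorted(os.listdir(path)) if f.endswith(".hea")]
        if not heas:
            raise ParseError(f"{path}: no .hea header file found")
        hea_path = os.path.join(path, heas[0])
    else:
        hea_path = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea_path):
        raise ParseError(f"{hea_path}: header file not found")
    with open(hea_path) as fh:
        header = fh.readline().split()
    if len(header) < 3:
        raise ParseError(f"{hea_path}: line 1: malformed header")
    name = header[0]
    try:
        fs = float(header[2])
    except ValueError as exc:
        raise ParseError(f"{hea_path}: line 1: bad sampling rate {header[2]!r}") from exc
    csv_path = os.path.join(os.path.dirname(hea_path), name + ".csv")
    try:
        df = pd.read_csv(csv_path)
    except (FileNotFoundError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{csv_path}: {exc}") from exc
    if "voltage" not in df.columns:
        raise ParseError(f"{csv_path}: line 1: missing column 'voltage'")
    return ECGRecord(samples=df["voltage"].to_numpy(dtype=float), fs=fs)


def _read_annotation_sidecar(path: str | os.PathLike) -> list[tuple[str, float]]:
    path = os.fspath(path)
    stem = path[:-4] if path.endswith(".csv") else path
    side = stem + ".annotations.csv"
    if not os.path.exists(side):
        return []
    df = pd.read_csv(side)
    if "label" not in df.columns or "time_s" not in df.columns:
        raise ParseError(f"{side}: line 1: expected columns label,time_s")
    return [(str(r.label), float(r.time_s)) for r in df.itertuples()]


def detect_r_peaks(ecg: ECGRecord, refractory_s: float = 0.25) -> RPeakTrain:
    """Detect R peaks with a Pan-Tompkins-style energy detector.

    Bandpass 5-25 Hz, differentiate, square, 150-ms moving-window integration,
    adaptive threshold, 250-ms refractory period; each candidate is refined to
    the local raw-signal extremum.
    """
    if ecg.fs < 100:
        raise ValidationError(f"sampling rate {ecg.fs:g} Hz below the 100 Hz minimum")
    if ecg.duration < 10:
        raise InsufficientDataError(
            f"recording of {ecg.duration:.1f} s too short for peak detection (need >= 10 s)"
        )
    x = ecg.samples - np.mean(ecg.samples)
    if np.max(np.abs(x)) == 0:
        raise DetectionError("flat-line ECG: zero signal variance")

    nyq = ecg.fs / 2.0
    sos = sps.butter(2, [5 / nyq, 25 / nyq], btype="band", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * ecg.fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    thr = 0.25 * float(np.percentile(mwi, 99))
    dist = max(1, int(round(refractory_s * ecg.fs)))
    locs, _ = sps.find_peaks(mwi, height=thr, distance=dist)
    if locs.size == 0:
        raise DetectionError("no QRS candidates above threshold")

    # refine each candidate to the dominant raw deflection within +/-60 ms
    half = int(round(0.060 * ecg.fs))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        seg = bp[lo:hi]
        refined.append(lo + int(np.argmax(np.abs(seg))))
    refined = np.unique(refined)
    # enforce the refractory constraint after refinement
    keep = [refined[0]]
    for idx in refined[1:]:
        if idx - keep[-1] >= dist:
            keep.append(idx)
    times = ecg.t0 + np.asarray(keep, dtype=float) / ecg.fs
    return RPeakTrain(times=times)


def rr_from_peaks(peaks: RPeakTrain) -> RRSeries:
    """Successive R-peak differences in ms; onset of each interval is its first beat."""
    t = peaks.times
    if t.size < 2:
        raise InsufficientDataError("need at least 2 R peaks to form an interval")
    intervals = np.diff(t) * 1000.0
    return RRSeries(intervals=intervals, onsets=t[:-1])


def read_rr_csv(path: str | os.PathLike) -> RRSeries:
    """Read a precomputed R-R list: CSV with columns ``onset_s, rr_ms``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    for col in ("onset_s", "rr_ms"):
        if col not in df.columns:
            raise ParseError(f"{path}: line 1: missing required column {col!r}")
    flags = (
        df["flag"].to_numpy(dtype=object)
        if "flag" in df.columns
        else None
    )
    return RRSeries(
        intervals=df["rr_ms"].to_numpy(dtype=float),
        onsets=df["onset_s"].to_numpy(dtype=float),
        flags=flags,
    )


def clean_rr(rr: RRSeries, lo: float = RR_MIN_MS, hi: float = RR_MAX_MS) -> RRSeries:
    """Replace isolated out-of-range intervals by the mean of their accepted neighbours.

    Intervals outside ``[lo, hi]`` ms (paroxysmal/ectopic beats) are replaced
    by the average of the preceding and following in-range intervals. An
    out-of-range interval at either end of the series lacks two neighbours and
    is dropped (counted in ``n_excluded_boundary``). Two or more consecutive
    out-of-range intervals are not correctable by this rule and raise
    :class:`RRCleaningError`.
    """
    if rr.intervals.size == 0:
        raise InsufficientDataError("empty R-R series")
    vals = rr.intervals.copy()
    out = (vals < lo) | (vals > hi)
    if np.any(out[:-1] & out[1:]):
        first = int(np.argmax(out[:-1] & out[1:]))
        raise RRCleaningError(
            f"two or more consecutive out-of-range intervals at index {first}; "
            "record not correctable by neighbour averaging"
        )
    flags = np.full(vals.size, FLAG_ACCEPTED, dtype=object)
    keep = np.ones(vals.size, dtype=bool)
    n_excl = rr.n_excluded_boundary
    for i in np.flatnonzero(out):
        if i == 0 or i == vals.size - 1:
            keep[i] = False
            n_excl += 1
        else:
            vals[i] = 0.5 * (vals[i - 1] + vals[i + 1])
            flags[i] = FLAG_REPLACED
    # preserve pre-existing replacement flags on already-clean input
    prev_replaced = rr.flags == FLAG_REPLACED
    flags[prev_replaced & (flags == FLAG_ACCEPTED)] = FLAG_REPLACED
    return RRSeries(
        intervals=vals[keep],
        onsets=rr.onsets[keep],
        flags=flags[keep],
        n_excluded_boundary=n_excl,
    )


def resample_tachogram(rr: RRSeries, min_span_s: float = 30.0) -> Tachogram:
    """Resample the interval-vs-onset-time curve on a uniform grid at the mean heart rate.

    The resampling rate is ``1000 / mean(intervals)`` Hz (mean beats per
    second over the whole cleaned recording). Cubic-spline interpolation,
    falling back to linear when fewer than 4 beats are available.
    """
    if rr.span < min_span_s:
        raise InsufficientDataError(
            f"R-R span {rr.span:.1f} s shorter than the {min_span_s:g} s minimum"
        )
    rate = 1000.0 / float(np.mean(rr.intervals))
    t0 = float(rr.onsets[0])
    n = int(np.floor((rr.onsets[-1] - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    if rr.intervals.size >= 4:
        interp = CubicSpline(rr.onsets, rr.intervals)
        values = interp(grid)
    else:
        values = np.interp(grid, rr.onsets, rr.intervals)
    return Tachogram(values=values, rate=rate, t_start=t0)
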