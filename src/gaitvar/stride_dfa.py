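"""Stride intervals from a foot accelerometer and detrended fluctuation
analysis of the resulting interval series."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from gaitvar._exceptions import (
    DegenerateSeriesError,
    SeriesTooShortError,
)
from gaitvar.io_segmentation import AccelTrace, WalkingBout, vector_norm

logger = logging.getLogger(__name__)

#: Fewer detected strides than this is an error: the smallest DFA box (16)
#: needs headroom to fit a meaningful box-size range.
MIN_STRIDES = 64

PLAUSIBLE_INTERVAL_S = (0.4, 2.5)


@dataclass
class StrideDetectionConfig:
    min_prominence: float = 1.0          # g, on the gravity-free foot norm
    plausible_s: tuple[float, float] = PLAUSIBLE_INTERVAL_S
    channel: str = "norm"                # or 'ax'/'ay'/'az'
    min_strides: int = MIN_STRIDES


@dataclass
class StrideSeries:
    """Ordered stride durations plus the sample indices of their events."""

    intervals: np.ndarray      # seconds, after the plausibility gate
    source_peaks: np.ndarray   # sample indices in the source trace
    excluded: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.source_peaks = np.asarray(self.source_peaks, dtype=np.int64)
        if np.any(self.intervals <= 0):
            raise ValueError("stride intervals must be positive")

    @property
    def n(self) -> int:
        return len(self.intervals)


@dataclass
class DFAResult:
    alpha: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_r2: float


def detect_strides(foot: AccelTrace, bout: WalkingBout | None = None,
                   cfg: StrideDetectionConfig | None = None) -> StrideSeries:
    """Detect stride events as prominent peaks of the foot signal.

    Peaks of the gravity-free vector norm (default channel) with prominence
    >= ``cfg.min_prominence`` are located in two passes: a permissive first
    pass, then a second pass whose minimum peak separation is half the
    median stride time of the first.  Intervals outside the plausibility
    gate are excluded and logged together with their neighbours.
    """
    cfg = cfg or StrideDetectionConfig()
    s, e = (bout.start_idx, bout.end_idx) if bout is not None else (0, len(foot))
    if cfg.channel == "norm":
        sig = vector_norm(foot)[s:e]
    else:
        sig = getattr(foot, cfg.channel)[s:e]

    lo_s, hi_s = cfg.plausible_s
    first, _ = find_peaks(sig, prominence=cfg.min_prominence,
                          distance=max(1, int(round(0.5 * lo_s * foot.fs))))
    if len(first) < 2:
        raise SeriesTooShortError(
            f"found {len(first)} peaks; cannot form stride intervals")
    med_stride = float(np.median(np.diff(first))) / foot.fs
    peaks, _ = find_peaks(sig, prominence=cfg.min_prominence,
                          distance=max(1, int(round(0.5 * med_stride * foot.fs))))
    peaks = peaks + s

    intervals = np.diff(peaks) / foot.fs
    ok = (intervals >= lo_s) & (intervals <= hi_s)
    excluded = np.flatnonzero(~ok)
    if len(excluded):
        for k in excluded:
            logger.warning(
                "excluding implausible stride interval %.3f s between peaks "
                "%d and %d (neighbours: %s s)",
                intervals[k], peaks[k], peaks[k + 1],
                intervals[max(0, k - 1): k + 2].round(3).tolist(),
            )
    kept = intervals[ok]
    if len(kept) < cfg.min_strides:
        raise SeriesTooShortError(
            f"detected {len(kept)} plausible strides; need >= "
            f"{cfg.min_strides} for fluctuation analysis"
        )
    return StrideSeries(intervals=kept, source_peaks=peaks, excluded=excluded)


def _box_mse(profile: np.ndarray, n: int, order: int) -> np.ndarray:
    """Mean squared detrending residual of each non-overlapping box."""
    k = len(profile) // n
    boxes = profile[: k * n].reshape(k, n)
    t = np.arange(n, dtype=float)
    # least-squares polynomial detrend, vectorized across boxes
    design = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(design, boxes.T, rcond=None)
    resid = boxes.T - design @ coef
    return np.mean(resid**2, axis=0)


def dfa(intervals, box_min: int = 16, box_max: int | None = None,
        n_boxes: int = 16, order: int = 1,
        coverage: str = "both") -> DFAResult:
    """Detrended fluctuation analysis of a stride-interval series.

    The mean-centred series is integrated (cumulative sum), partitioned
    into non-overlapping boxes of each size — from the start and, with
    ``coverage='both'`` (default), also from the end, averaging the two
    coverages — a least-squares linear trend (``order=1``) is removed per
    box, and F(n) is the RMS residual.  ``alpha`` is the log-log slope of
    F(n) over ``n_boxes`` box sizes evenly spaced on the log axis between
    ``box_min`` and ``floor(N/2)``.
    """
    x = intervals.intervals if isinstance(intervals, StrideSeries) \
        else np.asarray(intervals, dtype=float)
    n_total = len(x)
    if n_total < 2 * box_min * 2:
        raise SeriesTooShortError(
            f"series of length {n_total} too short for box_min={box_min}")
    box_max = int(n_total // 2) if box_max is None else min(int(box_max),
                                                            n_total // 2)
    sizes = np.unique(np.round(
        2.0 ** np.linspace(np.log2(box_min), np.log2(box_max), n_boxes)
    ).astype(int))
    sizes = sizes[(sizes >= box_min) & (sizes <= box_max)]

    profile = np.cumsum(x - np.mean(x))
    fluct = np.empty(len(sizes))
    for i, n in enumerate(sizes):
        mse = _box_mse(profile, n, order)
        if coverage == "both":
            mse = np.concatenate([mse, _box_mse(profile[::-1], n, order)])
        elif coverage != "forward":
            raise ValueError(f"unknown coverage {coverage!r}")
        fluct[i] = np.sqrt(np.mean(mse))
    if np.any(fluct == 0):
        raise DegenerateSeriesError("F(n) = 0 for some box size "
                                    "(constant or degenerate series)")

    log_n, log_f = np.log(sizes), np.log(fluct)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    pred = slope * log_n + intercept
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((log_f - pred) ** 2)) / ss_tot
    return DFAResult(alpha=float(slope), box_sizes=sizes, fluctuations=fluct,
                     fit_r2=r2)


def classify_persistence(alpha: float) -> str:
    """'persistent' if 0.7 <= alpha <= 1.0, 'anti-persistent' if alpha < 0.5,
    else 'indeterminate'."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if 0.7 <= alpha <= 1.0:
        return "persistent"
    if alpha < 0.5:
        return "anti-persistent"
    return "indeterminate"


def write_stride_series(path, series: StrideSeries, sep: str = "\t") -> None:
    """Export intervals as two-column delimited text (index, interval_s)."""
    data = np.column_stack([np.arange(series.n), series.intervals])
    np.savetxt(path, data, delimiter=sep, header=f"index{sep}interval_s",
               comments="", fmt=["%d", "%.9f"])


def read_stride_series(path, sep: str = "\t") -> StrideSeries:
    """Read a two-column (index, interval_s) delimited file."""
    data = np.loadtxt(path, delimiter=sep, skiprows=1, ndmin=2)
    intervals = data[:, 1]
    # source peaks unknown for externally produced series: synthesise
    # cumulative indices at 1 Hz bookkeeping resolution
    peaks = np.concatenate([[0], np.cumsum(intervals)]).round().astype(np.int64)
    return StrideSeries(intervals=intervals, source_peaks=peaks)
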