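"""Raw-trace input, walking-bout detection, tilt calibration, vector norm.

All acceleration values are expressed in g.  Sample indexing is 0-based and
ranges are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from gaitvar._exceptions import CalibrationError, DataError, FormatError

logger = logging.getLogger(__name__)

#: Standard gravity, used to convert m/s^2 inputs to g.
G_MS2 = 9.81

_SITES = ("lumbar", "foot")


@dataclass
class AccelTrace:
    """Uniformly sampled 3-axis acceleration record.

    Sample ``i`` is at time ``t0 + i / fs``.  Channels are raw sensor axes;
    anatomical meaning (AP/V/ML) is assigned later via an axis map.
    """

    t0: float
    fs: float
    site: str
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.ax)
        if n < 2 or len(self.ay) != n or len(self.az) != n:
            raise DataError("channels must have equal length >= 2")
        if self.site not in _SITES:
            raise DataError(f"site must be one of {_SITES}, got {self.site!r}")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def channels(self) -> np.ndarray:
        """Return the three channels stacked as an (n, 3) array."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class WalkingBout:
    """A steady-walking span of a trace, ``[start_idx, end_idx)``."""

    source: AccelTrace
    start_idx: int
    end_idx: int
    label: str = "segment1"

    def __post_init__(self) -> None:
        if not (0 <= self.start_idx < self.end_idx <= len(self.source)):
            raise DataError(
                f"invalid bout range [{self.start_idx}, {self.end_idx}) for "
                f"trace of length {len(self.source)}"
            )

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def duration_s(self) -> float:
        return len(self) / self.source.fs

    def channels(self) -> np.ndarray:
        return self.source.channels()[self.start_idx : self.end_idx]


@dataclass
class CalibratedSignals:
    """Tilt-corrected anatomical axes plus the gravity-free vector norm.

    ``v`` retains the +1 g static component; ``norm`` has 1 g subtracted.
    """

    fs: float
    ap: np.ndarray
    v: np.ndarray
    ml: np.ndarray
    norm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ap)
        if not (len(self.v) == len(self.ml) == len(self.norm) == n):
            raise DataError("all four signals must have the same length")

    def __len__(self) -> int:
        return len(self.ap)

    def axis(self, name: str) -> np.ndarray:
        """Return one signal by anatomical name: AP, V, ML, or N."""
        key = name.strip().lower()
        table = {"ap": self.ap, "v": self.v, "ml": self.ml,
                 "n": self.norm, "norm": self.norm}
        if key not in table:
            raise KeyError(f"unknown axis {name!r}; expected AP, V, ML or N")
        return table[key]


@dataclass
class TraceSchema:
    """Column mapping and unit declaration for a delimited trace file.

    ``time`` may be None for files without a time column (then ``fs`` is
    required).  ``unit`` is ``"g"`` or ``"m/s2"``; m/s^2 values are divided
    by 9.81 on read.
    """

    ax: str = "ax"
    ay: str = "ay"
    az: str = "az"
    time: str | None = "time"
    unit: str = "g"
    fs: float | None = None
    site: str = "lumbar"
    sep: str = ","


@dataclass
class SegmentationConfig:
    """Parameters of the automated walking-bout gate.

    ``explicit_ranges`` is a manual override: when set, exactly those
    ``(start, end)`` index ranges are returned, regardless of content.
    ``bridge_gaps_s > 0`` merges active runs separated by short pauses
    (default: split at every pause).
    """

    min_bout_s: float = 60.0
    activity_threshold: float = 0.01  # moving variance of the norm, g^2
    window_s: float = 2.0
    sf_band: tuple[float, float] = (1.2, 3.0)
    bridge_gaps_s: float = 0.0
    explicit_ranges: list[tuple[int, int]] | None = None


def read_trace(path, schema: TraceSchema | None = None) -> AccelTrace:
    """Read a delimited-text acceleration record into an :class:`AccelTrace`.

    The sampling rate is inferred from the median time step unless the
    schema overrides it.  Sampling jitter beyond 1% of the median step is
    rejected.
    """
    schema = schema or TraceSchema()
    try:
        df = pd.read_csv(path, sep=schema.sep, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in (schema.ax, schema.ay, schema.az):
        if col not in df.columns:
            raise FormatError(f"missing acceleration column {col!r} in {path}")
    chans = [df[c].to_numpy(dtype=float) for c in (schema.ax, schema.ay, schema.az)]
    if any(np.isnan(c).any() for c in chans):
        raise DataError(f"non-numeric or missing acceleration values in {path}")
    if schema.unit == "m/s2":
        chans = [c / G_MS2 for c in chans]
    elif schema.unit != "g":
        raise FormatError(f"unknown unit {schema.unit!r}; expected 'g' or 'm/s2'")

    t0 = 0.0
    if schema.time is not None and schema.time in df.columns:
        t = df[schema.time].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"non-monotone time column in {path}")
        med = float(np.median(dt))
        if np.max(np.abs(dt - med)) > 0.01 * med:
            raise DataError(f"non-uniform sampling in {path} (jitter > 1%)")
        fs = schema.fs if schema.fs is not None else 1.0 / med
        t0 = float(t[0])
    else:
        if schema.time is not None and schema.fs is None:
            raise FormatError(
                f"missing time column {schema.time!r} and no fs override in schema"
            )
        if schema.fs is None:
            raise FormatError("schema must provide fs when there is no time column")
        fs = schema.fs
    return AccelTrace(t0=t0, fs=float(fs), site=schema.site,
                      ax=chans[0], ay=chans[1], az=chans[2])


def write_trace(path, trace: AccelTrace, schema: TraceSchema | None = None) -> None:
    """Write a trace as delimited text, round-trippable via :func:`read_trace`.

    Values are written in full float precision so the round trip is
    bit-exact.
    """
    schema = schema or TraceSchema()
    cols = {}
    if schema.time is not None:
        cols[schema.time] = trace.t0 + np.arange(len(trace)) / trace.fs
    cols[schema.ax] = trace.ax
    cols[schema.ay] = trace.ay
    cols[schema.az] = trace.az
    pd.DataFrame(cols).to_csv(path, sep=schema.sep, index=False,
                              float_format="%.17g")


def vector_norm(ax, ay=None, az=None) -> np.ndarray:
    """Gravity-free vector magnitude: sqrt(ax^2 + ay^2 + az^2) - 1, in g.

    Accepts three channel arrays, an (n, 3) array, an :class:`AccelTrace`,
    or a :class:`WalkingBout`.  Orientation-independent by construction.
    """
    if ay is None:
        if isinstance(ax, (AccelTrace, WalkingBout)):
            arr = ax.channels()
        else:
            arr = np.asarray(ax, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise DataError("expected an (n, 3) array of channels")
        ax, ay, az = arr[:, 0], arr[:, 1], arr[:, 2]
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if ax.shape != ay.shape or ax.shape != az.shape:
        raise DataError("channel shape mismatch")
    return np.sqrt(ax**2 + ay**2 + az**2) - 1.0


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(freqs[np.argmax(spec)])


def detect_walking_bouts(trace: AccelTrace,
                         cfg: SegmentationConfig | None = None) -> list[WalkingBout]:
    """Isolate steady-walking bouts of a trace.

    A sample is *active* when the moving-window variance of the gravity-free
    norm exceeds ``cfg.activity_threshold``.  Contiguous active runs longer
    than ``cfg.min_bout_s`` whose dominant frequency falls in ``cfg.sf_band``
    become bouts.  Explicit index ranges in the config always win.

    Returns an empty list when nothing qualifies.
    """
    cfg = cfg or SegmentationConfig()
    if cfg.explicit_ranges is not None:
        return [WalkingBout(trace, s, e, label=f"segment{i + 1}")
                for i, (s, e) in enumerate(cfg.explicit_ranges)]

    norm = vector_norm(trace)
    win = max(3, int(round(cfg.window_s * trace.fs)))
    mean = uniform_filter1d(norm, win, mode="nearest")
    mean_sq = uniform_filter1d(norm**2, win, mode="nearest")
    var = np.maximum(mean_sq - mean**2, 0.0)
    active = var > cfg.activity_threshold

    # contiguous runs of active samples
    edges = np.flatnonzero(np.diff(active.astype(np.int8)))
    starts = list(edges[~active[edges]] + 1)
    ends = list(edges[active[edges]] + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(len(active))
    runs = list(zip(starts, ends))

    if cfg.bridge_gaps_s > 0 and len(runs) > 1:
        gap = int(round(cfg.bridge_gaps_s * trace.fs))
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged

    min_len = int(round(cfg.min_bout_s * trace.fs))
    bouts: list[WalkingBout] = []
    for s, e in runs:
        if e - s < min_len:
            logger.info("discarding short active span [%d, %d)", s, e)
            continue
        f_dom = _dominant_frequency(norm[s:e], trace.fs)
        if not (cfg.sf_band[0] <= f_dom <= cfg.sf_band[1]):
            logger.info("discarding span [%d, %d): dominant frequency %.2f Hz "
                        "outside band %s", s, e, f_dom, cfg.sf_band)
            continue
        bouts.append(WalkingBout(trace, s, e, label=f"segment{len(bouts) + 1}"))
    return bouts


def _anatomical_channels(bout, axis_map: dict[str, str] | None):
    """Map raw channels to (AP, V, ML) order, auto-assigning V if needed."""
    arr = bout.channels() if hasattr(bout, "channels") else np.asarray(bout, float)
    raw = {"ax": arr[:, 0], "ay": arr[:, 1], "az": arr[:, 2]}
    if axis_map is None:
        means = {k: abs(float(np.mean(v))) for k, v in raw.items()}
        v_key = max(means, key=means.get)
        rest = [k for k in ("ax", "ay", "az") if k != v_key]
        axis_map = {"ap": rest[0], "v": v_key, "ml": rest[1]}
        warnings.warn(
            "no axis map declared; assigning V to channel "
            f"{v_key!r} (largest mean) and AP/ML to {rest} in order",
            stacklevel=3,
        )
    signs = {}
    resolved = {}
    for anat in ("ap", "v", "ml"):
        key = axis_map[anat]
        sign = 1.0
        if key.startswith("-"):
            sign, key = -1.0, key[1:]
        resolved[anat] = raw[key]
        signs[anat] = sign
    return (resolved["ap"] * signs["ap"],
            resolved["v"] * signs["v"],
            resolved["ml"] * signs["ml"])


def calibrate_tilt(bout: WalkingBout | AccelTrace,
                   axis_map: dict[str, str] | None = None) -> CalibratedSignals:
    """Rotate the per-bout mean gravity vector onto the vertical axis.

    Two successive planar rotations computed from the mean accelerations:
    first in the sagittal (AP-V) plane, then in the frontal (ML-V) plane.
    The output V axis retains its +1 g static component; ``norm`` is the
    gravity-free vector magnitude of the raw channels (rotation-invariant,
    so it is computed before rotation).

    ``axis_map`` maps anatomical names to raw channels, e.g.
    ``{"ap": "ax", "v": "ay", "ml": "az"}`` (prefix a channel with ``-`` to
    flip its sign).  When omitted, V is auto-assigned to the channel with
    the largest absolute mean and a warning is issued.
    """
    fs = bout.fs if isinstance(bout, AccelTrace) else bout.source.fs
    ap, v, ml = _anatomical_channels(bout, axis_map)

    m_ap, m_v, m_ml = float(np.mean(ap)), float(np.mean(v)), float(np.mean(ml))
    g_mag = float(np.sqrt(m_ap**2 + m_v**2 + m_ml**2))
    if not (0.5 <= g_mag <= 1.5):
        raise CalibrationError(
            f"mean acceleration magnitude {g_mag:.3f} g outside [0.5, 1.5] g; "
            "sensor not near-static-gravity on average"
        )

    norm = np.sqrt(ap**2 + v**2 + ml**2) - 1.0

    # sagittal rotation: zero the mean AP component
    th1 = np.arctan2(m_ap, m_v)
    ap1 = ap * np.cos(th1) - v * np.sin(th1)
    v1 = ap * np.sin(th1) + v * np.cos(th1)
    # frontal rotation: zero the mean ML component
    m_v1 = float(np.mean(v1))
    th2 = np.arctan2(m_ml, m_v1)
    ml2 = ml * np.cos(th2) - v1 * np.sin(th2)
    v2 = ml * np.sin(th2) + v1 * np.cos(th2)

    return CalibratedSignals(fs=fs, ap=ap1, v=v2, ml=ml2, norm=norm)
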