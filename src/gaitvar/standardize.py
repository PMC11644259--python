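"""Step-frequency estimation and the fixed-size analysis segment.

Every analysed walking segment is truncated to ``n_steps`` steps and
resampled onto a uniform grid of ``n_steps * samples_per_step`` points
(defaults: 250 steps x 75 samples = 18,750), so one step spans exactly 75
samples and one stride 150 samples regardless of the walker's cadence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from gaitvar._exceptions import EstimationError, TruncationError
from gaitvar.io_segmentation import CalibratedSignals

#: Defaults of the standardized grid.
N_STEPS = 250
SAMPLES_PER_STEP = 75
STANDARD_LENGTH = N_STEPS * SAMPLES_PER_STEP  # 18,750
SF_BAND = (1.2, 3.0)


@dataclass
class StepFrequencyEstimate:
    """Dominant frequency of the vertical acceleration spectrum."""

    sf: float
    spectrum_peak_power: float  # fraction of in-band power near the peak
    band: tuple[float, float]
    at_band_edge: bool = False


@dataclass
class StandardizedSegment:
    """One walking segment on the standardized 18,750-sample grid."""

    ap: np.ndarray
    v: np.ndarray
    ml: np.ndarray
    norm: np.ndarray
    sf: float
    fs: float
    samples_per_step: int = SAMPLES_PER_STEP
    meta: dict = field(default_factory=dict)

    @property
    def samples_per_stride(self) -> int:
        return 2 * self.samples_per_step

    @property
    def n_samples(self) -> int:
        return len(self.ap)

    def __post_init__(self) -> None:
        n = len(self.ap)
        if not (len(self.v) == len(self.ml) == len(self.norm) == n):
            raise ValueError("all four signals must have the same length")

    def axis(self, name: str) -> np.ndarray:
        key = name.strip().lower()
        table = {"ap": self.ap, "v": self.v, "ml": self.ml,
                 "n": self.norm, "norm": self.norm}
        if key not in table:
            raise KeyError(f"unknown axis {name!r}; expected AP, V, ML or N")
        return table[key]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def estimate_step_frequency(v_signal: np.ndarray, fs: float,
                            band: tuple[float, float] = SF_BAND,
                            min_peak_fraction: float = 0.12,
                            ) -> StepFrequencyEstimate:
    """Locate the dominant frequency of the vertical axis within ``band``.

    The magnitude spectrum is zero-padded (8x) and the peak refined by
    parabolic interpolation around the maximum bin.  The relative peak
    power (power within +-2 native bins of the peak, over total in-band
    power) must exceed ``min_peak_fraction``; a flat spectrum raises
    :class:`EstimationError`.  A peak at a band edge sets ``at_band_edge``
    and emits a warning.
    """
    x = np.asarray(v_signal, dtype=float)
    if len(x) < 30 * fs:
        raise EstimationError(
            f"need >= 30 s of signal for step-frequency estimation, "
            f"got {len(x) / fs:.1f} s"
        )
    x = x - np.mean(x)
    n = len(x)

    # native-resolution power for the peak-significance gate
    pow_native = np.abs(np.fft.rfft(x)) ** 2
    f_native = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (f_native >= band[0]) & (f_native <= band[1])
    if not np.any(in_band):
        raise EstimationError(f"search band {band} contains no frequency bin")
    band_pow = pow_native[in_band]
    band_f = f_native[in_band]
    k_peak = int(np.argmax(band_pow))
    df = f_native[1] - f_native[0]
    near = np.abs(band_f - band_f[k_peak]) <= 2 * df
    peak_fraction = float(band_pow[near].sum() / band_pow.sum())
    if peak_fraction < min_peak_fraction:
        raise EstimationError(
            f"no dominant spectral peak in band {band} "
            f"(peak fraction {peak_fraction:.3f} < {min_peak_fraction})"
        )

    # refined location on a zero-padded spectrum
    n_pad = int(2 ** np.ceil(np.log2(n))) * 8
    mag = np.abs(np.fft.rfft(x, n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    idx_band = np.flatnonzero(sel)
    k = idx_band[np.argmax(mag[idx_band])]
    # "at the edge" means within one native-resolution bin of a band limit
    at_edge = (freqs[k] - band[0] < df) or (band[1] - freqs[k] < df)
    if at_edge:
        warnings.warn(
            f"step-frequency peak at band edge ({freqs[k]:.2f} Hz); "
            "estimate may be truncated", stacklevel=2)
        sf = float(freqs[k])
    else:
        # parabolic interpolation on the magnitude spectrum
        a, b, c = mag[k - 1], mag[k], mag[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        sf = float(freqs[k] + delta * (freqs[1] - freqs[0]))
    return StepFrequencyEstimate(sf=sf, spectrum_peak_power=peak_fraction,
                                 band=tuple(band), at_band_edge=at_edge)


def truncate_to_steps(signals: CalibratedSignals, sf: float,
                      n_steps: int = N_STEPS) -> CalibratedSignals:
    """Keep the first ``round(n_steps / sf * fs)`` samples of every axis."""
    n_keep = round_half_away(n_steps / sf * signals.fs)
    if len(signals) < n_keep:
        raise TruncationError(
            f"bout has {len(signals)} samples but {n_keep} are needed for "
            f"{n_steps} steps at sf = {sf:.3f} Hz "
            f"(short by {n_keep - len(signals)})"
        )
    return CalibratedSignals(
        fs=signals.fs,
        ap=signals.ap[:n_keep].copy(),
        v=signals.v[:n_keep].copy(),
        ml=signals.ml[:n_keep].copy(),
        norm=signals.norm[:n_keep].copy(),
    )


def _resample(y: np.ndarray, n_out: int, kind: str) -> np.ndarray:
    x_old = np.arange(len(y), dtype=float)
    x_new = np.linspace(0.0, len(y) - 1.0, n_out)
    if kind == "cubic":
        return CubicSpline(x_old, y)(x_new)
    if kind == "linear":
        return np.interp(x_new, x_old, y)
    raise ValueError(f"unknown interpolation kind {kind!r}")


def resample_to_standard(truncated: CalibratedSignals, sf: float,
                         n_steps: int = N_STEPS,
                         samples_per_step: int = SAMPLES_PER_STEP,
                         interpolation: str = "cubic",
                         meta: dict | None = None) -> StandardizedSegment:
    """Interpolate a truncated bout onto the standardized uniform grid.

    Each axis is interpolated independently onto ``n_steps *
    samples_per_step`` uniformly spaced points spanning the same time
    interval; the norm is resampled as a signal in its own right, not
    recomputed from the resampled axes.
    """
    n_out = n_steps * samples_per_step
    return StandardizedSegment(
        ap=_resample(truncated.ap, n_out, interpolation),
        v=_resample(truncated.v, n_out, interpolation),
        ml=_resample(truncated.ml, n_out, interpolation),
        norm=_resample(truncated.norm, n_out, interpolation),
        sf=sf,
        fs=truncated.fs,
        samples_per_step=samples_per_step,
        meta=dict(meta or {}),
    )


def standardize_bout(signals: CalibratedSignals,
                     band: tuple[float, float] = SF_BAND,
                     n_steps: int = N_STEPS,
                     samples_per_step: int = SAMPLES_PER_STEP,
                     interpolation: str = "cubic",
                     meta: dict | None = None) -> StandardizedSegment:
    """Convenience chain: estimate SF, truncate, resample."""
    est = estimate_step_frequency(signals.v, signals.fs, band=band)
    trunc = truncate_to_steps(signals, est.sf, n_steps=n_steps)
    return resample_to_standard(trunc, est.sf, n_steps=n_steps,
                                samples_per_step=samples_per_step,
                                interpolation=interpolation, meta=meta)
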