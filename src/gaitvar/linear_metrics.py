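"""Linear variability metrics: movement intensity and ACF regularity."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitvar.standardize import StandardizedSegment

#: r values are clamped to +-(1 - CLAMP_EPS) before the Fisher transform.
CLAMP_EPS = 1e-12


@dataclass
class IntensityResult:
    rms_norm: float
    rms_ml: float
    rms_ratio: float


@dataclass
class RegularityResult:
    """Autocorrelation peaks at the step and stride lags.

    ``r`` values live in [-1, 1]; ``z`` values are their Fisher transforms
    (atanh of the clamped r).  ``flags`` lists scales at which no interior
    local maximum was found in the search window (value still reported as
    the window maximum).
    """

    step_regularity_r: float
    stride_regularity_r: float
    step_regularity_z: float
    stride_regularity_z: float
    step_lag: int
    stride_lag: int
    flags: list = field(default_factory=list)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def movement_intensity(segment: StandardizedSegment) -> IntensityResult:
    """RMS of the vector norm, RMS of ML, and their ratio (ML / norm).

    No mean removal is applied beyond the 1 g already subtracted from the
    norm.
    """
    rms_norm = _rms(segment.norm)
    rms_ml = _rms(segment.ml)
    return IntensityResult(rms_norm=rms_norm, rms_ml=rms_ml,
                           rms_ratio=rms_ml / rms_norm)


def unbiased_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased autocorrelation of the mean-centred signal, lags 0..max_lag.

    Lag-k sums are divided by N - k and the sequence is normalized by its
    zero-lag value, so the result is 1.0 exactly at lag 0.
    """
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    n = len(x)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} >= series length {n}")
    # FFT-based raw autocovariance sums
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=n_fft)
    raw = np.fft.irfft(f * np.conj(f), n=n_fft)[: max_lag + 1]
    acf = raw / (n - np.arange(max_lag + 1))
    return acf / acf[0]


def fisher_z(r: float, clamp_eps: float = CLAMP_EPS) -> float:
    """atanh with r clamped to +-(1 - clamp_eps)."""
    r = float(np.clip(r, -1.0 + clamp_eps, 1.0 - clamp_eps))
    return float(np.arctanh(r))


def _window_peak(acf: np.ndarray, lo: int, hi: int) -> tuple[int, float, bool]:
    """Max of acf over inclusive lag window [lo, hi]; ties -> smaller lag.

    Also reports whether that maximum is an interior local maximum of the
    window (used to flag undefined regularity).
    """
    window = acf[lo : hi + 1]
    k = int(np.argmax(window))
    lag = lo + k
    is_local = 0 < k < len(window) - 1 and window[k] >= window[k - 1] \
        and window[k] >= window[k + 1]
    # a peak sitting exactly on the window edge may still be a local max
    # of the full ACF
    if not is_local and 0 < lag < len(acf) - 1:
        is_local = acf[lag] >= acf[lag - 1] and acf[lag] >= acf[lag + 1]
    return lag, float(window[k]), is_local


def acf_regularity(segment: StandardizedSegment,
                   window_frac: float = 0.5,
                   max_lag: int = 250) -> RegularityResult:
    """Step/stride regularity from the unbiased ACF of the vector norm.

    The step peak is the ACF maximum over lags ``[0.5, 1.5] x
    samples_per_step`` and the stride peak over ``[1.5, 2.5] x
    samples_per_step`` (windows set by ``window_frac``).  Peak values are
    Fisher-transformed after clamping.  The unbiased estimator is only
    searched up to ``max_lag`` (well below N/2) where it is well behaved.
    """
    sps = segment.samples_per_step
    acf = unbiased_acf(segment.norm, max_lag)

    step_lo = int(round((1.0 - window_frac) * sps))
    step_hi = int(round((1.0 + window_frac) * sps))
    stride_lo = step_hi + 1
    stride_hi = min(int(round((2.0 + window_frac) * sps)), max_lag)

    flags = []
    step_lag, step_r, step_ok = _window_peak(acf, step_lo, step_hi)
    if not step_ok:
        flags.append("step_peak_not_local_max")
    stride_lag, stride_r, stride_ok = _window_peak(acf, stride_lo, stride_hi)
    if not stride_ok:
        flags.append("stride_peak_not_local_max")

    return RegularityResult(
        step_regularity_r=step_r,
        stride_regularity_r=stride_r,
        step_regularity_z=fisher_z(step_r),
        stride_regularity_z=fisher_z(stride_r),
        step_lag=step_lag,
        stride_lag=stride_lag,
        flags=flags,
    )
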