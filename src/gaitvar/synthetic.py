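"""Seed-deterministic generators for ground-truthed test inputs.

Three families:

- stride-interval series with a controllable fluctuation scaling exponent
  (fractional Gaussian noise via circulant embedding, with a power-law
  spectral-synthesis fallback covering the nonstationary range);
- gait-like 3-axis lumbar and foot acceleration built on such a series,
  with known tilt, amplitudes, impact events and noise;
- a chaotic benchmark trajectory plus an independent variational estimate
  of its largest Lyapunov exponent for validating divergence-curve slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from gaitvar._exceptions import GeneratorError
from gaitvar.io_segmentation import AccelTrace
from gaitvar.stride_dfa import StrideSeries


@dataclass
class SynthSpec:
    """Parameters of one synthetic walking trial.

    ``mean_stride_s`` defaults to ``2 / sf`` (two steps per stride).
    ``target_alpha`` is the fluctuation scaling exponent imposed on the
    stride-interval series; the spectral mapping used is
    ``power ~ f^-(2*alpha - 1)`` on the interval series itself.
    """

    seed: int
    n_strides: int = 125
    target_alpha: float = 0.9
    sf: float = 1.9                       # step frequency, Hz
    mean_stride_s: float | None = None
    sd_stride_s: float = 0.012
    fs: float = 256.0
    tilt_deg: float = 8.0                 # sagittal-plane sensor tilt
    axis_amplitudes: tuple[float, float, float] = (0.30, 0.36, 0.23)  # AP,V,ML g
    harmonics: int = 3
    noise_sd: float = 0.01                # g, additive white noise
    amp_jitter: float = 0.02              # per-stride amplitude CV
    impact_amp: float = 0.15              # g, step-onset transient (lumbar)
    foot_spike_amp: float = 4.0           # g, stride impact spike (foot)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GeneratorError("seed is mandatory")
        if not (0.0 < self.target_alpha < 1.5):
            raise GeneratorError(
                f"target_alpha must lie in (0, 1.5), got {self.target_alpha}")
        if self.mean_stride_s is None:
            self.mean_stride_s = 2.0 / self.sf
        if self.sd_stride_s >= self.mean_stride_s / 5:
            raise GeneratorError(
                "sd_stride_s must be below mean_stride_s / 5 "
                f"({self.sd_stride_s} >= {self.mean_stride_s / 5:.3f})")


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    if np.min(lam) < -1e-8:
        raise GeneratorError(
            f"circulant embedding not positive semidefinite for alpha={hurst}; "
            "use method='spectral' instead")
    lam = np.maximum(lam, 0.0)
    m = 2 * n
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    a = rng.standard_normal(n - 1)
    b = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (a + 1j * b)
    w[n + 1:] = np.conj(w[n - 1:0:-1])
    return np.fft.fft(w)[:n].real


def _power_law_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^beta noise via spectral synthesis (unit variance)."""
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    freqs = np.fft.rfftfreq(n_fft)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    spec = amp * (re + 1j * im)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_fft)[:n]
    sd = np.std(x)
    if sd == 0:
        raise GeneratorError("degenerate spectral synthesis")
    return (x - np.mean(x)) / sd


def gen_stride_series(spec: SynthSpec,
                      method: str = "auto") -> tuple[StrideSeries, dict]:
    """Stride-interval series with imposed scaling exponent.

    ``method``: ``'davies-harte'`` (exact fGn, needs ``0 < alpha < 1``),
    ``'spectral'`` (power-law synthesis, whole (0, 1.5) range), or
    ``'auto'`` (Davies-Harte where defined, else spectral).  The raw series
    is standardized and rescaled to ``mean_stride_s`` / ``sd_stride_s``.

    Returns the series and a ground-truth record.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = spec.target_alpha
    if method == "auto":
        method = "davies-harte" if 0.0 < alpha < 1.0 else "spectral"
    if method == "davies-harte":
        if not (0.0 < alpha < 1.0):
            raise GeneratorError(
                "davies-harte requires 0 < alpha < 1; use method='spectral'")
        x = _fgn_davies_harte(spec.n_strides, alpha, rng)
        x = (x - np.mean(x)) / np.std(x)
    elif method == "spectral":
        x = _power_law_noise(spec.n_strides, 2.0 * alpha - 1.0, rng)
    else:
        raise GeneratorError(f"unknown method {method!r}")

    intervals = spec.mean_stride_s + spec.sd_stride_s * x
    if np.any(intervals <= 0):
        raise GeneratorError("generated non-positive stride interval; "
                             "reduce sd_stride_s")
    onsets_s = np.concatenate([[0.0], np.cumsum(intervals)])
    peaks = np.round(onsets_s * spec.fs).astype(np.int64)
    series = StrideSeries(intervals=intervals, source_peaks=peaks)
    truth = {
        "target_alpha": alpha,
        "method": method,
        "seed": spec.seed,
        "mean_stride_s": spec.mean_stride_s,
        "sd_stride_s": spec.sd_stride_s,
        "onsets_s": onsets_s,
        "spectral_beta": 2.0 * alpha - 1.0,
    }
    return series, truth


def _stride_phase(onsets_s: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Continuous stride phase (in strides) sampled at fs over the walk."""
    total = onsets_s[-1]
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    k = np.clip(np.searchsorted(onsets_s, t, side="right") - 1, 0,
                len(onsets_s) - 2)
    dur = onsets_s[k + 1] - onsets_s[k]
    phase = k + (t - onsets_s[k]) / dur
    return t, np.minimum(phase, len(onsets_s) - 1)


def _harmonic_sum(phase: np.ndarray, cycles_per_stride: float,
                  n_harm: int, phase_offsets: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phase)
    for h in range(1, n_harm + 1):
        out += np.sin(2 * np.pi * cycles_per_stride * h * phase
                      + phase_offsets[h - 1]) / h
    return out


def gen_trunk_accel(stride_series: StrideSeries, spec: SynthSpec,
                    truth: dict | None = None) -> tuple[AccelTrace, dict]:
    """Gait-like lumbar trace built on a stride-interval series.

    AP and V carry energy at step frequency (2 cycles/stride), ML at stride
    frequency (1 cycle/stride, modelling left-right asymmetry); each
    stride's waveform is time-warped to its interval.  A short
    impact-sharpening transient is added at every step onset, the declared
    tilt rotation is applied, and white noise is added.  The ground-truth
    record contains the untilted AP/V/ML signals and event indices.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    onsets_s = np.concatenate([[0.0], np.cumsum(stride_series.intervals)])
    t, phase = _stride_phase(onsets_s, spec.fs)
    n = len(t)
    a_ap, a_v, a_ml = spec.axis_amplitudes
    n_strides = len(stride_series.intervals)

    # fixed, deterministic harmonic phase offsets
    offs = np.linspace(0.0, np.pi / 3, spec.harmonics)

    # per-stride amplitude jitter (seeded)
    if spec.amp_jitter > 0:
        gains = 1.0 + spec.amp_jitter * rng.standard_normal(n_strides + 1)
        gains = np.clip(gains, 0.2, None)
        gain = gains[np.clip(phase.astype(int), 0, n_strides)]
    else:
        gain = np.ones(n)

    ap = a_ap * gain * _harmonic_sum(phase, 2.0, spec.harmonics, offs)
    v = a_v * gain * _harmonic_sum(phase, 2.0, spec.harmonics, offs + 0.7)
    ml = a_ml * gain * _harmonic_sum(phase, 1.0, spec.harmonics, offs + 1.3)

    # impact transient at each step onset (phase = k and k + 0.5)
    step_phase = (phase * 2.0) % 1.0
    impact = spec.impact_amp * np.exp(-0.5 * (step_phase / 0.03) ** 2) \
        * np.sin(2 * np.pi * 18.0 * step_phase)
    v = v + impact
    ap = ap + 0.5 * impact

    v_g = v + 1.0  # static gravity before tilt

    th = np.deg2rad(spec.tilt_deg)
    ax = ap * np.cos(th) + v_g * np.sin(th)
    ay = -ap * np.sin(th) + v_g * np.cos(th)
    az = ml.copy()

    if spec.noise_sd > 0:
        ax = ax + spec.noise_sd * rng.standard_normal(n)
        ay = ay + spec.noise_sd * rng.standard_normal(n)
        az = az + spec.noise_sd * rng.standard_normal(n)

    trace = AccelTrace(t0=0.0, fs=spec.fs, site="lumbar", ax=ax, ay=ay, az=az)
    step_onsets = np.round(np.sort(np.concatenate(
        [onsets_s[:-1], onsets_s[:-1] + stride_series.intervals / 2.0]
    )) * spec.fs).astype(np.int64)
    record = {
        "ap": ap, "v": v_g, "ml": ml,
        "tilt_deg": spec.tilt_deg,
        "sf_true": 2.0 / float(np.mean(stride_series.intervals)),
        "step_onset_idx": step_onsets,
        "stride_onset_idx": np.round(onsets_s * spec.fs).astype(np.int64),
        "axis_map": {"ap": "ax", "v": "ay", "ml": "az"},
    }
    if truth:
        record.update({k: v for k, v in truth.items() if k != "onsets_s"})
    return trace, record


def gen_foot_accel(stride_series: StrideSeries, spec: SynthSpec,
                   ) -> tuple[AccelTrace, dict]:
    """Foot trace: baseline noise plus one impact spike per stride onset.

    A series of ``n_strides`` intervals yields ``n_strides + 1`` spikes
    (fencepost: both ends of every stride are marked).  Ground-truth spike
    sample indices are returned.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    onsets_s = np.concatenate([[0.0], np.cumsum(stride_series.intervals)])
    # lead-in/out margin so the boundary spikes are proper local maxima
    margin = int(round(0.05 * spec.fs))
    n = int(round(onsets_s[-1] * spec.fs)) + 1 + 2 * margin
    idx = np.round(onsets_s * spec.fs).astype(np.int64) + margin

    noise = spec.noise_sd if spec.noise_sd > 0 else 0.0
    ax = noise * rng.standard_normal(n) if noise else np.zeros(n)
    ay = noise * rng.standard_normal(n) if noise else np.zeros(n)
    az = 1.0 + (noise * rng.standard_normal(n) if noise else np.zeros(n))

    # triangular spike, 5 samples wide, peak at the onset sample
    for j in idx:
        for off, w in ((-2, 0.25), (-1, 0.6), (0, 1.0), (1, 0.6), (2, 0.25)):
            k = j + off
            if 0 <= k < n:
                ax[k] += spec.foot_spike_amp * w
    trace = AccelTrace(t0=0.0, fs=spec.fs, site="foot", ax=ax, ay=ay, az=az)
    return trace, {"spike_idx": idx, "intervals_s": stride_series.intervals}


def gen_walking_trial(spec: SynthSpec, rest_s: float = 0.0,
                      ) -> tuple[AccelTrace, AccelTrace, dict]:
    """Full trial: lumbar + foot traces sharing one stride-interval series.

    ``rest_s`` pads near-still (gravity + small noise) spans before and
    after the walking bout; the ground-truth record carries the walking
    span indices for bout-detection validation.
    """
    series, truth = gen_stride_series(spec)
    lumbar, rec = gen_trunk_accel(series, spec, truth)
    foot, foot_rec = gen_foot_accel(series, spec)
    rec.update(foot_rec)
    rec["intervals_s"] = series.intervals
    if rest_s > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 31]))
        n_rest = int(round(rest_s * spec.fs))
        sd = max(spec.noise_sd, 1e-4)

        def pad(tr: AccelTrace, grav_axis: str) -> AccelTrace:
            chans = {}
            for name in ("ax", "ay", "az"):
                base = 1.0 if name == grav_axis else 0.0
                pre = base + sd * rng.standard_normal(n_rest)
                post = base + sd * rng.standard_normal(n_rest)
                chans[name] = np.concatenate([pre, getattr(tr, name), post])
            return AccelTrace(t0=tr.t0, fs=tr.fs, site=tr.site, **chans)

        walk_len = len(lumbar)
        lumbar = pad(lumbar, "ay")
        foot = pad(foot, "az")
        rec["walk_span"] = (n_rest, n_rest + walk_len)
        rec["spike_idx"] = rec["spike_idx"] + n_rest
        rec["step_onset_idx"] = rec["step_onset_idx"] + n_rest
        rec["stride_onset_idx"] = rec["stride_onset_idx"] + n_rest
    else:
        rec["walk_span"] = (0, len(lumbar))
    return lumbar, foot, rec


# ---------------------------------------------------------------------------
# chaotic benchmark fixture + independent variational oracle
# ---------------------------------------------------------------------------

LORENZ_PARAMS = (10.0, 28.0, 8.0 / 3.0)  # sigma, rho, beta


def _lorenz_deriv(state: np.ndarray, sigma: float, rho: float,
                  beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def _rk4_step(f, state: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def gen_lorenz(duration_s: float = 300.0, dt: float = 0.01,
               initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0),
               params: tuple[float, float, float] = LORENZ_PARAMS,
               transient_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step 4th-order integration of the Lorenz system.

    Returns ``(x, states)`` after discarding the transient: the x-component
    series (for delay embedding) and the full (n, 3) state trajectory (for
    the variational oracle).
    """
    sigma, rho, beta = params
    f = lambda s: _lorenz_deriv(s, sigma, rho, beta)  # noqa: E731
    n_trans = int(round(transient_s / dt))
    n_keep = int(round(duration_s / dt))
    state = np.asarray(initial_state, dtype=float)
    for _ in range(n_trans):
        state = _rk4_step(f, state, dt)
    states = np.empty((n_keep, 3))
    for i in range(n_keep):
        states[i] = state
        state = _rk4_step(f, state, dt)
    return states[:, 0].copy(), states


def benettin_lyapunov(duration_s: float = 300.0, dt: float = 0.01,
                      initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0),
                      params: tuple[float, float, float] = LORENZ_PARAMS,
                      transient_s: float = 10.0) -> float:
    """Largest Lyapunov exponent via the variational (tangent-map) method.

    Integrates the flow together with one tangent vector, renormalizing at
    every step; the exponent is the time-average of the log stretch
    factors, in nats per second.  Independent of any divergence-curve
    machinery.
    """
    sigma, rho, beta = params

    def jac(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([[-sigma, sigma, 0.0],
                         [rho - z, -1.0, -x],
                         [y, x, -beta]])

    f = lambda s: _lorenz_deriv(s, sigma, rho, beta)  # noqa: E731
    state = np.asarray(initial_state, dtype=float)
    n_trans = int(round(transient_s / dt))
    for _ in range(n_trans):
        state = _rk4_step(f, state, dt)

    v = np.array([1.0, 0.0, 0.0])
    n_steps = int(round(duration_s / dt))
    n_align = max(1, n_steps // 10)  # let the tangent align before averaging
    log_sum = 0.0
    counted = 0
    for i in range(n_steps):
        # combined RK4 step of state and tangent vector
        def g(sv):
            s, w = sv[:3], sv[3:]
            return np.concatenate([f(s), jac(s) @ w])

        sv = _rk4_step(g, np.concatenate([state, v]), dt)
        state, v = sv[:3], sv[3:]
        nv = np.linalg.norm(v)
        if i >= n_align:
            log_sum += np.log(nv)
            counted += 1
        v /= nv
    return log_sum / (counted * dt)
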