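"""Shared fixtures.

Heavy simulations (the 50-pair divergence suite) are session-scoped so the
unit suite and the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitvar.io_segmentation import CalibratedSignals, calibrate_tilt
from gaitvar.nonlinear_metrics import compute_lds_aci
from gaitvar.standardize import (
    StandardizedSegment,
    estimate_step_frequency,
    resample_to_standard,
    truncate_to_steps,
)
from gaitvar.synthetic import SynthSpec, gen_stride_series, gen_trunk_accel

AXIS_MAP = {"ap": "ax", "v": "ay", "ml": "az"}


def run_lumbar_pipeline(spec: SynthSpec) -> tuple[StandardizedSegment, dict]:
    """Generator -> calibration -> standardization, returning ground truth."""
    series, truth = gen_stride_series(spec)
    trace, record = gen_trunk_accel(series, spec, truth)
    cal = calibrate_tilt(trace, AXIS_MAP)
    est = estimate_step_frequency(cal.v, cal.fs)
    trunc = truncate_to_steps(cal, est.sf)
    segment = resample_to_standard(trunc, est.sf)
    record["sf_estimate"] = est.sf
    return segment, record


def make_segment_from_arrays(ap, v, ml, norm, sf: float = 2.0,
                             fs: float = 256.0) -> StandardizedSegment:
    return StandardizedSegment(ap=np.asarray(ap, float), v=np.asarray(v, float),
                               ml=np.asarray(ml, float),
                               norm=np.asarray(norm, float), sf=sf, fs=fs)


@pytest.fixture(scope="session")
def gait_segment() -> StandardizedSegment:
    """One standard synthetic walking segment (persistent stride structure)."""
    segment, _ = run_lumbar_pipeline(SynthSpec(seed=42, n_strides=135))
    return segment


@pytest.fixture(scope="session")
def lorenz_oracle():
    """(divergence-curve slope, variational estimate) for the chaotic
    benchmark; computed once per session."""
    from gaitvar.nonlinear_metrics import (
        EmbeddingSpec,
        embed,
        fit_exponents,
        rosenstein_divergence,
    )
    from gaitvar.synthetic import benettin_lyapunov, gen_lorenz

    x, _ = gen_lorenz(duration_s=300.0, dt=0.01)
    att = embed(x, EmbeddingSpec(m=3, tau=11, theiler_w=200))
    curve = rosenstein_divergence(att, samples_per_stride=100,
                                  t_max_strides=4.0, theiler_w=200)
    exps = fit_exponents(curve, lds_window=(0.5, 1.5), aci_window=(0.5, 1.5))
    oracle = benettin_lyapunov(duration_s=300.0, dt=0.01)
    return exps.lds, oracle


@pytest.fixture(scope="session")
def aci_pair_suite():
    """ACI-AP for 50 paired segments: persistent (0.9) vs anti-persistent
    (0.25) stride-interval structure, waveform noise seeds shared within
    each pair.  Returns (aci_persistent, aci_antipersistent) arrays.
    """
    aci_p, aci_a = [], []
    for i in range(50):
        for alpha, sink in ((0.9, aci_p), (0.25, aci_a)):
            spec = SynthSpec(seed=1000 + i, n_strides=135, target_alpha=alpha)
            segment, _ = run_lumbar_pipeline(spec)
            result = compute_lds_aci(segment, axes=("AP",))
            sink.append(result.exponents["AP"].aci)
    return np.array(aci_p), np.array(aci_a)
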