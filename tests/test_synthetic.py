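import numpy as np
import pytest

from gaitvar._exceptions import GeneratorError
from gaitvar.linear_metrics import acf_regularity
from gaitvar.standardize import resample_to_standard, truncate_to_steps
from gaitvar.stride_dfa import dfa
from gaitvar.io_segmentation import calibrate_tilt
from gaitvar.synthetic import (
    SynthSpec,
    benettin_lyapunov,
    gen_foot_accel,
    gen_lorenz,
    gen_stride_series,
    gen_trunk_accel,
    gen_walking_trial,
)
from tests.conftest import AXIS_MAP, run_lumbar_pipeline


def _lag1_rho(x):
    x = x - np.mean(x)
    return float(np.sum(x[:-1] * x[1:]) / np.sum(x * x))


class TestSpecValidation:
    def test_seed_mandatory(self):
        with pytest.raises((GeneratorError, TypeError)):
            SynthSpec(seed=None)

    def test_alpha_range(self):
        with pytest.raises(GeneratorError):
            SynthSpec(seed=1, target_alpha=1.6)

    def test_sd_gate(self):
        with pytest.raises(GeneratorError):
            SynthSpec(seed=1, mean_stride_s=1.0, sd_stride_s=0.3)


class TestGenStrideSeries:
    def test_rescaling_contract(self):
        spec = SynthSpec(seed=7, n_strides=512, target_alpha=0.9,
                         mean_stride_s=1.05, sd_stride_s=0.02)
        series, truth = gen_stride_series(spec)
        assert np.mean(series.intervals) == pytest.approx(1.05, abs=0.005)
        assert np.std(series.intervals) == pytest.approx(0.02, abs=0.004)
        assert truth["target_alpha"] == 0.9

    def test_alpha_half_is_white(self):
        rhos = []
        for rep in range(200):
            spec = SynthSpec(seed=5000 + rep, n_strides=512, target_alpha=0.5)
            series, _ = gen_stride_series(spec)
            rhos.append(_lag1_rho(series.intervals))
        rhos = np.abs(rhos)
        assert np.mean(rhos) < 0.05
        assert np.mean(rhos <= 0.1) >= 0.95

    def test_alpha_quarter_anticorrelated(self):
        neg = 0
        for rep in range(200):
            spec = SynthSpec(seed=6000 + rep, n_strides=512,
                             target_alpha=0.25)
            series, _ = gen_stride_series(spec)
            neg += _lag1_rho(series.intervals) < 0
        assert neg >= 0.95 * 200

    def test_davies_harte_requires_alpha_below_one(self):
        spec = SynthSpec(seed=1, target_alpha=1.2)
        with pytest.raises(GeneratorError, match="spectral"):
            gen_stride_series(spec, method="davies-harte")
        series, truth = gen_stride_series(spec)  # auto falls back
        assert truth["method"] == "spectral"

    def test_full_loop_alpha_recovery(self):
        for target in (0.3, 0.5, 0.8, 1.0):
            rec = []
            for rep in range(200):
                spec = SynthSpec(seed=8000 + rep, n_strides=512,
                                 target_alpha=target)
                series, _ = gen_stride_series(spec)
                rec.append(dfa(series).alpha)
            assert np.mean(rec) == pytest.approx(target, abs=0.1)

    def test_seed_determinism(self):
        spec = SynthSpec(seed=99, n_strides=128)
        s1, _ = gen_stride_series(spec)
        s2, _ = gen_stride_series(SynthSpec(seed=99, n_strides=128))
        np.testing.assert_array_equal(s1.intervals, s2.intervals)


class TestGenTrunkAccel:
    def test_zero_noise_equal_strides_periodic(self):
        spec = SynthSpec(seed=13, n_strides=135, sd_stride_s=0.0,
                         noise_sd=0.0, amp_jitter=0.0)
        segment, _ = run_lumbar_pipeline(spec)
        res = acf_regularity(segment)
        # stride-periodic by construction; the ML axis models left-right
        # asymmetry, so step regularity sits just below stride regularity
        assert res.stride_regularity_r > 0.9999
        assert res.step_regularity_r > 0.99

    def test_ml_amplitude_calibration(self, gait_segment):
        from gaitvar.linear_metrics import movement_intensity
        assert movement_intensity(gait_segment).rms_ratio == pytest.approx(
            0.65, abs=0.02)

    def test_tilt_recovery(self):
        spec = SynthSpec(seed=31, n_strides=100, tilt_deg=10.0, noise_sd=0.0)
        series, truth = gen_stride_series(spec)
        trace, rec = gen_trunk_accel(series, spec, truth)
        cal = calibrate_tilt(trace, AXIS_MAP)
        for got, want in ((cal.ap, rec["ap"]), (cal.v, rec["v"]),
                          (cal.ml, rec["ml"])):
            err = np.sqrt(np.mean((got - want) ** 2))
            assert err < 0.01 * np.sqrt(np.mean(np.square(want)))

    def test_seed_determinism(self):
        spec = SynthSpec(seed=55, n_strides=90)
        series, truth = gen_stride_series(spec)
        t1, _ = gen_trunk_accel(series, spec, truth)
        t2, _ = gen_trunk_accel(series, spec, truth)
        np.testing.assert_array_equal(t1.ax, t2.ax)
        np.testing.assert_array_equal(t1.ay, t2.ay)


class TestGenFootAccel:
    def test_fencepost_spike_count(self):
        spec = SynthSpec(seed=17, n_strides=125)
        series, _ = gen_stride_series(spec)
        _, truth = gen_foot_accel(series, spec)
        assert len(truth["spike_idx"]) == 126

    def test_spikes_prominent(self):
        spec = SynthSpec(seed=18, n_strides=80)
        series, _ = gen_stride_series(spec)
        foot, truth = gen_foot_accel(series, spec)
        from gaitvar.io_segmentation import vector_norm
        norm = vector_norm(foot)
        assert np.all(norm[truth["spike_idx"]] >= 3.0)


class TestGenWalkingTrial:
    def test_ground_truth_bookkeeping(self):
        spec = SynthSpec(seed=23, n_strides=80)
        lumbar, foot, rec = gen_walking_trial(spec, rest_s=10.0)
        s, e = rec["walk_span"]
        assert s == int(round(10.0 * spec.fs))
        assert e == len(lumbar) - s
        # first foot spike follows the rest span plus the foot lead-in margin
        assert rec["spike_idx"][0] == s + int(round(0.05 * spec.fs))


class TestLorenzOracle:
    def test_benettin_canonical_value(self):
        lam = benettin_lyapunov(duration_s=300.0, dt=0.01)
        assert lam == pytest.approx(0.9, rel=0.05)

    def test_integration_convergence(self):
        l1 = benettin_lyapunov(duration_s=200.0, dt=0.01)
        l2 = benettin_lyapunov(duration_s=200.0, dt=0.005)
        assert abs(l2 - l1) / abs(l1) < 0.02

    def test_fixed_point_regime_negative(self):
        lam = benettin_lyapunov(duration_s=60.0, dt=0.01,
                                params=(10.0, 0.5, 8.0 / 3.0))
        assert lam < 0

    def test_trajectory_shape(self):
        x, states = gen_lorenz(duration_s=50.0, dt=0.01)
        assert len(x) == 5000
        assert states.shape == (5000, 3)
        np.testing.assert_array_equal(x, states[:, 0])
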