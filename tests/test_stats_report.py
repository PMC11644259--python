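import numpy as np
import pandas as pd
import pytest

from gaitvar._exceptions import DataError
from gaitvar.stats_report import (
    aggregate_segments,
    cohort_table,
    hedges_g,
    hedges_g_from_summary,
    metric_correlation,
    relative_change,
    remove_outliers,
    validate_tidy,
)


def _tidy(rows):
    return pd.DataFrame(rows, columns=["participant", "group", "condition",
                                       "segment", "metric", "value"])


def _cohort(rng, n_a=30, n_b=30, shift=0.0, metric="m"):
    rows = []
    for i in range(n_a):
        base = rng.standard_normal()
        for seg in (1, 2):
            rows.append((f"O{i}", "older", "normal", seg, metric,
                         base + 0.1 * rng.standard_normal()))
    for i in range(n_b):
        base = rng.standard_normal() + shift
        for seg in (1, 2):
            rows.append((f"Y{i}", "young", "normal", seg, metric,
                         base + 0.1 * rng.standard_normal()))
    return _tidy(rows)


class TestAggregateSegments:
    def test_mean_of_two_segments(self):
        df = _tidy([("p1", "older", "normal", 1, "aci_ap", 0.020),
                    ("p1", "older", "normal", 2, "aci_ap", 0.024)])
        agg = aggregate_segments(df)
        assert len(agg) == 1
        assert agg["value"].iloc[0] == pytest.approx(0.022)
        assert not agg["single_segment"].iloc[0]

    def test_single_segment_flagged(self):
        df = _tidy([("p1", "older", "normal", 1, "aci_ap", 0.020)])
        agg = aggregate_segments(df)
        assert agg["value"].iloc[0] == pytest.approx(0.020)
        assert agg["single_segment"].iloc[0]

    def test_group_means_match_strata(self):
        rng = np.random.default_rng(0)
        df = _cohort(rng, shift=0.5)
        agg = aggregate_segments(df)
        older = agg.loc[agg["group"] == "older", "value"]
        young = agg.loc[agg["group"] == "young", "value"]
        # aggregation preserves the imposed stratum difference
        assert young.mean() - older.mean() == pytest.approx(
            0.5, abs=3 * 1.0 / np.sqrt(30))

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError):
            validate_tidy(pd.DataFrame({"value": [1.0]}))


class TestHedgesG:
    def test_summary_level_cohort_value(self):
        # group summaries at the published precision reproduce the printed
        # effect within rounding
        g = hedges_g_from_summary(0.022, 0.009, 59, 0.028, 0.006, 42)
        assert g == pytest.approx(-0.75, abs=0.005)
        assert abs(g - (-0.77)) < 0.03

    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(30)
        res = hedges_g(a, a.copy(), seed=0)
        assert res.g == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_two_point_symmetry(self):
        res = hedges_g([0.0, 1.0], [0.0, 1.0], n_boot=200, seed=0)
        assert res.g == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(20), 1 + rng.standard_normal(25)
        assert hedges_g(a, b, seed=1).g == pytest.approx(
            -hedges_g(b, a, seed=1).g)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DataError):
            hedges_g([1.0, 1.0, 1.0], [1.0, 1.0])
        with pytest.raises(DataError):
            hedges_g_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        excluded = 0
        for i in range(500):
            a = rng.standard_normal(59)
            b = rng.standard_normal(42)
            res = hedges_g(a, b, seed=i)
            excluded += not (res.ci_low <= 0.0 <= res.ci_high)
        assert excluded / 500 <= 0.03

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(15), rng.standard_normal(18)
        r1 = hedges_g(a, b, seed=11)
        r2 = hedges_g(a, b, seed=11)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestRelativeChange:
    def test_printed_scaling_exponent_change(self):
        assert relative_change(0.74, 0.39) == pytest.approx(-47.3, abs=0.1)
        assert round(relative_change(0.74, 0.39)) == -47

    def test_printed_aci_change(self):
        assert relative_change(0.022, 0.016) == pytest.approx(-27.3, abs=0.1)
        assert round(relative_change(0.022, 0.016)) == -27

    def test_no_change(self):
        assert relative_change(0.5, 0.5) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(DataError):
            relative_change(0.0, 1.0)


class TestCohortTable:
    def test_bookkeeping(self):
        rng = np.random.default_rng(3)
        df = pd.concat([_cohort(rng, metric="m1"), _cohort(rng, metric="m2")])
        table = cohort_table(aggregate_segments(df), n_boot=200)
        assert len(table) == 2
        assert set(table["metric"]) == {"m1", "m2"}
        assert (table["n_older"] == 30).all()
        assert (table["n_young"] == 30).all()

    def test_missing_group_flagged(self):
        rng = np.random.default_rng(5)
        df = _cohort(rng, n_b=0)
        table = cohort_table(aggregate_segments(df), n_boot=200)
        assert (table["flag"] == "missing_group").all()
        assert table["g"].isna().all()

    def test_imposed_effect_recovered(self):
        rng = np.random.default_rng(8)
        df = _cohort(rng, n_a=60, n_b=42, shift=-0.8)
        table = cohort_table(aggregate_segments(df), n_boot=1000, seed=0)
        row = table.iloc[0]
        half_width = (row["ci_high"] - row["ci_low"]) / 2
        assert abs(row["g"] - 0.8) <= half_width


class TestOutliersAndCorrelation:
    def test_outlier_filter_off_by_default_semantics(self):
        rng = np.random.default_rng(6)
        df = _cohort(rng)
        spiked = pd.concat([df, _tidy([("X", "older", "normal", 1, "m",
                                        50.0)])], ignore_index=True)
        cleaned = remove_outliers(spiked)
        assert len(cleaned) == len(spiked) - 1
        assert not (cleaned["value"] == 50.0).any()

    def test_correlated_metrics_positive_r(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(40):
            latent = rng.standard_normal()
            rows.append((f"p{i}", "older", "normal", 1, "aci_ap",
                         latent + 0.3 * rng.standard_normal()))
            rows.append((f"p{i}", "older", "normal", 1, "dfa_alpha",
                         latent + 0.3 * rng.standard_normal()))
        r, p, n = metric_correlation(_tidy(rows), "aci_ap", "dfa_alpha")
        assert r > 0.5
        assert n == 40
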