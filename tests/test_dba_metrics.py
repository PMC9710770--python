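"""Static/dynamic decomposition and the six DBA metrics.

The brute-force oracle recomputes every metric by direct summation from
first principles, independently of the vectorised implementation.
"""

import numpy as np
import pandas as pd
import pytest

from accelstates.core_io import AccelTrace, BoutAnnotation, Ethogram, ValidationError
from accelstates.dba_metrics import (
    METRIC_NAMES,
    MetricConfig,
    compute_metrics,
    decompose,
    metric_correlations,
    per_sample_odba,
)


def _trace(ax, ay=None, az=None, water=None, f=1.0):
    n = len(ax)
    z = np.zeros(n)
    return AccelTrace(
        "t", "test", f,
        np.arange(n) / f,
        np.asarray(ax, float),
        z if ay is None else np.asarray(ay, float),
        z if az is None else np.asarray(az, float),
        np.full(n, 100.0) if water is None else np.asarray(water, float),
    )


def brute_force_median_decompose(raw, w):
    """Sliding truncated-window median, sample by sample."""
    n = len(raw)
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = raw[i] - np.median(raw[lo:hi])
    return out


def brute_force_metrics(xd, yd, zd, odba_conv, delta_conv, ddof=1):
    """Direct per-formula evaluation on one window."""
    n = len(xd)
    o = [abs(xd[i]) + abs(yd[i]) + abs(zd[i]) if odba_conv == "sum_of_abs"
         else abs(xd[i] + yd[i] + zd[i]) for i in range(n)]
    v = [np.sqrt(xd[i] ** 2 + yd[i] ** 2 + zd[i] ** 2) for i in range(n)]
    do = dv = 0.0
    for i in range(n - 1):
        dx, dy, dz = xd[i + 1] - xd[i], yd[i + 1] - yd[i], zd[i + 1] - zd[i]
        do += (abs(dx) + abs(dy) + abs(dz)) if delta_conv == "sum_of_abs" else abs(dx + dy + dz)
        dv += np.sqrt(dx**2 + dy**2 + dz**2)
    return {
        "TODBA": sum(o),
        "TVeDBA": sum(v),
        "dODBA": do,
        "dVeDBA": dv,
        "SDODBA": np.std(o, ddof=ddof),
        "SDVeDBA": np.std(v, ddof=ddof),
    }


class TestDecompose:
    def test_constant_trace_zero_dynamic(self):
        dyn = decompose(_trace(np.full(50, 0.7)), 5)
        np.testing.assert_array_equal(dyn.xd, np.zeros(50))

    def test_single_impulse_against_oracle(self):
        raw = np.zeros(7)
        raw[3] = 1.0
        dyn = decompose(_trace(raw), 5)
        np.testing.assert_allclose(dyn.xd, brute_force_median_decompose(raw, 5))
        assert dyn.xd[3] == pytest.approx(1.0)  # impulse minus 0 baseline

    def test_fast_waveform_much_shorter_than_window(self, rng):
        # three-level zero-mean cycle: the 21-sample window holds 7 of each
        # level, so the running median is exactly 0 and dynamic == raw
        raw = np.tile([0.5, 0.0, -0.5], 70)
        dyn = decompose(_trace(raw), 21)
        np.testing.assert_allclose(dyn.xd, brute_force_median_decompose(raw, 21))
        np.testing.assert_allclose(dyn.xd[20:-20], raw[20:-20], atol=1e-12)

    def test_square_wave_removed_by_mean_smoother(self):
        # a 50/50 two-level square wave defeats a median (the one-sample
        # majority alternates) but a running mean leaves static ~ 0
        raw = np.tile([0.5, -0.5], 100)
        dyn = decompose(_trace(raw), 21, method="mean")
        np.testing.assert_allclose(dyn.xd[20:-20], raw[20:-20], atol=0.03)

    def test_random_trace_matches_sliding_oracle(self, rng):
        raw = rng.normal(size=101)
        for w in (3, 9, 31):
            dyn = decompose(_trace(np.clip(raw, -2, 2)), w)
            np.testing.assert_allclose(
                dyn.xd, brute_force_median_decompose(np.clip(raw, -2, 2), w), atol=1e-12
            )

    def test_even_or_short_window_rejected(self):
        with pytest.raises(ValidationError):
            decompose(_trace(np.zeros(50)), 4)
        with pytest.raises(ValidationError):
            decompose(_trace(np.zeros(10)), 21)

    def test_mean_smoother_option(self):
        raw = np.arange(9, dtype=float) / 10
        dyn = decompose(_trace(raw), 3, method="mean")
        # interior: mean of linear ramp equals centre value -> dynamic 0
        np.testing.assert_allclose(dyn.xd[1:-1], 0.0, atol=1e-12)


class TestComputeMetrics:
    def test_zero_dynamic_gives_all_zero_metrics(self):
        dyn = decompose(_trace(np.full(30, 1.0)), 5)
        table = compute_metrics(dyn, MetricConfig(sampling_window=10))
        assert (table[list(METRIC_NAMES)].to_numpy() == 0).all()

    def test_hand_computed_three_sample_window(self):
        # dynamics Xd=[0,0.3,0.3], Yd=Zd=0 within a 3-sample window
        raw = np.array([0.0, 0.3, 0.3])
        trace = _trace(raw)
        dyn = decompose(trace, 3)
        object.__setattr__(dyn, "xd", raw)  # inject the dynamics directly
        object.__setattr__(dyn, "yd", np.zeros(3))
        object.__setattr__(dyn, "zd", np.zeros(3))
        table = compute_metrics(dyn, MetricConfig(sampling_window=3))
        row = table.iloc[0]
        assert row.TODBA == pytest.approx(0.6)
        assert row.TVeDBA == pytest.approx(0.6)
        assert row.dODBA == pytest.approx(0.3)
        assert row.dVeDBA == pytest.approx(0.3)

    @pytest.mark.parametrize("odba_conv", ["sum_of_abs", "abs_of_sum"])
    @pytest.mark.parametrize("delta_conv", ["sum_of_abs", "abs_of_sum"])
    def test_oracle_equivalence_both_conventions(self, rng, odba_conv, delta_conv):
        n = 60
        trace = _trace(
            np.clip(rng.normal(0, 0.3, n), -2, 2),
            np.clip(rng.normal(0, 0.3, n), -2, 2),
            np.clip(rng.normal(1, 0.3, n), -2, 2),
        )
        dyn = decompose(trace, 5)
        cfg = MetricConfig(
            sampling_window=10, odba_convention=odba_conv, delta_convention=delta_conv
        )
        table = compute_metrics(dyn, cfg)
        for j, row in table.iterrows():
            s = slice(j, j + 10)
            exp = brute_force_metrics(dyn.xd[s], dyn.yd[s], dyn.zd[s], odba_conv, delta_conv)
            for m in METRIC_NAMES:
                assert row[m] == pytest.approx(exp[m], abs=1e-9), m

    def test_l2_never_exceeds_l1(self, rng):
        n = 200
        trace = _trace(
            np.clip(rng.normal(0, 0.4, n), -2, 2),
            np.clip(rng.normal(0, 0.4, n), -2, 2),
            np.clip(rng.normal(0, 0.4, n), -2, 2),
        )
        dyn = decompose(trace, 7)
        table = compute_metrics(
            dyn, MetricConfig(odba_convention="sum_of_abs", delta_convention="sum_of_abs")
        )
        assert (table.TVeDBA <= table.TODBA + 1e-12).all()
        assert (table.dVeDBA <= table.dODBA + 1e-12).all()

    def test_invariant_to_constant_axis_offset(self, rng):
        n = 120
        base = rng.normal(0, 0.3, (3, n))
        t1 = _trace(*(np.clip(base, -1, 1)))
        shifted = np.clip(base, -1, 1) + 0.5
        t2 = _trace(*shifted)
        c1 = compute_metrics(decompose(t1, 7))
        c2 = compute_metrics(decompose(t2, 7))
        pd.testing.assert_frame_equal(c1, c2)

    def test_metrics_scale_linearly_with_dynamics(self, rng):
        n = 80
        raw = np.clip(rng.normal(0, 0.2, n), -1, 1)
        d1 = decompose(_trace(raw), 7)
        d3 = decompose(_trace(3 * raw), 7)
        m1 = compute_metrics(d1)[list(METRIC_NAMES)]
        m3 = compute_metrics(d3)[list(METRIC_NAMES)]
        np.testing.assert_allclose(m3.to_numpy(), 3 * m1.to_numpy(), rtol=1e-9)

    def test_training_windows_confined_to_bouts(self):
        n = 40
        trace = _trace(np.zeros(n))
        eth = Ethogram(
            (
                BoutAnnotation("t", "terrestrial-motionless", 0, 15),
                BoutAnnotation("t", "aquatic-in-motion", 20, 40),
            )
        )
        dyn = decompose(trace, 3)
        table = compute_metrics(dyn, MetricConfig(sampling_window=10), bouts=eth)
        # bout 1: samples 0..14 -> 6 windows; bout 2: samples 20..39 -> 11
        assert len(table) == 6 + 11
        assert set(table.state_true) == {"terrestrial-motionless", "aquatic-in-motion"}
        # no window straddles the gap
        assert not ((table.t_end >= 15) & (table.t_end < 29)).any()

    def test_window_under_two_samples_rejected(self):
        trace = _trace(np.zeros(64), f=0.125)
        dyn = decompose(trace, 24)
        with pytest.raises(ValidationError, match="[Ll]engthen"):
            compute_metrics(dyn, MetricConfig(sampling_window=10))

    def test_water_summary_is_window_median(self, rng):
        n = 30
        water = rng.uniform(0, 1000, n)
        trace = _trace(np.zeros(n), water=water)
        table = compute_metrics(decompose(trace, 3), MetricConfig(sampling_window=10))
        for j, row in table.iterrows():
            assert row.water == pytest.approx(np.median(water[j : j + 10]))


class TestMetricCorrelations:
    def test_duplicated_columns_correlate_perfectly(self, labelled_table):
        corr, _ = metric_correlations(labelled_table)
        # TODBA and TVeDBA are near-duplicates on the preset; diagonal exact
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["TODBA", "TODBA"] == 1.0

    def test_independent_noise_columns_uncorrelated(self, rng):
        n = 10_000
        fake = pd.DataFrame(rng.normal(size=(n, 6)), columns=list(METRIC_NAMES))
        corr, mean_r = metric_correlations(fake)
        off = corr.to_numpy()[np.triu_indices(6, k=1)]
        assert np.max(np.abs(off)) < 0.05
        assert abs(mean_r) < 0.05

    def test_hand_computed_three_window_table(self):
        df = pd.DataFrame(
            {
                "dODBA": [1.0, 2.0, 3.0],
                "dVeDBA": [1.0, 2.0, 3.0],
                "TODBA": [3.0, 2.0, 1.0],
                "TVeDBA": [1.0, 2.0, 3.0],
                "SDODBA": [1.0, 2.0, 3.0],
                "SDVeDBA": [1.0, 2.0, 3.0],
            }
        )
        corr, mean_r = metric_correlations(df)
        assert corr.loc["dODBA", "TODBA"] == pytest.approx(-1.0)
        assert corr.loc["dODBA", "dVeDBA"] == pytest.approx(1.0)
        # upper triangle: ten +1 pairs and five -1 pairs -> mean 1/3
        assert mean_r == pytest.approx(1 / 3)

    def test_zero_variance_metric_excluded_from_mean(self):
        df = pd.DataFrame(
            {
                "dODBA": [1.0, 2.0, 3.0],
                "dVeDBA": [1.0, 2.0, 3.0],
                "TODBA": [5.0, 5.0, 5.0],  # zero variance
                "TVeDBA": [1.0, 2.0, 3.0],
                "SDODBA": [1.0, 2.0, 3.0],
                "SDVeDBA": [1.0, 2.0, 3.0],
            }
        )
        corr, mean_r = metric_correlations(df)
        assert np.isnan(corr.loc["dODBA", "TODBA"])
        assert mean_r == pytest.approx(1.0)

    def test_too_few_windows_rejected(self):
        df = pd.DataFrame({m: [1.0, 2.0] for m in METRIC_NAMES})
        with pytest.raises(ValidationError):
            metric_correlations(df)
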