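"""Trace conditioning, event detection on constructed pulses, raster
statistics, depth-binned correlation, and spine turnover."""

import numpy as np
import pytest
from scipy import stats

from cortexpheno.calcium import (
    depth_bin_correlation,
    design_lowpass,
    detect_events,
    dff,
    fraction_active,
    lowpass,
    neuropil_subtract,
    slice_group_compare,
    spine_turnover,
    traces_to_raster,
)
from cortexpheno.errors import ConfigurationError, DesignError


class TestNeuropilSubtract:
    def test_zero_neuropil_is_identity(self):
        t = np.arange(10.0)
        np.testing.assert_array_equal(neuropil_subtract(t, np.zeros(10)), t)

    def test_equal_traces_cancel(self):
        t = np.random.default_rng(0).normal(size=50)
        np.testing.assert_array_equal(neuropil_subtract(t, t), np.zeros(50))

    def test_random_vectors_elementwise(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=100), rng.normal(size=100)
        np.testing.assert_array_equal(neuropil_subtract(a, b), a - b)

    def test_length_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            neuropil_subtract(np.zeros(5), np.zeros(6))


class TestLowpass:
    def test_dc_preserved(self):
        out = lowpass(np.full(500, 7.0))
        np.testing.assert_allclose(out, 7.0, rtol=0.01)

    def test_stopband_attenuation(self):
        """A 0.9 x Nyquist sinusoid is attenuated by at least 25 dB."""
        n = 4000
        x = np.sin(np.pi * 0.9 * np.arange(n))
        y = lowpass(x)
        core = slice(500, -500)
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert 20 * np.log10(ratio) <= -25

    def test_passband_flat(self):
        """A 0.3 x Nyquist sinusoid passes within 1 dB."""
        n = 4000
        x = np.sin(np.pi * 0.3 * np.arange(n))
        y = lowpass(x)
        core = slice(500, -500)
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert abs(20 * np.log10(ratio)) <= 1

    def test_unity_dc_gain_of_design(self):
        taps = design_lowpass()
        assert taps.sum() == pytest.approx(1.0, abs=1e-6)

    def test_short_trace_raises(self):
        with pytest.raises(ConfigurationError):
            lowpass(np.zeros(10))


class TestDff:
    def test_constant_trace_at_baseline(self):
        d, sigma = dff(np.full(100, 50.0))
        np.testing.assert_array_equal(d, 0.0)
        assert sigma == 0.0

    def test_trace_at_twice_baseline(self):
        trace = np.full(100, 50.0)
        trace[:30] = 25.0  # 20th percentile = 25
        d, _ = dff(trace)
        assert d[50] == pytest.approx(1.0)

    def test_percentile_baseline_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        trace = rng.uniform(10, 20, size=501)
        d, _ = dff(trace)
        srt = np.sort(trace)
        f0 = srt[int(round(0.20 * (len(trace) - 1)))]  # exact order statistic at 501 points
        np.testing.assert_allclose(d, (trace - f0) / f0, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ConfigurationError):
            dff(np.linspace(-5, 5, 100))


def _pulse(peak, decay_frames, n=600, onset=100, floor=0.0):
    """One-frame rise to `peak`, exponential decay with the given constant."""
    x = np.full(n, floor)
    t = np.arange(n - onset)
    x[onset:] = peak * np.exp(-t / decay_frames)
    return x


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        events, raster = detect_events(np.zeros(200), sigma=0.0)
        assert events == [] and raster.sum() == 0

    def test_qualifying_pulse_is_one_event(self):
        """Peak 10 sigma, integral ~250 sigma-frames: passes the 2.5/8/200
        sigma criteria exactly once."""
        sigma = 0.1
        # decay constant 26 frames -> area ~= 10 * 26 = 260 sigma-frames
        trace = _pulse(10 * sigma, 26.0)
        events, raster = detect_events(trace, sigma)
        assert len(events) == 1
        assert events[0].peak >= 8 * sigma
        assert events[0].area >= 200 * sigma
        assert raster[events[0].onset: events[0].end].all()

    def test_low_peak_rejected_despite_area(self):
        """Peak 5 sigma with integral 300 sigma-frames fails the 8-sigma rule."""
        sigma = 0.1
        trace = _pulse(5 * sigma, 80.0)  # area ~= 5 * 80 = 400 sigma-frames
        assert trace.sum() / sigma > 300
        events, _ = detect_events(trace, sigma)
        assert events == []

    def test_small_area_rejected_despite_peak(self):
        sigma = 0.1
        trace = _pulse(10 * sigma, 5.0)  # area ~= 50 sigma-frames
        events, _ = detect_events(trace, sigma)
        assert events == []

    def test_overlapping_candidates_merge(self):
        sigma = 0.1
        trace = _pulse(10 * sigma, 26.0)
        trace[102] += 5 * sigma  # second suprathreshold rise inside the event
        events, _ = detect_events(trace, sigma)
        assert len(events) == 1

    def test_event_ends_below_half_sigma(self):
        sigma = 0.1
        trace = _pulse(10 * sigma, 26.0)
        events, _ = detect_events(trace, sigma)
        end = events[0].end
        assert trace[end] < 0.5 * sigma
        assert trace[end - 1] >= 0.5 * sigma

    def test_raster_invariant_to_positive_rescaling(self):
        """Scaling the raw fluorescence by a > 0 leaves the raster unchanged
        (percentile baseline makes dF/F and sigma scale together)."""
        rng = np.random.default_rng(3)
        trace = 100.0 + 5 * _pulse(1.0, 20.0, n=800) + rng.normal(0, 0.05, 800)
        d1, s1 = dff(trace)
        d2, s2 = dff(3.7 * trace)
        _, r1 = detect_events(d1, s1)
        _, r2 = detect_events(d2, s2)
        np.testing.assert_array_equal(r1, r2)


class TestFractionActive:
    def test_examples(self):
        row = np.zeros(10, dtype=int)
        row[3] = 1
        assert fraction_active(row) == pytest.approx(0.1)
        assert fraction_active(np.zeros(5)) == 0.0

    def test_matches_popcount(self):
        rng = np.random.default_rng(4)
        row = rng.integers(0, 2, 1000)
        assert fraction_active(row) == pytest.approx(int(row.sum()) / 1000)


class TestDepthBinCorrelation:
    def test_identical_rows_same_bin_give_unit_diagonal(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 2, 500)
        raster = np.vstack([row, row])
        m = depth_bin_correlation(raster, np.array([10.0, 20.0]))
        assert m.matrix[0, 0] == pytest.approx(1.0)
        assert m.pair_counts[0, 0] == 1

    def test_independent_rows_near_zero(self):
        """Independent Bernoulli rows over 36,000 frames: mean entries below
        the 3/sqrt(frames) null bound."""
        rng = np.random.default_rng(6)
        n_frames = 36_000
        raster = (rng.random((16, n_frames)) < 0.05).astype(np.uint8)
        depths = rng.uniform(0, 600, 16)
        m = depth_bin_correlation(raster, depths)
        defined = m.matrix[~np.isnan(m.matrix)]
        assert np.abs(np.nanmean(m.matrix)) < 3 / np.sqrt(n_frames)
        assert defined.size > 0

    def test_symmetry_and_neuron_order_invariance(self):
        rng = np.random.default_rng(7)
        raster = (rng.random((12, 2000)) < 0.1).astype(np.uint8)
        depths = rng.uniform(0, 600, 12)
        m1 = depth_bin_correlation(raster, depths)
        np.testing.assert_allclose(m1.matrix, m1.matrix.T, equal_nan=True)
        perm = rng.permutation(12)
        m2 = depth_bin_correlation(raster[perm], depths[perm])
        np.testing.assert_allclose(m1.matrix, m2.matrix, equal_nan=True)
        np.testing.assert_array_equal(m1.pair_counts, m2.pair_counts)

    def test_deep_neurons_excluded_and_counted(self):
        rng = np.random.default_rng(8)
        raster = (rng.random((5, 1000)) < 0.2).astype(np.uint8)
        depths = np.array([10.0, 50.0, 100.0, 650.0, 700.0])
        m = depth_bin_correlation(raster, depths)
        assert m.n_excluded_depth == 2

    def test_shared_latent_elevates_only_loaded_block(self):
        """A latent factor loaded on bins 1-2 only: elevated correlation is
        confined to the upper-left 2x2 block and matches the closed form
        within 3 Monte-Carlo SEs."""
        from cortexpheno.config import CalciumConfig, LatentFactor, SimConfig
        from cortexpheno.synthetic import gen_calcium_traces

        cfg = SimConfig(seed=13)
        cfg.calcium = CalciumConfig(
            n_neurons=48, n_frames=36_000, event_rate_hz=0.05,
            latent_factors=[LatentFactor(rate_hz=0.3, loadings=(0.8, 0.8, 0, 0, 0, 0, 0, 0))],
        )
        ts, truth = gen_calcium_traces(cfg)
        m = depth_bin_correlation(truth.raster, ts.depths_um)
        # closed-form expectations per bin pair
        bins = (ts.depths_um // 75).astype(int)
        se = 3.0 / np.sqrt(cfg.calcium.n_frames)
        for bi in range(8):
            for bj in range(8):
                if m.pair_counts[bi, bj] == 0:
                    continue
                pairs = [
                    truth.expected_correlation(i, j)
                    for i in np.flatnonzero(bins == bi)
                    for j in np.flatnonzero(bins == bj)
                    if i < j
                ] + [
                    truth.expected_correlation(j, i)
                    for i in np.flatnonzero(bins == bi)
                    for j in np.flatnonzero(bins == bj)
                    if j < i
                ]
                expected = np.mean(pairs)
                assert abs(m.matrix[bi, bj] - expected) < se
                if bi >= 2 or bj >= 2:
                    assert expected < 0.01  # no latent outside the loaded block

    def test_all_excluded_raises(self):
        raster = np.ones((3, 100), dtype=np.uint8)
        with pytest.raises(DesignError):
            depth_bin_correlation(raster, np.array([700.0, 800.0, 900.0]))


def _bin_matrix(value, n_bins=8):
    m = np.full((n_bins, n_bins), value, dtype=float)
    return m


class TestSliceGroupCompare:
    def _mats(self, values_wt, values_het):
        from cortexpheno.calcium import BinCorrMatrix

        edges = np.arange(9) * 75.0
        mats = []
        for k, v in enumerate(values_wt):
            mats.append(BinCorrMatrix(_bin_matrix(v), np.ones((8, 8), int), edges, f"wt{k}", "WT"))
        for k, v in enumerate(values_het):
            mats.append(BinCorrMatrix(_bin_matrix(v), np.ones((8, 8), int), edges, f"het{k}", "HET"))
        return mats

    def test_identical_groups_give_t_zero_p_one(self):
        res = slice_group_compare(self._mats([0.005, 0.005], [0.005, 0.005]))
        assert (res.stats["t"] == 0).all()
        assert (res.stats["p"] == 1).all()

    def test_t_matches_pooled_oracle(self):
        wt, het = [0.004, 0.006, 0.005], [0.002, 0.003, 0.001]
        res = slice_group_compare(self._mats(wt, het))
        t_ref, p_ref = stats.ttest_ind(wt, het, equal_var=True)
        row = res.stats.set_index("metric").loc["mean_corr"]
        assert row["t"] == pytest.approx(t_ref, abs=1e-12)
        assert row["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_planted_group_difference_detected(self):
        """0.003 group difference with slice SD 0.001 at n = 8 vs 10:
        detected at p < 0.05 in at least 90% of 200 simulations."""
        rng = np.random.default_rng(20)
        hits = 0
        for _ in range(200):
            wt = rng.normal(0.005, 0.001, 8)
            het = rng.normal(0.002, 0.001, 10)
            res = slice_group_compare(self._mats(wt, het))
            hits += res.stats.set_index("metric").loc["mean_corr", "p"] < 0.05
        assert hits >= 180

    def test_single_slice_group_raises(self):
        with pytest.raises(DesignError):
            slice_group_compare(self._mats([0.005], [0.004, 0.003]))

    def test_superficial_mean_uses_rows_within_cut(self):
        from cortexpheno.calcium import BinCorrMatrix

        m = _bin_matrix(0.0)
        m[:4, :] = 0.01  # superficial rows (bins 0-3, upper edges <= 300)
        edges = np.arange(9) * 75.0
        mats = [BinCorrMatrix(m.copy(), np.ones((8, 8), int), edges, f"s{k}", g)
                for k, g in enumerate(["WT", "WT", "HET", "HET"])]
        res = slice_group_compare(mats)
        assert res.per_slice["superficial_mean"].iloc[0] == pytest.approx(0.01)


class TestSpineTurnover:
    def test_identical_sessions(self):
        out = spine_turnover({1, 2, 3}, {1, 2, 3}, 10.0)
        assert out["pct_formed"] == 0.0 and out["pct_eliminated"] == 0.0

    def test_set_arithmetic(self):
        s1 = set(range(100))
        s2 = set(range(10, 100)) | set(range(1000, 1015))  # 90 retained + 15 new
        out = spine_turnover(s1, s2, 50.0)
        assert out["pct_eliminated"] == pytest.approx(10.0)
        assert out["pct_formed"] == pytest.approx(15.0)

    def test_density_scaling(self):
        out = spine_turnover(set(range(20)), set(range(20)), 25.0)
        assert out["density_per_10um"] == pytest.approx(8.0)

    def test_empty_first_session_raises(self):
        with pytest.raises(DesignError):
            spine_turnover(set(), {1}, 10.0)


class TestEndToEnd:
    def test_null_generator_groups_indistinguishable(self):
        """Zero latent loading: detected-activity group means do not differ
        between genotype groups more often than chance allows."""
        from cortexpheno.config import CalciumConfig, SimConfig
        from cortexpheno.synthetic import gen_calcium_traces

        rejections = 0
        n_runs = 10
        for run in range(n_runs):
            fracs = {"WT": [], "HET": []}
            for s in range(6):
                geno = "WT" if s < 3 else "HET"
                cfg = SimConfig(seed=700 + run)
                cfg.calcium = CalciumConfig(n_neurons=8, n_frames=3000)
                ts, _ = gen_calcium_traces(cfg, genotype=geno, stream_index=100 * run + s)
                raster, _ = traces_to_raster(ts.traces, ts.neuropil)
                fracs[geno].append(raster.mean())
            p = stats.ttest_ind(fracs["WT"], fracs["HET"]).pvalue
            rejections += p < 0.05
        assert rejections <= 2
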