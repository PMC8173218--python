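"""Encoding-model machinery: HRF, regressors, per-vertex R^2, ROIs."""

import numpy as np
import pytest

from netphys.brain_link import (
    EncodingResult,
    HRFSpec,
    build_design,
    channel_regressor,
    clip_average,
    hrf_kernel,
    regressor_count_match,
    roi_topk,
    vertex_regression,
    vertex_regression_map,
)
from netphys.synthetic import (
    PlantedSelectivitySpec,
    SyntheticBrainSpec,
    gen_activation_dataset,
    gen_vertex_timeseries,
)


class TestHRFKernel:
    def test_peak_at_four_seconds(self):
        spec = HRFSpec()
        h = hrf_kernel(spec)
        assert abs(np.argmax(h) * spec.dt - 4.0) <= spec.dt

    def test_causal_and_unit_peak(self):
        h = hrf_kernel(HRFSpec())
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_impulse_convolution_reproduces_kernel(self):
        h = hrf_kernel(HRFSpec())
        impulse = np.zeros(50)
        impulse[0] = 1.0
        np.testing.assert_allclose(np.convolve(impulse, h)[:50], h[:50])

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            HRFSpec(dt=0.0)


class TestChannelRegressor:
    def test_standardization_contract(self, rng):
        series = np.abs(rng.normal(1, 1, size=2400))
        reg = channel_regressor(series, HRFSpec(), tr_seconds=2.0)
        assert reg.mean() == pytest.approx(0.0, abs=1e-9)
        assert reg.std() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_input_raises_zero_variance(self):
        with pytest.raises(ValueError, match="zero-variance"):
            channel_regressor(np.zeros(2400), HRFSpec(), tr_seconds=2.0)

    def test_boxcar_matches_step_by_step_oracle(self):
        spec = HRFSpec()
        series = np.zeros(2400)
        series[400:800] = 3.0  # 40 s boxcar
        reg = channel_regressor(series, spec, tr_seconds=2.0)
        # hand-assembled composition: log1p -> causal conv -> bin mean -> z
        logged = np.log1p(series)
        kern = hrf_kernel(spec)
        conv = np.convolve(logged, kern)[:2400]
        binned = conv.reshape(-1, 20).mean(axis=1)
        z = (binned - binned.mean()) / binned.std()
        np.testing.assert_allclose(reg, z, atol=1e-12)

    def test_negative_series_rejected(self):
        with pytest.raises(ValueError):
            channel_regressor([-1.0, 2.0], HRFSpec(), 2.0)


class TestVertexRegression:
    def test_exact_linear_combination_gives_unit_r2(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        assert vertex_regression(y, X) == pytest.approx(1.0, abs=1e-10)

    def test_null_vertex_mean_r2_matches_p_over_n_minus_1(self, rng):
        n, p = 240, 2
        X = rng.normal(size=(n, p))
        r2s = [vertex_regression(rng.normal(size=n), X) for _ in range(300)]
        expected = p / (n - 1)
        se = np.std(r2s) / np.sqrt(len(r2s))
        assert abs(np.mean(r2s) - expected) < 4 * se

    def test_adding_regressor_never_decreases_r2(self, rng):
        X = rng.normal(size=(60, 2))
        y = X[:, 0] + rng.normal(size=60)
        base = vertex_regression(y, X)
        more = vertex_regression(y, np.column_stack([X, rng.normal(size=60)]))
        assert more >= base - 1e-12

    def test_r2_invariant_to_affine_regressor_rescaling(self, rng):
        X = rng.normal(size=(80, 2))
        y = X @ [1.0, 0.3] + rng.normal(size=80)
        X2 = X.copy()
        X2[:, 0] = 5.0 * X2[:, 0] - 7.0
        assert vertex_regression(y, X) == pytest.approx(vertex_regression(y, X2),
                                                        abs=1e-12)

    def test_rank_deficient_design_flagged(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning, match="rank-deficient"):
            r2 = vertex_regression(x + rng.normal(size=50), X)
        assert 0.0 <= r2 <= 1.0

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError):
            vertex_regression(rng.normal(size=3), rng.normal(size=(3, 2)))


class TestSyntheticMixtures:
    def test_noiseless_mixture_reaches_unit_r2_everywhere_mixed(self, rng):
        series = np.abs(rng.normal(1, 1, size=(2, 2400)))
        mixing = np.vstack([rng.normal(size=(4, 2)), np.zeros((1, 2))])
        spec = SyntheticBrainSpec(mixing=mixing, tr_seconds=2.0, noise_sd=0.0, seed=5)
        vts = gen_vertex_timeseries(series, spec)
        for v in range(4):
            assert vertex_regression(vts.data[v], vts.design) == pytest.approx(
                1.0, abs=1e-10)

    def test_r2_decreases_monotonically_with_noise(self, rng):
        series = np.abs(rng.normal(1, 1, size=(1, 4800)))
        mixing = np.ones((1, 1))
        means = []
        for sd in (0.0, 0.5, 1.0, 2.0):
            r2s = []
            for seed in range(10):
                spec = SyntheticBrainSpec(mixing=mixing, tr_seconds=2.0,
                                          noise_sd=sd, seed=seed)
                vts = gen_vertex_timeseries(series, spec)
                r2s.append(vertex_regression(vts.data[0], vts.design))
            means.append(np.mean(r2s))
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_planted_roi_has_higher_r2_than_unmixed_vertices(self, rng):
        series = np.abs(rng.normal(1, 1, size=(2, 2400)))
        mixing = np.zeros((10, 2))
        mixing[:5] = rng.normal(0, 2, size=(5, 2))
        spec = SyntheticBrainSpec(mixing=mixing, tr_seconds=2.0, noise_sd=0.5, seed=1)
        vts = gen_vertex_timeseries(series, spec)
        res = vertex_regression_map(vts.data, vts.design)
        assert res.r2[:5].mean() > res.r2[5:].mean() + 0.2

    def test_mixing_shape_mismatch_rejected(self, rng):
        spec = SyntheticBrainSpec(mixing=np.ones((3, 4)), seed=0)
        with pytest.raises(ValueError):
            gen_vertex_timeseries(np.abs(rng.normal(1, 1, size=(2, 1200))), spec)


class TestClipAverage:
    def test_identical_clips_average_to_each(self):
        r = EncodingResult(np.array([0.2, 0.4]), (0,), 100)
        avg = clip_average([r, r])
        np.testing.assert_allclose(avg.r2, r.r2)

    def test_two_clip_mean(self):
        a = EncodingResult(np.array([0.2]), (0,), 100)
        b = EncodingResult(np.array([0.4]), (0,), 100)
        assert clip_average([a, b]).r2[0] == pytest.approx(0.3)

    def test_matches_loop_oracle(self, rng):
        clips = [EncodingResult(rng.random(7), (0,), 50) for _ in range(5)]
        avg = clip_average(clips)
        for v in range(7):
            assert avg.r2[v] == pytest.approx(
                sum(c.r2[v] for c in clips) / 5, abs=1e-12)

    def test_mismatched_vertex_sets_rejected(self):
        with pytest.raises(ValueError):
            clip_average([EncodingResult(np.zeros(3), (0,), 10),
                          EncodingResult(np.zeros(4), (0,), 10)])


class TestRoiTopK:
    def test_k_equals_n_returns_all(self):
        assert set(roi_topk(np.arange(5.0), k=5)) == set(range(5))

    def test_strictly_decreasing_map_gives_first_k(self):
        z = np.arange(10.0)[::-1]
        np.testing.assert_array_equal(roi_topk(z, k=3), [0, 1, 2])

    def test_matches_full_sort_oracle(self, rng):
        z = rng.normal(size=300)
        roi = roi_topk(z, k=50)
        thresh = np.sort(z)[::-1][49]
        assert set(roi) == set(np.flatnonzero(z >= thresh))

    def test_boundary_ties_broken_by_lowest_index(self):
        z = np.array([1.0, 2.0, 2.0, 2.0, 0.0])
        np.testing.assert_array_equal(roi_topk(z, k=2), [1, 2])

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            roi_topk(np.zeros(3), k=4)


class TestRegressorCountMatch:
    def _report(self, sig_ratio_pairs, seed):
        spec = PlantedSelectivitySpec(tuple(ch for ch, _ in sig_ratio_pairs), 0,
                                      5.0, 0.1)
        from netphys.selectivity import test_channels

        ds = gen_activation_dataset(5, 30, 16, (2, 2), spec, seed=seed)
        return test_channels(ds, "cat000")

    def test_counts_2_vs_4_keeps_top_2(self):
        a = self._report([(1, None), (2, None)], seed=10)
        b = self._report([(3, None), (4, None), (5, None), (6, None)], seed=11)
        assert a.n_significant == 2 and b.n_significant == 4
        ch_a, ch_b = regressor_count_match(a, b)
        assert len(ch_a) == len(ch_b) == 2
        ranked = b.frame[b.frame["significant"]].sort_values(
            "selective_ratio", ascending=False).index[:2]
        assert list(ch_b) == list(ranked)

    def test_equal_counts_identity(self):
        a = self._report([(1, None), (2, None)], seed=12)
        ch_a, ch_b = regressor_count_match(a, a)
        np.testing.assert_array_equal(ch_a, ch_b)
        assert set(ch_a) == {1, 2}

    def test_zero_significant_rejected(self, null_dataset):
        from netphys.selectivity import test_channels

        null_rep = test_channels(null_dataset, "cat000")
        a = self._report([(1, None)], seed=13)
        if null_rep.n_significant == 0:
            with pytest.raises(ValueError):
                regressor_count_match(a, null_rep)


def test_design_builder_stacks_standardized_columns(rng):
    series = np.abs(rng.normal(1, 1, size=(3, 1200)))
    X = build_design(series, HRFSpec(), 2.0)
    assert X.shape == (60, 3)
    np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-9)
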