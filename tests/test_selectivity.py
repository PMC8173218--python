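"""Selective-channel identification, Mann-Whitney U, sparseness."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from netphys.selectivity import (
    CategoryProfile,
    category_profile,
    find_candidates,
    lifetime_sparseness,
    mann_whitney_u,
    selective_ratio,
)
from netphys.selectivity import test_channels as run_test_channels
from netphys.synthetic import PlantedSelectivitySpec, gen_activation_dataset


class TestCategoryProfile:
    def test_single_image_per_category_is_identity(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        prof = category_profile(X, ["a", "b"])
        np.testing.assert_allclose(prof.means, X.T)

    def test_two_image_mean(self):
        X = np.array([[1.0], [3.0]])
        prof = category_profile(X, ["a", "a"])
        assert prof.means[0, 0] == 2.0

    def test_matches_pandas_groupby_oracle(self, rng):
        X = rng.random((50, 6))
        cats = rng.choice(list("abcd"), size=50)
        prof = category_profile(X, cats)
        oracle = pd.DataFrame(X).groupby(cats).mean().sort_index()
        np.testing.assert_allclose(prof.means, oracle.to_numpy().T, atol=1e-12)
        np.testing.assert_array_equal(prof.category_names, oracle.index.to_numpy())


class TestFindCandidates:
    def _profile(self, rows):
        return CategoryProfile(np.asarray(rows, float),
                               np.array([f"c{i}" for i in range(len(rows[0]))]))

    def test_strict_maximum_is_candidate(self):
        prof = self._profile([[2.0, 1.0, 0.5]])
        assert list(find_candidates(prof, "c0")) == [0]

    def test_exact_tie_disqualifies(self):
        prof = self._profile([[2.0, 2.0, 0.5]])
        assert list(find_candidates(prof, "c0")) == []

    def test_planted_channels_are_candidates(self, planted_dataset):
        from netphys.activations import channel_mean

        prof = category_profile(channel_mean(planted_dataset),
                                planted_dataset.categories)
        assert {3, 11} <= set(find_candidates(prof, "cat000"))


def _enumerate_two_sided_p(x, y):
    """Independent full-enumeration oracle for the exact U-test p-value."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, N = len(x), len(pooled)
    off = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - off
    us = [ranks[list(c)].sum() - off for c in itertools.combinations(range(N), n1)]
    us = np.array(us)
    total = math.comb(N, n1)
    p = 2.0 * min((us <= u_obs + 1e-9).sum(), (us >= u_obs - 1e-9).sum()) / total
    return min(1.0, p)


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/20 assignments

    def test_identical_multisets_midrank_convention(self):
        u, p = mann_whitney_u([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert u == pytest.approx(3 * 3 / 2)
        assert p == 1.0

    def test_exact_agrees_with_scipy_on_tiefree_samples(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 6, size=2)
            pooled = rng.permutation(20)[: n1 + n2].astype(float)
            x, y = pooled[:n1], pooled[n1:]
            u, p = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_agrees_with_enumeration_oracle_with_ties(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 5, size=2)
            x = rng.integers(0, 3, size=n1).astype(float)
            y = rng.integers(0, 3, size=n2).astype(float)
            u, p = mann_whitney_u(x, y)
            assert p == pytest.approx(_enumerate_two_sided_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=30)
        y = rng.normal(0.6, 1.0, size=30)
        _, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        off = 30 * 31 / 2.0
        u_obs = ranks[:30].sum() - off
        hits_le = hits_ge = 0
        n_resample = 20_000
        prng = np.random.default_rng(99)
        for _ in range(n_resample):
            perm = prng.permutation(60)
            u = ranks[perm[:30]].sum() - off
            hits_le += u <= u_obs + 1e-9
            hits_ge += u >= u_obs - 1e-9
        p_perm = min(1.0, 2.0 * min(hits_le, hits_ge) / n_resample)
        assert abs(p - p_perm) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestTestChannels:
    def test_planted_channels_recovered_exactly(self, planted_dataset):
        report = run_test_channels(planted_dataset, "cat000", alpha=0.05)
        assert set(report.significant_channels) == {3, 11}
        # invariant: significant implies candidate
        sig = report.frame[report.frame["significant"]]
        assert sig["is_candidate"].all()

    def test_bonferroni_with_single_channel(self):
        spec = PlantedSelectivitySpec((0,), 0, 3.0, 0.2)
        ds = gen_activation_dataset(3, 20, 1, (2, 2), spec, seed=1)
        report = run_test_channels(ds, "cat000")
        row = report.frame.loc[0]
        assert row["p_corrected"] == pytest.approx(row["p_raw"])

    def test_corrected_p_is_capped_product(self, planted_dataset):
        report = run_test_channels(planted_dataset, "cat000")
        cand = report.frame[report.frame["is_candidate"]]
        np.testing.assert_allclose(
            cand["p_corrected"], np.minimum(1.0, cand["p_raw"] * report.n_tests)
        )

    def test_label_shuffle_destroys_planted_significance(self, planted_dataset, rng):
        from netphys.activations import ActivationDataset

        shuffled = ActivationDataset(
            planted_dataset.activations,
            rng.permutation(planted_dataset.categories),
            planted_dataset.layer_name,
        )
        report = run_test_channels(shuffled, "cat000")
        assert report.n_significant == 0

    def test_missing_target_rejected(self, planted_dataset):
        with pytest.raises(ValueError):
            run_test_channels(planted_dataset, "nope")


class TestSelectiveRatio:
    def _profile(self, row):
        return CategoryProfile(np.asarray([row], float),
                               np.array([f"c{i}" for i in range(len(row))]))

    def test_direct_division(self):
        assert selective_ratio(self._profile([2.0, 1.0]), 0, "c0") == 2.0

    def test_tie_gives_unity(self):
        assert selective_ratio(self._profile([1.5, 1.5]), 0, "c0") == 1.0

    def test_five_category_sort_oracle(self):
        row = [3.0, 1.5, 1.0, 0.5, 0.2]
        ratio = selective_ratio(self._profile(row), 0, "c0")
        runner = sorted(row[1:], reverse=True)[0]
        assert ratio == pytest.approx(row[0] / runner) == 2.0

    def test_ratio_above_one_iff_candidate(self, rng):
        means = rng.random((20, 5)) + 0.01
        prof = CategoryProfile(means, np.array([f"c{i}" for i in range(5)]))
        cands = set(find_candidates(prof, "c0").tolist())
        for ch in range(20):
            r = selective_ratio(prof, ch, "c0")
            assert (r > 1.0) == (ch in cands)

    def test_zero_runner_up_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(selective_ratio(self._profile([1.0, 0.0]), 0, "c0"))


class TestLifetimeSparseness:
    def test_one_hot_collapses_to_one_over_n(self):
        row = np.zeros(205)
        row[0] = 1.0
        assert lifetime_sparseness(row) == pytest.approx(1 / 205)

    def test_worked_three_category_example(self):
        # raw (2, 1, 0) -> normalized (1, 0.5, 0) -> S = 0.6
        assert lifetime_sparseness([2.0, 1.0, 0.0]) == pytest.approx(0.6)

    def test_term_by_term_summation_oracle(self, rng):
        for _ in range(20):
            row = rng.random(rng.integers(2, 30))
            S = lifetime_sparseness(row)
            r = (row - row.min()) / (row.max() - row.min())
            n = len(r)
            num = sum(float(v) / n for v in r) ** 2
            den = sum(float(v) ** 2 / n for v in r)
            assert S == pytest.approx(num / den, abs=1e-12)

    def test_constant_profile_maps_to_one_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert lifetime_sparseness([2.0, 2.0, 2.0]) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 100.0), min_size=2, max_size=20),
           st.floats(0.1, 10.0))
    def test_in_unit_interval_and_scale_invariant(self, row, scale):
        row = np.asarray(row)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = lifetime_sparseness(row)
            s2 = lifetime_sparseness(row * scale)
        assert 0.0 < s1 <= 1.0 + 1e-12
        assert s1 == pytest.approx(s2, rel=1e-9)
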